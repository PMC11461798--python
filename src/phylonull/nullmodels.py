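"""Phylogenetic null models: MNTD, NTI, betaMNTD, betaNTI.

The null scheme shuffles taxon labels uniformly across *all* tips of the
metacommunity tree (the regional pool), recomputing the statistic on each
randomised labelling.  Standardised deviates follow the field's sign
conventions:

* ``NTI  = (null_mean - observed) / null_sd`` — positive NTI means the
  community is more phylogenetically clustered than expected by chance;
  NTI > 2 is read as significant clustering, NTI < -2 as overdispersion.
* ``bNTI = (observed - null_mean) / null_sd`` — bNTI > 2 is read as
  heterogeneous selection, bNTI < -2 as homogeneous selection, values in
  between as stochastic assembly.

Classification uses strict inequalities (|z| exactly equal to the
threshold is called stochastic).  A degenerate null (zero spread, e.g. a
sample containing the entire metacommunity) reports z = 0 with a flag
rather than an infinity.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from itertools import combinations
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .datamodel import CommunityDataset, PhyloTree

#: relative tolerance below which a null standard deviation is treated as 0
_DEGENERATE_RTOL = 1e-12

#: cap on floats held by one chunk of null submatrices (memory control)
_CHUNK_BUDGET = 20_000_000


class NullModelError(ValueError):
    pass


@dataclass(frozen=True)
class NullModelResult:
    """Observed statistic against its tip-shuffle null distribution."""

    metric: Literal["NTI", "bNTI"]
    observed: float
    null_mean: float
    null_sd: float
    z: float
    n_null: int
    degenerate: bool
    seed: int


@dataclass(frozen=True)
class AssemblyCall:
    metric: Literal["NTI", "bNTI"]
    call: str
    threshold: float = 2.0


def classify(result: NullModelResult, threshold: float = 2.0) -> AssemblyCall:
    """Map a standardised deviate to an assembly-process call.

    NTI: z > t -> clustered, z < -t -> dispersed, else stochastic.
    bNTI: z > t -> heterogeneous_selection, z < -t -> homogeneous_selection,
    else stochastic.  Degenerate nulls are always stochastic.
    """
    z = 0.0 if result.degenerate else result.z
    if result.metric == "NTI":
        if z > threshold:
            call = "clustered"
        elif z < -threshold:
            call = "dispersed"
        else:
            call = "stochastic"
    else:
        if z > threshold:
            call = "heterogeneous_selection"
        elif z < -threshold:
            call = "homogeneous_selection"
        else:
            call = "stochastic"
    return AssemblyCall(result.metric, call, threshold)


def subseed(master_seed: int, *parts: str) -> int:
    """Stable sub-seed derived from a master seed and string identifiers.

    Uses SHA-256 so results do not depend on interpreter hash randomisation
    or on the order units are evaluated in.
    """
    digest = hashlib.sha256(
        (":".join([str(int(master_seed)), *parts])).encode()
    ).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


# ---------------------------------------------------------------------------
# Observed statistics
# ---------------------------------------------------------------------------

def cophenetic_distances(tree: PhyloTree) -> pd.DataFrame:
    """Tip-pair path-length distance matrix (delegates to the tree)."""
    return tree.cophenetic()


def _weights(abund: np.ndarray, weighted: bool) -> np.ndarray:
    if weighted:
        total = abund.sum()
        return abund / total
    return np.full(abund.shape, 1.0 / len(abund))


def mntd(
    abundances: pd.Series | dict,
    dist: pd.DataFrame,
    weighted: bool = False,
) -> float:
    """Mean nearest taxon distance of one community.

    For each present taxon, take the distance to its closest *other*
    present taxon; average (abundance-weighted if ``weighted``).  Undefined
    for communities of fewer than two taxa.
    """
    ab = pd.Series(abundances).astype(float)
    ab = ab[ab > 0]
    if len(ab) < 2:
        raise NullModelError("MNTD undefined for communities with < 2 taxa")
    missing = set(ab.index) - set(dist.index)
    if missing:
        raise NullModelError(f"taxa missing from distance matrix: {sorted(missing)[:5]}")
    sub = dist.loc[ab.index, ab.index].to_numpy(copy=True)
    np.fill_diagonal(sub, np.inf)
    mins = sub.min(axis=1)
    return float(mins @ _weights(ab.to_numpy(), weighted))


def bmntd(
    abund_a: pd.Series | dict,
    abund_b: pd.Series | dict,
    dist: pd.DataFrame,
    weighted: bool = True,
) -> float:
    """Between-community mean nearest taxon distance (betaMNTD).

    Mean over taxa of A of the distance to the closest taxon present in B,
    averaged symmetrically with the B->A direction.  A taxon present in
    both communities has nearest-neighbour distance 0.
    """
    a = pd.Series(abund_a).astype(float)
    b = pd.Series(abund_b).astype(float)
    a = a[a > 0]
    b = b[b > 0]
    if len(a) == 0 or len(b) == 0:
        raise NullModelError("betaMNTD undefined for empty communities")
    cross = dist.loc[a.index, b.index].to_numpy()
    d_ab = cross.min(axis=1) @ _weights(a.to_numpy(), weighted)
    d_ba = cross.min(axis=0) @ _weights(b.to_numpy(), weighted)
    return float(0.5 * (d_ab + d_ba))


# ---------------------------------------------------------------------------
# Null machinery
# ---------------------------------------------------------------------------

def _null_subsets(rng: np.random.Generator, n_null: int, n_tips: int, idx: np.ndarray) -> np.ndarray:
    """Null tip positions for one index set under full-label shuffles.

    Row r holds perm_r[idx] where perm_r is a uniform random permutation of
    all tip positions; abundances stay attached to their taxon while the
    taxon lands on a random tip.
    """
    perms = np.argsort(rng.random((n_null, n_tips)), axis=1)
    return perms[:, idx]


def _null_mntd_batch(
    D: np.ndarray, positions: np.ndarray, w: np.ndarray
) -> np.ndarray:
    """MNTD for each row of null positions, chunked to bound memory."""
    n_null, k = positions.shape
    out = np.empty(n_null)
    chunk = max(1, int(_CHUNK_BUDGET // (k * k)))
    diag = np.arange(k)
    for start in range(0, n_null, chunk):
        pos = positions[start : start + chunk]
        sub = D[pos[:, :, None], pos[:, None, :]]
        sub[:, diag, diag] = np.inf
        out[start : start + chunk] = sub.min(axis=2) @ w
    return out


def _null_bmntd_batch(
    D: np.ndarray,
    pos_a: np.ndarray,
    pos_b: np.ndarray,
    w_a: np.ndarray,
    w_b: np.ndarray,
) -> np.ndarray:
    n_null, ka = pos_a.shape
    kb = pos_b.shape[1]
    out = np.empty(n_null)
    chunk = max(1, int(_CHUNK_BUDGET // (ka * kb)))
    for start in range(0, n_null, chunk):
        cross = D[pos_a[start : start + chunk, :, None], pos_b[start : start + chunk, None, :]]
        d_ab = cross.min(axis=2) @ w_a
        d_ba = cross.min(axis=1) @ w_b
        out[start : start + chunk] = 0.5 * (d_ab + d_ba)
    return out


def _standardize(observed: float, nulls: np.ndarray, sign: int) -> tuple[float, float, float, bool]:
    null_mean = float(nulls.mean())
    null_sd = float(nulls.std(ddof=0))
    degenerate = null_sd <= _DEGENERATE_RTOL * max(1.0, abs(null_mean))
    if degenerate:
        return null_mean, null_sd, 0.0, True
    z = sign * (observed - null_mean) / null_sd
    return null_mean, null_sd, float(z), False


# ---------------------------------------------------------------------------
# NTI / bNTI
# ---------------------------------------------------------------------------

def nti(
    sample: pd.Series | dict,
    dataset: CommunityDataset,
    n_null: int = 1000,
    weighted: bool = False,
    seed: int = 0,
    threshold: float = 2.0,
) -> tuple[NullModelResult, AssemblyCall]:
    """Nearest taxon index of one community against the metacommunity.

    The metacommunity is every tip of the dataset's tree.  ``weighted``
    selects the abundance-weighted MNTD; the default is presence/absence.
    The deviate is exactly invariant under uniform rescaling of all branch
    lengths (observed and null scale together).
    """
    dist = dataset.cophenetic()
    # z is computed on a max-normalized copy of the distance matrix: the
    # deviate is mathematically scale-free, and normalizing first makes it
    # numerically scale-free too (uniform branch rescaling cannot move z by
    # an ulp).  Reported distances stay on the original scale.
    D = dist.to_numpy(dtype=float)
    scale = D.max() or 1.0
    Dn = D / scale
    ab = pd.Series(sample).reindex(dist.index).fillna(0.0)
    observed = mntd(ab, dist, weighted=weighted)
    idx = np.flatnonzero(ab.to_numpy() > 0)
    w = _weights(ab.to_numpy()[idx], weighted)
    sub = Dn[np.ix_(idx, idx)].copy()
    np.fill_diagonal(sub, np.inf)
    observed_n = float(sub.min(axis=1) @ w)
    rng = np.random.default_rng(seed)
    positions = _null_subsets(rng, n_null, len(dist), idx)
    nulls = _null_mntd_batch(Dn, positions, w)
    null_mean, null_sd, z, degenerate = _standardize(observed_n, nulls, sign=-1)
    result = NullModelResult(
        "NTI", observed, null_mean * scale, null_sd * scale, z, n_null, degenerate, seed
    )
    return result, classify(result, threshold)


def bnti(
    sample_a: pd.Series | dict,
    sample_b: pd.Series | dict,
    dataset: CommunityDataset,
    n_null: int = 1000,
    weighted: bool = True,
    seed: int = 0,
    threshold: float = 2.0,
) -> tuple[NullModelResult, AssemblyCall]:
    """Beta nearest taxon index between two communities.

    Each null replicate applies one shared permutation of all metacommunity
    tip labels to both communities before recomputing betaMNTD, so taxa
    shared between the samples remain shared under the null.
    """
    dist = dataset.cophenetic()
    D = dist.to_numpy(dtype=float)
    scale = D.max() or 1.0  # see nti(): normalization keeps z scale-free
    Dn = D / scale
    a = pd.Series(sample_a).reindex(dist.index).fillna(0.0)
    b = pd.Series(sample_b).reindex(dist.index).fillna(0.0)
    observed = bmntd(a, b, dist, weighted=weighted)
    idx_a = np.flatnonzero(a.to_numpy() > 0)
    idx_b = np.flatnonzero(b.to_numpy() > 0)
    w_a = _weights(a.to_numpy()[idx_a], weighted)
    w_b = _weights(b.to_numpy()[idx_b], weighted)
    cross = Dn[np.ix_(idx_a, idx_b)]
    observed_n = float(0.5 * (cross.min(axis=1) @ w_a + cross.min(axis=0) @ w_b))
    rng = np.random.default_rng(seed)
    n_tips = len(dist)
    perms = np.argsort(rng.random((n_null, n_tips)), axis=1)
    nulls = _null_bmntd_batch(Dn, perms[:, idx_a], perms[:, idx_b], w_a, w_b)
    null_mean, null_sd, z, degenerate = _standardize(observed_n, nulls, sign=+1)
    result = NullModelResult(
        "bNTI", observed, null_mean * scale, null_sd * scale, z, n_null, degenerate, seed
    )
    return result, classify(result, threshold)


# ---------------------------------------------------------------------------
# Dataset-level drivers
# ---------------------------------------------------------------------------

def nti_table(
    dataset: CommunityDataset,
    n_null: int = 1000,
    weighted: bool = False,
    seed: int = 0,
    threshold: float = 2.0,
) -> pd.DataFrame:
    """NTI for every sample; per-sample sub-seeds make the result
    independent of evaluation order."""
    rows = []
    for sid in dataset.sample_ids:
        res, call = nti(
            dataset.table.sample_vector(sid),
            dataset,
            n_null=n_null,
            weighted=weighted,
            seed=subseed(seed, "nti", sid),
            threshold=threshold,
        )
        rows.append(
            {
                "sample": sid,
                "observed": res.observed,
                "null_mean": res.null_mean,
                "null_sd": res.null_sd,
                "z": res.z,
                "degenerate": res.degenerate,
                "call": call.call,
            }
        )
    return pd.DataFrame(rows).set_index("sample")


def bnti_group(
    dataset: CommunityDataset,
    grouping: Sequence[str],
    n_null: int = 1000,
    weighted: bool = True,
    seed: int = 0,
    threshold: float = 2.0,
) -> pd.DataFrame:
    """bNTI for all unordered within-group sample pairs.

    Groups are the joint levels of the given metadata variables; pairs that
    straddle groups are never compared.  Singleton groups contribute no
    pairs.  Pair sub-seeds hash the sorted pair of sample ids, so the
    output is invariant to sample ordering.
    """
    rows = []
    for level, members in sorted(dataset.groups(grouping).items()):
        for sid_a, sid_b in combinations(sorted(members), 2):
            res, call = bnti(
                dataset.table.sample_vector(sid_a),
                dataset.table.sample_vector(sid_b),
                dataset,
                n_null=n_null,
                weighted=weighted,
                seed=subseed(seed, "bnti", sid_a, sid_b),
                threshold=threshold,
            )
            rows.append(
                {
                    "sample_a": sid_a,
                    "sample_b": sid_b,
                    "group": "/".join(level),
                    "observed": res.observed,
                    "null_mean": res.null_mean,
                    "null_sd": res.null_sd,
                    "z": res.z,
                    "degenerate": res.degenerate,
                    "call": call.call,
                }
            )
    columns = [
        "sample_a", "sample_b", "group", "observed",
        "null_mean", "null_sd", "z", "degenerate", "call",
    ]
    return pd.DataFrame(rows, columns=columns)
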