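"""Phylogenetic signal of environmental preference (niche conservatism).

Null-model assembly metrics are only interpretable if closely related taxa
actually favour similar environments.  This module tests that assumption:
each taxon's environmental optimum is the abundance-weighted mean of
one-hot-encoded categorical sample variables, and a multivariate Mantel
correlogram relates between-taxon optimum distances to phylogenetic
distances.  Signal is present when taxa separated by *short* phylogenetic
distances have significantly similar optima.

Phylogenetic distances are divided by their maximum before binning, so
distance classes are comparable across trees; optimum distances are
already bounded by the one-hot encoding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .datamodel import CommunityDataset, CommunityTable, DataModelError, SampleMetadata


@dataclass(frozen=True)
class CorrelogramResult:
    class_index: int
    class_midpoint: float
    mantel_r: float
    n_pairs_in_class: int
    p_raw: float
    p_holm: float
    n_permutations: int
    seed: int


def encode_metadata(metadata: SampleMetadata, variables: Sequence[str]) -> pd.DataFrame:
    """One-hot indicator matrix (samples x levels) for categorical variables.

    Each variable contributes one binary column per level; within a
    variable's block every sample has exactly one 1.  A variable constant
    across samples carries no contrast and is a hard error.
    """
    blocks = []
    for var in variables:
        levels = metadata.levels(var)  # raises on unknown variable
        if len(levels) < 2:
            raise DataModelError(f"metadata variable {var!r} is constant")
        col = metadata.data[var]
        block = pd.DataFrame(
            {f"{var}={lvl}": (col == lvl).astype(float) for lvl in levels},
            index=metadata.data.index,
        )
        blocks.append(block)
    return pd.concat(blocks, axis=1)


def taxon_optima(table: CommunityTable, encoded: pd.DataFrame) -> pd.DataFrame:
    """Abundance-weighted mean environment per taxon.

    optimum(taxon, dim) = sum_s rel(taxon, s) * encoded(s, dim)
                          / sum_s rel(taxon, s)
    over per-sample relative abundances.  Taxa never observed are excluded.
    """
    missing = set(table.sample_ids) - set(encoded.index)
    if missing:
        raise DataModelError(f"samples without encoded metadata: {sorted(missing)}")
    rel = table.relative_abundance()
    enc = encoded.loc[list(table.sample_ids)]
    weights = rel.T  # taxa x samples
    totals = weights.sum(axis=1)
    observed = totals > 0
    optima = (weights.loc[observed] @ enc).div(totals[observed], axis=0)
    return optima


def _holm(p_raw: np.ndarray) -> np.ndarray:
    """Holm step-down adjusted p-values."""
    m = len(p_raw)
    order = np.argsort(p_raw)
    adjusted = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p_raw[i])
        adjusted[i] = min(1.0, running)
    return adjusted


def sturges_classes(n_pairs: int) -> int:
    """Sturges' rule on the number of distance pairs."""
    return int(np.ceil(np.log2(n_pairs) + 1))


def mantel_correlogram(
    optima_dist: pd.DataFrame,
    phylo_dist: pd.DataFrame,
    n_classes: int | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    tail: str = "greater",
) -> list[CorrelogramResult]:
    """Mantel correlogram of optimum distance against phylogenetic distance.

    Phylogenetic distances are binned into ``n_classes`` equal-width
    classes (Sturges' rule on the pair count by default).  For each class
    the Mantel statistic is the Pearson correlation between the optimum
    distances and the class-membership indicator, sign-flipped so that
    positive r means pairs *inside* the class are more similar than
    average.  p-values come from permuting taxon labels of the optimum
    matrix (``p = (1 + #{r_perm >= r_obs}) / (n_perm + 1)`` for the
    positive tail) and are Holm-corrected progressively: the corrected
    p for class k applies Holm to the first k tested classes.
    """
    taxa = list(phylo_dist.index)
    if list(optima_dist.index) != taxa:
        optima_dist = optima_dist.loc[taxa, taxa]
    t = len(taxa)
    if t < 4:
        raise DataModelError("Mantel correlogram needs at least 4 taxa")
    iu = np.triu_indices(t, 1)
    x_sq = optima_dist.to_numpy(dtype=float)
    d_phy = phylo_dist.to_numpy(dtype=float)[iu]
    n_pairs = len(d_phy)
    k_classes = n_classes or sturges_classes(n_pairs)
    edges = np.linspace(d_phy.min(), d_phy.max(), k_classes + 1)
    # right-inclusive last bin so the maximum distance belongs to a class
    which = np.clip(np.digitize(d_phy, edges[1:-1], right=False), 0, k_classes - 1)
    midpoints = 0.5 * (edges[:-1] + edges[1:])

    x_obs = x_sq[iu]
    mu_x, sd_x = x_obs.mean(), x_obs.std()
    if sd_x == 0:
        raise DataModelError("optimum distances are constant; no contrast to test")

    members = [which == k for k in range(k_classes)]
    usable = [k for k in range(k_classes) if members[k].sum() >= 2]
    for k in range(k_classes):
        if k not in usable and members[k].sum() > 0:
            warnings.warn(f"distance class {k} has <2 pairs; skipped", stacklevel=2)
    mask = np.stack([members[k] for k in usable]).astype(float)
    counts = mask.sum(axis=1)
    mu_m = counts / n_pairs
    sd_m = np.sqrt(mu_m * (1 - mu_m))

    def class_r(x_vec: np.ndarray) -> np.ndarray:
        s = mask @ x_vec
        # -corr(x, membership): positive r = within-class pairs more similar
        return -(s / n_pairs - mu_x * mu_m) / (sd_x * sd_m)

    r_obs = class_r(x_obs)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(usable))
    for _ in range(n_perm):
        p = rng.permutation(t)
        x_perm = x_sq[np.ix_(p, p)][iu]
        r_perm = class_r(x_perm)
        if tail == "greater":
            exceed += r_perm >= r_obs
        else:
            exceed += np.abs(r_perm) >= np.abs(r_obs)
    p_raw = (1.0 + exceed) / (n_perm + 1.0)

    # progressive Holm: class k corrected within the first k tested classes
    p_holm = np.array([_holm(p_raw[: i + 1])[i] for i in range(len(usable))])
    p_holm = np.maximum.accumulate(p_holm)

    return [
        CorrelogramResult(
            class_index=k,
            class_midpoint=float(midpoints[k]),
            mantel_r=float(r_obs[j]),
            n_pairs_in_class=int(counts[j]),
            p_raw=float(p_raw[j]),
            p_holm=float(p_holm[j]),
            n_permutations=n_perm,
            seed=seed,
        )
        for j, k in enumerate(usable)
    ]


def correlogram_frame(results: list[CorrelogramResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


def signal_check(
    dataset: CommunityDataset,
    variables: Sequence[str],
    n_classes: int | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[bool, list[CorrelogramResult]]:
    """Is there phylogenetic signal in environmental preference?

    True iff at least one class in the shortest third of tested distance
    classes is significant after Holm correction with positive Mantel r.
    """
    if len(dataset.sample_ids) < 2:
        raise DataModelError("phylogenetic signal needs at least 2 samples")
    encoded = encode_metadata(dataset.metadata.subset(dataset.sample_ids), variables)
    optima = taxon_optima(dataset.table, encoded)
    taxa = list(optima.index)
    opt_dist = pd.DataFrame(
        squareform(pdist(optima.to_numpy())), index=taxa, columns=taxa
    )
    phylo = dataset.cophenetic().loc[taxa, taxa]
    phylo = phylo / phylo.to_numpy().max()
    results = mantel_correlogram(
        opt_dist, phylo, n_classes=n_classes, n_perm=n_perm, seed=seed
    )
    n_short = int(np.ceil(len(results) / 3))
    detected = any(
        r.p_holm < alpha and r.mantel_r > 0 for r in results[:n_short]
    )
    return detected, results
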