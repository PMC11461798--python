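"""Per-sample similarity between a full and a filtered dataset.

Removing suspect taxa should leave a sample's community essentially
unchanged if those taxa were rare — and abundance-based similarities
(Bray-Curtis, weighted UniFrac) indeed stay near 1.  Presence-based,
tree-aware similarity (unweighted UniFrac) can collapse when the removed
tips subtend long branches, which is exactly the distortion this module
quantifies.  All similarities live in [0, 1] and equal 1 on identical
inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio.diversity.beta import unweighted_unifrac, weighted_unifrac

from .datamodel import CommunityDataset, DataModelError, PhyloTree

METRICS = ("bray_curtis", "sorensen", "weighted_unifrac", "unweighted_unifrac")


@dataclass(frozen=True)
class SimilarityComparison:
    sample_id: str
    metric: str
    similarity: float
    removed_abundance_fraction: float


def _check_pair(x: np.ndarray, y: np.ndarray) -> None:
    if x.shape != y.shape:
        raise DataModelError("similarity inputs must share the taxon space")
    if (x < 0).any() or (y < 0).any():
        raise DataModelError("negative abundances")
    if x.sum() == 0 and y.sum() == 0:
        raise DataModelError("both vectors are all-zero")


def bray_curtis_similarity(x, y) -> float:
    """1 - sum|x_i - y_i| / sum(x_i + y_i)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _check_pair(x, y)
    return float(1.0 - np.abs(x - y).sum() / (x + y).sum())


def sorensen_similarity(x, y) -> float:
    """2 * |shared taxa| / (|taxa in x| + |taxa in y|) on presence sets."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _check_pair(x, y)
    px, py = x > 0, y > 0
    denom = px.sum() + py.sum()
    if denom == 0:
        raise DataModelError("both vectors are all-zero")
    return float(2.0 * (px & py).sum() / denom)


def unifrac_similarity(x, y, taxa, tree: PhyloTree, weighted: bool) -> float:
    """1 - UniFrac distance between two communities on one tree.

    Unweighted UniFrac compares the branch length unique to either
    presence set against the branch length leading to their union.
    Weighted UniFrac moves relative abundance along branches and is used
    in its normalised form so the distance — hence the similarity — stays
    in [0, 1].
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _check_pair(x, y)
    if x.sum() == 0 or y.sum() == 0:
        raise DataModelError("UniFrac undefined for an empty community")
    taxa = list(taxa)
    sk = tree.skbio_tree
    if weighted:
        # compositional: removal changes library size, so compare relative
        # abundances.  skbio truncates count vectors to integers, so scale
        # compositions to parts-per-1e8 counts (well below the 1e-6
        # agreement tolerance used against reference implementations).
        xi = np.round(x / x.sum() * 1e8).astype(np.int64)
        yi = np.round(y / y.sum() * 1e8).astype(np.int64)
        d = weighted_unifrac(xi, yi, taxa=taxa, tree=sk, normalized=True)
    else:
        # presence sets only; binarize so fractional abundances are not
        # truncated away by skbio's integer count handling
        d = unweighted_unifrac((x > 0).astype(np.int64), (y > 0).astype(np.int64), taxa=taxa, tree=sk)
    return float(np.clip(1.0 - d, 0.0, 1.0))


def compare_datasets(
    full: CommunityDataset, filtered: CommunityDataset
) -> pd.DataFrame:
    """Similarity of each shared sample between the full and filtered data.

    Vectors are compared on the union taxon space (taxa absent from the
    filtered table count as zeros), and both UniFrac variants run on the
    *full* tree, so that removed taxa contribute their unique branches.
    Returns one row per sample x metric with the removed abundance
    fraction alongside.
    """
    shared = [s for s in full.sample_ids if s in set(filtered.sample_ids)]
    if not shared:
        raise DataModelError("no shared samples between datasets")
    extra_taxa = set(filtered.taxon_ids) - set(full.taxon_ids)
    if extra_taxa:
        raise DataModelError(
            f"filtered dataset has taxa absent from the full one: {sorted(extra_taxa)[:5]}"
        )
    taxa = list(full.taxon_ids)
    full_mat = full.table.data
    filt_mat = filtered.table.data.reindex(index=shared, columns=taxa, fill_value=0.0)
    rows = []
    for sid in shared:
        x = full_mat.loc[sid].to_numpy(dtype=float)
        y = filt_mat.loc[sid].to_numpy(dtype=float)
        removed = float(
            x[~np.isin(taxa, list(filtered.taxon_ids))].sum() / x.sum()
        )
        values = {
            "bray_curtis": bray_curtis_similarity(x, y),
            "sorensen": sorensen_similarity(x, y),
            "weighted_unifrac": unifrac_similarity(x, y, taxa, full.tree, weighted=True),
            "unweighted_unifrac": unifrac_similarity(x, y, taxa, full.tree, weighted=False),
        }
        for metric, sim in values.items():
            rows.append(
                {
                    "sample": sid,
                    "metric": metric,
                    "similarity": sim,
                    "removed_abundance_fraction": removed,
                }
            )
    return pd.DataFrame(rows, columns=["sample", "metric", "similarity", "removed_abundance_fraction"])
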