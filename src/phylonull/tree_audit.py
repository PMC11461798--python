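"""Detection and removal of suspected misclassified long-branch tips.

Amplicon datasets occasionally carry non-target sequences (host, fungal,
archaeal rRNA) that the classifier labels as bacteria.  On a phylogenetic
tree inferred from the target gene these show up as tips with extreme
terminal branch lengths, and they distort every tree-based statistic far
beyond their abundance.  This module replaces manual visual screening with
a robust standardised score: the deviation of each tip's branch metric
from the median, in units of the normalised median absolute deviation
(MAD).  Tips whose score exceeds a threshold (default 5) are flagged.

Scoring is one-sided (only unusually *long* branches are suspect) and
never consults abundances: the outliers this targets are typically rare
(~0.1% mean relative abundance) yet phylogenetically blatant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd

from .datamodel import CommunityDataset, DataModelError, PhyloTree

Method = Literal["terminal_mad", "root_to_tip_mad"]

#: normal-consistency constant for the median absolute deviation
MAD_SCALE = 1.4826
#: normal-consistency constant for the interquartile range (fallback scale)
IQR_SCALE = 1.349


@dataclass
class OutlierReport:
    """Per-tip branch metrics, robust scores and flags."""

    records: pd.DataFrame  # columns: terminal_length, root_to_tip, score, flagged
    method: Method
    threshold: float

    @property
    def flagged(self) -> tuple[str, ...]:
        return tuple(self.records.index[self.records["flagged"]])

    def to_tsv(self, path) -> None:
        self.records.to_csv(path, sep="\t", index_label="tip")


def branch_metrics(tree: PhyloTree) -> pd.DataFrame:
    """Terminal (pendant) branch length and root-to-tip distance per tip."""
    term = tree.terminal_branch_lengths()
    r2t = tree.root_to_tip_distances()
    return pd.DataFrame({"terminal_length": term, "root_to_tip": r2t}).loc[
        list(tree.tip_labels)
    ]


def _robust_scores(values: np.ndarray) -> np.ndarray:
    """Signed robust deviates (value - median) / scale.

    Scale is the normalised MAD; if the MAD is zero (more than half the
    values identical) the normalised IQR is used instead; if that is also
    zero the data carry no usable spread and all scores are 0, so nothing
    is flagged.
    """
    med = np.median(values)
    mad = np.median(np.abs(values - med))
    scale = MAD_SCALE * mad
    if scale == 0:
        q75, q25 = np.percentile(values, [75, 25])
        scale = (q75 - q25) / IQR_SCALE
    if scale == 0:
        return np.zeros_like(values, dtype=float)
    return (values - med) / scale


def score_outliers(
    metrics: pd.DataFrame,
    method: Method = "terminal_mad",
    threshold: float = 5.0,
) -> OutlierReport:
    """Standardise branch metrics and flag tips with score > threshold."""
    if len(metrics) < 4:
        raise DataModelError("outlier scoring needs at least 4 tips")
    column = {"terminal_mad": "terminal_length", "root_to_tip_mad": "root_to_tip"}.get(method)
    if column is None:
        raise ValueError(f"unknown method: {method!r}")
    values = metrics[column].to_numpy(dtype=float)
    scores = _robust_scores(values)
    records = metrics.copy()
    records["score"] = scores
    records["flagged"] = scores > threshold
    return OutlierReport(records, method, threshold)


def audit_tree(
    tree: PhyloTree,
    method: Method = "terminal_mad",
    threshold: float = 5.0,
    max_iter: int = 1,
) -> OutlierReport:
    """Score the tree's tips, optionally re-screening after removal.

    With ``max_iter > 1`` flagged tips are pruned and the remainder
    re-scored, which can unmask secondary outliers whose scores were
    diluted by more extreme ones; iteration stops when a round flags
    nothing.  The returned report covers all tips of the original tree,
    with the scores from the round in which each tip was last evaluated.
    """
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    current = tree
    all_flagged: list[str] = []
    records = score_outliers(branch_metrics(current), method, threshold).records.copy()
    for _ in range(max_iter):
        rep = score_outliers(branch_metrics(current), method, threshold)
        records.loc[rep.records.index, ["score", "flagged"]] = rep.records[
            ["score", "flagged"]
        ]
        newly = [t for t in rep.flagged if t not in all_flagged]
        if not newly:
            break
        all_flagged.extend(newly)
        if current.n_tips - len(newly) < 4:
            break
        current = current.prune_tips(newly)
    records.loc[all_flagged, "flagged"] = True
    return OutlierReport(records, method, threshold)


def remove_outliers(
    dataset: CommunityDataset, flagged: Iterable[str]
) -> tuple[CommunityDataset, pd.DataFrame]:
    """Prune flagged tips from the tree and drop them from the table.

    Samples are kept intact.  Returns the filtered dataset plus a
    per-sample summary of the relative abundance the removed taxa held
    (``removed_abundance_fraction``) and how many of them each sample
    contained (``n_removed_present``).
    """
    flagged = sorted(set(flagged))
    missing = set(flagged) - set(dataset.tree.tip_labels)
    if missing:
        raise DataModelError(f"flagged tips not in tree: {sorted(missing)}")
    rel = dataset.table.relative_abundance()
    in_table = [t for t in flagged if t in dataset.table.taxon_ids]
    summary = pd.DataFrame(
        {
            "removed_abundance_fraction": rel[in_table].sum(axis=1) if in_table else 0.0,
            "n_removed_present": (dataset.table.data[in_table] > 0).sum(axis=1)
            if in_table
            else 0,
        },
        index=rel.index,
    )
    if not flagged:
        return dataset, summary
    new_tree = dataset.tree.prune_tips(flagged)
    new_table = dataset.table.drop_taxa(in_table)
    filtered = CommunityDataset(new_table, new_tree, dataset.metadata)
    return filtered, summary


def export_suspects(
    flagged: Iterable[str], sequences: Mapping[str, str], path
) -> int:
    """Write the flagged tips' sequences to FASTA for external verification
    (e.g. a nucleotide BLAST search against non-bacterial databases).

    Returns the number of records written.  Raises if any flagged tip has
    no sequence; warns (and writes an empty file) when nothing is flagged.
    """
    flagged = sorted(set(flagged))
    missing = [t for t in flagged if t not in sequences]
    if missing:
        raise DataModelError(f"no sequence for flagged tips: {missing}")
    if not flagged:
        warnings.warn("no flagged tips; writing empty FASTA", stacklevel=2)
    with open(path, "w") as fh:
        for tip in flagged:
            fh.write(f">{tip}\n{sequences[tip]}\n")
    return len(flagged)
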