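"""Robustness protocol: how do tree defects and metacommunity choice move
NTI/betaNTI, and how often do assembly conclusions change?

Two perturbations are orchestrated end to end:

* **outlier removal** — audit the tree for long-branch tips, remove them,
  and re-estimate every statistic on the filtered dataset;
* **metacommunity subsetting** — drop sample types, shrink the regional
  pool (tree and table) to the taxa still observed, and re-estimate.

Before/after estimates share per-unit sub-seeds, so paired deltas reflect
the perturbation rather than Monte-Carlo noise.  Conclusion changes are
tabulated per sample type as a before x after cross-tabulation with
percentages to one decimal place.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import pandas as pd

from .datamodel import CommunityDataset, DataModelError
from .nullmodels import bnti_group, nti_table
from .similarity import compare_datasets
from .tree_audit import OutlierReport, audit_tree, remove_outliers

Predicate = Callable[[pd.Series], bool]


@dataclass
class ConclusionChangeTable:
    """Cross-tabulation of assembly calls before vs after a perturbation."""

    group: str
    cells: pd.DataFrame  # columns: call_before, call_after, n, pct_of_group
    pct_changed: float

    @classmethod
    def from_calls(cls, group: str, before: pd.Series, after: pd.Series) -> "ConclusionChangeTable":
        joined = pd.DataFrame({"call_before": before, "call_after": after}).dropna()
        total = len(joined)
        if total == 0:
            return cls(group, pd.DataFrame(columns=["call_before", "call_after", "n", "pct_of_group"]), 0.0)
        counts = (
            joined.value_counts(["call_before", "call_after"])
            .rename("n")
            .reset_index()
        )
        counts["pct_of_group"] = (100.0 * counts["n"] / total).round(1)
        changed = counts.loc[counts.call_before != counts.call_after, "n"].sum()
        return cls(group, counts, round(100.0 * changed / total, 1))

    @property
    def total(self) -> int:
        return int(self.cells["n"].sum()) if len(self.cells) else 0


def change_tables_by_group(
    before: pd.DataFrame,
    after: pd.DataFrame,
    groups: Mapping[str, Sequence[str]],
    unit_col: str | None = None,
) -> list[ConclusionChangeTable]:
    """One change table per group of unit ids (samples or pairs)."""
    b = before if unit_col is None else before.set_index(unit_col)
    a = after if unit_col is None else after.set_index(unit_col)
    out = []
    for name, units in groups.items():
        units = [u for u in units if u in b.index and u in a.index]
        out.append(
            ConclusionChangeTable.from_calls(
                name, b.loc[units, "call"], a.loc[units, "call"]
            )
        )
    return out


def delta_records(
    before: pd.DataFrame, after: pd.DataFrame, metric: str
) -> pd.DataFrame:
    """Paired z deltas (after - before) for units present in both runs."""
    shared = before.index.intersection(after.index)
    df = pd.DataFrame(
        {
            "metric": metric,
            "z_before": before.loc[shared, "z"],
            "z_after": after.loc[shared, "z"],
            "degenerate": before.loc[shared, "degenerate"]
            | after.loc[shared, "degenerate"],
        },
        index=shared,
    )
    df["delta"] = df["z_after"] - df["z_before"]
    return df


@dataclass
class OutlierImpactResult:
    report: OutlierReport
    removal_summary: pd.DataFrame
    similarity: pd.DataFrame
    nti_before: pd.DataFrame
    nti_after: pd.DataFrame
    nti_deltas: pd.DataFrame
    nti_changes: list[ConclusionChangeTable]
    bnti_before: pd.DataFrame | None = None
    bnti_after: pd.DataFrame | None = None
    bnti_deltas: pd.DataFrame | None = None
    bnti_changes: list[ConclusionChangeTable] = field(default_factory=list)
    filtered: CommunityDataset | None = None


def _type_groups(dataset: CommunityDataset, variable: str) -> dict[str, list[str]]:
    return {"/".join(k): v for k, v in dataset.groups([variable]).items()}


def outlier_impact(
    dataset: CommunityDataset,
    method: str = "terminal_mad",
    threshold: float = 5.0,
    max_iter: int = 1,
    n_null: int = 1000,
    weighted_nti: bool = False,
    weighted_bnti: bool = True,
    seed: int = 0,
    group_variable: str = "sample_type",
    bnti_grouping: Sequence[str] | None = ("sample_type",),
) -> OutlierImpactResult:
    """Full outlier-removal experiment on one dataset.

    Audits the tree, removes flagged tips, quantifies per-sample
    composition change (four similarity indices on the full tree), and
    re-estimates NTI (and betaNTI within groups, if ``bnti_grouping``)
    with identical per-unit seeds before and after.
    """
    report = audit_tree(dataset.tree, method=method, threshold=threshold, max_iter=max_iter)
    filtered, removal_summary = remove_outliers(dataset, report.flagged)
    groups = _type_groups(dataset, group_variable)

    nti_before = nti_table(dataset, n_null=n_null, weighted=weighted_nti, seed=seed)
    if report.flagged:
        similarity = compare_datasets(dataset, filtered)
        nti_after = nti_table(filtered, n_null=n_null, weighted=weighted_nti, seed=seed)
    else:
        similarity = compare_datasets(dataset, dataset)
        nti_after = nti_before.copy()

    result = OutlierImpactResult(
        report=report,
        removal_summary=removal_summary,
        similarity=similarity,
        nti_before=nti_before,
        nti_after=nti_after,
        nti_deltas=delta_records(nti_before, nti_after, "NTI"),
        nti_changes=change_tables_by_group(nti_before, nti_after, groups),
        filtered=filtered,
    )

    if bnti_grouping:
        b_before = bnti_group(dataset, bnti_grouping, n_null=n_null, weighted=weighted_bnti, seed=seed)
        b_after = (
            bnti_group(filtered, bnti_grouping, n_null=n_null, weighted=weighted_bnti, seed=seed)
            if report.flagged
            else b_before.copy()
        )
        for df in (b_before, b_after):
            df["pair"] = df["sample_a"] + "|" + df["sample_b"]
        bi = b_before.set_index("pair")
        ai = b_after.set_index("pair")
        pair_groups = {
            g: bi.index[bi["group"] == g].tolist() for g in bi["group"].unique()
        }
        result.bnti_before = b_before
        result.bnti_after = b_after
        result.bnti_deltas = delta_records(bi, ai, "bNTI")
        result.bnti_changes = change_tables_by_group(bi, ai, pair_groups)
    return result


# ---------------------------------------------------------------------------
# Metacommunity richness experiment
# ---------------------------------------------------------------------------

def metacommunity_subset(
    dataset: CommunityDataset, keep: Predicate | Mapping[str, Sequence[str]]
) -> CommunityDataset:
    """Restrict the dataset — and hence the null-model metacommunity — to
    the samples a predicate keeps.

    Taxa no longer observed in any remaining sample are dropped from the
    table *and pruned from the tree*: every taxon present in the subset is
    regarded as the whole regional pool for that analysis.
    """
    if callable(keep):
        pred = keep
    else:
        allowed = {k: set(v) for k, v in keep.items()}
        def pred(row: pd.Series) -> bool:
            return all(row[k] in v for k, v in allowed.items())
    md = dataset.metadata.data
    kept_samples = [s for s in dataset.sample_ids if pred(md.loc[s])]
    if len(kept_samples) < 2:
        raise DataModelError("metacommunity subset keeps fewer than 2 samples")
    sub_table = dataset.table.subset_samples(kept_samples)
    observed = [t for t in sub_table.taxon_ids if sub_table.data[t].sum() > 0]
    sub_table = sub_table.drop_taxa([t for t in sub_table.taxon_ids if t not in set(observed)])
    sub_tree = dataset.tree.keep_tips(observed)
    return CommunityDataset(sub_table, sub_tree, dataset.metadata.subset(kept_samples))


@dataclass
class RichnessImpactResult:
    subset_name: str
    dataset: CommunityDataset
    nti_deltas: pd.DataFrame
    nti_changes: list[ConclusionChangeTable]
    bnti_deltas: pd.DataFrame | None = None
    bnti_changes: list[ConclusionChangeTable] = field(default_factory=list)
    taxa_lost_fraction: float = 0.0


def richness_impact(
    dataset: CommunityDataset,
    subsets: Mapping[str, Predicate | Mapping[str, Sequence[str]]],
    n_null: int = 1000,
    weighted_nti: bool = False,
    weighted_bnti: bool = True,
    seed: int = 0,
    group_variable: str = "sample_type",
    bnti_grouping: Sequence[str] | None = ("sample_type",),
) -> list[RichnessImpactResult]:
    """Re-estimate NTI/betaNTI under reduced metacommunities.

    For each named subset predicate, samples outside the subset are
    dropped and the regional pool shrinks to the remaining observed taxa;
    statistics for the surviving (focal) samples are compared against
    their values under the full metacommunity, with shared per-unit seeds.
    """
    full_nti = nti_table(dataset, n_null=n_null, weighted=weighted_nti, seed=seed)
    full_bnti = None
    if bnti_grouping:
        full_bnti = bnti_group(dataset, bnti_grouping, n_null=n_null, weighted=weighted_bnti, seed=seed)
        full_bnti["pair"] = full_bnti["sample_a"] + "|" + full_bnti["sample_b"]
        full_bnti = full_bnti.set_index("pair")
    results = []
    n_taxa_full = len(dataset.taxon_ids)
    for name, keep in subsets.items():
        sub = metacommunity_subset(dataset, keep)
        lost = 1.0 - len(sub.taxon_ids) / n_taxa_full
        sub_nti = nti_table(sub, n_null=n_null, weighted=weighted_nti, seed=seed)
        groups = _type_groups(sub, group_variable)
        res = RichnessImpactResult(
            subset_name=name,
            dataset=sub,
            nti_deltas=delta_records(full_nti, sub_nti, "NTI"),
            nti_changes=change_tables_by_group(full_nti, sub_nti, groups),
            taxa_lost_fraction=lost,
        )
        if bnti_grouping:
            sub_bnti = bnti_group(sub, bnti_grouping, n_null=n_null, weighted=weighted_bnti, seed=seed)
            sub_bnti["pair"] = sub_bnti["sample_a"] + "|" + sub_bnti["sample_b"]
            sub_bnti = sub_bnti.set_index("pair")
            pair_groups = {
                g: sub_bnti.index[sub_bnti["group"] == g].tolist()
                for g in sub_bnti["group"].unique()
            }
            res.bnti_deltas = delta_records(full_bnti, sub_bnti, "bNTI")
            res.bnti_changes = change_tables_by_group(full_bnti, sub_bnti, pair_groups)
        results.append(res)
    return results
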