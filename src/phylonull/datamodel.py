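"""Core domain types: phylogenetic tree, community table, metadata, dataset.

All downstream analyses (null models, UniFrac comparisons, outlier audits)
consume these types.  Construction validates the invariants once, so later
stages can assume identifier consistency instead of re-checking it.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode


class DataModelError(ValueError):
    """Raised when an input violates a structural invariant."""


# ---------------------------------------------------------------------------
# PhyloTree
# ---------------------------------------------------------------------------

class PhyloTree:
    """Rooted phylogenetic tree with branch lengths and unique tip labels.

    Thin wrapper around :class:`skbio.TreeNode` that enforces:

    * unique, non-empty tip labels,
    * branch lengths present and >= 0 on every non-root edge,
    * at least one strictly positive branch length.

    Zero-length terminal branches are legitimate (identical sequences), so
    nearest-taxon distances of 0 can occur.
    """

    def __init__(self, tree: TreeNode):
        self._tree = tree
        self._validate()
        # an edge above the root has no meaning for tip-tip distances and
        # would silently inflate shared branch length in UniFrac; drop it
        self._tree.length = None
        self._cophenetic: pd.DataFrame | None = None

    # -- construction -------------------------------------------------------

    @classmethod
    def from_newick(cls, source) -> "PhyloTree":
        """Parse a single-tree Newick string, path, or file handle."""
        if isinstance(source, str) and "(" in source:
            tree = TreeNode.read(io.StringIO(source))
        else:
            tree = TreeNode.read(str(source))
        return cls(tree)

    def _validate(self) -> None:
        tips = list(self._tree.tips())
        if not tips:
            raise DataModelError("tree has no tips")
        labels = [t.name for t in tips]
        if any(l is None or l == "" for l in labels):
            raise DataModelError("tree contains unnamed tips")
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        if dupes:
            raise DataModelError(f"duplicate tip labels: {dupes}")
        any_positive = False
        for node in self._tree.traverse(include_self=False):
            if node.length is None:
                raise DataModelError(
                    f"missing branch length on edge above {node.name or 'an internal node'}"
                )
            if node.length < 0:
                raise DataModelError(f"negative branch length above {node.name!r}")
            if node.length > 0:
                any_positive = True
        if not any_positive:
            raise DataModelError("all branch lengths are zero")

    # -- basic accessors ----------------------------------------------------

    @property
    def tip_labels(self) -> tuple[str, ...]:
        return tuple(t.name for t in self._tree.tips())

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self._tree.tips())

    @property
    def skbio_tree(self) -> TreeNode:
        return self._tree

    def copy(self) -> "PhyloTree":
        return PhyloTree(self._tree.copy())

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<PhyloTree with {self.n_tips} tips>"

    # -- distances ----------------------------------------------------------

    def cophenetic(self) -> pd.DataFrame:
        """Tip-to-tip path-length (cophenetic) distance matrix.

        Symmetric with zero diagonal; entry (i, j) is the sum of branch
        lengths on the path between tips i and j.  Cached after first call.
        """
        if self._cophenetic is None:
            dm = self._tree.tip_tip_distances()
            self._cophenetic = pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids)
        return self._cophenetic

    def terminal_branch_lengths(self) -> pd.Series:
        """Length of each tip's pendant edge, indexed by tip label."""
        return pd.Series(
            {t.name: float(t.length) for t in self._tree.tips()}, name="terminal_length"
        )

    def root_to_tip_distances(self) -> pd.Series:
        """Path-length distance from the root to each tip."""
        depths: dict[str, float] = {}
        # preorder accumulation; root itself has depth 0
        stack = [(self._tree, 0.0)]
        while stack:
            node, depth = stack.pop()
            if node.is_tip():
                depths[node.name] = depth
            else:
                for child in node.children:
                    stack.append((child, depth + float(child.length or 0.0)))
        return pd.Series(depths, name="root_to_tip").loc[list(self.tip_labels)]

    # -- editing ------------------------------------------------------------

    def prune_tips(self, labels: Iterable[str]) -> "PhyloTree":
        """Return a new tree with the given tips removed."""
        drop = set(labels)
        missing = drop - set(self.tip_labels)
        if missing:
            raise DataModelError(f"tips not in tree: {sorted(missing)}")
        keep = [l for l in self.tip_labels if l not in drop]
        if len(keep) < 2:
            raise DataModelError("pruning would leave fewer than two tips")
        sheared = self._tree.copy().shear(keep)
        sheared.prune()
        if sheared.length is None:
            sheared.length = 0.0
        return PhyloTree(sheared)

    def keep_tips(self, labels: Iterable[str]) -> "PhyloTree":
        keep = set(labels)
        return self.prune_tips([l for l in self.tip_labels if l not in keep])

    def reroot_longest_branch(self) -> "PhyloTree":
        """Root at the midpoint of the single longest branch.

        Ties are broken by the lexicographically smallest tip label found in
        the subtree below each candidate edge, making the operation
        deterministic.
        """
        tree = self._tree.copy()
        candidates = []
        for node in tree.traverse(include_self=False):
            smallest_tip = min(t.name for t in (node.tips() if not node.is_tip() else [node]))
            candidates.append((-(node.length or 0.0), smallest_tip, id(node), node))
        candidates.sort(key=lambda c: (c[0], c[1]))
        _, _, _, edge_child = candidates[0]
        half = (edge_child.length or 0.0) / 2.0
        parent = edge_child.parent
        mid = TreeNode(name=None, length=half)
        parent.remove(edge_child)
        edge_child.length = half
        mid.append(edge_child)
        parent.append(mid)
        rerooted = tree.root_at(mid)
        for node in rerooted.traverse(include_self=True):
            if node.length is None:
                node.length = 0.0
        return PhyloTree(rerooted)

    def to_newick(self) -> str:
        out = io.StringIO()
        self._tree.write(out)
        return out.getvalue()


# ---------------------------------------------------------------------------
# CommunityTable
# ---------------------------------------------------------------------------

class CommunityTable:
    """Sample x taxon abundance matrix (read counts or relative abundances).

    Counts must be non-negative and finite; sample and taxon identifiers
    unique; no sample may be entirely zero.  Taxa that are zero everywhere
    are permitted (they simply never contribute to any community).
    """

    def __init__(self, data: pd.DataFrame):
        if data.index.has_duplicates:
            raise DataModelError(
                f"duplicate sample ids: {sorted(data.index[data.index.duplicated()])}"
            )
        if data.columns.has_duplicates:
            raise DataModelError(
                f"duplicate taxon ids: {sorted(data.columns[data.columns.duplicated()])}"
            )
        try:
            values = data.to_numpy(dtype=float)
        except (TypeError, ValueError) as exc:
            raise DataModelError(f"non-numeric abundance values: {exc}") from exc
        if not np.isfinite(values).all():
            raise DataModelError("non-finite abundance values")
        if (values < 0).any():
            bad = data.index[(values < 0).any(axis=1)].tolist()
            raise DataModelError(f"negative abundances in samples: {bad}")
        zero = data.index[(values.sum(axis=1) == 0)].tolist()
        if zero:
            raise DataModelError(f"all-zero samples: {zero}")
        self._data = data.astype(float)

    @property
    def data(self) -> pd.DataFrame:
        """The underlying samples x taxa DataFrame (do not mutate)."""
        return self._data

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(self._data.index)

    @property
    def taxon_ids(self) -> tuple[str, ...]:
        return tuple(self._data.columns)

    def sample_vector(self, sample_id: str) -> pd.Series:
        return self._data.loc[sample_id]

    def relative_abundance(self) -> pd.DataFrame:
        """Per-sample relative abundances (rows sum to 1)."""
        return self._data.div(self._data.sum(axis=1), axis=0)

    def drop_taxa(self, taxa: Iterable[str], allow_empty_samples: bool = False) -> "CommunityTable":
        drop = set(taxa)
        missing = drop - set(self.taxon_ids)
        if missing:
            raise DataModelError(f"taxa not in table: {sorted(missing)}")
        kept = self._data.drop(columns=list(drop))
        if not allow_empty_samples:
            zero = kept.index[kept.sum(axis=1) == 0].tolist()
            if zero:
                raise DataModelError(
                    f"dropping taxa would leave all-zero samples: {zero}"
                )
        return CommunityTable(kept)

    def subset_samples(self, sample_ids: Sequence[str]) -> "CommunityTable":
        missing = set(sample_ids) - set(self.sample_ids)
        if missing:
            raise DataModelError(f"samples not in table: {sorted(missing)}")
        return CommunityTable(self._data.loc[list(sample_ids)])

    def __repr__(self) -> str:  # pragma: no cover
        return f"<CommunityTable {len(self.sample_ids)} samples x {len(self.taxon_ids)} taxa>"


# ---------------------------------------------------------------------------
# SampleMetadata
# ---------------------------------------------------------------------------

class SampleMetadata:
    """Categorical per-sample variables (sample type, regime, ...)."""

    def __init__(self, data: pd.DataFrame):
        if data.index.has_duplicates:
            raise DataModelError("duplicate sample ids in metadata")
        self._data = data.astype(str)

    @property
    def data(self) -> pd.DataFrame:
        return self._data

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(self._data.index)

    @property
    def variables(self) -> tuple[str, ...]:
        return tuple(self._data.columns)

    def levels(self, variable: str) -> tuple[str, ...]:
        if variable not in self._data.columns:
            raise DataModelError(f"unknown metadata variable: {variable!r}")
        return tuple(sorted(self._data[variable].unique()))

    def subset(self, sample_ids: Sequence[str]) -> "SampleMetadata":
        return SampleMetadata(self._data.loc[list(sample_ids)])

    def covers(self, sample_ids: Iterable[str]) -> bool:
        return set(sample_ids) <= set(self._data.index)


# ---------------------------------------------------------------------------
# CommunityDataset
# ---------------------------------------------------------------------------

@dataclass
class AlignmentReport:
    """Identifier reconciliation performed by :func:`align_dataset`."""

    pruned_tips: tuple[str, ...] = ()
    dropped_taxa: tuple[str, ...] = ()

    @property
    def clean(self) -> bool:
        return not self.pruned_tips and not self.dropped_taxa


@dataclass
class CommunityDataset:
    """Abundance table + tree + metadata with a strict taxon/tip bijection.

    Every taxon in the table is a tip of the tree and vice versa; every
    sample has a metadata row.  Constructed through :func:`align_dataset`
    (or directly when the caller guarantees consistency).
    """

    table: CommunityTable
    tree: PhyloTree
    metadata: SampleMetadata
    alignment: AlignmentReport = field(default_factory=AlignmentReport)

    def __post_init__(self) -> None:
        taxa = set(self.table.taxon_ids)
        tips = set(self.tree.tip_labels)
        if taxa != tips:
            raise DataModelError(
                f"taxon/tip mismatch: {sorted(taxa - tips)[:5]} only in table, "
                f"{sorted(tips - taxa)[:5]} only in tree"
            )
        if not self.metadata.covers(self.table.sample_ids):
            missing = set(self.table.sample_ids) - set(self.metadata.sample_ids)
            raise DataModelError(f"samples without metadata: {sorted(missing)}")

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return self.table.sample_ids

    @property
    def taxon_ids(self) -> tuple[str, ...]:
        return self.table.taxon_ids

    def cophenetic(self) -> pd.DataFrame:
        """Cophenetic matrix ordered to match the table's taxon columns."""
        taxa = list(self.table.taxon_ids)
        return self.tree.cophenetic().loc[taxa, taxa]

    def groups(self, variables: Sequence[str]) -> dict[tuple[str, ...], list[str]]:
        """Sample ids grouped by the joint level of the given variables."""
        for v in variables:
            if v not in self.metadata.variables:
                raise DataModelError(f"unknown metadata variable: {v!r}")
        md = self.metadata.data.loc[list(self.sample_ids), list(variables)]
        out: dict[tuple[str, ...], list[str]] = {}
        for sid, row in md.iterrows():
            out.setdefault(tuple(row), []).append(sid)
        return out
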