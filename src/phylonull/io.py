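"""Readers and writers for trees, abundance tables, metadata and reports.

Formats are deliberately plain: single-tree Newick with mandatory branch
lengths, UTF-8 tab-separated tables with a header, FASTA for sequences.
Identifier matching is exact and case-sensitive everywhere; silent
case-folding would hide upstream bookkeeping errors.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import pandas as pd

from .datamodel import (
    AlignmentReport,
    CommunityDataset,
    CommunityTable,
    DataModelError,
    PhyloTree,
    SampleMetadata,
)

Orientation = Literal["samples_as_rows", "taxa_as_rows"]


def read_newick(path) -> PhyloTree:
    """Read a single rooted tree with branch lengths from a Newick file."""
    return PhyloTree.from_newick(Path(path))


def write_newick(tree: PhyloTree, path) -> None:
    Path(path).write_text(tree.to_newick())


def read_community_table(path, orientation: Orientation = "samples_as_rows") -> CommunityTable:
    """Read a dense TSV abundance table.

    ``orientation`` states what the file's rows are; the in-memory table is
    always samples x taxa, so reading a transposed file with
    ``taxa_as_rows`` yields the identical object.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if orientation == "taxa_as_rows":
        df = df.T
    elif orientation != "samples_as_rows":
        raise ValueError(f"unknown orientation: {orientation!r}")
    return CommunityTable(df)


def write_community_table(table: CommunityTable, path, orientation: Orientation = "samples_as_rows") -> None:
    df = table.data if orientation == "samples_as_rows" else table.data.T
    df.to_csv(path, sep="\t", index_label="id")


def read_metadata(path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    return SampleMetadata(df)


def write_metadata(metadata: SampleMetadata, path) -> None:
    metadata.data.to_csv(path, sep="\t", index_label="sample_id")


def read_fasta(path) -> dict[str, str]:
    """Minimal FASTA reader returning {id: sequence} with ids taken up to
    the first whitespace; full headers are preserved separately by callers
    that need them (see :func:`phylonull.tree_audit.export_suspects`)."""
    records: dict[str, str] = {}
    header = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if header is not None:
                    records[header] = "".join(chunks)
                header = line[1:].split()[0]
                chunks = []
            elif header is not None:
                chunks.append(line.strip())
    if header is not None:
        records[header] = "".join(chunks)
    return records


def align_dataset(
    table: CommunityTable,
    tree: PhyloTree,
    metadata: SampleMetadata,
    policy: Literal["strict", "prune"] = "strict",
) -> CommunityDataset:
    """Reconcile table taxa with tree tips and attach metadata.

    ``strict`` raises on any taxon/tip mismatch, enumerating the orphans.
    ``prune`` drops tree tips absent from the table and table taxa absent
    from the tree, recording both sets in the returned dataset's
    ``alignment`` report.  Idempotent: aligning an aligned dataset is the
    identity.
    """
    taxa = set(table.taxon_ids)
    tips = set(tree.tip_labels)
    orphan_taxa = sorted(taxa - tips)
    orphan_tips = sorted(tips - taxa)
    if policy == "strict":
        if orphan_taxa or orphan_tips:
            raise DataModelError(
                f"strict alignment failed: taxa without tips {orphan_taxa}, "
                f"tips without taxa {orphan_tips}"
            )
        report = AlignmentReport()
    elif policy == "prune":
        if orphan_tips:
            tree = tree.prune_tips(orphan_tips)
        if orphan_taxa:
            table = table.drop_taxa(orphan_taxa)
        report = AlignmentReport(tuple(orphan_tips), tuple(orphan_taxa))
    else:
        raise ValueError(f"unknown policy: {policy!r}")
    if not metadata.covers(table.sample_ids):
        missing = sorted(set(table.sample_ids) - set(metadata.sample_ids))
        raise DataModelError(f"samples without metadata: {missing}")
    return CommunityDataset(table, tree, metadata, report)


def richness(table: CommunityTable, scope: Literal["per_sample", "regional"] = "regional"):
    """Number of taxa with positive abundance.

    ``per_sample`` returns a Series over samples; ``regional`` returns the
    size of the regional pool (taxa present in at least one sample).
    """
    present = table.data > 0
    if scope == "per_sample":
        return present.sum(axis=1)
    if scope == "regional":
        return int(present.any(axis=0).sum())
    raise ValueError(f"unknown scope: {scope!r}")
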