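"""Independent brute-force reference implementations used only by tests.

Everything here is deliberately written with plain loops and/or a different
tree library (dendropy) than the package uses for its own computation, so
agreement between the two routes is informative.
"""

from __future__ import annotations

import io
import itertools

import dendropy
import numpy as np


def dendropy_distances(newick: str) -> dict[tuple[str, str], float]:
    """Tip-pair patristic distances via dendropy's distance matrix."""
    tree = dendropy.Tree.get(data=newick, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    out = {}
    taxa = list(tree.taxon_namespace)
    for a, b in itertools.combinations(taxa, 2):
        d = pdm.patristic_distance(a, b)
        out[(a.label, b.label)] = d
        out[(b.label, a.label)] = d
    for a in taxa:
        out[(a.label, a.label)] = 0.0
    return out


def brute_mntd(weights: dict[str, float], dist: dict[tuple[str, str], float], weighted: bool) -> float:
    taxa = [t for t, w in weights.items() if w > 0]
    minima = {}
    for t in taxa:
        minima[t] = min(dist[(t, u)] for u in taxa if u != t)
    if weighted:
        total = sum(weights[t] for t in taxa)
        return sum(weights[t] * minima[t] for t in taxa) / total
    return sum(minima.values()) / len(taxa)


def brute_bmntd(
    wa: dict[str, float], wb: dict[str, float], dist: dict[tuple[str, str], float], weighted: bool
) -> float:
    a = [t for t, w in wa.items() if w > 0]
    b = [t for t, w in wb.items() if w > 0]
    min_ab = {t: min(dist[(t, u)] for u in b) for t in a}
    min_ba = {t: min(dist[(t, u)] for u in a) for t in b}
    if weighted:
        ta, tb = sum(wa[t] for t in a), sum(wb[t] for t in b)
        d_ab = sum(wa[t] * min_ab[t] for t in a) / ta
        d_ba = sum(wb[t] * min_ba[t] for t in b) / tb
    else:
        d_ab = sum(min_ab.values()) / len(a)
        d_ba = sum(min_ba.values()) / len(b)
    return 0.5 * (d_ab + d_ba)


def exhaustive_nti_z(
    labels: list[str],
    weights: dict[str, float],
    dist: dict[tuple[str, str], float],
    weighted: bool,
) -> float:
    """Exact NTI over all permutations of metacommunity tip labels."""
    present = [t for t in labels if weights.get(t, 0) > 0]
    obs = brute_mntd(weights, dist, weighted)
    nulls = []
    for perm in itertools.permutations(labels):
        relabel = dict(zip(labels, perm))
        w = {relabel[t]: weights[t] for t in present}
        nulls.append(brute_mntd(w, dist, weighted))
    nulls = np.array(nulls)
    return float((nulls.mean() - obs) / nulls.std())


def exhaustive_bnti_z(
    labels: list[str],
    wa: dict[str, float],
    wb: dict[str, float],
    dist: dict[tuple[str, str], float],
    weighted: bool,
) -> float:
    """Exact betaNTI over all shared permutations of tip labels."""
    pa = [t for t in labels if wa.get(t, 0) > 0]
    pb = [t for t in labels if wb.get(t, 0) > 0]
    obs = brute_bmntd(wa, wb, dist, weighted)
    nulls = []
    for perm in itertools.permutations(labels):
        relabel = dict(zip(labels, perm))
        na = {relabel[t]: wa[t] for t in pa}
        nb = {relabel[t]: wb[t] for t in pb}
        nulls.append(brute_bmntd(na, nb, dist, weighted))
    nulls = np.array(nulls)
    return float((obs - nulls.mean()) / nulls.std())


# ---------------------------------------------------------------------------
# UniFrac by explicit branch enumeration (dendropy bipartitions)
# ---------------------------------------------------------------------------

def _edge_tipsets(newick: str):
    tree = dendropy.Tree.get(data=newick, schema="newick")
    edges = []
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        tips = frozenset(l.taxon.label for l in node.leaf_iter())
        edges.append((tips, float(node.edge.length or 0.0)))
    root_to_tip = {}
    for leaf in tree.leaf_node_iter():
        d = 0.0
        node = leaf
        while node.parent_node is not None:
            d += float(node.edge.length or 0.0)
            node = node.parent_node
        root_to_tip[leaf.taxon.label] = d
    return edges, root_to_tip


def brute_unweighted_unifrac(newick: str, set_a: set[str], set_b: set[str]) -> float:
    """Distance = unique branch length / branch length leading to either set."""
    edges, _ = _edge_tipsets(newick)
    unique = shared_or = 0.0
    for tips, length in edges:
        in_a = bool(tips & set_a)
        in_b = bool(tips & set_b)
        if in_a or in_b:
            shared_or += length
            if in_a != in_b:
                unique += length
    return unique / shared_or


def brute_weighted_unifrac(
    newick: str, abund_a: dict[str, float], abund_b: dict[str, float]
) -> float:
    """Normalized weighted UniFrac: sum_e len * |pA - pB| over the branch
    flow, normalized by sum_tips d(root, tip) * (pA + pB)."""
    edges, root_to_tip = _edge_tipsets(newick)
    ta = sum(abund_a.values())
    tb = sum(abund_b.values())
    u = 0.0
    for tips, length in edges:
        pa = sum(abund_a.get(t, 0.0) for t in tips) / ta
        pb = sum(abund_b.get(t, 0.0) for t in tips) / tb
        u += length * abs(pa - pb)
    c = sum(
        d * (abund_a.get(t, 0.0) / ta + abund_b.get(t, 0.0) / tb)
        for t, d in root_to_tip.items()
    )
    return u / c
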