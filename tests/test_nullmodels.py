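"""MNTD/betaMNTD statistics and their tip-shuffle null models."""

import numpy as np
import pandas as pd
import pytest

import phylonull as pn
from phylonull.nullmodels import NullModelError, NullModelResult, classify

import oracles
from conftest import TOY_NEWICK, random_dataset


def _dataset_from_tree(newick: str, communities: dict[str, dict[str, float]]):
    tree = pn.PhyloTree.from_newick(newick)
    labels = list(tree.tip_labels)
    rows = {
        sid: [float(com.get(t, 0.0)) for t in labels] for sid, com in communities.items()
    }
    table = pn.CommunityTable(pd.DataFrame.from_dict(rows, orient="index", columns=labels))
    md = pn.SampleMetadata(
        pd.DataFrame({"sample_type": ["x"] * len(rows)}, index=list(rows))
    )
    return pn.CommunityDataset(table, tree, md)


class TestCopheneticDistances:
    def test_toy_path_sums(self, toy_tree):
        d = pn.cophenetic_distances(toy_tree)
        assert d.loc["t1", "t2"] == pytest.approx(2.0)
        assert d.loc["t1", "t3"] == pytest.approx(5.0)
        assert np.allclose(np.diag(d.to_numpy()), 0)
        assert np.allclose(d.to_numpy(), d.to_numpy().T)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_independent_path_enumeration(self, seed):
        tree = pn.simulate_tree(8, seed=seed)
        ref = oracles.dendropy_distances(tree.to_newick())
        d = pn.cophenetic_distances(tree)
        for a in tree.tip_labels:
            for b in tree.tip_labels:
                assert d.loc[a, b] == pytest.approx(ref[(a, b)], abs=1e-9)


class TestMNTD:
    def test_toy_two_taxon_community(self, toy_tree):
        d = pn.cophenetic_distances(toy_tree)
        assert pn.mntd({"t1": 1, "t2": 1}, d) == pytest.approx(2.0)

    def test_two_taxon_weighting_irrelevant(self, toy_tree):
        d = pn.cophenetic_distances(toy_tree)
        assert pn.mntd({"t1": 9, "t3": 1}, d, weighted=True) == pytest.approx(
            pn.mntd({"t1": 1, "t3": 1}, d, weighted=False)
        )

    def test_undefined_below_two_taxa(self, toy_tree):
        with pytest.raises(NullModelError):
            pn.mntd({"t1": 1}, pn.cophenetic_distances(toy_tree))

    @pytest.mark.parametrize("weighted", [False, True])
    def test_matches_brute_force_scan(self, weighted):
        tree = pn.simulate_tree(10, seed=4)
        d = pn.cophenetic_distances(tree)
        rng = np.random.default_rng(4)
        taxa = list(rng.choice(list(tree.tip_labels), size=5, replace=False))
        weights = {t: float(rng.lognormal()) for t in taxa}
        ref = oracles.brute_mntd(weights, oracles.dendropy_distances(tree.to_newick()), weighted)
        assert pn.mntd(weights, d, weighted=weighted) == pytest.approx(ref, rel=1e-9)


class TestBetaMNTD:
    def test_identical_communities_zero(self, toy_tree):
        d = pn.cophenetic_distances(toy_tree)
        com = {"t1": 2.0, "t3": 1.0}
        assert pn.bmntd(com, com, d) == pytest.approx(0.0)

    def test_single_pair_path(self, toy_tree):
        d = pn.cophenetic_distances(toy_tree)
        assert pn.bmntd({"t1": 1}, {"t3": 1}, d) == pytest.approx(5.0)

    def test_empty_community_rejected(self, toy_tree):
        d = pn.cophenetic_distances(toy_tree)
        with pytest.raises(NullModelError):
            pn.bmntd({}, {"t1": 1}, d)

    @pytest.mark.parametrize("weighted", [False, True])
    def test_matches_brute_force(self, weighted):
        tree = pn.simulate_tree(12, seed=5)
        rng = np.random.default_rng(5)
        tips = list(tree.tip_labels)
        wa = {t: float(rng.lognormal()) for t in rng.choice(tips, 5, replace=False)}
        wb = {t: float(rng.lognormal()) for t in rng.choice(tips, 5, replace=False)}
        ref = oracles.brute_bmntd(wa, wb, oracles.dendropy_distances(tree.to_newick()), weighted)
        assert pn.bmntd(wa, wb, pn.cophenetic_distances(tree), weighted=weighted) == pytest.approx(ref, rel=1e-9)


class TestNTI:
    def test_complete_community_degenerate(self, toy_tree):
        ds = _dataset_from_tree(TOY_NEWICK, {"s": {"t1": 1, "t2": 1, "t3": 1}})
        res, call = pn.nti(ds.table.sample_vector("s"), ds, n_null=99, seed=0)
        assert res.degenerate and res.z == 0.0
        assert call.call == "stochastic"

    def test_seed_reproducibility(self, small_scenario):
        ds, _ = small_scenario
        vec = ds.table.sample_vector(ds.sample_ids[0])
        r1, _ = pn.nti(vec, ds, n_null=199, seed=11)
        r2, _ = pn.nti(vec, ds, n_null=199, seed=11)
        assert r1 == r2

    def test_scale_invariance_exact(self):
        ds = _dataset_from_tree(
            "((t1:1,t2:2):1,((t3:1,t4:3):2,t5:1):1);",
            {"s": {"t1": 1, "t3": 2, "t5": 1}},
        )
        scaled = ds.tree.skbio_tree.copy()
        for node in scaled.traverse(include_self=False):
            node.length *= 7
        ds7 = pn.CommunityDataset(ds.table, pn.PhyloTree(scaled), ds.metadata)
        vec = ds.table.sample_vector("s")
        for weighted in (False, True):
            z1 = pn.nti(vec, ds, n_null=499, seed=3, weighted=weighted)[0].z
            z2 = pn.nti(vec, ds7, n_null=499, seed=3, weighted=weighted)[0].z
            assert z1 == z2  # bit-for-bit

    @pytest.mark.parametrize("weighted", [False, True])
    def test_small_tree_matches_exhaustive_permutations(self, weighted):
        newick = "((t1:1,t2:2):1,(t3:1.5,t4:0.5):2);"
        com = {"t1": 1.0, "t2": 3.0}
        ds = _dataset_from_tree(newick, {"s": com})
        labels = list(ds.tree.tip_labels)
        dist = oracles.dendropy_distances(newick)
        weights = {t: com.get(t, 0.0) for t in labels}
        z_exact = oracles.exhaustive_nti_z(labels, weights, dist, weighted)
        res, _ = pn.nti(ds.table.sample_vector("s"), ds, n_null=4000, seed=0, weighted=weighted)
        assert res.z == pytest.approx(z_exact, abs=0.1)


class TestBetaNTI:
    def test_identical_communities_nonpositive_z(self, small_scenario):
        ds, _ = small_scenario
        vec = ds.table.sample_vector(ds.sample_ids[0])
        res, _ = pn.bnti(vec, vec, ds, n_null=199, seed=0)
        assert res.observed == pytest.approx(0.0)
        assert res.z <= 0

    def test_classification_thresholds(self):
        def call_for(z):
            res = NullModelResult("bNTI", 0, 0, 1, z, 10, False, 0)
            return classify(res).call

        assert call_for(2.1) == "heterogeneous_selection"
        assert call_for(-2.5) == "homogeneous_selection"
        assert call_for(0.3) == "stochastic"
        assert call_for(2.0) == "stochastic"  # strict inequality
        assert call_for(-2.0) == "stochastic"

    def test_nti_classification_thresholds(self):
        def call_for(z):
            res = NullModelResult("NTI", 0, 0, 1, z, 10, False, 0)
            return classify(res).call

        assert call_for(2.5) == "clustered"
        assert call_for(-2.5) == "dispersed"
        assert call_for(2.0) == "stochastic"

    def test_three_tip_exhaustive(self):
        newick = "((t1:1,t2:1):1,t3:3);"
        ds = _dataset_from_tree(newick, {"a": {"t1": 1}, "b": {"t3": 1}})
        labels = list(ds.tree.tip_labels)
        dist = oracles.dendropy_distances(newick)
        z_exact = oracles.exhaustive_bnti_z(
            labels, {"t1": 1.0}, {"t3": 1.0}, dist, weighted=True
        )
        res, _ = pn.bnti(
            ds.table.sample_vector("a"), ds.table.sample_vector("b"), ds, n_null=4000, seed=1
        )
        assert res.z == pytest.approx(z_exact, abs=0.1)


class TestGroupedBetaNTI:
    def _dataset(self, sizes):
        types = []
        for label, n in sizes.items():
            types += [label] * n
        ds = random_dataset(n_tips=20, n_samples=len(types), richness=6, seed=8)
        md = pn.SampleMetadata(
            pd.DataFrame({"sample_type": types}, index=list(ds.sample_ids))
        )
        return pn.CommunityDataset(ds.table, ds.tree, md)

    def test_pair_counts(self):
        ds = self._dataset({"g": 4})
        assert len(pn.bnti_group(ds, ["sample_type"], n_null=49, seed=0)) == 6

    def test_two_groups_pair_counts(self):
        ds = self._dataset({"g": 2, "h": 3})
        res = pn.bnti_group(ds, ["sample_type"], n_null=49, seed=0)
        assert len(res) == 1 + 3

    def test_singleton_group_contributes_no_pairs(self):
        ds = self._dataset({"g": 1, "h": 2})
        res = pn.bnti_group(ds, ["sample_type"], n_null=49, seed=0)
        assert len(res) == 1

    def test_order_independence(self):
        ds = self._dataset({"g": 3})
        res1 = pn.bnti_group(ds, ["sample_type"], n_null=99, seed=5)
        reordered = ds.table.subset_samples(list(ds.sample_ids)[::-1])
        ds2 = pn.CommunityDataset(reordered, ds.tree, ds.metadata)
        res2 = pn.bnti_group(ds2, ["sample_type"], n_null=99, seed=5)
        key = ["sample_a", "sample_b"]
        merged = res1.merge(res2, on=key, suffixes=("_1", "_2"))
        assert len(merged) == len(res1)
        np.testing.assert_allclose(merged.z_1, merged.z_2)


class TestNullCalibration:
    def test_random_communities_z_centred(self):
        """Uniform random communities should give z ~ N(0,1)-ish: mean near
        0 and |z|>2 rare (the smoke-scale version of the full calibration in
        the acceptance suite)."""
        tree = pn.simulate_tree(60, seed=21)
        labels = list(tree.tip_labels)
        table = pn.CommunityTable(
            pd.DataFrame([np.ones(len(labels))], index=["s"], columns=labels)
        )
        md = pn.SampleMetadata(pd.DataFrame({"v": ["x"]}, index=["s"]))
        ds = pn.CommunityDataset(table, tree, md)
        rng = np.random.default_rng(3)
        zs = []
        for _ in range(100):
            picks = rng.choice(labels, size=12, replace=False)
            res, _ = pn.nti(
                pd.Series(1.0, index=picks), ds, n_null=199, seed=int(rng.integers(2**31))
            )
            zs.append(res.z)
        zs = np.array(zs)
        assert abs(zs.mean()) < 0.25
        assert np.mean(np.abs(zs) > 2) <= 0.1
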