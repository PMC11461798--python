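"""Long-branch outlier screening: scoring, removal, export."""

import numpy as np
import pandas as pd
import pytest

import phylonull as pn
from phylonull.datamodel import DataModelError

import oracles
from conftest import random_dataset


def star_tree(lengths: dict[str, float]) -> pn.PhyloTree:
    body = ",".join(f"{k}:{v}" for k, v in lengths.items())
    return pn.PhyloTree.from_newick(f"({body});")


class TestBranchMetrics:
    def test_toy_values(self, toy_tree):
        m = pn.branch_metrics(toy_tree)
        assert m.loc["t3", "terminal_length"] == pytest.approx(3.0)
        assert m.loc["t1", "root_to_tip"] == pytest.approx(2.0)
        assert m.loc["t3", "root_to_tip"] == pytest.approx(3.0)

    def test_ultrametric_root_to_tip_equal(self):
        tree = pn.simulate_tree(16, model="coalescent", seed=2, branch_model="clock")
        r2t = pn.branch_metrics(tree)["root_to_tip"]
        np.testing.assert_allclose(r2t, r2t.iloc[0], rtol=1e-6)

    @pytest.mark.parametrize("seed", [0, 3])
    def test_matches_path_enumeration(self, seed):
        tree = pn.simulate_tree(10, seed=seed)
        ref = oracles._edge_tipsets(tree.to_newick())[1]
        r2t = pn.branch_metrics(tree)["root_to_tip"]
        for tip, d in ref.items():
            assert r2t[tip] == pytest.approx(d, abs=1e-9)


class TestScoreOutliers:
    def test_equal_branches_nothing_flagged(self):
        tree = star_tree({f"t{i}": 0.01 for i in range(10)})
        report = pn.score_outliers(pn.branch_metrics(tree))
        assert not report.records["flagged"].any()
        assert (report.records["score"] == 0).all()

    def test_planted_tip_flagged_against_jittered_bulk(self):
        # concentrated bulk near 0.01 with one extreme tip at 0.5
        rng = np.random.default_rng(0)
        lengths = {f"t{i}": 0.01 * (1 + 0.05 * rng.standard_normal()) for i in range(100)}
        lengths["bad"] = 0.5
        report = pn.score_outliers(pn.branch_metrics(star_tree(lengths)))
        assert report.flagged == ("bad",)
        med = np.median(list(lengths.values()))
        mad = 1.4826 * np.median(np.abs(np.array(list(lengths.values())) - med))
        assert report.records.loc["bad", "score"] == pytest.approx((0.5 - med) / mad)

    def test_infinite_threshold_flags_nothing(self):
        tree = pn.simulate_tree(30, seed=1)
        report = pn.score_outliers(pn.branch_metrics(tree), threshold=np.inf)
        assert report.flagged == ()

    def test_too_few_tips_rejected(self):
        tree = pn.PhyloTree.from_newick("((a:1,b:1):1,c:2);")
        with pytest.raises(DataModelError):
            pn.score_outliers(pn.branch_metrics(tree))

    def test_flag_iff_score_above_threshold(self):
        tree = pn.simulate_tree(50, seed=7)
        report = pn.score_outliers(pn.branch_metrics(tree), threshold=1.0)
        assert (report.records["flagged"] == (report.records["score"] > 1.0)).all()

    def test_root_to_tip_method(self):
        tree = pn.simulate_tree(50, seed=7)
        report = pn.score_outliers(pn.branch_metrics(tree), method="root_to_tip_mad")
        assert report.method == "root_to_tip_mad"
        assert np.isfinite(report.records["score"]).all()


class TestPlantedRecovery:
    def test_precision_and_recall_on_grown_outliers(self):
        hits = fp = total_flagged = total_planted = 0
        for s in range(8):
            base = pn.simulate_tree(150, seed=500 + s)
            grown, planted = pn.plant_outliers(base, 0.012, 10.0, seed=s)
            flagged = set(pn.audit_tree(grown).flagged)
            planted = set(planted)
            hits += len(flagged & planted)
            fp += len(flagged - planted)
            total_flagged += len(flagged)
            total_planted += len(planted)
        assert fp == 0
        assert hits == total_planted == total_flagged

    @pytest.mark.parametrize("log_sd", [0.4, 0.5])
    def test_false_positive_control_lognormal_bulk(self, log_sd):
        flagged = tips = 0
        for s in range(10):
            tree = pn.simulate_tree(
                200, seed=900 + s, branch_model="iid_lognormal", branch_log_sd=log_sd
            )
            flagged += len(pn.audit_tree(tree).flagged)
            tips += tree.n_tips
        assert flagged / tips <= 0.01

    def test_iterative_rescreen_unmasks_secondary_outlier(self):
        rng = np.random.default_rng(1)
        lengths = {f"t{i}": 0.01 * (1 + 0.05 * rng.standard_normal()) for i in range(100)}
        lengths["huge"] = 5.0
        lengths["large"] = 0.08
        tree = star_tree(lengths)
        one_pass = set(pn.audit_tree(tree, max_iter=1).flagged)
        two_pass = set(pn.audit_tree(tree, max_iter=3).flagged)
        assert one_pass <= two_pass
        assert "huge" in one_pass
        assert "large" in two_pass


class TestRemoveOutliers:
    def test_taxa_bookkeeping(self):
        ds = random_dataset(n_tips=40, n_samples=3, richness=30, seed=6)
        before = len(ds.taxon_ids)
        flagged = list(ds.taxon_ids[:3])
        filtered, summary = pn.remove_outliers(ds, flagged)
        assert len(filtered.taxon_ids) == before - 3
        assert set(summary.index) == set(ds.sample_ids)
        observed_before = pn.richness(ds.table)
        observed_after = pn.richness(filtered.table)
        observed_flagged = sum(ds.table.data[t].sum() > 0 for t in flagged)
        assert observed_before - observed_after == observed_flagged

    def test_empty_set_is_identity(self):
        ds = random_dataset(seed=6)
        filtered, summary = pn.remove_outliers(ds, [])
        assert filtered is ds
        assert (summary["removed_abundance_fraction"] == 0).all()

    def test_unknown_tip_rejected(self):
        ds = random_dataset(seed=6)
        with pytest.raises(DataModelError):
            pn.remove_outliers(ds, ["not-a-tip"])

    def test_absent_taxa_removal_leaves_sample_untouched(self):
        ds = random_dataset(n_tips=30, n_samples=2, richness=5, seed=2)
        sid = ds.sample_ids[0]
        absent = [t for t in ds.taxon_ids if ds.table.data.loc[sid, t] == 0][:3]
        filtered, _ = pn.remove_outliers(ds, absent)
        x = ds.table.data.loc[sid, list(filtered.taxon_ids)].to_numpy()
        y = filtered.table.data.loc[sid].to_numpy()
        assert pn.bray_curtis_similarity(x, y) == pytest.approx(1.0)

    def test_commutes_with_alignment(self):
        ds = random_dataset(n_tips=30, n_samples=3, richness=25, seed=3)
        flagged = list(ds.taxon_ids[:2])
        pruned_first = pn.align_dataset(
            ds.table.drop_taxa(flagged), ds.tree.prune_tips(flagged), ds.metadata, "strict"
        )
        removed, _ = pn.remove_outliers(ds, flagged)
        assert set(pruned_first.taxon_ids) == set(removed.taxon_ids)
        pd.testing.assert_frame_equal(
            pruned_first.table.data, removed.table.data, check_like=True
        )


class TestExportSuspects:
    def test_round_trip(self, tmp_path):
        seqs = {"a": "ACGT", "b": "GGCC", "c": "TTAA"}
        path = tmp_path / "suspects.fasta"
        n = pn.export_suspects(["a", "c"], seqs, path)
        assert n == 2
        assert set(pn.read_fasta(path)) == {"a", "c"}

    def test_missing_sequence_rejected(self, tmp_path):
        with pytest.raises(DataModelError, match="b"):
            pn.export_suspects(["b"], {"a": "ACGT"}, tmp_path / "x.fasta")

    def test_empty_flag_set_warns_and_writes_empty(self, tmp_path):
        path = tmp_path / "empty.fasta"
        with pytest.warns(UserWarning):
            assert pn.export_suspects([], {"a": "ACGT"}, path) == 0
        assert path.read_text() == ""
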