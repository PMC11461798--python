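import numpy as np
import pandas as pd
import pytest

import phylonull as pn

TOY_NEWICK = "((t1:1,t2:1):1,t3:3);"


@pytest.fixture
def toy_tree() -> pn.PhyloTree:
    """Three-tip toy tree: two close tips (unit branches) and one distant."""
    return pn.PhyloTree.from_newick(TOY_NEWICK)


@pytest.fixture
def toy_dataset(toy_tree) -> pn.CommunityDataset:
    table = pn.CommunityTable(
        pd.DataFrame(
            [[1.0, 1.0, 0.0], [0.0, 1.0, 1.0]],
            index=["s1", "s2"],
            columns=["t1", "t2", "t3"],
        )
    )
    metadata = pn.SampleMetadata(
        pd.DataFrame({"sample_type": ["a", "b"]}, index=["s1", "s2"])
    )
    return pn.CommunityDataset(table, toy_tree, metadata)


@pytest.fixture(scope="session")
def small_scenario() -> tuple[pn.CommunityDataset, pn.ScenarioTruth]:
    """Small filtering-regime dataset reused by read-only tests."""
    cfg = pn.ScenarioConfig(
        n_tips=60,
        n_samples_per_type={"fish": 4, "rearing_water": 3, "intake_water": 2},
        target_richness=15,
        seed=42,
    )
    return pn.simulate_dataset(cfg)


def random_dataset(
    n_tips=30, n_samples=4, richness=8, seed=0, sample_types=("a", "b")
) -> pn.CommunityDataset:
    """Arbitrary consistent dataset built directly (no assembly structure)."""
    tree = pn.simulate_tree(n_tips, seed=seed)
    labels = list(tree.tip_labels)
    rng = np.random.default_rng(seed)
    rows = {}
    meta = {}
    for i in range(n_samples):
        picks = rng.choice(n_tips, size=richness, replace=False)
        vec = np.zeros(n_tips)
        vec[picks] = rng.lognormal(0, 1, size=richness)
        sid = f"s{i}"
        rows[sid] = vec
        meta[sid] = {"sample_type": sample_types[i % len(sample_types)]}
    table = pn.CommunityTable(pd.DataFrame.from_dict(rows, orient="index", columns=labels))
    metadata = pn.SampleMetadata(pd.DataFrame.from_dict(meta, orient="index"))
    return pn.CommunityDataset(table, tree, metadata)
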