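"""Synthetic metacommunities with planted tree defects and known assembly.

The generator emulates the structure of 16S amplicon surveys of host-
associated systems (fish gut plus intake/rearing water): a metacommunity
tree of a few hundred to a few thousand tips in which ~1% of tips are
planted "misclassified" outliers whose terminal branches are many-fold
longer than the bulk; outlier taxa rare within samples (mean relative
abundance ~0.1%); several sample types of differing composition so that
subsetting to one type shrinks the regional taxon pool by a tunable
fraction.

Assembly is controlled per sample type: under the ``filtering`` regime a
Brownian-motion niche trait evolved on the tree sets inclusion
probabilities through a Gaussian kernel around a type-specific optimum
(phylogenetically clustered communities); under ``neutral`` every taxon is
equally likely, matched to the same expected richness.  Every dataset
carries its ground truth (planted tips, regimes, optima) for recovery
tests.

All randomness flows from one master seed through named SHA-256
sub-streams (tree, outliers, traits, communities), so any stage is
reproducible in isolation.
"""

from __future__ import annotations

import random as _random
from dataclasses import dataclass, field
from typing import Literal, Mapping

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim

from .datamodel import (
    CommunityDataset,
    CommunityTable,
    DataModelError,
    PhyloTree,
    SampleMetadata,
)
from .nullmodels import subseed


@dataclass
class ScenarioConfig:
    """Study conditions for one synthetic dataset."""

    n_tips: int = 200
    tree_model: Literal["birth_death", "coalescent"] = "birth_death"
    branch_model: Literal["iid_normal", "iid_lognormal", "clock"] = "iid_normal"
    branch_scale: float = 0.05  # typical edge length, substitutions/site
    branch_cv: float = 0.2  # spread of iid_normal edge lengths (CV)
    branch_log_sd: float = 0.4  # log-SD of iid_lognormal edge lengths
    outlier_fraction: float = 0.012
    outlier_multiplier: float = 10.0
    sample_types: tuple[str, ...] = ("fish", "rearing_water", "intake_water")
    # fish-dominated design, echoing host-microbiome surveys where the host
    # compartment is sampled far more densely than the water compartments
    n_samples_per_type: int | Mapping[str, int] = field(
        default_factory=lambda: {"fish": 16, "rearing_water": 6, "intake_water": 4}
    )
    assembly_regime: Literal["filtering", "neutral"] | Mapping[str, str] = "filtering"
    filtering_strength: float = 0.3  # sigma of the niche kernel, in trait-SD units
    optima_quantiles: tuple[float, float] = (0.2, 0.8)  # trait quantiles spanned by type optima
    target_richness: int = 50  # expected taxa per sample
    mean_outlier_abundance: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.outlier_fraction < 0.5):
            raise ValueError("outlier_fraction must be in [0, 0.5)")
        if self.outlier_multiplier <= 1:
            raise ValueError("outlier_multiplier must be > 1")
        if self.filtering_strength <= 0:
            raise ValueError("filtering_strength must be > 0")

    def samples_of(self, sample_type: str) -> int:
        if isinstance(self.n_samples_per_type, Mapping):
            return int(self.n_samples_per_type[sample_type])
        return int(self.n_samples_per_type)

    def regime_of(self, sample_type: str) -> str:
        if isinstance(self.assembly_regime, Mapping):
            return str(self.assembly_regime[sample_type])
        return str(self.assembly_regime)


@dataclass
class ScenarioTruth:
    """Ground truth carried alongside a generated dataset."""

    planted_outliers: tuple[str, ...]
    regimes: dict[str, str]
    optima: dict[str, float]
    traits: pd.Series = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

def _relabel(tree: dendropy.Tree) -> str:
    """Deterministic tip names t000... in leaf traversal order; newick out."""
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = f"t{i:04d}"
    return tree.as_string(schema="newick", suppress_rooting=True)


def simulate_tree(
    n_tips: int,
    model: str = "birth_death",
    seed: int = 0,
    branch_model: str = "iid_normal",
    branch_scale: float = 0.05,
    branch_cv: float = 0.2,
    branch_log_sd: float = 0.4,
) -> PhyloTree:
    """Random metacommunity tree (stand-in for an inferred 16S gene tree).

    The topology comes from a ``birth_death`` (pure-birth, unit rate) or
    ``coalescent`` (Kingman, unit population size) process.  Branch lengths
    follow ``branch_model``:

    * ``iid_normal`` (default) — every edge is an independent
      Normal(branch_scale, branch_cv * branch_scale) draw truncated to be
      positive.  Gene trees built from short marker genes have pendant
      edges clustered within a few fold of each other, a bulk this
      emulates; against it a many-fold-longer planted branch is
      unambiguous.
    * ``iid_lognormal`` — edges are branch_scale * Lognormal(0,
      branch_log_sd): a skewed, heavier-tailed bulk used to stress-test
      outlier screening.
    * ``clock`` — keep the simulator's event times (ultrametric for the
      coalescent; expected height 2(1 - 1/n) at unit population size).
    """
    if n_tips < 8:
        raise ValueError("simulate_tree needs n_tips >= 8")
    rng = _random.Random(int(seed))
    if model == "birth_death":
        tr = treesim.birth_death_tree(
            birth_rate=1.0, death_rate=0.0, num_extant_tips=n_tips, rng=rng
        )
    elif model == "coalescent":
        tns = dendropy.TaxonNamespace([f"x{i}" for i in range(n_tips)])
        tr = treesim.pure_kingman_tree(taxon_namespace=tns, pop_size=1, rng=rng)
    else:
        raise ValueError(f"unknown tree model: {model!r}")
    newick = _relabel(tr)
    tree = PhyloTree.from_newick(newick)
    edges = [n for n in tree.skbio_tree.traverse(include_self=False)]
    if branch_model == "iid_normal":
        brng = np.random.default_rng(subseed(seed, "branch-lengths"))
        draws = brng.normal(branch_scale, branch_cv * branch_scale, size=len(edges))
        draws = np.abs(draws)  # reflect the (negligible) negative tail
        for node, length in zip(edges, draws):
            node.length = float(max(length, 1e-9))
    elif branch_model == "iid_lognormal":
        brng = np.random.default_rng(subseed(seed, "branch-lengths"))
        draws = branch_scale * brng.lognormal(0.0, branch_log_sd, size=len(edges))
        for node, length in zip(edges, draws):
            node.length = float(length)
    elif branch_model == "clock":
        for node in edges:
            if node.length is None or node.length <= 0:
                node.length = 1e-9
    else:
        raise ValueError(f"unknown branch model: {branch_model!r}")
    return PhyloTree(tree.skbio_tree)


def plant_outliers(
    tree: PhyloTree,
    outlier_fraction: float = 0.012,
    outlier_multiplier: float = 10.0,
    seed: int = 0,
) -> tuple[PhyloTree, tuple[str, ...]]:
    """Grow the terminal branches of a random ~1% subset of tips.

    Emulates misclassified non-target sequences: the observable defect (an
    extreme pendant edge) is reproduced by growing the chosen tips'
    terminal branches, without modelling foreign evolution.  The grown
    length is ``outlier_multiplier * max(own_length, bulk_median)``: a
    straight multiple of the tip's own pendant edge, floored at the bulk
    median so a tip that happened to sit on a near-zero pendant edge still
    becomes a genuine many-fold-above-the-bulk outlier.  At least one tip
    is planted whenever ``outlier_fraction > 0``.
    """
    n = tree.n_tips
    n_out = int(np.floor(outlier_fraction * n))
    if outlier_fraction > 0:
        n_out = max(1, n_out)
    if n_out == 0 or outlier_multiplier == 1.0:
        return tree.copy(), ()
    rng = np.random.default_rng(seed)
    labels = sorted(tree.tip_labels)
    chosen = tuple(sorted(rng.choice(labels, size=n_out, replace=False)))
    grown = tree.copy()
    bulk_median = float(np.median([float(t.length) for t in grown.skbio_tree.tips()]))
    for t in grown.skbio_tree.tips():
        if t.name in chosen:
            t.length = outlier_multiplier * max(float(t.length), bulk_median)
    return PhyloTree(grown.skbio_tree), chosen


def evolve_niche_trait(tree: PhyloTree, seed: int = 0) -> pd.Series:
    """Brownian-motion trait along branches (variance = branch length).

    Close relatives end up with similar trait values — the niche-
    conservatism assumption that gives NTI/betaNTI their meaning.
    """
    rng = np.random.default_rng(seed)
    values: dict[int, float] = {id(tree.skbio_tree): 0.0}
    traits: dict[str, float] = {}
    for node in tree.skbio_tree.preorder(include_self=False):
        parent_value = values[id(node.parent)]
        step = rng.normal(0.0, np.sqrt(max(node.length or 0.0, 0.0)))
        values[id(node)] = parent_value + step
        if node.is_tip():
            traits[node.name] = values[id(node)]
    return pd.Series(traits, name="trait").loc[list(tree.tip_labels)]


# ---------------------------------------------------------------------------
# Communities
# ---------------------------------------------------------------------------

def _inclusion_probabilities(
    weights: np.ndarray, target_richness: float
) -> np.ndarray:
    """Scale raw inclusion weights so expected richness hits the target,
    respecting the [0, 1] cap (a few fixed-point iterations suffice)."""
    p = weights / weights.sum() * target_richness
    for _ in range(20):
        p = np.clip(p, 0.0, 1.0)
        shortfall = target_richness - p.sum()
        free = p < 1.0
        if abs(shortfall) < 1e-9 or not free.any():
            break
        p[free] *= 1.0 + shortfall / p[free].sum()
    return np.clip(p, 0.0, 1.0)


def simulate_communities(
    tree: PhyloTree,
    traits: pd.Series,
    config: ScenarioConfig,
    planted: tuple[str, ...] = (),
    seed: int = 0,
) -> tuple[CommunityDataset, ScenarioTruth]:
    """Draw sample communities on the tree under the configured regimes.

    Filtering regime: type optima are spread across the trait range
    (quantiles 0.15..0.85) and taxa enter a sample with probability
    proportional to a Gaussian kernel exp(-(trait-opt)^2 / 2 sigma^2),
    sigma = ``filtering_strength`` x trait SD, rescaled to the target
    expected richness.  Neutral regime: uniform inclusion at the same
    expected richness, so NTI contrasts reflect assembly rather than
    richness.  Included taxa get lognormal abundances; planted outlier
    taxa are rescaled to ``mean_outlier_abundance`` relative abundance.
    """
    rng = np.random.default_rng(seed)
    labels = list(tree.tip_labels)
    trait = traits.loc[labels].to_numpy()
    sd = trait.std()
    if sd == 0:
        sd = 1.0
    sigma = config.filtering_strength * sd

    types = list(config.sample_types)
    lo, hi = config.optima_quantiles
    qs = np.linspace(lo, hi, len(types)) if len(types) > 1 else np.array([0.5 * (lo + hi)])
    optima = {t: float(np.quantile(trait, q)) for t, q in zip(types, qs)}
    planted_mask = np.isin(labels, list(planted))

    rows: dict[str, np.ndarray] = {}
    meta_rows: dict[str, dict[str, str]] = {}
    regimes: dict[str, str] = {}
    for stype in types:
        regime = config.regime_of(stype)
        regimes[stype] = regime
        if regime == "filtering":
            weights = np.exp(-((trait - optima[stype]) ** 2) / (2 * sigma**2))
        elif regime == "neutral":
            weights = np.ones_like(trait)
        else:
            raise ValueError(f"unknown regime: {regime!r}")
        probs = _inclusion_probabilities(weights, min(config.target_richness, len(labels)))
        for i in range(config.samples_of(stype)):
            sid = f"{stype}_{i:02d}"
            for attempt in range(100):
                included = rng.random(len(labels)) < probs
                if included.sum() >= 2:
                    break
            else:
                raise DataModelError(f"sample {sid} drew <2 taxa in 100 attempts")
            abund = np.zeros(len(labels))
            abund[included] = rng.lognormal(mean=0.0, sigma=1.0, size=int(included.sum()))
            # planted outliers are rare: pin their relative abundance
            out_here = included & planted_mask
            if out_here.any():
                rest = abund[included & ~planted_mask].sum()
                if rest > 0:
                    abund[out_here] = config.mean_outlier_abundance * rest
            rows[sid] = abund
            meta_rows[sid] = {"sample_type": stype, "regime": regime}

    table = CommunityTable(pd.DataFrame.from_dict(rows, orient="index", columns=labels))
    metadata = SampleMetadata(pd.DataFrame.from_dict(meta_rows, orient="index"))
    dataset = CommunityDataset(table, tree, metadata)
    truth = ScenarioTruth(tuple(planted), regimes, optima, traits)
    return dataset, truth


def simulate_dataset(config: ScenarioConfig) -> tuple[CommunityDataset, ScenarioTruth]:
    """Full scenario: tree -> planted outliers -> traits -> communities.

    Traits are evolved on the *base* tree, before outlier branches are
    grown: a misclassified sequence is an artefact of classification, not
    an ecologically divergent organism, so its niche is unremarkable even
    though its branch is extreme.
    """
    base = simulate_tree(
        config.n_tips,
        config.tree_model,
        subseed(config.seed, "tree"),
        branch_model=config.branch_model,
        branch_scale=config.branch_scale,
        branch_cv=config.branch_cv,
        branch_log_sd=config.branch_log_sd,
    )
    defective, planted = plant_outliers(
        base,
        config.outlier_fraction,
        config.outlier_multiplier,
        subseed(config.seed, "outliers"),
    )
    traits = evolve_niche_trait(base, subseed(config.seed, "traits"))
    return simulate_communities(
        defective, traits, config, planted, subseed(config.seed, "communities")
    )
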