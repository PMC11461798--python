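# Methods

## Null models

`nti` and `bnti` implement the tip-label shuffle ("taxa.labels") null: each
replicate applies one uniform random permutation of *all* metacommunity tip
labels to the cophenetic distance matrix and recomputes the statistic. For
βNTI both communities are pushed through the same permutation, so taxa
shared between two samples remain shared under the null. The metacommunity
is always the full tip set of the dataset's tree; subsetting the dataset
(see below) is the only way the pool shrinks.

Sign conventions: `NTI = (null_mean − obs)/null_sd` so positive values mean
clustering, and `βNTI = (obs − null_mean)/null_sd` so values above +2 mean
heterogeneous and below −2 homogeneous selection. Classification uses
strict inequalities; |z| exactly at the threshold is called stochastic.
NTI defaults to presence/absence MNTD and βNTI to abundance-weighted
βMNTD, mirroring the defaults of the tools these metrics are usually
computed with; both expose a `weighted` flag.

Numerical choices:

* The distance matrix is divided by its maximum before the null loop. The
  deviate is mathematically scale-free; normalising first makes it
  numerically scale-free as well, so uniform branch rescaling reproduces z
  bit-for-bit under a fixed seed. Reported observed/null statistics stay on
  the input scale.
* A null standard deviation below `1e-12 · max(1, |null_mean|)` is treated
  as degenerate: the result carries `z = 0` with a `degenerate` flag and is
  classified stochastic. The tolerance matters because a sample containing
  the whole metacommunity yields null MNTDs that are the same multiset
  summed in different orders — float noise of ~1e-16 instead of an exact 0.
* Null replicates are vectorised (all permutations drawn as one argsort,
  statistic evaluated on stacked submatrices) and chunked to bound memory
  at ~160 MB regardless of community size.
* Reproducibility: dataset-level drivers derive per-sample and per-pair
  sub-seeds from the master seed by SHA-256 hashing of the identifiers
  (`subseed`), so results are independent of evaluation order and stable
  across processes. βNTI pair seeds hash the sorted id pair.

## Long-branch screen

`audit_tree` standardises each tip's terminal branch length (default) or
root-to-tip distance as a robust deviate
`(x − median) / (1.4826 · MAD)`; tips with score above the threshold
(default 5) are flagged. If the MAD is zero the normalised IQR
(`IQR/1.349`) substitutes; if that is also zero the data carry no spread
and nothing is flagged. Scoring is one-sided (only long branches are
suspicious) and never consults abundances — the targeted contaminants are
phylogenetically blatant but numerically rare. `max_iter > 1` prunes
flagged tips and re-screens, which can unmask secondary outliers whose
scores were diluted by more extreme ones. Flagged tips can be exported to
FASTA for external verification before removal.

A 5-MAD one-sided rule implies a false-positive budget set by the bulk's
tail: effectively zero for a near-normal bulk, ~0.3% per tip for a
lognormal bulk with log-SD 0.4, and ~1.2% at log-SD 0.6. The screen is a
bulk-versus-extreme separator, not a general heavy-tail outlier test.

## Similarity impact

`compare_datasets` compares each sample's full vector against its filtered
vector on the union taxon space, with both UniFrac variants computed on the
*full* tree so removed taxa contribute their unique branches. Weighted
UniFrac uses the normalised variant (distances in [0, 1], similarity
`1 − d`) on per-sample relative abundances, since taxon removal changes
library size. Compositions are scaled to parts-per-1e8 integer counts
before the UniFrac calls (the backend truncates count vectors to
integers); the discretisation error is below 1e-6. Edge lengths above the
root are discarded at tree construction — such an edge would count as
branch length shared by every tip set and silently inflate similarities.

## Phylogenetic signal

Categorical sample variables are one-hot encoded (the only encoding that
makes an abundance-weighted mean of categories well-defined); each taxon's
environmental optimum is its relative-abundance-weighted mean encoded
environment. Optimum distances are Euclidean; phylogenetic distances are
divided by their maximum before binning. Distance classes follow Sturges'
rule on the pair count (overridable); the per-class Mantel statistic is the
Pearson correlation between optimum distances and class membership,
sign-flipped so positive r means within-class pairs are more similar.
Permutation p-values shuffle taxon labels of the optimum matrix,
`p = (1 + #{r_perm ≥ r_obs})/(n_perm + 1)` for the positive tail
(1000 permutations by default), Holm-corrected progressively (class k is
corrected within the first k tested classes, then a running maximum
enforces monotonicity). Classes with fewer than two pairs are skipped with
a warning. `signal_check` reports signal when at least one class in the
shortest third of tested classes has positive r and corrected p < 0.05.

## Perturbation pipeline

`outlier_impact` chains audit → removal → similarity → null models;
`richness_impact` re-estimates the statistics under reduced
metacommunities defined by metadata predicates, dropping unobserved taxa
from both table and tree so the null pool genuinely shrinks. Before/after
runs share per-unit sub-seeds, making paired deltas reflect the
perturbation rather than Monte-Carlo noise. Conclusion changes are
tabulated per sample type as before × after cross-tabulations with
percentages to one decimal place (cell percentages are group-relative; the
cell counts allow any other denominator).

## Synthetic data

The generator emulates the structure of host-associated amplicon surveys:

* **Tree.** Birth-death (pure-birth) or Kingman coalescent topology.
  Branch lengths default to iid truncated-normal draws
  (`branch_scale = 0.05` substitutions/site, CV 0.2): short-marker gene
  trees have pendant edges clustered within a few fold of each other, and
  a concentrated bulk is what makes a ten-fold outlier branch meaningful.
  An iid-lognormal mode (log-SD 0.4 by default) provides a skewed bulk for
  stress-testing the screen, and a clock mode preserves simulator times
  (used for coalescent distributional checks: expected height 2(1 − 1/n)).
* **Planted outliers.** A fraction (default 1.2%, ≥1 tip) of tips get
  terminal branch `multiplier × max(own length, bulk median)` (default
  10×). The floor guarantees every planted tip is a genuine many-fold
  outlier even if it sat on a near-zero pendant edge; traits are evolved
  on the *base* tree because a misclassified sequence is an artefact of
  classification, not an ecologically divergent organism.
* **Communities.** A Brownian-motion niche trait evolves along branches.
  Under the filtering regime each sample type has a trait optimum (type
  optima at quantiles 0.2–0.8 of the trait distribution by default) and
  taxa enter samples with probability ∝ exp(−(trait − optimum)²/2σ²),
  σ = 0.3 × trait SD, rescaled to an expected per-sample richness of 50
  on the default 200-tip tree (a gut-like ~25% pool occupancy that gives
  the null models adequate power). The neutral regime uses uniform
  inclusion at the same expected richness, so NTI contrasts reflect
  assembly, not richness. Included taxa receive lognormal(0, 1)
  abundances; planted outliers present in a sample are pinned to ~0.1%
  relative abundance. The default design is fish-dominated
  (16 fish / 6 rearing-water / 4 intake-water samples), echoing surveys
  where the host compartment is sampled most densely.
* **Ground truth.** Every dataset carries the planted tip set, per-type
  regimes and optima, and the trait vector.

With these defaults, filtering-regime datasets are phylogenetically
clustered (mean NTI ≈ 2.2–3.6 across seeds) and carry detectable
phylogenetic signal; neutral datasets are calibrated (mean NTI ≈ 0,
|z| > 2 in ≈5% of random communities). Subsetting to fish + rearing water
sheds ≈20–25% of the regional pool; narrowing the optima spread
(`optima_quantiles=(0.35, 0.65)`) brings the one-type (fish-only) loss
into the 20–45% range typical of real surveys, at somewhat weaker
clustering.

What the generator does **not** emulate: compositional zero-inflation and
sequencing-depth variation, taxon-taxon interactions, multiple correlated
niche axes, and phylogenetic placement error beyond the planted pendant
edges. Passing tests therefore demonstrate correctness of the machinery
and the direction/order-of-magnitude of the distortions, not quantitative
agreement with any particular survey.

## Problem sizes

Simulation-based checks use 200–300-tip trees (500 for the
outlier-removal direction test, where ≥6 planted outliers make the paired
effect visible above Monte-Carlo noise), 26 samples, 99–999 null
replicates per estimate and 20 replicate datasets per directional claim;
exhaustive-permutation oracles run on trees of ≤7 tips where all n!
label permutations are enumerable. These sizes were chosen so each claim
is tested at comfortable statistical resolution.

## Known limitations

* The tip-shuffle null is the only null model offered (no frequency- or
  richness-preserving swaps, no Raup–Crick).
* Branch-length outliers are the only screened defect; chimeras or
  placement errors that do not produce long branches pass silently.
* The Mantel correlogram tests one-hot categorical environments only;
  continuous variables would need standardisation choices this package
  does not make.
* Rooting is trusted from the input; `reroot_longest_branch` (midpoint of
  the single longest branch, ties broken by smallest subtree tip label) is
  provided as a deterministic convention, not a claim about optimal
  rooting.
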