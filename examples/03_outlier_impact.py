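"""How removing rare long-branch taxa changes community similarity and
assembly conclusions.

Generates a filtering-regime dataset with planted outliers (~0.1% mean
relative abundance), removes them, and compares each sample's composition
before vs after with four similarity indices, then re-estimates NTI with
shared seeds so paired differences isolate the perturbation.
"""

import phylonull as pn

ds, truth = pn.simulate_dataset(pn.ScenarioConfig(n_tips=300, seed=0))
impact = pn.outlier_impact(ds, n_null=499, seed=3, bnti_grouping=None)

print(f"tips flagged and removed: {len(impact.report.flagged)} "
      f"(planted: {len(truth.planted_outliers)})")
print("\nmean full-vs-filtered similarity per index:")
print(impact.similarity.groupby("metric")["similarity"].mean().round(4).to_string())
print("\nabundance-based indices barely move (the removed taxa are rare);")
print("presence-based tree-aware similarity (unweighted UniFrac) drops,")
print("because the removed tips subtend long branches.\n")

d = impact.nti_deltas["delta"]
print(f"NTI change after removal: mean {d.mean():+.3f} "
      f"({(d > 0).mean() * 100:.0f}% of samples increased)")
for t in impact.nti_changes:
    print(f"  sample type {t.group}: {t.pct_changed}% of conclusions changed")
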