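"""The recommended robustness protocol: re-estimate NTI/betaNTI under
reduced metacommunities and count conclusion changes.

Drops sample types from a simulated survey (fish + rearing water + intake
water), shrinks the regional taxon pool to what the remaining samples
observed, and re-runs the null models with shared per-unit seeds.  A
conclusion that flips under modest pool changes was never robust.
"""

import phylonull as pn

ds, _ = pn.simulate_dataset(pn.ScenarioConfig(seed=21, outlier_fraction=0.0))
subsets = {
    "fish+rearing": {"sample_type": ["fish", "rearing_water"]},
    "fish_only": {"sample_type": ["fish"]},
}
results = pn.richness_impact(ds, subsets, n_null=499, seed=9)

print(f"full metacommunity: {len(ds.taxon_ids)} taxa\n")
for res in results:
    nti_d = res.nti_deltas["delta"]
    bnti_d = res.bnti_deltas["delta"]
    print(f"subset {res.subset_name}: {len(res.dataset.taxon_ids)} taxa "
          f"({res.taxa_lost_fraction * 100:.1f}% of the pool lost)")
    print(f"  mean NTI change  {nti_d.mean():+.2f}   mean betaNTI change {bnti_d.mean():+.2f}")
    for t in res.nti_changes:
        print(f"  NTI conclusions changed in group {t.group}: {t.pct_changed}%")
    print()
print("Shrinking the pool makes null communities resemble the observed ones:"
      "\nNTI falls and betaNTI rises, pushing borderline calls across the"
      "\n+-2 threshold - exactly why the metacommunity definition must be"
      "\nreported and stress-tested.")
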