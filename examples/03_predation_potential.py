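"""Predation potential: a consumption-weighted community abundance score.

Each species' captures are weighted by its published per-capita aphid
consumption rate (scaled so a rate of 100 aphids/day has weight 1), giving a
single community-level index of the biological-control service the trapped
assemblage could deliver.  The score drops into the same trend machinery as
plain capture counts.
"""

import coccitrend as ct

config, species = ct.study_default_scenario()
registry = ct.registry_from_profiles(species)
aggregates = ct.aggregate(ct.cull(ct.generate_scenario(config, species)), registry)
habitat_map = ct.HabitatMap(dict(config.treatments))

weights = ct.PredationWeights.from_registry(registry)
table = weights.as_dict()
print("per-species weights (consumption rate / 100):")
for name in sorted(table)[:5]:
    print(f"  {name}: {table[name]:.2f}")
print("  ...")

series = ct.series_by_group(aggregates, habitat_map, "predation", weights)
fits = ct.phase_analysis(series)
overall = fits[0]
print(f"\npredation potential, 1993-2023: {overall.pct_change_total:+.1f}% total "
      f"({overall.pct_change_per_year:+.1f}%/year), p = {overall.p_value:.2g}")
for f in fits[1:]:
    print(f"  phase {f.label} ({f.window[0]}-{f.window[1]}): "
          f"{f.pct_change_total:+.1f}% total, p = {f.p_value:.2g}")

# The score also feeds the GAM exactly like a count series.
fit = ct.fit_gam(series)
t = ct.smooth_significance(fit)
print(f"\nGAM smooth: edf = {t.edf:.2f}, F = {t.F:.1f}, p = {t.p_value:.2g}")
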