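"""Simulate a 31-year trap-capture survey and estimate phase-wise trends.

Walks the first half of the analysis chain: generate synthetic trap records
under the default study design, apply the standard culling rules, aggregate
to analysis units, and fit simple linear regressions of captures per trap
against year — for the whole series and for each dynamical phase.
"""

import coccitrend as ct

# The default scenario: 14 species (10 native, 4 exotic), 10 treatments in
# three habitat classes, 6 replicates, weekly traps from 1993 to 2023.
config, species = ct.study_default_scenario()
records = ct.generate_scenario(config, species)
print(f"generated {len(records):,} trap records "
      f"({records['year'].min()}-{records['year'].max()})")

# Culling keeps years >= 1993 and days of year <= 222 (the consistently
# sampled part of every season).
culled = ct.cull(records)
print(f"{len(records) - len(culled):,} records culled, {len(culled):,} kept")

# Aggregate to (treatment, replicate, year) units: per-species capture sums
# plus native/exotic/all group rows, with effort = number of trap-weeks.
registry = ct.registry_from_profiles(species)
aggregates = ct.aggregate(culled, registry)
habitat_map = ct.HabitatMap(dict(config.treatments))

# Whole-series and phase-wise linear trends for native species combined.
series = ct.series_by_group(aggregates, habitat_map, "native")
fits = ct.phase_analysis(series)
print("\nnative captures per trap, linear trends:")
print(f"{'window':>12} {'slope':>8} {'p':>8} {'total %':>8} {'%/year':>7}")
for f in fits:
    stars = "*" if f.significant else " "
    print(f"{f.label:>12} {f.slope:8.4f} {f.p_value:8.2g} "
          f"{f.pct_change_total:8.1f} {f.pct_change_per_year:7.1f}{stars}")
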