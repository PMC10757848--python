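"""Apply the data-quality edits and contemporary grouping.

Yield bounds 0.5–45 kg, 400-day DIM cap, age-at-first-calving window
21–60 months, birth years 1980–2019, at least 10 records per cow, and
year-season groups of at least 5 cows.
"""

from milkres import (
    SimulationConfig,
    apply_record_filters,
    build_year_season_groups,
    simulate_herd,
)

herd = simulate_herd(SimulationConfig(n_base_animals=40, n_cows=150, seed=42))
records, meta, log = apply_record_filters(herd.records, herd.meta)

print("edit log (rule -> rows removed, in application order):")
for rule, n in log.items():
    print(f"  {rule:30s} {n}")

meta, census = build_year_season_groups(meta)
print(f"\nyear-season groups: {len(census)}, "
      f"{meta['ys_excluded'].sum()} cows in groups below the 5-cow minimum")
print(census.head(8).to_string(index=False))
# Cows flagged ys_excluded keep their records but sit out the fixed-
# effect and genetic analyses, which fit year-season as a factor.
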