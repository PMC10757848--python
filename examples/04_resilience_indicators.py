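"""Compute the seven resilience phenotypes for every cow.

LnVar (log variance of deviations; lower = more resilient), r_auto
(lag-1 autocorrelation; lower = faster recovery), Skew (less negative =
more resilient against milk-depressing disturbances); each from actual
(1) and standardized (2) deviations, plus RawVar and average yield.
"""

from milkres import (
    SimulationConfig,
    apply_record_filters,
    assemble_phenotypes,
    build_year_season_groups,
    compute_deviations,
    fit_all_curves,
    four_sd_edit,
    simulate_herd,
)

herd = simulate_herd(SimulationConfig(n_base_animals=40, n_cows=150, seed=42))
records, meta, _ = apply_record_filters(herd.records, herd.meta)
meta, _ = build_year_season_groups(meta)

fits, _ = fit_all_curves(records, tau=0.7)
devs = {a: compute_deviations(g, fits[a]) for a, g in records.groupby("animal_id")}
pheno = assemble_phenotypes(devs, records, meta)

for col in ("lnvar1", "lnvar2", "rauto1", "skew1", "rawvar"):
    pheno[col], n = four_sd_edit(pheno[col])  # >4 SD from the mean -> missing

print(pheno[["animal_id", "lnvar1", "lnvar2", "rauto1", "rauto2",
             "skew1", "skew2", "rawvar", "amy"]].head(8).round(3).to_string(index=False))
print("\ncolumn means:")
print(pheno[["lnvar1", "lnvar2", "rauto1", "rauto2", "skew1", "skew2",
             "rawvar", "amy"]].mean().round(3))
# lnvar2 is negative because standardized deviations are ratios (~15%
# of expectation), so their variance is far below 1.
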