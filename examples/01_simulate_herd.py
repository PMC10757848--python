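"""Simulate a small pedigreed dairy herd and look at its structure.

Generates 150 cows in three agroecological zones with test-day milk
records every 14 days, then prints the herd census and a few records.
"""

from milkres import SimulationConfig, simulate_herd

herd = simulate_herd(SimulationConfig(n_base_animals=40, n_cows=150, seed=42))

print(f"pedigree: {len(herd.pedigree)} animals "
      f"({herd.pedigree.is_founder().sum()} founders)")
print(f"records : {len(herd.records)} test-day milk weights")
print("\ncows per zone / breed group:")
print(herd.meta.groupby(["env", "breed_group"]).size().unstack(fill_value=0))
print("\nfirst records of one cow (yield in kg at each day in milk):")
print(herd.records.head(6).to_string(index=False))
print("\nexit records (death from disease / disposal for slaughter):",
      len(herd.longevity))
# The simulated truth (breeding values, disturbance episodes) rides
# along in herd.true_values for parameter-recovery experiments.
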