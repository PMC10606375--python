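"""Replicate metrics and the per-timepoint formulation comparison.

Generates noisy synthetic permeation datasets for the cream and ointment
(5 replicates each, 15 % multiplicative lognormal noise, seeded), then runs
the per-timepoint one-way ANOVA between the two groups — the analysis used
to ask at which sampling times the formulations differ significantly.
"""

import logging

from dermasim import metrics, presets, synth

logging.basicConfig(level=logging.WARNING)

datasets = {}
for vehicle in ("cream", "ointment"):
    cfg = presets.default_config("ivpt", vehicle)
    datasets[vehicle] = synth.generate_dataset(
        cfg, synth.NoiseModel(replicate_cv=0.15, n_replicates=5, seed=42),
        group=vehicle)

table = metrics.compare_groups_per_timepoint(datasets["cream"],
                                             datasets["ointment"])
print("time_h   F-stat     p-value   significant")
for row in table:
    print(f"{row['time_h']:5.0f}  {row['f_stat']:9.3f}  {row['p_value']:9.4f}"
          f"   {'*' if row['significant'] else ''}")

print("\n'*' marks sampling times where the cumulative permeation of the two")
print("formulations differs at the 95 % confidence level (raw p-values, one")
print("test per time point, mirroring the usual Franz-cell reporting).")
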