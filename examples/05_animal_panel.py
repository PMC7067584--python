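"""Summarise modularity across a panel of animals, one feature at a time.

Simulates a 15-animal panel (40 cells each) in which one feature is truly
continuous and another truly modular, estimates k_est per animal, and
compares the count of animals detected as modular against the expected
rates under a continuous null (~0.07) and under an always-modular
alternative (~0.8) with exact binomial tests.
"""

import numpy as np

from modgap import (
    animal_panel_summary,
    calibrate_thresholds,
    make_mixture_spec,
    sample_modular,
    FeatureSample,
)
from modgap.power import panel_to_frame

rng = np.random.default_rng(8)
spec = make_mixture_spec(2, separation_sd=5.0)
panel = []
for i in range(15):
    panel.append(FeatureSample(f"mouse{i + 1:02d}", "continuous_feature", rng.random(40)))
    panel.append(sample_modular(40, spec, rng=rng, animal_id=f"mouse{i + 1:02d}",
                                feature_name="modular_feature"))

table = calibrate_thresholds(n=40, kmax=8, alpha_per_k=0.01, null_reps=1000, B=100, seed=0)
summaries = animal_panel_summary(panel, table, p0_null=0.07, p0_modular=0.8,
                                 rng=9, min_n=34)
print(panel_to_frame(summaries).to_string(index=False))
for name, s in summaries.items():
    print(f"{name}: k_est histogram (k=1..8) = {s.k_histogram(8).tolist()}")

# The continuous feature should be detected in ~1 of 15 animals (p_vs_null
# large, p_vs_modular < 1e-6); the modular feature in most animals
# (p_vs_null < 1e-6), mirroring how per-animal panels discriminate the two
# hypotheses.
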