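"""Simulate three annotators and tabulate inter-observer reliability.

The noise model is calibrated so that the per-axis SD of the displacement
*between two annotators* is 0.74 mm, which puts ~97.5% of pairwise
landmark distances within 2 mm — the level reported for experienced
radiologists annotating cervical radiographs.
"""

import numpy as np

import cervimotion as cm
from cervimotion.metrics import reliability_table

rng = np.random.default_rng(0)
noise = cm.NoiseModel(sigma_mm=0.74)

pairs_by_view = {view: [] for view in cm.VIEWS}
for k in range(25):
    profile = cm.sample_motion_profile(rng=rng)
    case = cm.build_case(f"c{k}", profile)
    for view_name, view in case.views().items():
        r1, r2, r3 = cm.simulate_annotators(view, noise, rng=rng)
        pairs_by_view[view_name] += [(r1, r2), (r1, r3), (r2, r3)]

table = reliability_table(pairs_by_view)
print(table.round(1).to_string(index=False))
print()
print("Percentages of pairwise landmark distances within 1/2/3 mm, pooled")
print("over cases and annotator pairs per view; ~60/97.5/100% is the")
print("expected Rayleigh profile at the default calibration (the 2 mm")
print("level is the one the model is calibrated to).")
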