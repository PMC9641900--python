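"""A full simulated observer study: model-style vs reference measurements.

Simulates 50 cases annotated by three noisy annotators plus one
independent 'model' annotator, measures SIRM for everyone, and produces
the per-segment agreement panel (ICC, Pearson r, mean difference, SD,
RMSE, MAE, Bland-Altman limits) of the model against the reference
standard (the mean of the three annotators' measurements).
"""

import numpy as np

import cervimotion as cm
from cervimotion.geometry import measure_case
from cervimotion.metrics import agreement_table, reference_standard

rng = np.random.default_rng(1)
noise = cm.NoiseModel(sigma_mm=0.74)

model_rows, ref_rows = [], []
for k in range(50):
    profile = cm.sample_motion_profile(rng=rng)
    case = cm.build_case(f"c{k:03d}", profile)
    ref_views, model_views = {}, {}
    for name, view in case.views().items():
        ref_views[name] = reference_standard(cm.simulate_annotators(view, noise, rng=rng))
        model_views[name] = cm.perturb_annotations(
            view, noise.annotator_sigma_mm, rng=rng, annotator="model"
        )
    ref_rows.append(measure_case(cm.CaseTriple(case.case_id, **ref_views)).to_frame())
    model_rows.append(measure_case(cm.CaseTriple(case.case_id, **model_views)).to_frame())

import pandas as pd

model = pd.concat(model_rows, ignore_index=True)
ref = pd.concat(ref_rows, ignore_index=True)
table = agreement_table(model, ref, seed=0)
cols = ["pair", "segment", "icc", "r", "mean_diff", "sd_diff", "rmse", "mae",
        "loa_low", "loa_high", "p_value"]
print(table[cols].round(2).to_string(index=False))
print()
print("One row per segment x motion pair; LoA are the Bland-Altman 95%")
print("limits.  Both methods carry independent landmark noise, which")
print("propagates to a SIRM difference SD of ~4 deg at these vertebral")
print("dimensions, so ICC/r are moderate and track each segment's true")
print("motion variance (lowest at C2/3, whose motion range is smallest --")
print("the same segment that is hardest to measure reliably in practice).")
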