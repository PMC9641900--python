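"""Train the desk-scale landmark detector on synthetic renders.

Renders a small training/validation/test split of synthetic lateral
views, trains the two-branch heatmap-regression network on one CPU, and
reports held-out localization accuracy (PCK).  Uses a reduced epoch count
so the demo finishes in about a minute; the package default (90 epochs)
does better.
"""

import numpy as np

import cervimotion as cm
from cervimotion.detector import DetectorConfig, predict_landmarks, train_detector


def render_samples(n, rng):
    template, rcfg = cm.SpineTemplate(), cm.RenderConfig()
    samples = []
    for k in range(n):
        profile = cm.sample_motion_profile(rng=rng)
        view = cm.build_view_landmarks(
            template, profile, list(cm.VIEWS)[k % 3],
            pose_rotation_deg=float(rng.uniform(-6, 6)),
            spacing_mm=rcfg.spacing_mm, image_size_px=rcfg.image_size_px,
        )
        samples.append((cm.render_view(view, rcfg, rng=rng), view.coords()))
    return samples


rng = np.random.default_rng(0)
train, val, test = render_samples(120, rng), render_samples(30, rng), render_samples(30, rng)

cfg = DetectorConfig(seed=0, epochs=30)
model, history = train_detector(train, val, cfg)
print(history.tail(3).round(5).to_string(index=False))

errors = []
for image, landmarks in test:
    ann, confidence, flags = predict_landmarks(model, image, spacing_mm=1.0)
    errors.append(np.linalg.norm(ann.coords() - landmarks, axis=1))
errors = np.concatenate(errors)
print(f"\nheld-out median error {np.median(errors):.2f} px; "
      f"PCK@4px {np.mean(errors <= 4) * 100:.1f}%")
print("PCK@4px is the share of predicted landmarks within 4 px (one")
print("heatmap cell) of ground truth on images the model never saw.")
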