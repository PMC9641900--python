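import numpy as np
import pytest

import cervimotion as cm
from cervimotion.landmarks import SCHEME


@pytest.fixture(scope="session")
def flat_profile():
    """Zero-motion profile (all segmental rotations zero)."""
    zero = {s: 0.0 for s in cm.SEGMENTS}
    return cm.MotionProfile(fn_deg=dict(zero), ne_deg=dict(zero))


@pytest.fixture(scope="session")
def example_profile():
    """A fixed, hand-chosen motion profile used across geometry tests."""
    fn = dict(zip(cm.SEGMENTS, [3.0, 5.0, 7.0, 6.0, 4.0]))
    ne = dict(zip(cm.SEGMENTS, [2.0, 4.0, 5.0, 3.0, 2.0]))
    return cm.MotionProfile(fn_deg=fn, ne_deg=ne)


@pytest.fixture()
def neutral_view(flat_profile):
    return cm.build_view_landmarks(cm.SpineTemplate(), flat_profile, "neutral")


def make_render_samples(n, rng, render_cfg=None):
    """Rendered (image, landmarks) pairs drawn from the population defaults."""
    template = cm.SpineTemplate()
    rcfg = render_cfg or cm.RenderConfig()
    samples = []
    views = list(cm.VIEWS)
    for k in range(n):
        profile = cm.sample_motion_profile(rng=rng)
        rot = float(rng.uniform(-6, 6))
        trans = tuple(rng.uniform(-4, 4, 2))
        try:
            view = cm.build_view_landmarks(
                template, profile, views[k % 3],
                pose_rotation_deg=rot, pose_translation_mm=trans,
                spacing_mm=rcfg.spacing_mm, image_size_px=rcfg.image_size_px,
            )
        except cm.CervimotionError:
            view = cm.build_view_landmarks(
                template, profile, views[k % 3],
                spacing_mm=rcfg.spacing_mm, image_size_px=rcfg.image_size_px,
            )
        samples.append((cm.render_view(view, rcfg, rng=rng), view.coords()))
    return samples


def full_points(dx=0.0, dy=0.0):
    """A simple valid 22-point layout (stacked rectangles), pixel coords."""
    pts = {}
    y = 20.0
    pts["2-B3"] = (80.0 + dx, y + dy)
    pts["2-B4"] = (40.0 + dx, y + dy)
    y += 10
    for level in range(3, 8):
        pts[f"{level}-G1"] = (80.0 + dx, y + dy)
        pts[f"{level}-G2"] = (40.0 + dx, y + dy)
        pts[f"{level}-G3"] = (80.0 + dx, y + 13 + dy)
        pts[f"{level}-G4"] = (40.0 + dx, y + 13 + dy)
        y += 18
    assert set(pts) == set(SCHEME.ids)
    return pts
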