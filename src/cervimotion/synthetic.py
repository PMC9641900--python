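"""Articulated synthetic cervical spine: landmark sets, noise, renders.

The generator produces three-posture (flexion / neutral / extension)
landmark sets with known ground-truth segmental rotations, so the geometry,
metrics and detector modules are all testable without clinical data.

Model
-----
Vertebral bodies C3-C7 are rigid rectangles (default 16 mm wide, 13 mm
high) stacked caudal-to-cranial as a kinematic chain with a 5 mm
inter-body gap; C2 contributes only its inferior edge.  Each cranial
vertebra is rotated about the midpoint of the gap below it by the segment's
posture-dependent angle:

* neutral: a baseline lordosis (default 2 deg per segment),
* flexion: baseline - fn (the flexion-to-neutral rotation),
* extension: baseline + ne (the neutral-to-extension rotation),

so a case's measured SIRM equals (fn, ne, fn + ne) by construction.  The
per-segment (fn, ne) population defaults are the reference-standard means
and SDs reported for an adult clinical cohort, which makes the simulated
motion ranges realistic per segment (largest at C4/5-C5/6, smallest at
C2/3 and C6/7 on N/E).

Annotation noise is isotropic Gaussian per landmark.  ``sigma_mm`` is
calibrated on the *pairwise inter-annotator* displacement (per-axis SD of
the difference between two annotators); the default 0.74 mm puts ~97.5% of
pairwise landmark distances within 2 mm, matching reported inter-observer
reliability.  A single simulated annotator therefore deviates from the
consensus by sigma/sqrt(2) per axis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage
from skimage.draw import polygon as _polygon

from .errors import InvalidSplit, NegativeSD, OutOfFrame
from .geometry import SEGMENTS, measure_case
from .landmarks import SCHEME, CaseTriple, ViewAnnotation, VIEWS

#: per-segment (mean, SD) of the flexion->neutral rotation, degrees
FN_PARAMS = {
    "C2/3": (3.87, 2.19),
    "C3/4": (6.24, 3.49),
    "C4/5": (7.05, 3.69),
    "C5/6": (7.50, 4.08),
    "C6/7": (7.79, 4.01),
}
#: per-segment (mean, SD) of the neutral->extension rotation, degrees
NE_PARAMS = {
    "C2/3": (2.87, 1.74),
    "C3/4": (4.73, 3.47),
    "C4/5": (5.76, 3.84),
    "C5/6": (4.43, 2.93),
    "C6/7": (2.70, 1.90),
}


@dataclass(frozen=True)
class SpineTemplate:
    """Rigid-body dimensions of the simulated cervical spine (mm)."""

    body_width_mm: float = 16.0
    body_height_mm: float = 13.0
    gap_mm: float = 5.0
    baseline_theta_deg: float = 2.0  # neutral lordosis per segment

    def __post_init__(self):
        if min(self.body_width_mm, self.body_height_mm, self.gap_mm) <= 0:
            raise ValueError("all template dimensions must be > 0")


@dataclass(frozen=True)
class MotionProfile:
    """Ground-truth signed segmental rotations of one case (degrees)."""

    fn_deg: dict[str, float]
    ne_deg: dict[str, float]

    @property
    def fe_deg(self) -> dict[str, float]:
        return {s: self.fn_deg[s] + self.ne_deg[s] for s in SEGMENTS}

    def sirm(self, segment: str, pair: str) -> float:
        return {"F/N": self.fn_deg, "N/E": self.ne_deg, "F/E": self.fe_deg}[pair][segment]


@dataclass(frozen=True)
class NoiseModel:
    """Isotropic per-landmark annotation noise.

    ``sigma_mm`` is the per-axis SD of the *pairwise* inter-annotator
    displacement; individual simulated annotators use sigma/sqrt(2).
    """

    sigma_mm: float = 0.74
    seed: int = 0

    def __post_init__(self):
        if self.sigma_mm < 0:
            raise NegativeSD(f"sigma_mm must be >= 0, got {self.sigma_mm}")

    @property
    def annotator_sigma_mm(self) -> float:
        return self.sigma_mm / np.sqrt(2.0)


def sample_motion_profile(
    fn_params: dict[str, tuple[float, float]] | None = None,
    ne_params: dict[str, tuple[float, float]] | None = None,
    *,
    rng: np.random.Generator | int | None = None,
) -> MotionProfile:
    """Draw per-segment (fn, ne) rotations from independent normals."""
    fn_params = fn_params or FN_PARAMS
    ne_params = ne_params or NE_PARAMS
    for params in (fn_params, ne_params):
        for seg, (_, sd) in params.items():
            if sd < 0:
                raise NegativeSD(f"{seg}: SD {sd} < 0")
    rng = np.random.default_rng(rng)
    fn = {s: float(rng.normal(*fn_params[s])) for s in SEGMENTS}
    ne = {s: float(rng.normal(*ne_params[s])) for s in SEGMENTS}
    return MotionProfile(fn_deg=fn, ne_deg=ne)


def _rot(deg: float) -> np.ndarray:
    r = np.radians(deg)
    c, s = np.cos(r), np.sin(r)
    return np.array([[c, -s], [s, c]])


def _segment_angles(template: SpineTemplate, profile: MotionProfile, view: str) -> dict[str, float]:
    base = template.baseline_theta_deg
    if view == "neutral":
        return {s: base for s in SEGMENTS}
    if view == "flexion":
        return {s: base - profile.fn_deg[s] for s in SEGMENTS}
    if view == "extension":
        return {s: base + profile.ne_deg[s] for s in SEGMENTS}
    raise ValueError(f"unknown view {view!r}")


def spine_landmarks_mm(
    template: SpineTemplate,
    profile: MotionProfile,
    view: str,
    *,
    pose_rotation_deg: float = 0.0,
    pose_translation_mm: tuple[float, float] = (0.0, 0.0),
) -> dict[str, np.ndarray]:
    """Forward kinematics: all 22 landmarks in the metric y-up frame (mm).

    The patient faces +x (anterior corners at larger x).  C7 is placed at
    the pose; each cranial vertebra adds its segmental angle at the
    inter-body gap midpoint.
    """
    seg_angle = _segment_angles(template, profile, view)
    w, h, gap = template.body_width_mm, template.body_height_mm, template.gap_mm

    def corners(center, tilt):
        R = _rot(tilt)
        # local frame: +x anterior, +y superior
        return {
            "G1": center + R @ np.array([+w / 2, +h / 2]),
            "G2": center + R @ np.array([-w / 2, +h / 2]),
            "G3": center + R @ np.array([+w / 2, -h / 2]),
            "G4": center + R @ np.array([-w / 2, -h / 2]),
        }

    pts: dict[str, np.ndarray] = {}
    tilt = float(pose_rotation_deg)
    center = np.asarray(pose_translation_mm, dtype=float)
    # C7 upward: segments in caudal->cranial order
    chain = [("C7", None), ("C6", "C6/7"), ("C5", "C5/6"), ("C4", "C4/5"), ("C3", "C3/4")]
    for vertebra, segment in chain:
        if segment is not None:
            top = center + _rot(tilt) @ np.array([0.0, h / 2])
            pivot = top + _rot(tilt) @ np.array([0.0, gap / 2])
            tilt = tilt + seg_angle[segment]
            center = pivot + _rot(tilt) @ np.array([0.0, gap / 2 + h / 2])
        level = vertebra[1]
        for code, xy in corners(center, tilt).items():
            pts[f"{level}-{code}"] = xy
    # C2: inferior edge only, one gap above C3
    top = center + _rot(tilt) @ np.array([0.0, h / 2])
    pivot = top + _rot(tilt) @ np.array([0.0, gap / 2])
    tilt = tilt + seg_angle["C2/3"]
    edge_center = pivot + _rot(tilt) @ np.array([0.0, gap / 2])
    pts["2-B3"] = edge_center + _rot(tilt) @ np.array([+w / 2, 0.0])
    pts["2-B4"] = edge_center + _rot(tilt) @ np.array([-w / 2, 0.0])
    return pts


def build_view_landmarks(
    template: SpineTemplate,
    profile: MotionProfile,
    view: str,
    *,
    pose_rotation_deg: float = 0.0,
    pose_translation_mm: tuple[float, float] = (0.0, 0.0),
    spacing_mm: float = 0.143,
    image_size_px: tuple[int, int] | None = None,
    margin_mm: float = 8.0,
    annotator: str = "ground-truth",
) -> ViewAnnotation:
    """Project the kinematic chain to pixel coordinates as a ViewAnnotation.

    Without ``image_size_px`` the canvas is sized to fit the landmarks plus
    ``margin_mm`` on every side.  With it, the landmark cloud is centered on
    the canvas and :class:`OutOfFrame` is raised if it does not fit.
    """
    pts_mm = spine_landmarks_mm(
        template, profile, view,
        pose_rotation_deg=pose_rotation_deg,
        pose_translation_mm=pose_translation_mm,
    )
    xy = np.array([pts_mm[i] for i in SCHEME.ids])
    lo = xy.min(axis=0)
    hi = xy.max(axis=0)
    if image_size_px is None:
        width = int(np.ceil((hi[0] - lo[0] + 2 * margin_mm) / spacing_mm)) + 1
        height = int(np.ceil((hi[1] - lo[1] + 2 * margin_mm) / spacing_mm)) + 1
        origin_x = lo[0] - margin_mm
        top_y = hi[1] + margin_mm
    else:
        # center the untranslated chain on the canvas so the pose
        # translation shows up as an in-image shift
        width, height = image_size_px
        mid = (lo + hi) / 2 - np.asarray(pose_translation_mm, dtype=float)
        origin_x = mid[0] - (width - 1) / 2 * spacing_mm
        top_y = mid[1] + (height - 1) / 2 * spacing_mm
    points = {
        lid: (
            (pts_mm[lid][0] - origin_x) / spacing_mm,
            (top_y - pts_mm[lid][1]) / spacing_mm,
        )
        for lid in SCHEME.ids
    }
    if image_size_px is not None:
        for lid, (x, y) in points.items():
            if not (0 <= x <= width - 1 and 0 <= y <= height - 1):
                raise OutOfFrame(
                    f"{lid} at ({x:.1f}, {y:.1f}) px outside {width}x{height} canvas"
                )
    return ViewAnnotation(
        view=view,
        points=points,
        pixel_spacing_mm=spacing_mm,
        image_size_px=(width, height),
        facing="right",
        annotator=annotator,
    )


def build_case(
    case_id: str,
    profile: MotionProfile,
    template: SpineTemplate | None = None,
    *,
    poses: dict[str, tuple[float, tuple[float, float]]] | None = None,
    **view_kw,
) -> CaseTriple:
    """Build the flexion/neutral/extension triple of one case."""
    template = template or SpineTemplate()
    poses = poses or {}
    views = {}
    for view in VIEWS:
        rot, trans = poses.get(view, (0.0, (0.0, 0.0)))
        views[view] = build_view_landmarks(
            template, profile, view,
            pose_rotation_deg=rot, pose_translation_mm=trans, **view_kw,
        )
    return CaseTriple(case_id=case_id, **views)


def perturb_annotations(
    view: ViewAnnotation,
    noise_sigma_mm: float,
    *,
    rng: np.random.Generator | int | None = None,
    annotator: str = "simulated",
) -> ViewAnnotation:
    """Add independent Gaussian offsets (SD ``noise_sigma_mm`` per axis).

    Note this takes the literal per-axis SD of the perturbation being
    applied; to emulate one of several annotators whose *pairwise*
    displacement is calibrated, pass ``NoiseModel.annotator_sigma_mm``.
    """
    if noise_sigma_mm < 0:
        raise NegativeSD(f"noise sigma must be >= 0, got {noise_sigma_mm}")
    if noise_sigma_mm == 0:
        return replace(view, annotator=annotator)
    rng = np.random.default_rng(rng)
    sigma_px = noise_sigma_mm / view.pixel_spacing_mm
    offsets = rng.normal(0.0, sigma_px, size=(len(SCHEME), 2))
    points = {
        lid: (x + offsets[k, 0], y + offsets[k, 1])
        for k, (lid, (x, y)) in enumerate(view.points.items())
    }
    return replace(view, points=points, annotator=annotator)


def simulate_annotators(
    view: ViewAnnotation,
    noise: NoiseModel,
    n_annotators: int = 3,
    *,
    rng: np.random.Generator | int | None = None,
) -> list[ViewAnnotation]:
    """Simulate annotators around a consensus view.

    Each annotator deviates from the consensus by ``noise.sigma_mm/sqrt(2)``
    per axis, so any two annotators differ by per-axis SD ``sigma_mm`` and
    ~97.5% of their pairwise landmark distances fall within 2 mm at the
    default calibration.
    """
    rng = np.random.default_rng(noise.seed if rng is None else rng)
    return [
        perturb_annotations(
            view, noise.annotator_sigma_mm, rng=rng, annotator=f"R{k + 1}"
        )
        for k in range(n_annotators)
    ]


@dataclass(frozen=True)
class RenderConfig:
    """Rendering parameters for synthetic lateral views."""

    image_size_px: tuple[int, int] = (128, 128)
    spacing_mm: float = 1.0
    bone_intensity: float = 0.85
    background_intensity: float = 0.25
    gradient_amplitude: float = 0.20  # cranio-caudal soft-tissue gradient
    blur_sigma_px: float = 1.0
    noise_sd: float = 0.02
    c2_wedge_height_mm: float = 6.0


def render_view(
    view: ViewAnnotation,
    cfg: RenderConfig | None = None,
    *,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Render a grayscale image (uint8) from one view's landmarks.

    Vertebral bodies are filled quadrilaterals at bone intensity over a
    smooth background gradient; C2 is a wedge extruded from its inferior
    edge.  The landmark ground truth is exactly the polygon corners.
    """
    cfg = cfg or RenderConfig()
    width, height = view.image_size_px or cfg.image_size_px
    for lid, (x, y) in view.points.items():
        if not (0 <= x <= width - 1 and 0 <= y <= height - 1):
            raise OutOfFrame(f"{lid} at ({x:.1f}, {y:.1f}) outside {width}x{height}")
    rng = np.random.default_rng(rng)
    yy = np.arange(height, dtype=float)[:, None] / max(height - 1, 1)
    img = np.full((height, width), cfg.background_intensity) + cfg.gradient_amplitude * yy

    def fill(ids_ccw):
        xs = np.array([view.points[i][0] for i in ids_ccw])
        ys = np.array([view.points[i][1] for i in ids_ccw])
        rr, cc = _polygon(ys, xs, shape=(height, width))
        img[rr, cc] = cfg.bone_intensity

    for level in range(3, 8):
        fill([f"{level}-G1", f"{level}-G2", f"{level}-G4", f"{level}-G3"])
    # C2 wedge: extrude the B3-B4 edge toward the cranium (up in y-up = -y px)
    b3 = np.array(view.points["2-B3"])
    b4 = np.array(view.points["2-B4"])
    edge = b4 - b3
    up = np.array([edge[1], -edge[0]])
    norm = np.hypot(*up)
    if norm > 0:
        up = up / norm * (cfg.c2_wedge_height_mm / view.pixel_spacing_mm)
        if up[1] > 0:  # ensure the wedge goes toward smaller y (cranial)
            up = -up
        quad = np.array([b3, b4, b4 + up, b3 + up])
        rr, cc = _polygon(quad[:, 1], quad[:, 0], shape=(height, width))
        img[rr, cc] = cfg.bone_intensity

    if cfg.blur_sigma_px > 0:
        img = ndimage.gaussian_filter(img, cfg.blur_sigma_px)
    if cfg.noise_sd > 0:
        img = img + rng.normal(0.0, cfg.noise_sd, size=img.shape)
    return (np.clip(img, 0.0, 1.0) * 255).round().astype(np.uint8)


@dataclass(frozen=True)
class DatasetConfig:
    """Full configuration of a generated dataset."""

    n_cases: int = 10
    split: dict[str, float] = field(default_factory=lambda: {"train": 0.8, "val": 0.2})
    seed: int = 0
    template: SpineTemplate = field(default_factory=SpineTemplate)
    render: RenderConfig = field(default_factory=RenderConfig)
    noise: NoiseModel = field(default_factory=NoiseModel)
    pose_rotation_range_deg: float = 6.0
    pose_translation_range_mm: float = 4.0
    write_images: bool = True
    n_annotators: int = 0  # extra noisy annotation sets to write


def _assign_split(case_ids: list[str], split: dict[str, float], rng) -> dict[str, str]:
    fractions = np.array(list(split.values()), dtype=float)
    if len(fractions) == 0 or np.any(fractions < 0) or abs(fractions.sum() - 1.0) > 1e-9:
        raise InvalidSplit(f"split fractions must be >= 0 and sum to 1, got {split}")
    n = len(case_ids)
    counts = np.floor(fractions * n).astype(int)
    while counts.sum() < n:  # hand out the rounding remainder deterministically
        counts[int(np.argmax(fractions * n - counts))] += 1
    order = rng.permutation(n)
    assignment = {}
    pos = 0
    for name, k in zip(split, counts):
        for idx in order[pos:pos + k]:
            assignment[case_ids[idx]] = name
        pos += k
    return assignment


def generate_dataset(out_dir, cfg: DatasetConfig | None = None) -> dict:
    """Generate an on-disk dataset: images, landmark CSV, manifest JSON.

    Returns the manifest (also written to ``manifest.json``), which records
    the full configuration, the split assignment, and each case's
    ground-truth motion profile.  Deterministic for a fixed config.
    """
    from . import io as _io  # local import to avoid a cycle

    cfg = cfg or DatasetConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    case_ids = [f"case{k:04d}" for k in range(cfg.n_cases)]
    assignment = _assign_split(case_ids, cfg.split, rng)

    rows = []
    manifest_cases = {}
    for case_id in case_ids:
        profile = sample_motion_profile(rng=rng)
        poses = {}
        for view in VIEWS:
            rot = float(rng.uniform(-cfg.pose_rotation_range_deg, cfg.pose_rotation_range_deg))
            t = rng.uniform(-cfg.pose_translation_range_mm, cfg.pose_translation_range_mm, 2)
            poses[view] = (rot, tuple(float(v) for v in t))
        try:
            case = build_case(
                case_id, profile, cfg.template, poses=poses,
                spacing_mm=cfg.render.spacing_mm,
                image_size_px=cfg.render.image_size_px,
            )
        except OutOfFrame:
            # an extreme pose draw pushed corners off the canvas: keep the
            # motion profile, drop the offending pose offsets
            poses = {v: (poses[v][0], (0.0, 0.0)) for v in VIEWS}
            case = build_case(
                case_id, profile, cfg.template, poses=poses,
                spacing_mm=cfg.render.spacing_mm,
                image_size_px=cfg.render.image_size_px,
            )
        for view_name, view in case.views().items():
            if cfg.write_images:
                img = render_view(view, cfg.render, rng=rng)
                iio.imwrite(out / f"{case_id}_{view_name}.png", img)
            for lid, (x, y) in view.points.items():
                rows.append((case_id, view_name, lid, x, y, "ground-truth"))
            for k in range(cfg.n_annotators):
                noisy = perturb_annotations(
                    view, cfg.noise.annotator_sigma_mm, rng=rng, annotator=f"R{k + 1}"
                )
                for lid, (x, y) in noisy.points.items():
                    rows.append((case_id, view_name, lid, x, y, f"R{k + 1}"))
        manifest_cases[case_id] = {
            "split": assignment[case_id],
            "profile": {"fn_deg": profile.fn_deg, "ne_deg": profile.ne_deg},
            "poses": {v: [poses[v][0], list(poses[v][1])] for v in VIEWS},
        }

    _io.write_landmark_rows(out / "landmarks.csv", rows)
    meta = {
        "pixel_spacing_mm": cfg.render.spacing_mm,
        "width_px": cfg.render.image_size_px[0],
        "height_px": cfg.render.image_size_px[1],
    }
    (out / "landmarks.meta.json").write_text(json.dumps(meta, indent=1))
    manifest = {
        "config": _config_dict(cfg),
        "seed": cfg.seed,
        "cases": manifest_cases,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def _config_dict(cfg: DatasetConfig) -> dict:
    d = asdict(cfg)
    return d
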