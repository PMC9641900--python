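"""The 22-landmark scheme and validated annotation containers.

Lateral cervical radiographs are annotated with the four vertebral-body
corners of C3-C7 (G1 anterior-superior, G2 posterior-superior, G3
anterior-inferior, G4 posterior-inferior) and, for the atypically shaped C2,
only the two inferior corners (B3 anterior-inferior, B4 posterior-inferior):
22 points per view.  Landmark ids are strings ``"<vertebra>-<role code>"``,
e.g. ``"2-B3"`` or ``"4-G1"``.

Coordinates are 0-based pixel indices in the raster convention (origin
top-left, x rightward, y downward).  Downstream geometry converts to a y-up
metric frame; all angle signs assume the patient faces the +x direction
("facing right"), which :func:`standardize_facing` enforces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np

from .errors import (
    AmbiguousFacing,
    DuplicateLandmark,
    MissingLandmark,
    NonFiniteLandmark,
    NonPositiveSpacing,
    OutOfBounds,
    UnknownImageWidth,
)

VERTEBRAE = ("C2", "C3", "C4", "C5", "C6", "C7")

#: role code -> anatomical role
ROLE_OF_CODE = {
    "G1": "anterior-superior",
    "G2": "posterior-superior",
    "G3": "anterior-inferior",
    "G4": "posterior-inferior",
    "B3": "anterior-inferior",
    "B4": "posterior-inferior",
}

ANTERIOR_CODES = ("G1", "G3", "B3")
VIEWS = ("flexion", "neutral", "extension")


@dataclass(frozen=True)
class LandmarkDef:
    """One catalogue entry: id, vertebra, anatomical role, heatmap channel."""

    landmark_id: str
    vertebra: str
    role: str
    channel: int

    @property
    def is_anterior(self) -> bool:
        return "anterior" in self.role


def _build_scheme() -> tuple[LandmarkDef, ...]:
    entries = []
    channel = 0
    for code in ("B3", "B4"):
        entries.append(LandmarkDef(f"2-{code}", "C2", ROLE_OF_CODE[code], channel))
        channel += 1
    for level in range(3, 8):
        for code in ("G1", "G2", "G3", "G4"):
            entries.append(
                LandmarkDef(f"{level}-{code}", f"C{level}", ROLE_OF_CODE[code], channel)
            )
            channel += 1
    return tuple(entries)


class LandmarkScheme:
    """The fixed catalogue of 22 cervical landmarks.

    The channel order (C2 first, then C3..C7, each vertebra in G1..G4 order)
    is stable across the package: it defines detector heatmap channels and
    the canonical row order of array representations.
    """

    def __init__(self):
        self.entries: tuple[LandmarkDef, ...] = _build_scheme()
        self._by_id = {e.landmark_id: e for e in self.entries}

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __getitem__(self, landmark_id: str) -> LandmarkDef:
        return self._by_id[landmark_id]

    def __contains__(self, landmark_id: str) -> bool:
        return landmark_id in self._by_id

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(e.landmark_id for e in self.entries)

    def ids_of_vertebra(self, vertebra: str) -> tuple[str, ...]:
        return tuple(e.landmark_id for e in self.entries if e.vertebra == vertebra)

    def corners(self, vertebra: str) -> tuple[str, ...]:
        """G1..G4 ids of a typical vertebra (C3-C7), in role order."""
        level = vertebra[1]
        return tuple(f"{level}-G{i}" for i in range(1, 5))


#: module-level singleton; the catalogue is immutable
SCHEME = LandmarkScheme()


@dataclass(frozen=True)
class ViewAnnotation:
    """All 22 landmark coordinates of one view, plus image metadata.

    ``points`` maps landmark id to ``(x_px, y_px)``; pixel coordinates are
    0-based with origin at the top-left corner.
    """

    view: str
    points: Mapping[str, tuple[float, float]]
    pixel_spacing_mm: float
    image_size_px: tuple[int, int] | None = None  # (width, height)
    facing: str = "unknown"  # left | right | unknown
    annotator: str = ""

    def coords(self, order: tuple[str, ...] | None = None) -> np.ndarray:
        """(22, 2) array of (x, y) pixels in scheme channel order."""
        order = order or SCHEME.ids
        return np.array([self.points[i] for i in order], dtype=float)

    def with_points(self, pts: Mapping[str, tuple[float, float]], **kw) -> "ViewAnnotation":
        return replace(self, points=dict(pts), **kw)


@dataclass(frozen=True)
class CaseTriple:
    """The flexion/neutral/extension annotations of one case."""

    case_id: str
    flexion: ViewAnnotation
    neutral: ViewAnnotation
    extension: ViewAnnotation

    def __post_init__(self):
        for name in VIEWS:
            v = getattr(self, name)
            if v.view != name:
                raise ValueError(f"{name} slot holds a '{v.view}' annotation")
        spacings = {round(getattr(self, n).pixel_spacing_mm, 12) for n in VIEWS}
        if len(spacings) != 1:
            raise ValueError("pixel spacing differs across views")

    def views(self) -> dict[str, ViewAnnotation]:
        return {name: getattr(self, name) for name in VIEWS}


def validate_annotation(
    raw_points: Mapping[str, tuple[float, float]],
    spacing: float,
    *,
    view: str = "neutral",
    image_size_px: tuple[int, int] | None = None,
    facing: str = "unknown",
    annotator: str = "",
) -> ViewAnnotation:
    """Validate a raw landmark mapping into a :class:`ViewAnnotation`.

    Rejects missing, duplicate (case-insensitively colliding ids) and
    non-finite landmarks, non-positive pixel spacing, and out-of-bounds
    coordinates when an image size is given.
    """
    if not raw_points:
        raise MissingLandmark(SCHEME.ids)
    if spacing is None or not math.isfinite(spacing) or spacing <= 0:
        raise NonPositiveSpacing(f"pixel spacing must be > 0, got {spacing!r}")

    seen: dict[str, tuple[float, float]] = {}
    for key, xy in raw_points.items():
        norm = str(key).strip()
        if norm in seen:
            raise DuplicateLandmark(norm)
        seen[norm] = (float(xy[0]), float(xy[1]))

    unknown = [k for k in seen if k not in SCHEME]
    if unknown:
        raise DuplicateLandmark(f"unknown landmark ids: {', '.join(sorted(unknown))}")
    missing = [i for i in SCHEME.ids if i not in seen]
    if missing:
        raise MissingLandmark(missing)

    for lid, (x, y) in seen.items():
        if not (math.isfinite(x) and math.isfinite(y)):
            raise NonFiniteLandmark(f"{lid}: ({x}, {y})")
        if image_size_px is not None:
            w, h = image_size_px
            if not (0 <= x <= w - 1 and 0 <= y <= h - 1):
                raise OutOfBounds(f"{lid}: ({x}, {y}) outside {w}x{h} image")

    ordered = {i: seen[i] for i in SCHEME.ids}
    return ViewAnnotation(
        view=view,
        points=ordered,
        pixel_spacing_mm=float(spacing),
        image_size_px=tuple(image_size_px) if image_size_px else None,
        facing=facing,
        annotator=annotator,
    )


def _anterior_posterior_mean_x(view: ViewAnnotation) -> tuple[float, float]:
    ant, post = [], []
    for entry in SCHEME:
        x = view.points[entry.landmark_id][0]
        (ant if entry.is_anterior else post).append(x)
    return float(np.mean(ant)), float(np.mean(post))


def standardize_facing(view: ViewAnnotation) -> ViewAnnotation:
    """Normalize a view so the patient faces the +x direction.

    If the anterior landmarks already lie at larger x than the posterior
    ones the input is returned unchanged (tagged ``facing="right"``);
    otherwise the x coordinates are mirrored about the image width.
    Idempotent by construction.  Angle signs downstream are only meaningful
    on standardized views.
    """
    ant_x, post_x = _anterior_posterior_mean_x(view)
    if ant_x > post_x:
        if view.facing == "right":
            return view
        return replace(view, facing="right")
    if ant_x == post_x:
        raise AmbiguousFacing(
            "anterior and posterior landmarks have equal mean x; cannot "
            "determine patient facing"
        )
    if view.image_size_px is None:
        raise UnknownImageWidth("mirroring requires image_size_px")
    width = view.image_size_px[0]
    mirrored = {
        lid: (width - 1 - x, y) for lid, (x, y) in view.points.items()
    }
    return replace(view, points=mirrored, facing="right")
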