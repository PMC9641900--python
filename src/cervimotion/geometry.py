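"""Vertebral midplanes, segmental angles and SIRM.

The sagittal intervertebral rotational motion (SIRM) of a segment is the
change of the angle between the midplanes of its two vertebrae across two
postures.  The midplane of a typical vertebra (C3-C7) is the line through
the midpoint of its anterior corners (G1, G3) and the midpoint of its
posterior corners (G2, G4); for C2 the line through its two inferior
corners (B3, B4) stands in for the midplane.

Conventions
-----------
* Pixel coordinates (y down) are converted to a metric y-up frame before
  any trigonometry; only pixel spacing scales the result, so angles are
  invariant to translation, rotation, uniform scaling and (after facing
  standardization) mirroring.
* Angles are direction angles of the anterior-to-posterior midplane vector,
  wrapped to (-180, 180] with the tie at +/-180 mapped to +180.
* On facing-standardized views a positive segmental angle means the cranial
  vertebra is relatively extended (tilted open to the back).
* Signed SIRM convention: for each pair the later posture (E > N > F) minus
  the earlier, so F/E = theta_E - theta_F etc.  The additivity identity
  F/E = F/N + N/E holds exactly because F/E is computed as that sum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateVertebra
from .landmarks import SCHEME, CaseTriple, ViewAnnotation, standardize_facing

SEGMENTS = ("C2/3", "C3/4", "C4/5", "C5/6", "C6/7")
PAIRS = ("F/E", "F/N", "N/E")
VIEW_CODE = {"flexion": "F", "neutral": "N", "extension": "E"}

_DEGENERATE_TOL_MM = 1e-9


def wrap_angle_deg(angle: float) -> float:
    """Wrap an angle in degrees into (-180, 180]; +/-180 maps to +180."""
    wrapped = angle % 360.0
    if wrapped > 180.0:
        wrapped -= 360.0
    return wrapped


@dataclass(frozen=True)
class MidplaneLine:
    """A vertebral midplane in the metric y-up frame (mm)."""

    anterior_midpoint: tuple[float, float]
    posterior_midpoint: tuple[float, float]

    @property
    def angle_deg(self) -> float:
        """Signed direction angle of the anterior->posterior vector."""
        ax, ay = self.anterior_midpoint
        px, py = self.posterior_midpoint
        return wrap_angle_deg(math.degrees(math.atan2(py - ay, px - ax)))


def midplane(corners_mm: np.ndarray) -> MidplaneLine:
    """Midplane of a typical vertebra from its 4 corners (G1..G4, mm, y-up).

    Anterior midpoint = mid(G1, G3); posterior midpoint = mid(G2, G4).
    """
    c = np.asarray(corners_mm, dtype=float)
    if c.shape != (4, 2) or not np.all(np.isfinite(c)):
        raise ValueError("expected 4 finite corner points (G1..G4)")
    anterior = (c[0] + c[2]) / 2.0
    posterior = (c[1] + c[3]) / 2.0
    if float(np.hypot(*(anterior - posterior))) < _DEGENERATE_TOL_MM:
        raise DegenerateVertebra("anterior and posterior midpoints coincide")
    return MidplaneLine(tuple(anterior), tuple(posterior))


def c2_line(b3_mm, b4_mm) -> MidplaneLine:
    """C2's stand-in midplane: the line through its inferior corners."""
    b3 = np.asarray(b3_mm, dtype=float)
    b4 = np.asarray(b4_mm, dtype=float)
    if float(np.hypot(*(b3 - b4))) < _DEGENERATE_TOL_MM:
        raise DegenerateVertebra("B3 and B4 coincide")
    return MidplaneLine(tuple(b3), tuple(b4))


def segmental_angle(cranial: MidplaneLine, caudal: MidplaneLine) -> float:
    """theta = wrap(angle(cranial) - angle(caudal)), signed degrees."""
    return wrap_angle_deg(cranial.angle_deg - caudal.angle_deg)


def _to_mm_yup(view: ViewAnnotation) -> dict[str, np.ndarray]:
    s = view.pixel_spacing_mm
    return {
        lid: np.array([x * s, -y * s]) for lid, (x, y) in view.points.items()
    }


def view_midplanes(view: ViewAnnotation) -> dict[str, MidplaneLine]:
    """Midplane (or C2 inferior-edge line) of every vertebra in one view."""
    pts = _to_mm_yup(view)
    lines: dict[str, MidplaneLine] = {}
    try:
        lines["C2"] = c2_line(pts["2-B3"], pts["2-B4"])
    except DegenerateVertebra as err:
        raise DegenerateVertebra(f"C2 ({view.view}): {err}") from err
    for level in range(3, 8):
        corners = np.array([pts[f"{level}-G{i}"] for i in range(1, 5)])
        try:
            lines[f"C{level}"] = midplane(corners)
        except DegenerateVertebra as err:
            raise DegenerateVertebra(f"C{level} ({view.view}): {err}") from err
    return lines


def view_segmental_angles(view: ViewAnnotation) -> dict[str, float]:
    """theta of the five segments C2/3..C6/7 for one view."""
    lines = view_midplanes(view)
    angles = {}
    for seg in SEGMENTS:
        cranial = "C" + seg.split("/")[0][-1]
        caudal = "C" + seg.split("/")[1]
        angles[seg] = segmental_angle(lines[cranial], lines[caudal])
    return angles


@dataclass(frozen=True)
class MotionMeasurement:
    """Per-case segmental angles (per view) and SIRM (per motion pair)."""

    case_id: str
    theta_deg: dict[str, dict[str, float]]  # segment -> {F, N, E}
    sirm_deg: dict[str, dict[str, float]]   # segment -> {F/E, F/N, N/E}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for seg in SEGMENTS:
            rows.append(
                {
                    "case_id": self.case_id,
                    "segment": seg,
                    "theta_F_deg": self.theta_deg[seg]["F"],
                    "theta_N_deg": self.theta_deg[seg]["N"],
                    "theta_E_deg": self.theta_deg[seg]["E"],
                    "sirm_FE_deg": self.sirm_deg[seg]["F/E"],
                    "sirm_FN_deg": self.sirm_deg[seg]["F/N"],
                    "sirm_NE_deg": self.sirm_deg[seg]["N/E"],
                }
            )
        return pd.DataFrame(rows)


def measure_case(case: CaseTriple, *, standardize: bool = True) -> MotionMeasurement:
    """Measure all 5 segments x 3 views and the 3 SIRM pairs of a case.

    Views are facing-standardized first (unless ``standardize=False``), so
    the result is identical for a case and its x-mirrored copy.  SIRM F/E is
    computed as F/N + N/E, which makes the additivity identity exact.
    """
    theta: dict[str, dict[str, float]] = {seg: {} for seg in SEGMENTS}
    for name, view in case.views().items():
        if standardize:
            view = standardize_facing(view)
        for seg, value in view_segmental_angles(view).items():
            theta[seg][VIEW_CODE[name]] = value

    sirm: dict[str, dict[str, float]] = {}
    for seg in SEGMENTS:
        fn = wrap_angle_deg(theta[seg]["N"] - theta[seg]["F"])
        ne = wrap_angle_deg(theta[seg]["E"] - theta[seg]["N"])
        sirm[seg] = {"F/N": fn, "N/E": ne, "F/E": fn + ne}
    return MotionMeasurement(case_id=case.case_id, theta_deg=theta, sirm_deg=sirm)


def measure_cases(cases, **kw) -> pd.DataFrame:
    """Measure a collection of cases into one long-format table."""
    frames = [measure_case(c, **kw).to_frame() for c in cases]
    if not frames:
        cols = ["case_id", "segment", "theta_F_deg", "theta_N_deg", "theta_E_deg",
                "sirm_FE_deg", "sirm_FN_deg", "sirm_NE_deg"]
        return pd.DataFrame(columns=cols)
    return pd.concat(frames, ignore_index=True)
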