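"""Readers and writers for the package's plain-text formats.

Landmark CSV: columns ``case_id,view,landmark,x_px,y_px,annotator`` with a
sidecar JSON (``<name>.meta.json``) holding ``pixel_spacing_mm``,
``width_px`` and ``height_px``.  Coordinates are written with ``repr``
(shortest round-trip float), so a write/read cycle is bit-exact.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import pandas as pd

from .errors import CaseMismatch, ParseError
from .landmarks import SCHEME, CaseTriple, ViewAnnotation, VIEWS, validate_annotation

LANDMARK_COLUMNS = ("case_id", "view", "landmark", "x_px", "y_px", "annotator")


def sidecar_path(csv_path) -> Path:
    p = Path(csv_path)
    return p.with_name(p.stem + ".meta.json")


def write_landmark_rows(path, rows, *, meta: dict | None = None) -> None:
    """Write raw landmark rows (tuples in LANDMARK_COLUMNS order)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(LANDMARK_COLUMNS)
        for case_id, view, landmark, x, y, annotator in rows:
            writer.writerow([case_id, view, landmark, repr(float(x)), repr(float(y)), annotator])
    if meta is not None:
        sidecar_path(path).write_text(json.dumps(meta, indent=1))


def write_annotations(path, cases, *, annotator: str = "") -> None:
    """Write CaseTriples (or single ViewAnnotations) to a landmark CSV."""
    rows = []
    meta = None
    for case in cases:
        if isinstance(case, CaseTriple):
            views = [(case.case_id, v) for v in case.views().values()]
        else:
            case_id, view = case
            views = [(case_id, view)]
        for case_id, view in views:
            for lid, (x, y) in view.points.items():
                rows.append((case_id, view.view, lid, x, y, annotator or view.annotator))
            if meta is None:
                meta = {
                    "pixel_spacing_mm": view.pixel_spacing_mm,
                    "width_px": view.image_size_px[0] if view.image_size_px else None,
                    "height_px": view.image_size_px[1] if view.image_size_px else None,
                }
    write_landmark_rows(path, rows, meta=meta)


def read_landmark_table(path) -> tuple[pd.DataFrame, dict]:
    """Read a landmark CSV and its sidecar metadata, with validation."""
    path = Path(path)
    try:
        with open(path, newline="") as fh:
            reader = csv.reader(fh)
            header = next(reader, None)
            if header is None or [h.strip() for h in header] != list(LANDMARK_COLUMNS):
                raise ParseError(
                    f"expected header {','.join(LANDMARK_COLUMNS)}, got {header}", line=1
                )
            records = []
            for lineno, row in enumerate(reader, start=2):
                if not row:
                    continue
                if len(row) != len(LANDMARK_COLUMNS):
                    raise ParseError(f"expected {len(LANDMARK_COLUMNS)} fields, got {len(row)}", line=lineno)
                case_id, view, landmark, x, y, annotator = row
                if view not in VIEWS:
                    raise ParseError(f"unknown view {view!r}", line=lineno)
                try:
                    x, y = float(x), float(y)
                except ValueError as err:
                    raise ParseError(str(err), line=lineno) from err
                records.append((case_id, view, landmark, x, y, annotator))
    except OSError as err:
        raise ParseError(f"cannot read {path}: {err}") from err
    frame = pd.DataFrame(records, columns=LANDMARK_COLUMNS)
    meta_file = sidecar_path(path)
    if not meta_file.exists():
        raise ParseError(f"missing sidecar metadata {meta_file.name}")
    meta = json.loads(meta_file.read_text())
    if "pixel_spacing_mm" not in meta:
        raise ParseError(f"{meta_file.name} lacks pixel_spacing_mm")
    return frame, meta


def annotations_from_table(
    frame: pd.DataFrame, meta: dict, *, annotator: str | None = None
) -> dict[str, dict[str, ViewAnnotation]]:
    """Group a landmark table into per-case, per-view ViewAnnotations."""
    if annotator is not None:
        frame = frame[frame["annotator"] == annotator]
    size = None
    if meta.get("width_px") and meta.get("height_px"):
        size = (int(meta["width_px"]), int(meta["height_px"]))
    out: dict[str, dict[str, ViewAnnotation]] = {}
    for (case_id, view), group in frame.groupby(["case_id", "view"], sort=True):
        pts = {r.landmark: (r.x_px, r.y_px) for r in group.itertuples()}
        ann = validate_annotation(
            pts,
            meta["pixel_spacing_mm"],
            view=view,
            image_size_px=size,
            annotator=str(group["annotator"].iloc[0]) if annotator is None else annotator,
        )
        out.setdefault(str(case_id), {})[str(view)] = ann
    return out


def triples_from_table(frame, meta, *, annotator=None) -> tuple[list[CaseTriple], list[str]]:
    """Assemble CaseTriples; returns (complete cases, skipped case ids)."""
    grouped = annotations_from_table(frame, meta, annotator=annotator)
    triples, skipped = [], []
    for case_id in sorted(grouped):
        views = grouped[case_id]
        if set(views) == set(VIEWS):
            triples.append(CaseTriple(case_id=case_id, **views))
        else:
            skipped.append(case_id)
    return triples, skipped


def read_case_triples(path, *, annotator=None) -> tuple[list[CaseTriple], list[str]]:
    frame, meta = read_landmark_table(path)
    return triples_from_table(frame, meta, annotator=annotator)


def write_motion_csv(path, frame: pd.DataFrame, *, decimals: int | None = 6) -> None:
    """Write a MotionMeasurement table (6-dp angles by default)."""
    fmt = f"%.{decimals}f" if decimals is not None else None
    frame.to_csv(path, index=False, float_format=fmt)


def read_motion_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def align_measurements(a: pd.DataFrame, b: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Align two motion tables on (case_id, segment); error if disjoint."""
    keys = ["case_id", "segment"]
    common = pd.merge(a[keys], b[keys], on=keys)
    if common.empty:
        raise CaseMismatch("no common (case_id, segment) rows between tables")
    a2 = pd.merge(common, a, on=keys).sort_values(keys).reset_index(drop=True)
    b2 = pd.merge(common, b, on=keys).sort_values(keys).reset_index(drop=True)
    return a2, b2
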