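"""Evaluation battery: reliability, PCK/MPCK, and agreement statistics.

The statistics mirror a standard method-comparison workflow for automated
radiographic measurements:

* landmark reliability — the percentage of paired landmark distances within
  1/2/3 mm thresholds (``<=`` at the boundary);
* PCK — the percentage of predicted landmarks within an r-mm radius of the
  reference; MPCK — the mean PCK of each vertebra's landmarks;
* agreement — mean difference, SD of differences (n-1 denominator), MAE,
  RMSE, Bland-Altman 95% limits of agreement (mean +/- 1.96 SD), Pearson r
  (Fisher-z CI), ICC(2,1) (two-way random effects, absolute agreement,
  single measures; McGraw-Wong F-based CI), and a paired two-sided t-test.
  MAE/RMSE CIs are seeded percentile bootstraps (2,000 resamples).
* paired MAE comparison — each rater's absolute error against the mean of
  the other two raters, versus the model's error against the same mean,
  compared with a paired t-test.

Reported p-values are raw and two-sided; no multiplicity correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    InvalidN,
    LengthMismatch,
    MismatchedLandmarks,
    SpacingMismatch,
)
from .landmarks import SCHEME, VERTEBRAE, ViewAnnotation


# ---------------------------------------------------------------------------
# reference standard

def reference_standard(annotations: list[ViewAnnotation]) -> ViewAnnotation:
    """Coordinate-wise mean of >= 2 annotations of the same view."""
    if len(annotations) < 2:
        raise ValueError("need at least two annotations")
    first = annotations[0]
    ids = set(first.points)
    for ann in annotations[1:]:
        if set(ann.points) != ids:
            raise MismatchedLandmarks("annotations have different landmark sets")
        if not math.isclose(ann.pixel_spacing_mm, first.pixel_spacing_mm):
            raise SpacingMismatch("annotations have different pixel spacing")
    stacks = np.stack([a.coords() for a in annotations])
    mean = stacks.mean(axis=0)
    points = {lid: tuple(mean[k]) for k, lid in enumerate(SCHEME.ids)}
    return first.with_points(points, annotator="reference")


def mean_vectors(vectors: list[np.ndarray]) -> np.ndarray:
    """Value-wise mean of measurement vectors (reference standard)."""
    arrs = [np.asarray(v, dtype=float) for v in vectors]
    if len({a.shape for a in arrs}) != 1:
        raise LengthMismatch("vectors have different lengths")
    return np.mean(arrs, axis=0)


# ---------------------------------------------------------------------------
# landmark distances, reliability, PCK

def landmark_distances_mm(a: ViewAnnotation, b: ViewAnnotation) -> np.ndarray:
    """Per-landmark Euclidean distance in mm, in scheme channel order."""
    if set(a.points) != set(b.points):
        raise MismatchedLandmarks("different landmark sets")
    if not math.isclose(a.pixel_spacing_mm, b.pixel_spacing_mm):
        raise SpacingMismatch(
            f"{a.pixel_spacing_mm} mm/px vs {b.pixel_spacing_mm} mm/px"
        )
    d_px = np.linalg.norm(a.coords() - b.coords(), axis=1)
    return d_px * a.pixel_spacing_mm


def distance_reliability(
    a: ViewAnnotation | list[ViewAnnotation],
    b: ViewAnnotation | list[ViewAnnotation],
    thresholds_mm=(1.0, 2.0, 3.0),
) -> dict[float, float]:
    """Percentage of pooled landmark distances within each threshold (<=)."""
    pairs = [(a, b)] if isinstance(a, ViewAnnotation) else list(zip(a, b))
    dists = np.concatenate([landmark_distances_mm(x, y) for x, y in pairs])
    return {
        float(t): float(np.mean(dists <= t) * 100.0) for t in thresholds_mm
    }


def reliability_table(
    annotations_by_view: dict[str, list[tuple[ViewAnnotation, ViewAnnotation]]],
    thresholds_mm=(1.0, 2.0, 3.0),
) -> pd.DataFrame:
    """Per-view reliability rows pooled over annotation pairs."""
    rows = []
    for view, pairs in annotations_by_view.items():
        a_list = [p[0] for p in pairs]
        b_list = [p[1] for p in pairs]
        pct = distance_reliability(a_list, b_list, thresholds_mm)
        rows.append({"view": view, **{f"within_{t:g}mm_pct": v for t, v in pct.items()}})
    return pd.DataFrame(rows)


def pck(
    preds: ViewAnnotation | list[ViewAnnotation],
    refs: ViewAnnotation | list[ViewAnnotation],
    radius_mm: float,
) -> float:
    """Pooled percentage of predictions within radius_mm of the reference."""
    pairs = [(preds, refs)] if isinstance(preds, ViewAnnotation) else list(zip(preds, refs))
    dists = np.concatenate([landmark_distances_mm(p, r) for p, r in pairs])
    return float(np.mean(dists <= radius_mm) * 100.0)


def pck_per_landmark(preds, refs, radius_mm: float) -> dict[str, float]:
    """PCK of each landmark id over a case collection."""
    pairs = [(preds, refs)] if isinstance(preds, ViewAnnotation) else list(zip(preds, refs))
    dists = np.stack([landmark_distances_mm(p, r) for p, r in pairs])  # (n, 22)
    within = (dists <= radius_mm).mean(axis=0) * 100.0
    return {lid: float(within[k]) for k, lid in enumerate(SCHEME.ids)}


def mpck(preds, refs, radius_mm: float) -> dict[str, float]:
    """Mean PCK of each vertebra's landmarks (MC2..MC7)."""
    per_lm = pck_per_landmark(preds, refs, radius_mm)
    out = {}
    for vertebra in VERTEBRAE:
        ids = SCHEME.ids_of_vertebra(vertebra)
        out[f"M{vertebra}"] = float(np.mean([per_lm[i] for i in ids]))
    return out


# ---------------------------------------------------------------------------
# ICC(2,1)

def icc_2_1(data: np.ndarray, alpha: float = 0.05) -> tuple[float, tuple[float, float]]:
    """ICC(2,1): two-way random effects, absolute agreement, single measures.

    ``data`` is (n subjects, k raters).  Returns (icc, (lo, hi)) with a
    McGraw-Wong F-based confidence interval.
    """
    x = np.asarray(data, dtype=float)
    n, k = x.shape
    if n < 3 or k < 2:
        raise InvalidN(f"need >= 3 subjects and >= 2 raters, got {x.shape}")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)  # rows (subjects)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)  # columns (raters)
    sse = np.sum((x - row_means[:, None] - col_means[None, :] + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        return float("nan"), (float("nan"), float("nan"))
    icc = (msr - mse) / denom

    # McGraw & Wong (1996) interval for ICC(A,1)
    if mse == 0:
        return float(icc), (float(icc), float(icc))
    fj = msc / mse
    a = (k * icc) / (n * (1 - icc)) if icc != 1 else np.inf
    b = 1 + (k * icc * (n - 1)) / (n * (1 - icc)) if icc != 1 else np.inf
    if not np.isfinite(a):
        return float(icc), (float(icc), float(icc))
    v = ((a * fj + b) ** 2) / (
        (a**2 * fj**2) / (k - 1) + b**2 / (n - 1)
    )
    f_lo = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_up = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (msr - f_lo * mse) / (
        f_lo * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    upper = n * (f_up * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f_up * msr
    )
    return float(icc), (float(lower), float(upper))


# ---------------------------------------------------------------------------
# agreement statistics

def mae(observed, predicted) -> float:
    o, p = _paired(observed, predicted)
    return float(np.mean(np.abs(o - p)))


def rmse(observed, predicted) -> float:
    o, p = _paired(observed, predicted)
    return float(np.sqrt(np.mean((o - p) ** 2)))


def summary_rmse(mean_diff: float, sd_diff: float, n: int) -> float:
    """RMSE from the summary pair (mean difference, sample SD, n).

    Uses the identity RMSE^2 = d_bar^2 + s^2 (n-1)/n, where s is the
    n-1-denominator SD of the differences.
    """
    if n < 2:
        raise InvalidN(f"need n >= 2, got {n}")
    if sd_diff < 0:
        raise ValueError("sd_diff must be >= 0")
    return float(np.sqrt(mean_diff**2 + sd_diff**2 * (n - 1) / n))


def _paired(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise LengthMismatch(f"paired vectors required, got {a.shape} and {b.shape}")
    return a, b


@dataclass(frozen=True)
class AgreementResult:
    """Agreement between a model and a reference measurement vector."""

    n: int
    mean_diff: float
    sd_diff: float
    mae: float
    mae_ci95: tuple[float, float]
    rmse: float
    rmse_ci95: tuple[float, float]
    loa_low: float
    loa_high: float
    icc: float
    icc_ci95: tuple[float, float]
    r: float
    r_ci95: tuple[float, float]
    t_stat: float
    p_value: float
    flags: tuple[str, ...] = ()

    def as_row(self) -> dict:
        row = {
            "n": self.n,
            "icc": self.icc, "icc_lo": self.icc_ci95[0], "icc_hi": self.icc_ci95[1],
            "r": self.r, "r_lo": self.r_ci95[0], "r_hi": self.r_ci95[1],
            "mean_diff": self.mean_diff, "sd_diff": self.sd_diff,
            "rmse": self.rmse, "rmse_lo": self.rmse_ci95[0], "rmse_hi": self.rmse_ci95[1],
            "mae": self.mae, "mae_lo": self.mae_ci95[0], "mae_hi": self.mae_ci95[1],
            "loa_low": self.loa_low, "loa_high": self.loa_high,
            "t_stat": self.t_stat, "p_value": self.p_value,
            "flags": ";".join(self.flags),
        }
        return row


def pearson_with_ci(x, y, alpha: float = 0.05) -> tuple[float, tuple[float, float]]:
    """Pearson r with a Fisher z-transform confidence interval."""
    x, y = _paired(x, y)
    n = len(x)
    r = float(stats.pearsonr(x, y).statistic)
    if abs(r) >= 1.0 or n < 4:
        return r, (r, r)
    z = np.arctanh(r)
    se = 1.0 / math.sqrt(n - 3)
    zc = stats.norm.ppf(1 - alpha / 2)
    return r, (float(np.tanh(z - zc * se)), float(np.tanh(z + zc * se)))


def _bootstrap_ci(diffs: np.ndarray, statistic, n_boot: int, rng, alpha: float):
    n = len(diffs)
    idx = rng.integers(0, n, size=(n_boot, n))
    samples = statistic(diffs[idx])
    lo, hi = np.percentile(samples, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def agreement_stats(
    model_vals,
    ref_vals,
    *,
    n_boot: int = 2000,
    seed: int = 0,
    alpha: float = 0.05,
) -> AgreementResult:
    """Full agreement panel between model and reference vectors.

    Differences are oriented model - reference throughout.  Degenerate
    inputs (identical vectors, zero variance) are flagged rather than
    returned as silent NaNs.
    """
    model, ref = _paired(model_vals, ref_vals)
    n = len(model)
    if n < 3:
        raise InvalidN(f"need n >= 3, got {n}")
    diffs = model - ref
    mean_diff = float(diffs.mean())
    sd_diff = float(diffs.std(ddof=1))
    mae_val = float(np.mean(np.abs(diffs)))
    rmse_val = float(np.sqrt(np.mean(diffs**2)))
    loa_low = mean_diff - 1.96 * sd_diff
    loa_high = mean_diff + 1.96 * sd_diff

    flags: list[str] = []
    rng = np.random.default_rng(seed)
    mae_ci = _bootstrap_ci(diffs, lambda d: np.mean(np.abs(d), axis=1), n_boot, rng, alpha)
    rmse_ci = _bootstrap_ci(diffs, lambda d: np.sqrt(np.mean(d**2, axis=1)), n_boot, rng, alpha)

    if np.allclose(model, ref):
        flags.append("perfect_agreement")
    zero_var = model.std() == 0 or ref.std() == 0

    if zero_var:
        flags.append("zero_variance")
        r, r_ci = float("nan"), (float("nan"), float("nan"))
        icc, icc_ci = float("nan"), (float("nan"), float("nan"))
    elif "perfect_agreement" in flags:
        r, r_ci = 1.0, (1.0, 1.0)
        icc, icc_ci = 1.0, (1.0, 1.0)
    else:
        r, r_ci = pearson_with_ci(model, ref, alpha)
        icc, icc_ci = icc_2_1(np.column_stack([model, ref]), alpha)

    if sd_diff == 0:
        t_stat, p_value = (0.0, 1.0) if mean_diff == 0 else (float("inf"), 0.0)
        flags.append("zero_diff_variance")
    else:
        res = stats.ttest_rel(model, ref)
        t_stat, p_value = float(res.statistic), float(res.pvalue)

    return AgreementResult(
        n=n, mean_diff=mean_diff, sd_diff=sd_diff,
        mae=mae_val, mae_ci95=mae_ci, rmse=rmse_val, rmse_ci95=rmse_ci,
        loa_low=loa_low, loa_high=loa_high,
        icc=icc, icc_ci95=icc_ci, r=r, r_ci95=r_ci,
        t_stat=t_stat, p_value=p_value, flags=tuple(flags),
    )


def agreement_table(
    model_frame: pd.DataFrame,
    ref_frame: pd.DataFrame,
    value_columns=("sirm_FE_deg", "sirm_FN_deg", "sirm_NE_deg"),
    *,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-segment x motion-pair agreement rows from aligned motion tables."""
    from .io import align_measurements

    m, r = align_measurements(model_frame, ref_frame)
    rows = []
    pair_of = {"sirm_FE_deg": "F/E", "sirm_FN_deg": "F/N", "sirm_NE_deg": "N/E"}
    for col in value_columns:
        for segment, seg_m in m.groupby("segment", sort=True):
            seg_r = r[r["segment"] == segment]
            result = agreement_stats(
                seg_m[col].to_numpy(), seg_r[col].to_numpy(), seed=seed
            )
            rows.append({"pair": pair_of.get(col, col), "segment": segment, **result.as_row()})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# rater-vs-model paired MAE comparison

def paired_mae_comparison(rater_vals: list, model_vals) -> pd.DataFrame:
    """Compare each rater's error with the model's, against the same baseline.

    For rater i the baseline is the mean of the other two raters; the
    rater's and the model's absolute deviations from that baseline are
    compared with a paired two-sided t-test.  Degenerate (all-identical)
    paired differences are flagged with p = 1.
    """
    raters = [np.asarray(v, dtype=float) for v in rater_vals]
    model = np.asarray(model_vals, dtype=float)
    if len(raters) != 3:
        raise LengthMismatch(f"need exactly 3 rater vectors, got {len(raters)}")
    if len({v.shape for v in raters} | {model.shape}) != 1:
        raise LengthMismatch("all four vectors must have equal length")
    rows = []
    for i in range(3):
        others = [raters[j] for j in range(3) if j != i]
        baseline = np.mean(others, axis=0)
        e_rater = np.abs(raters[i] - baseline)
        e_model = np.abs(model - baseline)
        delta = e_rater - e_model
        flags = []
        if np.ptp(delta) == 0:
            flags.append("degenerate_pairs")
            t_stat, p = 0.0, 1.0
        else:
            res = stats.ttest_rel(e_rater, e_model)
            t_stat, p = float(res.statistic), float(res.pvalue)
        rows.append(
            {
                "rater": f"R{i + 1}",
                "mae_rater": float(e_rater.mean()),
                "mae_model": float(e_model.mean()),
                "t_stat": t_stat,
                "p_value": p,
                "flags": ";".join(flags),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Bland-Altman plot

def bland_altman_plot(model_vals, ref_vals, *, ax=None, title: str | None = None):
    """Bland-Altman plot: mean vs difference with mean and 95% LoA lines."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    model, ref = _paired(model_vals, ref_vals)
    diffs = model - ref
    means = (model + ref) / 2.0
    md = diffs.mean()
    sd = diffs.std(ddof=1)
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    ax.scatter(means, diffs, s=12, alpha=0.7)
    ax.axhline(md, color="k", lw=1)
    for y in (md - 1.96 * sd, md + 1.96 * sd):
        ax.axhline(y, color="k", lw=1, ls="--")
    ax.set_xlabel("mean of methods (deg)")
    ax.set_ylabel("model - reference (deg)")
    if title:
        ax.set_title(title)
    return ax
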