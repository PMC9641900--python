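import math

import numpy as np
import pandas as pd
import pytest

import cervimotion as cm
from cervimotion import errors, metrics
from cervimotion.metrics import (
    agreement_stats,
    distance_reliability,
    icc_2_1,
    mpck,
    paired_mae_comparison,
    pck,
    reference_standard,
    summary_rmse,
)


def shift_view(view, lid, dx_mm=0.0, dy_mm=0.0):
    s = view.pixel_spacing_mm
    x, y = view.points[lid]
    return view.with_points({**view.points, lid: (x + dx_mm / s, y + dy_mm / s)})


class TestReferenceStandard:
    def test_identical_annotations(self, neutral_view):
        ref = reference_standard([neutral_view] * 3)
        assert np.allclose(ref.coords(), neutral_view.coords())

    def test_two_point_mean(self, neutral_view):
        a = neutral_view.with_points({**neutral_view.points, "3-G1": (0.0, 0.0)})
        b = neutral_view.with_points({**neutral_view.points, "3-G1": (2.0, 2.0)})
        ref = reference_standard([a, b])
        assert ref.points["3-G1"] == pytest.approx((1.0, 1.0))

    def test_mismatched_sets(self, neutral_view):
        renamed = dict(neutral_view.points)
        renamed["junk"] = renamed.pop("2-B3")
        broken = neutral_view.with_points(renamed)
        with pytest.raises(errors.MismatchedLandmarks):
            reference_standard([neutral_view, broken])


class TestReliability:
    def test_identical_is_100(self, neutral_view):
        pct = distance_reliability(neutral_view, neutral_view)
        assert all(v == 100.0 for v in pct.values())

    def test_one_of_22_displaced(self, neutral_view):
        moved = shift_view(neutral_view, "5-G2", dx_mm=1.5)
        pct = distance_reliability(neutral_view, moved)
        assert pct[1.0] == pytest.approx(100 * 21 / 22)
        assert pct[2.0] == 100.0

    def test_boundary_counts_as_within(self):
        from cervimotion.landmarks import validate_annotation
        from conftest import full_points

        ref = validate_annotation(full_points(), 0.5)
        moved = shift_view(ref, "5-G2", dx_mm=2.0)
        pct = distance_reliability(ref, moved)
        assert pct[2.0] == 100.0  # <= convention

    def test_monotone_in_threshold(self, neutral_view):
        rng = np.random.default_rng(0)
        noisy = cm.perturb_annotations(neutral_view, 1.0, rng=rng)
        thresholds = [0.5, 1.0, 1.5, 2.0, 3.0]
        pct = distance_reliability(neutral_view, noisy, thresholds)
        values = [pct[t] for t in thresholds]
        assert values == sorted(values)

    def test_spacing_mismatch(self, neutral_view):
        import dataclasses

        other = dataclasses.replace(neutral_view, pixel_spacing_mm=0.5)
        with pytest.raises(errors.SpacingMismatch):
            distance_reliability(neutral_view, other)


class TestPCK:
    def test_perfect_prediction(self, neutral_view):
        assert pck(neutral_view, neutral_view, 0.1) == 100.0

    def test_half_displaced(self):
        from cervimotion.landmarks import validate_annotation
        from conftest import full_points

        # integer pixel coordinates at spacing 0.5 keep the boundary exact
        ref = validate_annotation(full_points(), 0.5)
        moved = ref
        for lid in list(ref.points)[:11]:
            moved = shift_view(moved, lid, dx_mm=3.0)
        assert pck(moved, ref, 2.0) == pytest.approx(50.0)
        assert pck(moved, ref, 3.0) == pytest.approx(100.0)  # <= convention

    def test_radius_is_converted_through_spacing(self, neutral_view):
        # a 2 mm radius at 0.143 mm/px is 13.986 px: a 13 px displacement is
        # within, a 15 px displacement is not
        import dataclasses

        fine = dataclasses.replace(neutral_view, pixel_spacing_mm=0.143)
        near = fine.with_points(
            {**fine.points, "4-G1": (fine.points["4-G1"][0] + 13.0, fine.points["4-G1"][1])}
        )
        far = fine.with_points(
            {**fine.points, "4-G1": (fine.points["4-G1"][0] + 15.0, fine.points["4-G1"][1])}
        )
        assert pck(near, fine, 2.0) == 100.0
        assert pck(far, fine, 2.0) == pytest.approx(100 * 21 / 22)

    def test_mpck_perfect_and_c2_average(self, neutral_view):
        perfect = mpck([neutral_view], [neutral_view], 2.0)
        assert set(perfect) == {"MC2", "MC3", "MC4", "MC5", "MC6", "MC7"}
        assert all(v == 100.0 for v in perfect.values())
        # displace one of C2's two landmarks far away -> MC2 = 50%
        moved = shift_view(neutral_view, "2-B3", dx_mm=50.0)
        assert mpck([moved], [neutral_view], 2.0)["MC2"] == pytest.approx(50.0)


class TestAgreement:
    def test_hand_evaluated_mae_rmse(self):
        obs = [1.0, 2.0, 3.0]
        pred = [2.0, 2.0, 5.0]
        assert metrics.mae(obs, pred) == pytest.approx(1.0)
        assert metrics.rmse(obs, pred) == pytest.approx(math.sqrt(5 / 3))
        assert metrics.rmse(obs, pred) == pytest.approx(1.2910, abs=1e-4)

    def test_loa_from_mean_and_sd(self):
        # diffs with mean 0.5, sample SD exactly 1.0
        ref = np.zeros(3)
        model = np.array([-0.5, 0.5, 1.5])
        res = agreement_stats(model, ref)
        assert res.mean_diff == pytest.approx(0.5)
        assert res.sd_diff == pytest.approx(1.0)
        assert res.loa_low == pytest.approx(-1.46)
        assert res.loa_high == pytest.approx(2.46)
        assert res.loa_high - res.loa_low == pytest.approx(2 * 1.96 * res.sd_diff)

    def test_perfect_agreement_flagged(self):
        v = np.array([1.0, 2.0, 3.0, 4.0])
        res = agreement_stats(v, v.copy())
        assert "perfect_agreement" in res.flags
        assert res.mae == 0 and res.rmse == 0 and res.t_stat == 0 and res.p_value == 1
        assert res.icc == 1.0 and res.r == 1.0

    def test_zero_variance_flagged_not_nan_crash(self):
        res = agreement_stats(np.ones(5), np.zeros(5))
        assert "zero_variance" in res.flags
        assert res.mae == 1.0

    def test_mae_le_rmse_property(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            a, b = rng.normal(size=30), rng.normal(size=30)
            assert metrics.mae(a, b) <= metrics.rmse(a, b) + 1e-15

    def test_loa_covers_95pct_of_normal_diffs(self):
        rng = np.random.default_rng(8)
        diffs = rng.normal(0.3, 1.2, size=10_000)
        res = agreement_stats(diffs, np.zeros_like(diffs))
        coverage = np.mean((diffs >= res.loa_low) & (diffs <= res.loa_high))
        assert coverage == pytest.approx(0.95, abs=0.01)

    def test_orientation_is_model_minus_reference(self):
        res = agreement_stats([2.0, 3.0, 4.0], [1.0, 1.0, 1.0])
        assert res.mean_diff == pytest.approx(2.0)


class TestSummaryRMSE:
    def test_published_comparison_row(self):
        # d = -0.52, s = 1.57, n = 100 -> 1.64 at the printed precision
        assert summary_rmse(-0.52, 1.57, 100) == pytest.approx(1.64, abs=0.01)

    def test_zero_mean_closed_form(self):
        assert summary_rmse(0.0, 2.0, 50) == pytest.approx(2.0 * math.sqrt(49 / 50))

    def test_zero_sd(self):
        assert summary_rmse(3.0, 0.0, 10) == pytest.approx(3.0)

    def test_consistent_with_raw_differences(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            d = rng.normal(0.4, 1.3, size=37)
            raw = float(np.sqrt(np.mean(d**2)))
            summ = summary_rmse(d.mean(), d.std(ddof=1), len(d))
            assert summ == pytest.approx(raw, abs=1e-12)

    def test_invalid_n(self):
        with pytest.raises(errors.InvalidN):
            summary_rmse(0.0, 1.0, 1)


def icc_2_1_oracle(data):
    """Variance-components oracle via nested least-squares fits.

    Computes the two-way ANOVA sums of squares from residuals of explicit
    design-matrix regressions rather than mean arithmetic.
    """
    x = np.asarray(data, dtype=float)
    n, k = x.shape
    y = x.ravel()
    subj = np.repeat(np.eye(n), k, axis=0)
    rater = np.tile(np.eye(k), (n, 1))

    def rss(design):
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        return float(np.sum((y - design @ beta) ** 2))

    both = np.column_stack([subj, rater])
    sse = rss(both)
    ssr = rss(np.column_stack([np.ones(n * k), rater])) - sse  # subjects
    ssc = rss(np.column_stack([np.ones(n * k), subj])) - sse   # raters
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestICC:
    def test_matches_variance_components_oracle(self):
        rng = np.random.default_rng(20)
        for _ in range(20):
            data = rng.normal(0, 1, size=(10, 2)) + rng.normal(0, 1, size=(10, 1))
            icc, _ = icc_2_1(data)
            assert icc == pytest.approx(icc_2_1_oracle(data), abs=1e-9)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(21)
        for _ in range(5):
            data = rng.normal(0, 1, size=(12, 3)) + rng.normal(0, 2, size=(12, 1))
            icc, ci = icc_2_1(data)
            long = pd.DataFrame({
                "subj": np.repeat(np.arange(12), 3),
                "rater": np.tile(np.arange(3), 12),
                "score": data.ravel(),
            })
            res = pg.intraclass_corr(long, targets="subj", raters="rater", ratings="score")
            row = res[res["Type"] == "ICC(A,1)"].iloc[0]
            assert icc == pytest.approx(row["ICC"], abs=1e-9)

    def test_high_agreement_data(self):
        rng = np.random.default_rng(22)
        truth = rng.normal(10, 5, size=50)
        data = np.column_stack([truth + rng.normal(0, 0.1, 50),
                                truth + rng.normal(0, 0.1, 50)])
        icc, ci = icc_2_1(data)
        assert icc > 0.99
        assert ci[0] <= icc <= ci[1]


class TestPairedMAEComparison:
    def test_model_identical_to_rater_degenerate(self):
        rng = np.random.default_rng(30)
        r1 = rng.normal(size=20)
        r2 = rng.normal(size=20)
        r3 = rng.normal(size=20)
        table = paired_mae_comparison([r1, r2, r3], r1.copy())
        row = table[table["rater"] == "R1"].iloc[0]
        assert row["mae_rater"] == pytest.approx(row["mae_model"])
        assert row["p_value"] == 1.0
        assert "degenerate_pairs" in row["flags"]

    def test_symmetric_errors_give_t_zero(self):
        zeros = np.zeros(4)
        r1 = np.array([1.0, -1.0, 2.0, -2.0])
        model = np.array([2.0, 2.0, 1.0, 1.0])
        # e_r1 - e_model = [-1, -1, 1, 1]: mean 0 -> t = 0, p = 1
        table = paired_mae_comparison([r1, zeros, zeros], model)
        row = table[table["rater"] == "R1"].iloc[0]
        assert row["t_stat"] == pytest.approx(0.0, abs=1e-12)
        assert row["p_value"] == pytest.approx(1.0)

    def test_detects_uniformly_better_model(self):
        # model is closer to the baseline on every case; effect ~ 0.5 SD, n=100
        rng = np.random.default_rng(31)
        n = 100
        truth = rng.normal(0, 5, n)
        r2 = truth + rng.normal(0, 1, n)
        r3 = truth + rng.normal(0, 1, n)
        baseline = (r2 + r3) / 2
        r1 = baseline + rng.choice([-1, 1], n) * (1.0 + 0.5 * rng.random(n))
        model = baseline + rng.choice([-1, 1], n) * 0.5 * rng.random(n)
        table = paired_mae_comparison([r1, r2, r3], model)
        row = table[table["rater"] == "R1"].iloc[0]
        assert row["mae_model"] < row["mae_rater"]
        assert row["p_value"] < 0.05

    def test_length_mismatch(self):
        with pytest.raises(errors.LengthMismatch):
            paired_mae_comparison([np.zeros(3), np.zeros(3), np.zeros(4)], np.zeros(3))
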