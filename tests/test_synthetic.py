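import json
import math

import numpy as np
import pytest

import cervimotion as cm
from cervimotion import errors
from cervimotion.landmarks import SCHEME
from cervimotion.synthetic import FN_PARAMS, NE_PARAMS, _assign_split


class TestMotionProfile:
    def test_population_means_at_zero_sd(self):
        params_fn = {s: (m, 0.0) for s, (m, _) in FN_PARAMS.items()}
        params_ne = {s: (m, 0.0) for s, (m, _) in NE_PARAMS.items()}
        profile = cm.sample_motion_profile(params_fn, params_ne, rng=0)
        # population means: 7.05 + 5.76 at C4/5
        assert profile.fe_deg["C4/5"] == pytest.approx(12.81)
        assert profile.fn_deg["C2/3"] == pytest.approx(3.87)

    def test_seed_determinism(self):
        a = cm.sample_motion_profile(rng=123)
        b = cm.sample_motion_profile(rng=123)
        assert a == b

    def test_all_zero(self):
        zero = {s: (0.0, 0.0) for s in cm.SEGMENTS}
        profile = cm.sample_motion_profile(zero, zero, rng=0)
        assert all(v == 0 for v in profile.fn_deg.values())
        assert all(v == 0 for v in profile.fe_deg.values())

    def test_negative_sd(self):
        bad = {s: (0.0, -1.0) for s in cm.SEGMENTS}
        with pytest.raises(errors.NegativeSD):
            cm.sample_motion_profile(bad, None, rng=0)

    def test_fe_is_exact_sum(self):
        profile = cm.sample_motion_profile(rng=7)
        for s in cm.SEGMENTS:
            assert profile.fe_deg[s] == profile.fn_deg[s] + profile.ne_deg[s]


class TestForwardKinematics:
    def test_neutral_measures_baseline(self, flat_profile):
        template = cm.SpineTemplate(baseline_theta_deg=2.0)
        case = cm.build_case("b", flat_profile, template)
        m = cm.measure_case(case)
        for seg in cm.SEGMENTS:
            for v in ("F", "N", "E"):
                assert m.theta_deg[seg][v] == pytest.approx(2.0, abs=1e-9)

    def test_round_trip_recovery(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            profile = cm.sample_motion_profile(rng=rng)
            case = cm.build_case("rt", profile)
            m = cm.measure_case(case)
            for seg in cm.SEGMENTS:
                assert m.sirm_deg[seg]["F/N"] == pytest.approx(profile.fn_deg[seg], abs=1e-9)
                assert m.sirm_deg[seg]["N/E"] == pytest.approx(profile.ne_deg[seg], abs=1e-9)
                assert m.sirm_deg[seg]["F/E"] == pytest.approx(profile.fe_deg[seg], abs=1e-9)

    def test_global_pose_does_not_change_sirm(self, example_profile):
        base = cm.measure_case(cm.build_case("p0", example_profile))
        posed = cm.measure_case(
            cm.build_case("p15", example_profile,
                          poses={v: (15.0, (5.0, -3.0)) for v in cm.VIEWS})
        )
        for seg in cm.SEGMENTS:
            for pair in cm.PAIRS:
                assert posed.sirm_deg[seg][pair] == pytest.approx(
                    base.sirm_deg[seg][pair], abs=1e-9
                )

    def test_out_of_frame(self, example_profile):
        with pytest.raises(errors.OutOfFrame):
            cm.build_view_landmarks(
                cm.SpineTemplate(), example_profile, "neutral",
                spacing_mm=1.0, image_size_px=(32, 32),
            )


class TestAnnotationNoise:
    def test_zero_sigma_identity(self, neutral_view):
        out = cm.perturb_annotations(neutral_view, 0.0, rng=0)
        assert out.points == neutral_view.points

    def test_displacements_follow_rayleigh(self, neutral_view):
        # P(|d| < 2 mm) = 1 - exp(-4 / (2 sigma^2)) = 0.9746 at sigma 0.74
        sigma = 0.74
        rng = np.random.default_rng(99)
        dists = []
        for _ in range(500):  # 500 x 22 = 11,000 landmarks
            noisy = cm.perturb_annotations(neutral_view, sigma, rng=rng)
            d = (noisy.coords() - neutral_view.coords()) * neutral_view.pixel_spacing_mm
            dists.append(np.hypot(d[:, 0], d[:, 1]))
        frac = np.mean(np.concatenate(dists) < 2.0)
        expected = 1 - math.exp(-4 / (2 * sigma**2))
        assert frac == pytest.approx(expected, abs=0.005)

    def test_pairwise_distances_scale_sqrt2(self, neutral_view):
        # two independent perturbations differ by Rayleigh scale sigma*sqrt(2)
        sigma = 0.6
        a_rng, b_rng = np.random.default_rng(1), np.random.default_rng(2)
        dists = []
        for _ in range(400):
            a = cm.perturb_annotations(neutral_view, sigma, rng=a_rng)
            b = cm.perturb_annotations(neutral_view, sigma, rng=b_rng)
            d = (a.coords() - b.coords()) * neutral_view.pixel_spacing_mm
            dists.append(np.hypot(d[:, 0], d[:, 1]))
        dists = np.concatenate(dists)
        s_eff = sigma * math.sqrt(2)
        for r in (0.5, 1.0, 2.0):
            expected = 1 - math.exp(-(r**2) / (2 * s_eff**2))
            assert np.mean(dists < r) == pytest.approx(expected, abs=0.01)

    def test_simulated_annotators_match_interobserver_band(self, neutral_view):
        noise = cm.NoiseModel(sigma_mm=0.74, seed=0)
        rng = np.random.default_rng(17)
        dists = []
        for _ in range(30):  # 30 views x 3 pairs x 22 landmarks = 1,980 pairs
            r1, r2, r3 = cm.simulate_annotators(neutral_view, noise, rng=rng)
            for a, b in ((r1, r2), (r1, r3), (r2, r3)):
                d = (a.coords() - b.coords()) * neutral_view.pixel_spacing_mm
                dists.append(np.hypot(d[:, 0], d[:, 1]))
        frac = np.mean(np.concatenate(dists) <= 2.0) * 100
        assert 95.0 <= frac <= 99.0

    def test_reference_standard_sirm_error_in_clinical_band(self):
        # mean-of-3-annotators measurements vs ground truth: MAE ~ 1-2 deg
        from cervimotion.metrics import reference_standard

        rng = np.random.default_rng(23)
        noise = cm.NoiseModel(sigma_mm=0.74)
        errs = []
        for k in range(40):
            profile = cm.sample_motion_profile(rng=rng)
            case = cm.build_case(f"c{k}", profile)
            ref_views = {}
            for name, view in case.views().items():
                anns = cm.simulate_annotators(view, noise, rng=rng)
                ref_views[name] = reference_standard(anns)
            m = cm.measure_case(cm.CaseTriple(case_id=case.case_id, **ref_views))
            for seg in cm.SEGMENTS:
                for pair, truth in (("F/N", profile.fn_deg[seg]),
                                    ("N/E", profile.ne_deg[seg]),
                                    ("F/E", profile.fe_deg[seg])):
                    errs.append(abs(m.sirm_deg[seg][pair] - truth))
        mae = float(np.mean(errs))
        assert 0.5 <= mae <= 3.0


class TestRendering:
    def test_deterministic_given_seed(self, neutral_view):
        cfg = cm.RenderConfig()
        view = cm.build_view_landmarks(
            cm.SpineTemplate(), cm.sample_motion_profile(rng=1), "neutral",
            spacing_mm=cfg.spacing_mm, image_size_px=cfg.image_size_px,
        )
        a = cm.render_view(view, cfg, rng=5)
        b = cm.render_view(view, cfg, rng=5)
        assert np.array_equal(a, b)

    def test_body_brighter_than_background(self):
        cfg = cm.RenderConfig(noise_sd=0.0)
        view = cm.build_view_landmarks(
            cm.SpineTemplate(), cm.sample_motion_profile(rng=1), "neutral",
            spacing_mm=cfg.spacing_mm, image_size_px=cfg.image_size_px,
        )
        img = cm.render_view(view, cfg, rng=0)
        corners = np.array([view.points[i] for i in SCHEME.corners("C5")])
        cx, cy = corners.mean(axis=0)
        assert img[int(round(cy)), int(round(cx))] > img[5, 5]

    def test_out_of_frame_landmark_rejected(self, neutral_view):
        view = neutral_view.with_points(
            {**neutral_view.points, "2-B3": (-5.0, 10.0)},
            image_size_px=neutral_view.image_size_px,
        )
        with pytest.raises(errors.OutOfFrame):
            cm.render_view(view, cm.RenderConfig(image_size_px=neutral_view.image_size_px))


class TestDatasetGeneration:
    def test_split_counts_and_disjoint(self, tmp_path):
        cfg = cm.DatasetConfig(n_cases=10, seed=0, write_images=False)
        manifest = cm.generate_dataset(tmp_path / "ds", cfg)
        splits = [c["split"] for c in manifest["cases"].values()]
        assert splits.count("train") == 8 and splits.count("val") == 2
        assert len(manifest["cases"]) == 10

    def test_same_seed_same_manifest(self, tmp_path):
        cfg = cm.DatasetConfig(n_cases=5, seed=9, write_images=False)
        a = cm.generate_dataset(tmp_path / "a", cfg)
        b = cm.generate_dataset(tmp_path / "b", cfg)
        assert json.dumps(a, sort_keys=True) == json.dumps(b, sort_keys=True)

    def test_empty_dataset_valid(self, tmp_path):
        cfg = cm.DatasetConfig(n_cases=0, seed=0, write_images=False)
        manifest = cm.generate_dataset(tmp_path / "empty", cfg)
        assert manifest["cases"] == {}
        assert (tmp_path / "empty" / "manifest.json").exists()

    def test_invalid_split(self):
        with pytest.raises(errors.InvalidSplit):
            _assign_split(["a"], {"train": 0.5, "val": 0.2}, np.random.default_rng(0))

    def test_ground_truth_matches_manifest(self, tmp_path):
        from cervimotion import io as cio

        cfg = cm.DatasetConfig(n_cases=4, seed=2, write_images=False)
        manifest = cm.generate_dataset(tmp_path / "gt", cfg)
        triples, skipped = cio.read_case_triples(
            tmp_path / "gt" / "landmarks.csv", annotator="ground-truth"
        )
        assert not skipped
        for triple in triples:
            profile = manifest["cases"][triple.case_id]["profile"]
            m = cm.measure_case(triple)
            for seg in cm.SEGMENTS:
                assert m.sirm_deg[seg]["F/N"] == pytest.approx(
                    profile["fn_deg"][seg], abs=1e-6
                )
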