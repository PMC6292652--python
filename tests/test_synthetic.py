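import numpy as np
import pytest
from scipy import stats

from wavepatt.detection import detect_critical_points
from wavepatt.flow import compute_velocity_fields
from wavepatt.recording import Recording
from wavepatt.simulate import (
    PatternSpec,
    SimulationSpec,
    amplitude_profile,
    evaluate_detection,
    make_surrogate,
    phase_profile,
    random_eval_spec,
    simulate,
)


def spec_one(ptype="source_sink", sign=1, spin=1, x0=5.5, y0=5.5, **kw):
    pat = PatternSpec(ptype=ptype, x0=x0, y0=y0, sign=sign, spin=spin, **kw)
    return SimulationSpec(grid=(12, 12), n_steps=10, patterns=[pat])


class TestPhaseProfile:
    def test_source_distance(self):
        pat = PatternSpec(ptype="source_sink", x0=5.0, y0=5.0)
        assert phase_profile(pat, 8.0, 5.0, 0) == pytest.approx(3.0)

    def test_spiral_along_positive_x(self):
        pat = PatternSpec(ptype="spiral", x0=5.0, y0=5.0)
        # at (x0 + r, y0) the angular term vanishes
        assert phase_profile(pat, 7.5, 5.0, 0) == pytest.approx(2.5)

    def test_saddle_signs(self):
        pat = PatternSpec(ptype="saddle", x0=5.0, y0=5.0)
        assert phase_profile(pat, 6.0, 5.0, 0) == pytest.approx(1.0)
        assert phase_profile(pat, 5.0, 6.0, 0) == pytest.approx(-1.0)

    def test_sink_negates_radial_term(self):
        pat = PatternSpec(ptype="source_sink", x0=5.0, y0=5.0, sign=-1)
        assert phase_profile(pat, 8.0, 5.0, 0) == pytest.approx(-3.0)

    def test_moving_center(self):
        pat = PatternSpec(ptype="source_sink", x0=5.0, y0=5.0, vx=0.1)
        assert phase_profile(pat, 8.0, 5.0, 10.0) == pytest.approx(2.0)

    def test_plane_wave_ramp(self):
        pat = PatternSpec(ptype="plane_wave", x0=0.0, y0=0.0, direction=0.0)
        assert phase_profile(pat, 3.0, 7.0, 0) == pytest.approx(3.0)


class TestAmplitudeProfile:
    def test_peak_at_center(self):
        pat = PatternSpec(ptype="source_sink", x0=5.0, y0=5.0, A0=1.7)
        assert amplitude_profile(pat, 5.0, 5.0, 0) == pytest.approx(1.7)

    def test_decays_to_zero(self):
        pat = PatternSpec(ptype="source_sink", x0=5.0, y0=5.0, c=2.0)
        assert amplitude_profile(pat, 500.0, 5.0, 0) < 1e-12

    def test_radial_symmetry(self):
        pat = PatternSpec(ptype="source_sink", x0=5.0, y0=5.0, c=3.0)
        a1 = amplitude_profile(pat, 8.0, 5.0, 0)
        a2 = amplitude_profile(pat, 5.0, 8.0, 0)
        a3 = amplitude_profile(pat, 5.0 + 3 / np.sqrt(2), 5.0 + 3 / np.sqrt(2), 0)
        assert a1 == pytest.approx(a2)
        assert a1 == pytest.approx(a3)

    def test_gaussian_value(self):
        pat = PatternSpec(ptype="source_sink", x0=0.0, y0=0.0, A0=1.0, c=3.0)
        r = 2.0
        assert amplitude_profile(pat, r, 0.0, 0) == pytest.approx(
            np.exp(-(r**2) / (2 * 3.0**2))
        )

    def test_super_gaussian_variant(self):
        pat = PatternSpec(ptype="source_sink", x0=0.0, y0=0.0, A0=1.0, c=3.0)
        r = 2.0
        val = amplitude_profile(pat, r, 0.0, 0, envelope="super_gaussian")
        assert val == pytest.approx(np.exp(-(r**2) ** 2 / (2 * 3.0**2)))


class TestSimulate:
    def test_deterministic_given_seed(self):
        spec = spec_one()
        spec.noise_sigma_rel = 0.3
        spec.seed = 42
        a = simulate(spec)
        b = simulate(spec)
        np.testing.assert_array_equal(a.z, b.z)

    def test_truth_track_drift(self):
        pat = PatternSpec(ptype="source_sink", x0=5.0, y0=5.0, vx=0.1)
        assert pat.center_at(10) == (6.0, 5.0)
        spec = SimulationSpec(grid=(12, 12), n_steps=11, patterns=[pat])
        res = simulate(spec)
        row = res.truth[res.truth["t"] == 10].iloc[0]
        assert row.x == pytest.approx(6.0)

    def test_zero_noise_amplitude_matches_envelope(self):
        spec = spec_one()
        res = simulate(spec)
        pat = spec.patterns[0]
        yy, xx = np.meshgrid(np.arange(12), np.arange(12), indexing="ij")
        np.testing.assert_allclose(
            np.abs(res.z[:, :, 0]), amplitude_profile(pat, xx, yy, 0), atol=1e-12
        )

    def test_noise_scales_with_amplitude(self):
        pat = PatternSpec(ptype="source_sink", x0=5.5, y0=5.5, c=2.0)
        spec = SimulationSpec(
            grid=(12, 12), n_steps=200, patterns=[pat], noise_sigma_rel=0.5, seed=0
        )
        res = simulate(spec)
        clean = simulate(SimulationSpec(grid=(12, 12), n_steps=200, patterns=[pat]))
        resid = (res.z - clean.z).real
        sd_center = resid[5, 5].std()
        sd_corner = resid[0, 0].std()
        assert sd_center > 10 * sd_corner

    def test_end_to_end_static_source_detected(self):
        res = simulate(spec_one())
        vfs = compute_velocity_fields(res.phase, alpha=0.5, beta=10.0, is_phase=True)
        u, v = vfs.frame(4)
        cps = detect_critical_points(u, v)
        assert len(cps) == 1
        assert cps[0].cls == "unstable_node"
        assert np.hypot(cps[0].x - 5.5, cps[0].y - 5.5) < 1.0


class TestPlantedClassRecovery:
    """Zero noise, alpha <= 1: each generator class must be recovered at the
    planted location within 1 grid space."""

    @pytest.mark.parametrize(
        "ptype,sign,spin,expected",
        [
            ("source_sink", 1, 1, "unstable_node"),
            ("source_sink", -1, 1, "stable_node"),
            ("spiral", 1, 1, "unstable_focus"),
            ("spiral", -1, -1, "stable_focus"),
            ("saddle", 1, 1, "saddle"),
        ],
    )
    def test_class_recovered(self, ptype, sign, spin, expected):
        res = simulate(spec_one(ptype=ptype, sign=sign, spin=spin))
        vfs = compute_velocity_fields(res.phase, alpha=0.5, beta=10.0, is_phase=True)
        u, v = vfs.frame(4)
        cps = detect_critical_points(u, v)
        near = [c for c in cps if np.hypot(c.x - 5.5, c.y - 5.5) <= 1.0]
        assert len(near) >= 1
        assert near[0].cls == expected


class TestRandomEvalSpec:
    def test_constraints_hold(self):
        for seed in range(50):
            spec = random_eval_spec(seed)
            (p1, p2) = spec.patterns
            assert np.hypot(p1.x0 - p2.x0, p1.y0 - p2.y0) >= 2.0
            for p in spec.patterns:
                assert min(p.x0, 11 - p.x0, p.y0, 11 - p.y0) >= 2.0
                assert 1.0 <= p.A0 <= 2.0
                assert 3.0 <= p.c <= 5.0
                assert -0.1 <= p.vx <= 0.1 and -0.1 <= p.vy <= 0.1
                assert p.k == pytest.approx(2 * np.pi / 5)
                assert p.w == pytest.approx(2 * np.pi * 0.01)

    def test_same_seed_identical(self):
        a = random_eval_spec(7)
        b = random_eval_spec(7)
        assert a == b

    def test_drift_distribution_uniform(self):
        vxs = np.array([random_eval_spec(s).patterns[0].vx for s in range(1000)])
        # KS against Uniform(-0.1, 0.1)
        res = stats.kstest(vxs, stats.uniform(loc=-0.1, scale=0.2).cdf)
        assert res.pvalue > 0.01

    def test_impossible_constraints_raise(self):
        with pytest.raises(RuntimeError):
            random_eval_spec(0, grid=(5, 5), edge_margin=2.0, min_separation=10.0,
                             max_draws=100)


class TestMakeSurrogate:
    def test_moments_preserved(self, rng):
        sig = rng.normal(loc=2.0, scale=1.5, size=(4, 4, 2000, 1))
        rec = Recording(signal=sig, fs=1.0)
        sur = make_surrogate(rec, seed=1)
        mean_err = np.abs(sur.signal.mean(axis=2) - sig.mean(axis=2))
        # SE of the mean of 2000 samples with sd 1.5
        assert mean_err.max() < 3 * 1.5 / np.sqrt(2000) * 1.5
        sd_ratio = sur.signal.std(axis=2) / sig.std(axis=2)
        assert np.abs(sd_ratio - 1).max() < 0.12

    def test_zero_variance_source_constant(self):
        rec = Recording(signal=np.full((3, 3, 50, 1), 4.2), fs=1.0)
        sur = make_surrogate(rec, seed=0)
        np.testing.assert_allclose(sur.signal, 4.2)

    def test_different_seeds_differ(self, rng):
        rec = Recording(signal=rng.normal(size=(3, 3, 100, 1)), fs=1.0)
        a = make_surrogate(rec, seed=1)
        b = make_surrogate(rec, seed=2)
        assert not np.allclose(a.signal, b.signal)


class TestEvaluateDetection:
    def _truth(self, positions):
        import pandas as pd

        return pd.DataFrame(
            [
                {"t": t, "pattern": 0, "ptype": "source", "x": x, "y": y}
                for t, (x, y) in positions.items()
            ]
        )

    def _det(self, x, y, cls="unstable_node"):
        from wavepatt.detection import CriticalPoint

        return CriticalPoint(x=x, y=y, cls=cls, trace=1.0, det=1.0)

    def test_exact_detections(self):
        truth = self._truth({t: (5.0, 5.0) for t in range(5)})
        det = [[self._det(5.0, 5.0)] for _ in range(5)]
        m = evaluate_detection(truth, det)
        assert m.mean_displacement == 0.0
        assert m.pct_missed_or_misclassified == 0.0
        assert m.false_per_step == 0.0

    def test_no_detections(self):
        truth = self._truth({t: (5.0, 5.0) for t in range(5)})
        m = evaluate_detection(truth, [[] for _ in range(5)])
        assert m.pct_missed_or_misclassified == 100.0
        assert m.false_per_step == 0.0

    def test_extra_detection_is_false_positive(self):
        truth = self._truth({t: (5.0, 5.0) for t in range(5)})
        det = [[self._det(5.0, 5.0), self._det(10.0, 10.0)] for _ in range(5)]
        m = evaluate_detection(truth, det, match_radius=2.0)
        assert m.false_per_step == 1.0
        assert m.pct_missed_or_misclassified == 0.0

    def test_wrong_class_is_misclassified(self):
        truth = self._truth({0: (5.0, 5.0)})
        det = [[self._det(5.0, 5.0, cls="saddle")]]
        m = evaluate_detection(truth, det)
        assert m.n_misclassified == 1
        assert m.pct_missed_or_misclassified == 100.0
        assert m.false_per_step == 0.0

    def test_combine_nodes_foci_tolerates_focus(self):
        truth = self._truth({0: (5.0, 5.0)})
        det = [[self._det(5.0, 5.0, cls="unstable_focus")]]
        strict = evaluate_detection(truth, det)
        loose = evaluate_detection(truth, det, combine_nodes_foci=True)
        assert strict.n_misclassified == 1
        assert loose.n_matches == 1


class TestNoiseRobustness:
    def test_metrics_degrade_less_than_twofold(self):
        # noise sweep on the randomized two-pattern protocol: noise SD equal
        # to the signal amplitude must degrade localization and miss rate by
        # less than 2x relative to noise-free (fixed alpha=0.5, beta=10)
        from wavepatt.simulate import detection_benchmark

        clean = detection_benchmark(
            n_specs=10, alphas=(0.5,), betas=(10.0,), noise_sigma_rel=0.0, seed=3
        ).iloc[0]
        noisy = detection_benchmark(
            n_specs=10, alphas=(0.5,), betas=(10.0,), noise_sigma_rel=1.0, seed=3
        ).iloc[0]
        assert noisy.mean_displacement < 2 * clean.mean_displacement
        assert noisy.pct_missed_or_misclassified < 2 * max(
            clean.pct_missed_or_misclassified, 10.0
        )
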