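import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

import songdrift as sd
from songdrift.ddm import DDMParams, propagate_density


def song_of(label, n=33):
    return sd.SongModel(f"{label}x{n}", (label,) * n, "test")


class TestDeterministicIntegration:
    def test_dorsatus_rejected_at_step_10(self, ref_params):
        """Ten heterospecific subunits fix a rejection without noise."""
        traj = sd.integrate_deterministic(song_of("dorsatus"), ref_params)
        assert (traj.absorbed_at, traj.crossed, traj.outcome) == (10, "lower", "reject")
        assert (traj.evidence[10:] == ref_params.theta_minus).all()

    def test_mollis_rejected_at_step_10(self, ref_params):
        traj = sd.integrate_deterministic(song_of("mollis"), ref_params)
        assert traj.absorbed_at == 10

    def test_onset9dB_crossing_is_strict(self, ref_params):
        """28 * 15 = 420 equals the threshold and does not fix the decision;
        the 29th subunit strictly exceeds it."""
        traj = sd.integrate_deterministic(song_of("onset9dB"), ref_params)
        assert (traj.absorbed_at, traj.crossed) == (29, "upper")

    def test_block_decided_by_sign_rule(self, ref_params):
        traj = sd.integrate_deterministic(song_of("block"), ref_params)
        assert traj.absorbed_at is None
        assert traj.evidence[-1] == 33.0
        assert traj.outcome == "respond"

    def test_missing_weight_raises(self, ref_params):
        with pytest.raises(KeyError):
            sd.integrate_deterministic(song_of("unknown"), ref_params)


class TestParamValidation:
    def test_threshold_signs_enforced(self):
        with pytest.raises(ValueError):
            DDMParams(weights={}, sigma=1.0, theta_plus=-1.0, theta_minus=-2.0)
        with pytest.raises(ValueError):
            DDMParams(weights={}, sigma=-1.0, theta_plus=1.0, theta_minus=-2.0)

    def test_block_weight_anchored(self):
        with pytest.raises(ValueError):
            DDMParams(weights={"block": 2.0}, sigma=1.0, theta_plus=1.0, theta_minus=-1.0)


class TestSimulation:
    def test_sigma_zero_matches_deterministic(self, ref_params):
        params0 = DDMParams(
            weights=ref_params.weights, sigma=0.0,
            theta_plus=ref_params.theta_plus, theta_minus=ref_params.theta_minus,
        )
        for label in ("dorsatus", "block", "onset9dB"):
            out = sd.simulate_trial(song_of(label), params0, rng=1)
            det = sd.integrate_deterministic(song_of(label), params0)
            assert out.outcome == det.outcome
            assert out.step == (det.absorbed_at or 33)

    def test_trial_deterministic_given_rng_state(self, ref_params):
        song = sd.build_song("switch-at-11", ("block", "mollis"))
        a = sd.simulate_trial(song, ref_params, rng=77)
        b = sd.simulate_trial(song, ref_params, rng=77)
        assert a == b

    def test_symmetric_zero_drift_is_half(self):
        params = DDMParams(weights={"a": 0.0}, sigma=40.0, theta_plus=150.0, theta_minus=-150.0)
        cfg = sd.DynamicsConfig(n_reps=40_000, seed=5)
        p, se = sd.response_probability_mc(song_of("a"), params, cfg)
        assert abs(p - 0.5) < 3 * se + 1e-9

    def test_mc_probability_reproducible(self, ref_params):
        song = sd.build_song("switch-at-11", ("block", "mollis"))
        cfg = sd.DynamicsConfig(n_reps=2000, seed=9)
        assert sd.response_probability_mc(song, ref_params, cfg) == \
            sd.response_probability_mc(song, ref_params, cfg)

    def test_sigma_zero_probability_is_indicator(self, ref_params):
        params0 = DDMParams(
            weights=ref_params.weights, sigma=0.0,
            theta_plus=ref_params.theta_plus, theta_minus=ref_params.theta_minus,
        )
        p, se = sd.response_probability_mc(song_of("mollis"), params0)
        assert (p, se) == (0.0, 0.0)


class TestExactBackend:
    def test_single_step_closed_form(self):
        """With unreachable thresholds, one noisy step gives p = Phi(omega/sigma)."""
        params = DDMParams(weights={"a": 30.0}, sigma=50.0, theta_plus=1000.0, theta_minus=-1000.0)
        p = sd.response_probability_exact(song_of("a", 1), params)
        assert abs(p - norm.cdf(30.0 / 50.0)) < 1e-6

    def test_symmetric_zero_drift(self):
        params = DDMParams(weights={"a": 0.0}, sigma=40.0, theta_plus=150.0, theta_minus=-150.0)
        assert abs(sd.response_probability_exact(song_of("a"), params) - 0.5) < 1e-9

    def test_sigma_zero_refused(self, ref_params):
        params0 = DDMParams(weights={"a": 1.0}, sigma=0.0, theta_plus=10.0, theta_minus=-10.0)
        with pytest.raises(ValueError):
            sd.response_probability_exact(song_of("a"), params0)

    def test_grid_halving_stability(self, ref_params):
        song = sd.build_song("switch-at-11-reversed", ("block", "dorsatus"))
        p20 = sd.response_probability_exact(song, ref_params, sd.DynamicsConfig(grid_bins_per_sigma=20))
        p40 = sd.response_probability_exact(song, ref_params, sd.DynamicsConfig(grid_bins_per_sigma=40))
        assert abs(p20 - p40) < 1e-4

    def test_agrees_with_mc_on_reference_song(self, ref_params):
        song = sd.build_song("switch-at-11-reversed", ("block", "mollis"))
        p = sd.response_probability_exact(song, ref_params)
        phat, se = sd.response_probability_mc(song, ref_params, sd.DynamicsConfig(n_reps=100_000, seed=12))
        assert abs(p - phat) < 3 * se + 2e-4

    @given(st.integers(0, 10_000))
    @settings(max_examples=15)
    def test_monotone_in_weight(self, seed):
        """Raising one subunit's weight never lowers the response probability."""
        rng = np.random.default_rng(seed)
        w = float(rng.uniform(-60, 30))
        params_lo = DDMParams(weights={"a": w, "b": 10.0}, sigma=float(rng.uniform(20, 120)),
                              theta_plus=300.0, theta_minus=-400.0)
        params_hi = DDMParams(weights={"a": w + float(rng.uniform(0, 30)), "b": 10.0},
                              sigma=params_lo.sigma, theta_plus=300.0, theta_minus=-400.0)
        labels = tuple(rng.choice(["a", "b"], size=20))
        song = sd.SongModel("s", labels, "x")
        p_lo = sd.response_probability_exact(song, params_lo)
        p_hi = sd.response_probability_exact(song, params_hi)
        assert p_hi >= p_lo - 1e-6


class TestFirstPassage:
    def test_deterministic_limit_all_mass_at_step_10(self, ref_params):
        params0 = DDMParams(weights=ref_params.weights, sigma=0.0,
                            theta_plus=ref_params.theta_plus, theta_minus=ref_params.theta_minus)
        prof = sd.first_passage_profile(song_of("dorsatus"), params0)
        assert prof.p_lower[9] == 1.0
        assert prof.total() == 1.0

    @given(st.integers(0, 10_000))
    @settings(max_examples=15)
    def test_conservation_on_random_songs(self, seed):
        """Crossing masses plus terminal masses sum to one (exact backend)."""
        rng = np.random.default_rng(seed)
        params = DDMParams(
            weights={"a": float(rng.uniform(-80, 30)), "b": float(rng.uniform(-80, 30))},
            sigma=float(rng.uniform(10, 200)),
            theta_plus=float(rng.uniform(50, 600)),
            theta_minus=float(-rng.uniform(50, 900)),
        )
        song = sd.SongModel("s", tuple(rng.choice(["a", "b"], size=33)), "x")
        prof = sd.first_passage_profile(song, params)
        assert abs(prof.total() - 1.0) < 1e-9
        assert (prof.p_upper >= 0).all() and (prof.p_lower >= 0).all()

    def test_mc_and_exact_profiles_agree(self, ref_params):
        song = sd.build_song("switch-at-11", ("block", "mollis"))
        cfg = sd.DynamicsConfig(n_reps=100_000, seed=21)
        exact = sd.first_passage_profile(song, ref_params, cfg, backend="exact")
        mc = sd.first_passage_profile(song, ref_params, cfg, backend="mc")
        for pe, pm in zip(
            np.concatenate([exact.p_upper, exact.p_lower]),
            np.concatenate([mc.p_upper, mc.p_lower]),
        ):
            se = np.sqrt(max(pe * (1 - pe), 1e-12) / cfg.n_reps)
            assert abs(pe - pm) < 4 * se + 3e-4
        assert abs(mc.total() - 1.0) < 1e-12


class TestMeanTrajectory:
    def test_sigma_zero_equals_clamped_deterministic(self, ref_params):
        params0 = DDMParams(weights=ref_params.weights, sigma=0.0,
                            theta_plus=ref_params.theta_plus, theta_minus=ref_params.theta_minus)
        traj = sd.mean_trajectory(song_of("dorsatus"), params0)
        det = sd.integrate_deterministic(song_of("dorsatus"), params0)
        assert np.allclose(traj, det.evidence)

    def test_zero_drift_mean_stays_near_zero(self):
        params = DDMParams(weights={"a": 0.0}, sigma=30.0, theta_plus=500.0, theta_minus=-500.0)
        cfg = sd.DynamicsConfig(n_reps=20_000, seed=3)
        traj = sd.mean_trajectory(song_of("a"), params, cfg, backend="mc")
        bound = 3 * 30.0 * np.sqrt(33) / np.sqrt(cfg.n_reps)
        assert np.abs(traj).max() < bound + 1e-9

    def test_stays_within_thresholds(self, ref_params):
        song = sd.build_song("switch-at-11-reversed", ("block", "dorsatus"))
        traj = sd.mean_trajectory(song, ref_params, sd.DynamicsConfig(n_reps=5000, seed=2), backend="mc")
        assert traj.min() >= ref_params.theta_minus - 1e-9
        assert traj.max() <= ref_params.theta_plus + 1e-9

    def test_exact_backend_monotone_fall_during_negative_third(self, ref_params):
        """For the negative-first switch song the mean clamped evidence is
        non-increasing over the 11 heterospecific subunits."""
        song = sd.build_song("switch-at-11-reversed", ("block", "mollis"))
        traj = sd.mean_trajectory(song, ref_params, backend="exact")
        assert (np.diff(traj[:12]) <= 1e-9).all()

    def test_mc_and_exact_agree(self, ref_params):
        song = sd.build_song("switch-at-11", ("block", "mollis"))
        cfg = sd.DynamicsConfig(n_reps=100_000, seed=8)
        mc = sd.mean_trajectory(song, ref_params, cfg, backend="mc")
        exact = sd.mean_trajectory(song, ref_params, cfg, backend="exact")
        tol = 4 * ref_params.sigma * np.sqrt(33) / np.sqrt(cfg.n_reps)
        assert np.abs(mc - exact).max() < tol
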