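"""Tests of the simplex curve fit: exact recovery on clean data, robustness
on staircase data, determinism, and agreement with an independent
grid-search + linear-least-squares oracle."""

import math

import numpy as np
import pytest

from darkadapt import (DAParams, DarkAdaptationModel, FitConfig,
                       InsufficientDataError, ResponseSequence,
                       extract_fit_points, fit_participant, fit_sequence,
                       eval_model, make_observer, simulate_staircase)

from conftest import random_valid_params

TRUTH = DAParams(Bc=-1.5, Ic=2.0, Rc=-0.009, Ir=40.0, Rr=-0.0045, tb=700.0)


def clean_points(params=TRUTH, n=200, duration=2100.0):
    t = np.linspace(1.0, duration, n)
    return t, eval_model(params, t)


def make_sequence(times, intensities, detected=None, channel="green527"):
    if detected is None:
        detected = np.ones(len(times), bool)
    return ResponseSequence(channel=channel, times=times,
                            intensities=intensities, detected=detected)


class TestExtractFitPoints:
    def test_seen_only_keeps_detected_trials(self):
        t = np.arange(1.0, 11.0)
        seen = np.array([1, 0, 1, 0, 1, 0, 1, 0, 0, 0], bool)
        seq = make_sequence(t, np.linspace(1, 0, 10), seen)
        pts_t, pts_y = extract_fit_points(seq, "seen_only", min_points=4)
        assert len(pts_t) == 4
        assert np.all(np.diff(pts_t) > 0)

    def test_all_trials_keeps_everything(self):
        t = np.arange(1.0, 11.0)
        seq = make_sequence(t, np.linspace(1, 0, 10), np.zeros(10, bool))
        pts_t, _ = extract_fit_points(seq, "all_trials")
        assert len(pts_t) == len(seq)

    def test_too_few_points_raises(self):
        t = np.arange(1.0, 11.0)
        seen = np.zeros(10, bool)
        seen[:3] = True
        seq = make_sequence(t, np.linspace(1, 0, 10), seen)
        with pytest.raises(InsufficientDataError):
            extract_fit_points(seq, "seen_only")

    def test_noiseless_staircase_detections_bound_threshold(self, protocol):
        obs = make_observer(-1.56, -4.23, 11.4, slope=1e5, lapse_rate=0.0,
                            rng_seed=7)
        red, green = simulate_staircase(obs, protocol)
        for seq, true in ((red, obs.true_red), (green, obs.true_green)):
            t, y = extract_fit_points(seq, "seen_only")
            thresh = eval_model(true, t)
            # every detection lies at/above threshold and within one
            # down-step of it once the staircase has locked on
            settled = t > 120.0
            assert np.all(y[settled] >= thresh[settled] - 1e-9)
            assert np.all(y[settled] <= thresh[settled] + protocol.step_down_log + 1e-9)


class TestFitRecovery:
    def test_seed_at_truth_stays_at_truth(self):
        t, y = clean_points()
        res = DarkAdaptationModel(t, y).fit(start_params=TRUTH)
        assert res.sse < 1e-10
        np.testing.assert_allclose(res.params.as_array(), TRUTH.as_array(),
                                   rtol=1e-6)

    def test_perturbed_seed_recovers_within_one_percent(self):
        t, y = clean_points()
        pert = DAParams(Bc=TRUTH.Bc * 1.5, Ic=TRUTH.Ic * 0.5,
                        Rc=TRUTH.Rc * 1.5, Ir=TRUTH.Ir * 0.5,
                        Rr=TRUTH.Rr * 1.5, tb=TRUTH.tb * 0.5)
        res = DarkAdaptationModel(t, y).fit(start_params=pert)
        rel = np.abs((res.params.as_array() - TRUTH.as_array()) / TRUTH.as_array())
        assert np.all(rel < 0.01)

    def test_staircase_fit_recovers_observer(self, protocol):
        obs = make_observer(-1.56, -4.23, 11.4, slope=10.0, lapse_rate=0.02,
                            rng_seed=1)
        red, green = simulate_staircase(obs, protocol)
        pf = fit_participant(red, green)
        true = obs.true_outcome()
        assert abs(pf.outcome.trcb_minutes - true.trcb_minutes) * 60 < 60.0
        assert abs(pf.outcome.cone_threshold - true.cone_threshold) < 0.15
        assert abs(pf.outcome.rod_threshold - true.rod_threshold) < 0.15

    def test_objective_never_worse_than_seed(self, healthy_staircase):
        red, _ = healthy_staircase
        cfg = FitConfig()
        model = DarkAdaptationModel.from_sequence(red)
        res = model.fit(config=cfg)
        assert res.sse <= model.loss(res.seed_params) + 1e-12

    def test_bit_identical_across_repeated_runs(self, healthy_staircase):
        _, green = healthy_staircase
        a = fit_sequence(green)
        b = fit_sequence(green)
        assert a.params == b.params
        assert a.sse == b.sse and a.n_evals == b.n_evals

    def test_degenerate_constant_sequence_flagged(self):
        t = np.arange(1.0, 31.0) * 60.0
        seq = make_sequence(t, np.full(30, -2.0))
        res = fit_sequence(seq)
        assert not res.converged
        assert "degenerate_constant_intensity" in res.flags
        assert res.params.tb == pytest.approx(seq.test_duration / 2)

    def test_non_convergence_flagged_not_raised(self):
        t, y = clean_points(n=50)
        rng = np.random.default_rng(0)
        y = y + rng.normal(0, 0.3, len(y))
        cfg = FitConfig(max_evals=25, n_restarts=1)
        res = DarkAdaptationModel(t, y).fit(config=cfg)
        assert res.converged is False


class TestGridOracleEquivalence:
    """The simplex optimum must match an independent coarse-to-fine grid
    search over (tb, Rc, Rr) with the linear parameters (Bc, Ic, Ir)
    profiled out by least squares."""

    @staticmethod
    def grid_search_sse(t, y, duration=2100.0):
        def linear_sse(tb, rc, rr):
            f2 = np.exp(rc * np.minimum(t, tb))
            f3 = np.where(t >= tb, np.exp(rr * t) - math.exp(rr * tb), 0.0)
            X = np.column_stack([np.ones_like(t), f2, f3])
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            r = y - X @ beta
            return float(r @ r)

        tb_grid = np.linspace(120.0, duration - 120.0, 25)
        rc_grid = -10 ** np.linspace(-3.2, -1.4, 10)
        rr_grid = -10 ** np.linspace(-3.8, -1.8, 10)
        best = min(((linear_sse(tb, rc, rr), tb, rc, rr)
                    for tb in tb_grid for rc in rc_grid for rr in rr_grid))
        # refine around the coarse optimum
        _, tb0, rc0, rr0 = best
        tb_f = np.linspace(max(tb0 - 120, 30), min(tb0 + 120, duration - 30), 25)
        rc_f = rc0 * np.linspace(0.5, 2.0, 15)
        rr_f = rr0 * np.linspace(0.5, 2.0, 15)
        best = min(((linear_sse(tb, rc, rr), tb, rc, rr)
                    for tb in tb_f for rc in rc_f for rr in rr_f))
        return best[0]

    @staticmethod
    def clinical_range_params(rng):
        """Curve shapes spanning the clinically observed regime."""
        return DAParams(Bc=rng.uniform(-2.5, 0.0), Ic=rng.uniform(0.5, 3.0),
                        Rc=-10 ** rng.uniform(-2.7, -1.7),
                        Ir=rng.uniform(1.0, 50.0),
                        Rr=-10 ** rng.uniform(-3.2, -2.2),
                        tb=rng.uniform(300.0, 1400.0))

    def test_simplex_matches_grid_oracle(self):
        rng = np.random.default_rng(123)
        for _ in range(20):
            truth = self.clinical_range_params(rng)
            t = np.sort(rng.uniform(1.0, 2100.0, 40))
            y = eval_model(truth, t)
            res = DarkAdaptationModel(t, y).fit()
            oracle = self.grid_search_sse(t, y)
            assert res.sse <= oracle * 1.005 + 1e-8


class TestFitParticipant:
    def test_identical_channels_give_shared_cone_threshold(self, healthy_staircase):
        _, green = healthy_staircase
        red_copy = ResponseSequence(channel="red625", times=green.times,
                                    intensities=green.intensities,
                                    detected=green.detected)
        pf = fit_participant(red_copy, green)
        assert pf.outcome.cone_threshold == pf.green.params.Bc

    def test_insufficient_channel_marks_excluded(self, healthy_staircase):
        red, green = healthy_staircase
        empty = ResponseSequence(channel="red625", times=red.times[:8],
                                 intensities=red.intensities[:8],
                                 detected=np.zeros(8, bool))
        pf = fit_participant(empty, green)
        assert pf.excluded and "insufficient" in pf.reason
        assert pf.outcome is None

    def test_unpacks_as_triple(self, healthy_staircase):
        red, green = healthy_staircase
        r, g, outcome = fit_participant(red, green)
        assert r.model.channel == "red625"
        assert outcome.rod_threshold < outcome.cone_threshold
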