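"""Objective, acceptance rule, refinement, bootstrap and profiling
contracts (fast unit level; full parameter-recovery experiments live in the
acceptance suite)."""

import numpy as np
import pytest

from statewalk.fit import (
    AnnealingConfig,
    FitResult,
    anneal_fit,
    bootstrap_sse_threshold,
    metropolis_accept,
    profile_parameter,
    refine_fit,
    score_sse,
    temperature_schedule,
    _model_to_vector,
    _vector_to_model,
)
from statewalk.fixtures import make_one_state, make_tracks
from statewalk.model import MixtureModel, StateParams
from statewalk.pdf import PdfEvalConfig, mixture_bin_averaged_parallel
from statewalk.steps import Histogram, build_histogram, tracks_to_steps


def _model_histogram(model, pcfg, span=14.0, n_bins=80):
    """Histogram whose densities are exactly the model's bin averages
    (renormalized over the finite range; mass loss < 1e-12)."""
    edges = np.linspace(-span, span, n_bins + 1)
    d = mixture_bin_averaged_parallel(edges, model, pcfg)
    mass = np.sum(d * np.diff(edges))
    d = d / mass
    counts = np.round(d * np.diff(edges) * 1e6).astype(int)
    return Histogram(bin_edges=edges, densities=d, counts=counts, n_total=int(counts.sum()))


class TestScoreSse:
    def test_self_match_is_zero(self, persistent_state, pcfg_fast):
        m = MixtureModel([persistent_state], (1.0,))
        h = _model_histogram(m, pcfg_fast)
        assert score_sse(m, h, pcfg_fast) < 1e-12

    def test_single_bin_perturbation_adds_delta_squared(self, persistent_state, pcfg_fast):
        m = MixtureModel([persistent_state], (1.0,))
        h = _model_histogram(m, pcfg_fast)
        base = score_sse(m, h, pcfg_fast)
        delta = 0.37
        h.densities[40] += delta  # direct mutation: bypasses normalization on purpose
        assert score_sse(m, h, pcfg_fast) - base == pytest.approx(delta**2, rel=1e-4)

    def test_wrong_mean_scores_worse_than_truth(self, pcfg_fast):
        truth = MixtureModel([StateParams(3.0, 1.0, 0.7)], (1.0,))
        wrong = MixtureModel([StateParams(0.0, 1.0, 0.7)], (1.0,))
        ds = tracks_to_steps(make_one_state(truth.states[0], seed=5, n_tracks=20, n_steps=100))
        h = build_histogram(ds.dx_par)
        assert score_sse(wrong, h, pcfg_fast) > score_sse(truth, h, pcfg_fast)


class TestAnnealingRules:
    def test_improvements_always_accepted(self):
        assert metropolis_accept(-1.0, 0.5, u=0.999)
        assert metropolis_accept(0.0, 1e-9, u=0.999)

    @pytest.mark.parametrize("delta,temp", [(0.5, 1.0), (2.0, 0.7), (0.1, 0.05)])
    def test_uphill_acceptance_matches_boltzmann(self, delta, temp):
        p = np.exp(-delta / temp)
        assert metropolis_accept(delta, temp, u=p * 0.999)
        assert not metropolis_accept(delta, temp, u=p * 1.001)

    def test_zero_temperature_rejects_uphill(self):
        assert not metropolis_accept(0.1, 0.0, u=0.0)

    def test_temperature_schedule_is_geometric(self):
        acfg = AnnealingConfig(cooling_factor=0.8, n_epochs=5)
        np.testing.assert_allclose(
            temperature_schedule(2.0, acfg), 2.0 * 0.8 ** np.arange(5)
        )

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            AnnealingConfig(cooling_factor=1.0)
        with pytest.raises(ValueError):
            AnnealingConfig(t0=-1.0)

    def test_trace_is_monotone_and_model_valid(self, pcfg_fast):
        ds = tracks_to_steps(make_one_state(seed=3, n_tracks=5, n_steps=80))
        h = build_histogram(ds.dx_par)
        acfg = AnnealingConfig(n_restarts=2, n_epochs=8, steps_per_epoch=40, seed=1)
        fit = anneal_fit(h, 1, acfg, pcfg_fast)
        assert np.all(np.diff(fit.trace) <= 1e-15)
        assert fit.sse >= 0
        assert sum(fit.model.alphas) == pytest.approx(1.0)


class TestRefine:
    def test_at_optimum_stays_put(self, persistent_state, pcfg_fast):
        m = MixtureModel([persistent_state], (1.0,))
        h = _model_histogram(m, pcfg_fast)
        start = FitResult(model=m, sse=score_sse(m, h, pcfg_fast), n_states=1)
        out = refine_fit(start, h, pcfg_fast)
        assert out.sse <= start.sse + 1e-10

    def test_off_truth_start_improves(self, pcfg_fast):
        truth = MixtureModel([StateParams(3.0, 1.0, 0.7)], (1.0,))
        h = _model_histogram(truth, pcfg_fast)
        off = MixtureModel([StateParams(3.3, 1.1, 0.77)], (1.0,))
        start = FitResult(model=off, sse=score_sse(off, h, pcfg_fast), n_states=1)
        out = refine_fit(start, h, pcfg_fast)
        assert out.sse < start.sse
        assert out.model.states[0].mu_r == pytest.approx(3.0, abs=0.02)

    def test_boundary_alpha_stays_feasible(self, pcfg_fast):
        m = MixtureModel(
            [StateParams(3.0, 1.0, 0.7), StateParams(0.0, 2.0, 1.3)], (0.0, 1.0)
        )
        h = _model_histogram(m, pcfg_fast)
        start = FitResult(model=m, sse=score_sse(m, h, pcfg_fast), n_states=2)
        out = refine_fit(start, h, pcfg_fast, maxiter=300)
        assert 0.0 <= out.model.alphas[0] <= 1.0


class TestBootstrap:
    def _setup(self, pcfg):
        ds = tracks_to_steps(make_one_state(seed=4, n_tracks=10, n_steps=100))
        h = build_histogram(ds.dx_par)
        from statewalk.fixtures import ONE_STATE_MODEL

        fit = FitResult(
            model=ONE_STATE_MODEL, sse=score_sse(ONE_STATE_MODEL, h, pcfg), n_states=1
        )
        return ds, h, fit

    def test_single_replicate_returns_its_sse(self, pcfg_fast):
        ds, h, fit = self._setup(pcfg_fast)
        a = bootstrap_sse_threshold(ds, fit, n_boot=1, quantile=0.95, seed=9, pcfg=pcfg_fast, hist=h)
        b = bootstrap_sse_threshold(ds, fit, n_boot=1, quantile=0.05, seed=9, pcfg=pcfg_fast, hist=h)
        assert a == b >= 0.0

    def test_threshold_usually_exceeds_best_sse_on_clean_data(self, pcfg_fast):
        """The 95% bootstrap quantile should bound the true model's own SSE
        in most repeat calibrations (resampling oracle)."""
        ds, h, fit = self._setup(pcfg_fast)
        wins = sum(
            bootstrap_sse_threshold(
                ds, fit, n_boot=40, quantile=0.95, seed=s, pcfg=pcfg_fast, hist=h
            )
            > fit.sse
            for s in range(10)
        )
        assert wins >= 9

    def test_requires_at_least_one_replicate(self, pcfg_fast):
        ds, h, fit = self._setup(pcfg_fast)
        with pytest.raises(ValueError):
            bootstrap_sse_threshold(ds, fit, n_boot=0, pcfg=pcfg_fast, hist=h)


class TestProfile:
    def test_profile_minimum_at_estimate_and_ci_brackets(self, pcfg_fast):
        truth = MixtureModel([StateParams(3.0, 1.0, 0.7)], (1.0,))
        ds = tracks_to_steps(make_one_state(truth.states[0], seed=6, n_tracks=20, n_steps=100))
        h = build_histogram(ds.dx_par)
        start = FitResult(model=truth, sse=score_sse(truth, h, pcfg_fast), n_states=1)
        best = refine_fit(start, h, pcfg_fast)
        threshold = bootstrap_sse_threshold(
            ds, best, n_boot=60, seed=2, pcfg=pcfg_fast, hist=h
        )
        grid = np.linspace(2.7, 3.3, 7)
        prof = profile_parameter(best, h, "mu_r1", grid, threshold, pcfg=pcfg_fast)
        est = best.model.states[0].mu_r
        assert prof.ci_low <= est <= prof.ci_high
        # profiled SSE at the estimate's grid point cannot beat the estimate
        anchor = np.argmin(np.abs(grid - est))
        assert prof.profiled_sse[anchor] <= min(prof.profiled_sse) + 1e-6
        # truth inside the calibrated interval on clean synthetic data
        assert prof.ci_low <= 3.0 <= prof.ci_high

    def test_estimate_outside_grid_rejected(self, pcfg_fast):
        m = MixtureModel([StateParams(3.0, 1.0, 0.7)], (1.0,))
        h = _model_histogram(m, pcfg_fast)
        best = FitResult(model=m, sse=0.0, n_states=1)
        with pytest.raises(ValueError):
            profile_parameter(best, h, "mu_r1", np.linspace(5, 6, 5), 1.0, pcfg=pcfg_fast)

    def test_unknown_parameter_rejected(self, pcfg_fast):
        m = MixtureModel([StateParams(3.0, 1.0, 0.7)], (1.0,))
        h = _model_histogram(m, pcfg_fast)
        best = FitResult(model=m, sse=0.0, n_states=1)
        with pytest.raises(ValueError, match="unknown parameter"):
            profile_parameter(best, h, "alpha", np.linspace(0, 1, 5), 1.0, pcfg=pcfg_fast)

    def test_state_count_selection(self, mef_model, pcfg_fast):
        """One-state data keeps one state; clearly bimodal two-state data
        forces two (scaled-down decision experiment)."""
        from statewalk.fit import select_n_states
        from statewalk.fixtures import make_tracks

        acfg = AnnealingConfig(n_restarts=4, n_epochs=25, steps_per_epoch=80, seed=2)
        one = tracks_to_steps(make_one_state(seed=8, n_tracks=25, n_steps=200))
        sel1 = select_n_states(one, acfg, pcfg_fast, n_boot=80, weighting="pearson")
        assert sel1.n_states == 1

        sep = MixtureModel(
            [StateParams(5.0, 0.5, 0.3, "fast"), StateParams(0.0, 1.0, 2.5, "slow")],
            (0.4, 0.6),
        )
        two = tracks_to_steps(make_tracks(sep, 25, 200, seed=9))
        sel2 = select_n_states(two, acfg, pcfg_fast, n_boot=80, weighting="pearson")
        assert sel2.n_states == 2
        assert sel2.fit1.sse > sel2.threshold

    def test_vector_model_round_trip(self, mef_model):
        v = _model_to_vector(mef_model)
        back = _vector_to_model(v, 2, mef_model.dt)
        assert back.alphas[0] == pytest.approx(0.12, rel=1e-9)
        for a, b in zip(back.states, mef_model.states):
            assert a.mu_r == pytest.approx(b.mu_r)
            assert a.sigma_theta == pytest.approx(b.sigma_theta, rel=1e-12)
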