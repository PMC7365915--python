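"""Analytic step-density correctness: normalization, limits, symmetry,
Monte-Carlo equivalence at moderate sample size (the full 1e6-step check
lives in the acceptance suite)."""

import numpy as np
import pytest
from scipy.stats import norm

from statewalk.model import MixtureModel, StateParams, sample_steps
from statewalk.pdf import (
    PdfEvalConfig,
    PdfNormalizationError,
    bin_averaged_parallel,
    bin_averaged_perpendicular,
    mixture_bin_averaged_parallel,
    mixture_pdf_parallel,
    mixture_pdf_perpendicular,
    pdf_parallel,
    pdf_perpendicular,
    reference_flip_probability,
)
from statewalk.steps import build_histogram, tracks_to_steps
from statewalk.model import simulate_track


def _span(state, n_sig=8.0):
    w = n_sig * np.sqrt(state.sigma_r**2 + state.mu_r**2 + 1)
    return np.linspace(-w, w, 1601)


PARAM_GRID = [
    (mu, sr, st)
    for mu in (0.0, 1.0, 3.0)
    for sr in (0.5, 2.0)
    for st in (0.3, 0.7, 1.3, 3.0)
]


class TestNormalization:
    @pytest.mark.parametrize("mu,sr,st", PARAM_GRID[::3])  # subset; full grid in acceptance
    def test_parallel_and_perpendicular_integrate_to_one(self, mu, sr, st, pcfg):
        s = StateParams(mu, sr, st)
        edges = _span(s)
        for ba in (bin_averaged_parallel, bin_averaged_perpendicular):
            total = np.sum(ba(edges, s, 1.0, pcfg) * np.diff(edges))
            assert total == pytest.approx(1.0, abs=1e-6)

    def test_failing_self_check_raises(self):
        # far too few wrap terms for a huge angular dispersion
        s = StateParams(0.0, 1.0, 12.0)
        with pytest.raises(PdfNormalizationError):
            pdf_parallel(1.0, s, cfg=PdfEvalConfig(k_max=1))

    def test_dt_rescaling_matches_per_interval_convention(self, pcfg):
        # sigma_theta**2 * dt with dt = 4 equals a state with doubled sigmas at dt = 1
        a = StateParams(1.0, 0.5, 0.4)
        b = StateParams(1.0, 1.0, 0.8)
        for x in (0.5, 1.0, 2.5):
            assert pdf_parallel(x, a, dt=4.0, cfg=pcfg) == pytest.approx(
                pdf_parallel(x, b, dt=1.0, cfg=pcfg), rel=1e-9
            )


class TestLimits:
    def test_perfectly_persistent_limit_equals_step_normal(self, pcfg):
        s = StateParams(3.0, 1.0, 1e-4)
        for x in (2.0, 3.0, 4.0):
            assert pdf_parallel(x, s, cfg=pcfg) == pytest.approx(
                norm.pdf(x, 3.0, 1.0), abs=1e-4
            )

    def test_direction_uniform_limit_is_symmetric(self, pcfg):
        s = StateParams(2.0, 1.0, 10.0)
        xs = np.array([0.5, 1.0, 2.0, 4.0])
        f = pdf_parallel(xs, s, cfg=pcfg)
        g = pdf_parallel(-xs, s, cfg=pcfg)
        assert np.max(np.abs(f - g)) < 1e-6

    def test_wrap_truncation_is_adequate(self, persistent_state):
        xs = np.array([-2.0, 0.5, 3.0, 6.0])
        for st in (0.3, 1.3, 3.0):
            s = StateParams(1.0, 1.0, st)
            base = pdf_parallel(xs, s, cfg=PdfEvalConfig())
            more = pdf_parallel(xs, s, cfg=PdfEvalConfig(k_max=2 * (int(6 * st / 6.28) + 1) + 3))
            assert np.max(np.abs(base - more)) < 1e-10

    def test_quadrature_doubling_changes_nothing(self, persistent_state):
        xs = np.array([-1.0, 0.5, 3.0])
        a = pdf_parallel(xs, persistent_state, cfg=PdfEvalConfig(n_quad=400))
        b = pdf_parallel(xs, persistent_state, cfg=PdfEvalConfig(n_quad=800))
        assert np.max(np.abs(a - b)) < 1e-9

    def test_value_at_zero_is_finite_bin_average(self, persistent_state):
        v = pdf_parallel(0.0, persistent_state)
        assert np.isfinite(v) and v > 0


class TestSymmetryAndMixture:
    def test_perpendicular_density_is_even(self, persistent_state, pcfg):
        for y in (0.5, 1.0, 2.0):
            assert pdf_perpendicular(y, persistent_state, cfg=pcfg) == pytest.approx(
                pdf_perpendicular(-y, persistent_state, cfg=pcfg), abs=1e-12
            )

    def test_degenerate_mixture_weights_select_one_state(self, pcfg):
        s1 = StateParams(4.0, 0.5, 0.7)  # all-positive steps: no flip ambiguity
        s2 = StateParams(8.0, 0.5, 1.3)
        m1 = MixtureModel([s1, s2], (1.0, 0.0))
        m2 = MixtureModel([s1, s2], (0.0, 1.0))
        for x in (3.0, 4.0, 8.5):
            assert mixture_pdf_parallel(x, m1, pcfg) == pytest.approx(
                pdf_parallel(x, s1, cfg=pcfg), rel=1e-9
            )
            assert mixture_pdf_parallel(x, m2, pcfg) == pytest.approx(
                pdf_parallel(x, s2, cfg=pcfg), rel=1e-9
            )

    def test_mixture_is_convex_combination(self, pcfg):
        s1 = StateParams(3.0, 1.0, 0.7)
        s2 = StateParams(0.0, 2.0, 1.3)
        m = MixtureModel([s1, s2], (0.3, 0.7))
        x = 2.0
        expected = 0.3 * pdf_parallel(x, s1, cfg=pcfg) + 0.7 * pdf_parallel(x, s2, cfg=pcfg)
        assert mixture_pdf_parallel(x, m, pcfg, frame="polarity") == pytest.approx(
            expected, abs=1e-12
        )

    def test_flip_probability_values(self, mef_model):
        assert reference_flip_probability(
            MixtureModel([StateParams(0.0, 1.0, 1.0)], (1.0,))
        ) == pytest.approx(0.5)
        assert reference_flip_probability(
            MixtureModel([StateParams(8.0, 0.5, 1.0)], (1.0,))
        ) == pytest.approx(0.0, abs=1e-12)
        expected = 0.12 * norm.cdf(-3.0) + 0.88 * 0.5
        assert reference_flip_probability(mef_model) == pytest.approx(expected, rel=1e-12)


class TestMonteCarloEquivalence:
    @pytest.mark.parametrize("component", ["parallel", "perpendicular"])
    def test_single_state_polarity_frame_densities(self, persistent_state, pcfg_fast, component):
        """Empirical densities of the model's own step draws match the
        analytic solution bin by bin (4 sigma binomial envelopes)."""
        m = MixtureModel([persistent_state], (1.0,))
        n = 200_000
        r, turn, _ = sample_steps(m, n, rng=10)
        vals = r * np.cos(turn) if component == "parallel" else r * np.sin(turn)
        h = build_histogram(vals, bins=60)
        ba = bin_averaged_parallel if component == "parallel" else bin_averaged_perpendicular
        d = ba(h.bin_edges, persistent_state, 1.0, pcfg_fast)
        p = d * h.widths
        env = 4 * np.sqrt(p * (1 - p) / n) / h.widths
        check = p * n >= 10  # binomial normal approximation validity
        assert np.all(np.abs(h.densities - d)[check] <= env[check])

    def test_observed_frame_matches_transformed_tracks(self, mef_model, pcfg_fast):
        """The reflection-mixture density reproduces what track_to_steps
        measures, including the mirror peak from rearward steps."""
        ds = tracks_to_steps([simulate_track(mef_model, 200_000, rng=3)])
        h = build_histogram(ds.dx_par, bins=60)
        d = mixture_bin_averaged_parallel(h.bin_edges, mef_model, pcfg_fast)
        p = d * h.widths
        env = 4 * np.sqrt(p * (1 - p) / h.n_total) / h.widths
        check = p * h.n_total >= 10
        assert np.all(np.abs(h.densities - d)[check] <= env[check])

    def test_polarity_frame_misses_the_mirror_peak(self, mef_model, pcfg_fast):
        """Negative-step reference flips are real: ignoring them leaves
        systematic residuals near the mirrored mode."""
        ds = tracks_to_steps([simulate_track(mef_model, 200_000, rng=3)])
        h = build_histogram(ds.dx_par, bins=60)
        d = mixture_bin_averaged_parallel(h.bin_edges, mef_model, pcfg_fast, frame="polarity")
        p = np.clip(d * h.widths, 1e-12, None)
        env = 4 * np.sqrt(p * (1 - p) / h.n_total) / h.widths
        assert np.any(np.abs(h.densities - d) > env)
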