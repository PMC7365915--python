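"""Mixture-model inference from parallel-step histograms.

The mixture density for Δx∥ is scored against the empirical histogram by the
sum of squared differences (SSE) between bin-averaged analytic densities and
empirical bin densities.  The global search is simulated annealing with a
Metropolis acceptance rule and geometric cooling, run from several random
restarts; the best parameter set is then polished by a local simplex search.
Confidence statements come from profile curves: a parameter is fixed on a
grid, all others are re-optimized, and the interval is read off where the
profiled SSE stays below a threshold calibrated by bootstrap resampling of
the steps.

Parameters are searched in a transformed space — ``log sigma_r``,
``log sigma_theta`` and ``logit alpha`` — so Gaussian proposals and the
simplex can never leave the feasible region.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .model import MixtureModel, StateParams
from .pdf import (
    PdfEvalConfig,
    mixture_bin_averaged_parallel,
    mixture_bin_averaged_perpendicular,
)
from .steps import Histogram, StepDataset

__all__ = [
    "AnnealingConfig",
    "FitResult",
    "ProfileResult",
    "SelectionResult",
    "score_sse",
    "anneal_fit",
    "refine_fit",
    "fit_mixture",
    "fit_with_consistency",
    "consistency_check",
    "ConsistencyReport",
    "bootstrap_sse_threshold",
    "profile_parameter",
    "select_n_states",
    "metropolis_accept",
    "temperature_schedule",
]

log = logging.getLogger(__name__)

_LOGIT_EPS = 1e-12

# search box in transformed space, per parameter block
# (mu_r, log sigma_r, log sigma_theta, logit alpha); sigma_theta is capped at
# 20 rad/interval**0.5 — far beyond it the walk is already direction-uniform
_BOX = {
    "mu": (-1e3, 1e3),
    "lsr": (math.log(1e-3), math.log(1e3)),
    "lst": (math.log(1e-3), math.log(20.0)),
    "la": (-40.0, 40.0),
}


def _box_bounds(n_states: int) -> tuple[np.ndarray, np.ndarray]:
    lo = [_BOX["mu"][0], _BOX["lsr"][0], _BOX["lst"][0]] * n_states
    hi = [_BOX["mu"][1], _BOX["lsr"][1], _BOX["lst"][1]] * n_states
    if n_states == 2:
        lo.append(_BOX["la"][0])
        hi.append(_BOX["la"][1])
    return np.asarray(lo), np.asarray(hi)


@dataclass(frozen=True)
class AnnealingConfig:
    """Simulated-annealing schedule and proposal settings.

    ``t0 = None`` sets the initial temperature adaptively to the standard
    deviation of the objective over ``n_t0_probe`` random perturbations of
    the starting point, which targets a high early acceptance rate.
    ``proposal_scales`` are Gaussian proposal standard deviations in the
    transformed space, per parameter block ``(mu_r, log sigma_r,
    log sigma_theta, logit alpha)``.
    """

    t0: float | None = None
    cooling_factor: float = 0.90
    steps_per_epoch: int = 140
    n_epochs: int = 60
    proposal_scales: tuple[float, float, float, float] = (0.25, 0.15, 0.15, 0.4)
    n_restarts: int = 8
    n_t0_probe: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.cooling_factor < 1.0):
            raise ValueError("cooling_factor must lie in (0, 1)")
        if any(s <= 0 for s in self.proposal_scales):
            raise ValueError("proposal scales must be > 0")
        if self.t0 is not None and self.t0 <= 0:
            raise ValueError("t0 must be > 0")


@dataclass
class FitResult:
    """Point estimate with its objective value and per-epoch search trace."""

    model: MixtureModel
    sse: float
    n_states: int
    trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    restart_id: int = -1
    refined: bool = False
    #: every restart's result, best first (populated by anneal_fit)
    all_restarts: list["FitResult"] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.sse < 0:
            raise ValueError("sse must be >= 0")


@dataclass
class ProfileResult:
    """Profile curve for one parameter and the interval below a threshold."""

    param_name: str
    grid: np.ndarray
    profiled_sse: np.ndarray
    estimate: float
    threshold: float
    ci_low: float
    ci_high: float


@dataclass
class SelectionResult:
    """Outcome of the one-state vs two-state decision."""

    n_states: int
    fit1: FitResult
    fit2: FitResult
    threshold: float


# ---------------------------------------------------------------------------
# parameter vector <-> model


def _param_names(n_states: int) -> list[str]:
    names: list[str] = []
    for i in range(1, n_states + 1):
        names += [f"mu_r{i}", f"sigma_r{i}", f"sigma_theta{i}"]
    if n_states == 2:
        names.append("alpha")
    return names


def _model_to_vector(model: MixtureModel) -> np.ndarray:
    v: list[float] = []
    for s in model.states:
        v += [s.mu_r, math.log(s.sigma_r), math.log(s.sigma_theta)]
    if model.n_states == 2:
        a = min(max(model.alphas[0], _LOGIT_EPS), 1.0 - _LOGIT_EPS)
        v.append(math.log(a / (1.0 - a)))
    return np.asarray(v)


def _vector_to_model(v: np.ndarray, n_states: int, dt: float) -> MixtureModel:
    states = []
    for i in range(n_states):
        mu, lsr, lst = v[3 * i : 3 * i + 3]
        states.append(
            StateParams(float(mu), math.exp(lsr), math.exp(lst), label=f"state{i + 1}")
        )
    if n_states == 1:
        return MixtureModel(states, (1.0,), dt=dt)
    a = 1.0 / (1.0 + math.exp(-float(v[-1])))
    return MixtureModel(states, (a, 1.0 - a), dt=dt)


def _proposal_sd(acfg: AnnealingConfig, n_states: int) -> np.ndarray:
    s_mu, s_lsr, s_lst, s_la = acfg.proposal_scales
    sd = [s_mu, s_lsr, s_lst] * n_states
    if n_states == 2:
        sd.append(s_la)
    return np.asarray(sd)


# ---------------------------------------------------------------------------
# objective


def _weighted_sq(d_model: np.ndarray, hist: Histogram, weighting: str) -> float:
    if weighting == "none":
        return float(np.sum((d_model - hist.densities) ** 2))
    if weighting == "pearson":
        # inverse binomial variance of each bin density, evaluated at the
        # model density (Pearson chi-square), floored at one expected count
        floor = 1.0 / (hist.n_total * hist.widths)
        w = hist.n_total * hist.widths / np.maximum(d_model, floor)
        return float(np.sum(w * (d_model - hist.densities) ** 2))
    raise ValueError(f"weighting must be 'none' or 'pearson', got {weighting!r}")


def score_sse(
    model: MixtureModel,
    hist: Histogram,
    cfg: PdfEvalConfig = PdfEvalConfig(),
    frame: str = "observed",
    hist_perp: Histogram | None = None,
    weighting: str = "none",
) -> float:
    """Sum of squared differences between bin-averaged model and data densities.

    With ``hist_perp`` supplied the objective is the joint one: the parallel
    score plus the perpendicular score (used when the parallel-only fit fails
    the perpendicular consistency check).  ``weighting="pearson"`` divides
    each squared difference by the bin density's binomial variance under the
    model — the Pearson chi-square statistic, asymptotically equivalent to
    multinomial maximum likelihood and far more efficient than the
    unweighted sum when the informative structure lives in low-density bins.
    """
    d = mixture_bin_averaged_parallel(hist.bin_edges, model, cfg, frame=frame)
    sse = _weighted_sq(d, hist, weighting)
    if hist_perp is not None:
        dy = mixture_bin_averaged_perpendicular(hist_perp.bin_edges, model, cfg)
        sse += _weighted_sq(dy, hist_perp, weighting)
    return sse


def metropolis_accept(delta: float, temperature: float, u: float) -> bool:
    """Annealing acceptance: improvements always, otherwise with prob e^(-delta/T)."""
    if delta <= 0:
        return True
    if temperature <= 0:
        return False
    return u < math.exp(-delta / temperature)


def temperature_schedule(t0: float, acfg: AnnealingConfig) -> np.ndarray:
    """Geometric cooling: epoch e runs at ``t0 * cooling_factor**e``."""
    return t0 * acfg.cooling_factor ** np.arange(acfg.n_epochs)


# ---------------------------------------------------------------------------
# fitting


def _hist_moments(hist: Histogram) -> tuple[float, float]:
    w = hist.densities * hist.widths
    m = float(np.sum(w * hist.centers))
    var = float(np.sum(w * (hist.centers - m) ** 2))
    return m, math.sqrt(max(var, 1e-12))


def _sample_from_hist(hist: Histogram, rng: np.random.Generator, n: int) -> np.ndarray:
    p = hist.densities * hist.widths
    p = p / p.sum()
    idx = rng.choice(len(p), size=n, p=p)
    return hist.bin_edges[idx] + rng.random(n) * hist.widths[idx]

def _hist_quantile(hist: Histogram, q: float) -> float:
    cum = np.cumsum(hist.densities * hist.widths)
    i = int(np.searchsorted(cum, q))
    return float(hist.centers[min(i, len(cum) - 1)])


def _template_init(hist: Histogram, n_states: int, which: int) -> np.ndarray | None:
    """Deterministic mixture-style starting points (k-means-flavoured):
    a minority state seeded on a tail of the data, the majority state at the
    center.  Returns None when no template ``which`` exists."""
    m, s = _hist_moments(hist)
    if n_states == 1:
        if which > 0:
            return None
        return np.asarray([m, math.log(s), math.log(1.0)])
    templates = [
        (_hist_quantile(hist, 0.95), m, 0.15),
        (_hist_quantile(hist, 0.05), m, 0.15),
        (_hist_quantile(hist, 0.85), _hist_quantile(hist, 0.4), 0.3),
    ]
    if which >= len(templates):
        return None
    mu1, mu2, a = templates[which]
    return np.asarray(
        [
            mu1, math.log(s / 2), math.log(0.5),
            mu2, math.log(s), math.log(1.5),
            math.log(a / (1.0 - a)),
        ]
    )


def _random_init(
    hist: Histogram, n_states: int, rng: np.random.Generator, restart: int = -1
) -> np.ndarray:
    tpl = _template_init(hist, n_states, restart)
    if tpl is not None:
        return tpl
    # state means drawn from the data distribution itself spread restarts
    # over every mode of the histogram
    _, s = _hist_moments(hist)
    mus = _sample_from_hist(hist, rng, n_states)
    v: list[float] = []
    for mu in mus:
        v += [
            float(mu),
            math.log(s) + rng.uniform(math.log(0.2), math.log(1.2)),
            rng.uniform(math.log(0.2), math.log(2.5)),
        ]
    if n_states == 2:
        a = rng.uniform(0.05, 0.95)
        v.append(math.log(a / (1.0 - a)))
    return np.asarray(v)


def anneal_fit(
    hist: Histogram,
    n_states: int,
    acfg: AnnealingConfig = AnnealingConfig(),
    pcfg: PdfEvalConfig = PdfEvalConfig(),
    dt: float = 1.0,
    frame: str = "observed",
    hist_perp: Histogram | None = None,
    weighting: str = "none",
) -> FitResult:
    """Fit an ``n_states``-state mixture by multi-restart simulated annealing.

    Each restart draws a random data-informed starting point, then runs
    ``n_epochs`` epochs of ``steps_per_epoch`` Metropolis proposals at
    temperature ``t0 * cooling_factor**epoch``.  The best parameter set over
    all restarts is returned (without local refinement; see
    :func:`refine_fit`).
    """
    if n_states not in (1, 2):
        raise ValueError("n_states must be 1 or 2")
    if hist.n_total < 500:
        log.warning(
            "histogram built from only %d steps; fits below ~500 steps are unreliable",
            hist.n_total,
        )

    def objective(v: np.ndarray) -> float:
        sse = score_sse(
            _vector_to_model(v, n_states, dt), hist, pcfg, frame=frame,
            hist_perp=hist_perp, weighting=weighting,
        )
        if not math.isfinite(sse):
            raise FloatingPointError(f"non-finite SSE at parameter vector {v!r}")
        return sse

    sd = _proposal_sd(acfg, n_states)
    lo, hi = _box_bounds(n_states)
    results: list[FitResult] = []

    for restart in range(acfg.n_restarts):
        rng = np.random.default_rng([acfg.seed, restart])
        v = np.clip(_random_init(hist, n_states, rng, restart), lo, hi)
        sse = objective(v)

        t0 = acfg.t0
        if t0 is None:
            # probe with the same single-coordinate kernel the walk uses
            probes = []
            for _ in range(acfg.n_t0_probe):
                j = rng.integers(len(v))
                p = v.copy()
                p[j] = np.clip(p[j] + rng.normal(0.0, sd[j]), lo[j], hi[j])
                probes.append(objective(p))
            t0 = float(np.std(probes))
            if t0 <= 0:
                t0 = max(sse, 1e-6)

        local_best_v, local_best = v.copy(), sse
        trace = np.empty(acfg.n_epochs)
        for epoch, temperature in enumerate(temperature_schedule(t0, acfg)):
            for _ in range(acfg.steps_per_epoch):
                j = rng.integers(len(v))
                step = rng.normal(0.0, sd[j])
                u = rng.random()
                if not (lo[j] <= v[j] + step <= hi[j]):
                    continue  # proposals outside the search box are rejected
                cand = v.copy()
                cand[j] += step
                cand_sse = objective(cand)
                if metropolis_accept(cand_sse - sse, temperature, u):
                    v, sse = cand, cand_sse
                    if sse < local_best:
                        local_best_v, local_best = v.copy(), sse
            trace[epoch] = local_best

        results.append(
            FitResult(
                model=_vector_to_model(local_best_v, n_states, dt),
                sse=local_best,
                n_states=n_states,
                trace=trace,
                restart_id=restart,
            )
        )

    results.sort(key=lambda r: r.sse)
    best = results[0]
    best.all_restarts = results
    return best


def refine_fit(
    fit: FitResult,
    hist: Histogram,
    pcfg: PdfEvalConfig = PdfEvalConfig(),
    frame: str = "observed",
    maxiter: int = 4000,
    hist_perp: Histogram | None = None,
    weighting: str = "none",
) -> FitResult:
    """Polish a fit by Nelder-Mead simplex search in the transformed space.

    Never worse than the input: if the simplex ends higher (or fails to
    converge) the best iterate seen is kept.
    """
    if not math.isfinite(fit.sse):
        raise ValueError("refine_fit needs a finite starting SSE")
    n_states = fit.n_states
    dt = fit.model.dt
    lo, hi = _box_bounds(n_states)

    def objective(v: np.ndarray) -> float:
        if np.any(v < lo) or np.any(v > hi):
            excess = np.sum(np.maximum(lo - v, 0) + np.maximum(v - hi, 0))
            return 1e6 * (1.0 + excess)
        return score_sse(
            _vector_to_model(v, n_states, dt), hist, pcfg, frame=frame,
            hist_perp=hist_perp, weighting=weighting,
        )

    v0 = np.clip(_model_to_vector(fit.model), lo, hi)
    start_sse = objective(v0)  # re-scored with this pcfg; may differ from fit.sse
    res = minimize(
        objective,
        v0,
        method="Nelder-Mead",
        options={"maxiter": maxiter, "xatol": 1e-6, "fatol": 1e-12},
    )
    # restart the simplex once from the solution; cheap insurance against
    # premature collapse in 7 dimensions
    res = minimize(
        objective,
        res.x,
        method="Nelder-Mead",
        options={"maxiter": maxiter, "xatol": 1e-7, "fatol": 1e-13},
    )
    if not res.success:
        log.info("local refinement stopped early: %s", res.message)
    if res.fun <= start_sse:
        model, sse = _vector_to_model(res.x, n_states, dt), float(res.fun)
    else:
        model, sse = fit.model, start_sse
    return FitResult(
        model=model,
        sse=sse,
        n_states=n_states,
        trace=fit.trace,
        restart_id=fit.restart_id,
        refined=True,
    )


def fit_mixture(
    hist: Histogram,
    n_states: int,
    acfg: AnnealingConfig = AnnealingConfig(),
    pcfg: PdfEvalConfig = PdfEvalConfig(),
    dt: float = 1.0,
    frame: str = "observed",
    refine_top: int = 5,
    search_pcfg: PdfEvalConfig | None = None,
    hist_perp: Histogram | None = None,
    search_bins: int = 70,
    weighting: str = "none",
) -> FitResult:
    """Anneal, then locally refine the best ``refine_top`` restart results.

    The global search and the first refinement pass run on a cheapened
    objective — the histogram rebinned to about ``search_bins`` bins and a
    coarser quadrature (``search_pcfg``, default ``n_quad = 64``) — since
    they only need to find and rank basins; the winning candidate is then
    polished against the full-resolution histogram at full quadrature
    accuracy.  Returns the lowest-SSE refined fit.
    """
    from .steps import rebin

    if search_pcfg is None:
        search_pcfg = PdfEvalConfig(
            k_max=pcfg.k_max, n_quad=min(pcfg.n_quad, 64), rel_tol=max(pcfg.rel_tol, 1e-5)
        )
    s_hist = rebin(hist, search_bins)
    s_perp = rebin(hist_perp, search_bins) if hist_perp is not None else None
    best = anneal_fit(
        s_hist, n_states, acfg, search_pcfg, dt=dt, frame=frame,
        hist_perp=s_perp, weighting=weighting,
    )
    candidates = (best.all_restarts or [best])[:refine_top]
    coarse = [
        refine_fit(
            c, s_hist, search_pcfg, frame=frame, maxiter=2500,
            hist_perp=s_perp, weighting=weighting,
        )
        for c in candidates
    ]
    winner = min(coarse, key=lambda r: r.sse)
    out = refine_fit(winner, hist, pcfg, frame=frame, hist_perp=hist_perp, weighting=weighting)
    if frame == "observed":
        out.model = _canonical_sign(out.model)
    out.all_restarts = best.all_restarts
    return out


def _canonical_sign(model: MixtureModel) -> MixtureModel:
    """Resolve the mirror degeneracy of the observed frame.

    Negating every state's mu_r (forward motion <-> rearward motion with
    reversed polarity) leaves all observed-frame densities exactly
    unchanged — displacements alone cannot distinguish the two.  Fitted
    models are reported with non-negative occupancy-weighted mean drift.
    """
    drift = sum(a * s.mu_r for s, a in zip(model.states, model.alphas))
    if drift >= 0:
        return model
    states = [
        StateParams(-s.mu_r, s.sigma_r, s.sigma_theta, label=s.label) for s in model.states
    ]
    return MixtureModel(states, model.alphas, dt=model.dt)


@dataclass
class ConsistencyReport:
    """Outcome of checking a fitted model against the held-out Δy⊥ data."""

    ok: bool
    n_bad: int
    n_checked: int
    worst_ratio: float  # max |deviation| / envelope over checked bins
    chi2: float = 0.0
    chi2_threshold: float = 0.0


def consistency_check(
    model: MixtureModel,
    steps: StepDataset,
    pcfg: PdfEvalConfig = PdfEvalConfig(),
    bins="fd",
    n_sigma: float = 4.0,
    min_expected: float = 10.0,
    chi2_quantile: float = 0.995,
) -> ConsistencyReport:
    """Verify a fitted model against the held-out perpendicular distribution.

    The perpendicular components never enter the parallel-only objective, so
    agreement is genuine out-of-sample evidence.  Two tests run over the
    bins with at least ``min_expected`` expected counts (below that the
    normal approximation fails): each bin must match within ``n_sigma``
    binomial standard errors (catches localized misfit), and the aggregate
    Pearson chi-square over those bins must stay below the ``chi2_quantile``
    point of the chi-square distribution with that many degrees of freedom
    (catches diffuse misfit that no single bin reveals).
    """
    from scipy.stats import chi2 as chi2_dist

    from .steps import build_histogram

    hist = build_histogram(steps.dy_perp, bins=bins)
    d = mixture_bin_averaged_perpendicular(hist.bin_edges, model, pcfg)
    p = np.clip(d * hist.widths, 0.0, 1.0)
    env = n_sigma * np.sqrt(p * (1 - p) / hist.n_total) / hist.widths
    check = p * hist.n_total >= min_expected
    dev = np.abs(hist.densities - d)
    ratios = dev[check] / np.maximum(env[check], 1e-300)
    n_bad = int(np.sum(ratios > 1.0))
    n_checked = int(check.sum())
    w = hist.n_total * hist.widths / np.maximum(d, 1.0 / (hist.n_total * hist.widths))
    chi2 = float(np.sum((w * dev**2)[check]))
    chi2_threshold = float(chi2_dist.ppf(chi2_quantile, max(n_checked, 1)))
    return ConsistencyReport(
        ok=n_bad == 0 and chi2 <= chi2_threshold,
        n_bad=n_bad,
        n_checked=n_checked,
        worst_ratio=float(ratios.max()) if len(ratios) else 0.0,
        chi2=chi2,
        chi2_threshold=chi2_threshold,
    )


def fit_with_consistency(
    steps: StepDataset,
    n_states: int,
    acfg: AnnealingConfig = AnnealingConfig(),
    pcfg: PdfEvalConfig = PdfEvalConfig(),
    bins="fd",
    frame: str = "observed",
    weighting: str = "pearson",
) -> tuple[FitResult, ConsistencyReport, bool]:
    """Full estimation protocol: parallel-only fit, perpendicular check,
    joint refit on failure.

    The parallel distribution is the more informative one and fitting it
    alone is cheaper, but some parameter combinations (notably a minority
    state's angular dispersion) are only weakly constrained by it.  The
    perpendicular distribution is therefore used as an out-of-sample check
    of the parallel-only fit; when the check fails, the fit is repeated on
    the joint objective (parallel SSE + perpendicular SSE).

    Returns ``(fit, report, used_joint)``: the final fit, the consistency
    report for that final fit, and whether the joint refit was needed.
    """
    from .steps import build_histogram

    hist = build_histogram(steps.dx_par, bins=bins)
    fit = fit_mixture(hist, n_states, acfg, pcfg, dt=steps.dt, frame=frame, weighting=weighting)
    report = consistency_check(fit.model, steps, pcfg, bins=bins)
    if report.ok:
        return fit, report, False
    log.info(
        "parallel-only fit failed the perpendicular consistency check "
        "(%d/%d bins outside envelopes); refitting on the joint objective",
        report.n_bad,
        report.n_checked,
    )
    hist_perp = build_histogram(steps.dy_perp, bins=bins)
    fit = fit_mixture(
        hist, n_states, acfg, pcfg, dt=steps.dt, frame=frame,
        hist_perp=hist_perp, weighting=weighting,
    )
    report = consistency_check(fit.model, steps, pcfg, bins=bins)
    return fit, report, True


# ---------------------------------------------------------------------------
# calibration and profiling


def bootstrap_sse_threshold(
    steps: StepDataset,
    best: FitResult,
    n_boot: int = 200,
    quantile: float = 0.95,
    seed: int = 0,
    pcfg: PdfEvalConfig = PdfEvalConfig(),
    hist: Histogram | None = None,
    frame: str = "observed",
    weighting: str = "none",
    statistic: str = "data",
) -> float:
    """SSE threshold from bootstrap resampling of the pooled steps.

    Resamples the Δx∥ values with replacement (same N) and rebuilds the
    histogram on the *original* bin edges.  With ``statistic="data"`` (the
    default) each replicate is scored against the original empirical
    densities — the distance between two realizations of the same
    experiment, i.e. how large a score sampling noise alone can produce; a
    fitted model whose score exceeds the chosen quantile of that
    distribution misfits by more than a repeat experiment would.  With
    ``statistic="model"`` the fixed best-fit model is scored against each
    replicate instead; that variant inherits any model misfit into every
    replicate and is only meaningful for well-fitting models.  The
    threshold is the requested quantile of the replicate distribution.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if statistic not in ("data", "model"):
        raise ValueError(f"statistic must be 'data' or 'model', got {statistic!r}")
    values = steps.dx_par
    if hist is None:
        from .steps import build_histogram

        hist = build_histogram(values)
    edges = hist.bin_edges
    if statistic == "model":
        ref_d = mixture_bin_averaged_parallel(edges, best.model, pcfg, frame=frame)
    else:
        ref_d = hist.densities
    rng = np.random.default_rng(seed)
    n = len(values)
    sses = []
    n_skipped = 0
    for _ in range(n_boot):
        sample = values[rng.integers(0, n, size=n)]
        if np.ptp(sample) == 0:
            n_skipped += 1
            continue
        counts, _ = np.histogram(sample, bins=edges)
        dens = counts / (counts.sum() * np.diff(edges))
        rep = Histogram(bin_edges=edges, densities=dens, counts=counts)
        sses.append(_weighted_sq(ref_d, rep, weighting))
    if n_skipped:
        log.info("bootstrap: skipped %d degenerate replicates", n_skipped)
    if not sses:
        raise ValueError("all bootstrap replicates were degenerate")
    return float(np.quantile(sses, quantile))


def profile_parameter(
    best: FitResult,
    hist: Histogram,
    param_name: str,
    grid,
    threshold: float,
    acfg: AnnealingConfig = AnnealingConfig(),
    pcfg: PdfEvalConfig = PdfEvalConfig(),
    frame: str = "observed",
    maxiter: int = 2000,
    weighting: str = "none",
    hist_perp: Histogram | None = None,
) -> ProfileResult:
    """Profile curve: fix ``param_name`` on a grid, re-optimize the rest.

    Grid points are visited outward from the point estimate, warm-starting
    each local search from its inner neighbour's solution.  The confidence
    interval is the widest contiguous sub-grid containing the estimate on
    which the profiled SSE stays at or below ``threshold``.
    """
    names = _param_names(best.n_states)
    if param_name not in names:
        raise ValueError(f"unknown parameter {param_name!r}; choose from {names}")
    idx = names.index(param_name)
    n_states, dt = best.n_states, best.model.dt

    grid = np.asarray(grid, dtype=float)
    v_best = _model_to_vector(best.model)

    def to_internal(x: float) -> float:
        if param_name.startswith("sigma"):
            return math.log(x)
        if param_name == "alpha":
            x = min(max(x, _LOGIT_EPS), 1.0 - _LOGIT_EPS)
            return math.log(x / (1.0 - x))
        return x

    def from_internal(z: float) -> float:
        if param_name.startswith("sigma"):
            return math.exp(z)
        if param_name == "alpha":
            return 1.0 / (1.0 + math.exp(-z))
        return z

    estimate = from_internal(float(v_best[idx]))
    if not (grid.min() <= estimate <= grid.max()):
        raise ValueError(
            f"point estimate {estimate!r} for {param_name} lies outside the grid"
        )

    free = [i for i in range(len(v_best)) if i != idx]
    lo, hi = _box_bounds(n_states)

    def profiled(z_fixed: float, start: np.ndarray) -> tuple[float, np.ndarray]:
        def objective(vf: np.ndarray) -> float:
            v = np.empty(len(v_best))
            v[free] = vf
            v[idx] = z_fixed
            if np.any(v < lo) or np.any(v > hi):
                excess = np.sum(np.maximum(lo - v, 0) + np.maximum(v - hi, 0))
                return 1e6 * (1.0 + excess)
            return score_sse(
                _vector_to_model(v, n_states, dt), hist, pcfg, frame=frame,
                hist_perp=hist_perp, weighting=weighting,
            )

        res = minimize(
            objective,
            start[free],
            method="Nelder-Mead",
            options={"maxiter": maxiter, "xatol": 1e-5, "fatol": 1e-12},
        )
        v = np.empty(len(v_best))
        v[free] = res.x
        v[idx] = z_fixed
        return float(res.fun), v

    order = np.argsort(np.abs(grid - estimate))
    sse_grid = np.empty(len(grid))
    warm: dict[int, np.ndarray] = {}
    for rank, gi in enumerate(order):
        if rank == 0:
            start = v_best
        else:
            inner = min(
                (j for j in order[:rank]),
                key=lambda j: abs(grid[j] - grid[gi]),
            )
            start = warm[inner]
        sse_grid[gi], warm[gi] = profiled(to_internal(float(grid[gi])), start)

    ok = sse_grid <= threshold
    anchor = int(np.argmin(np.abs(grid - estimate)))
    lo = hi = anchor
    if ok[anchor]:
        while lo > 0 and ok[lo - 1]:
            lo -= 1
        while hi < len(grid) - 1 and ok[hi + 1]:
            hi += 1
    ci_low = min(float(grid[lo]), estimate)
    ci_high = max(float(grid[hi]), estimate)
    return ProfileResult(
        param_name=param_name,
        grid=grid,
        profiled_sse=sse_grid,
        estimate=estimate,
        threshold=threshold,
        ci_low=ci_low,
        ci_high=ci_high,
    )


def select_n_states(
    steps: StepDataset,
    acfg: AnnealingConfig = AnnealingConfig(),
    pcfg: PdfEvalConfig = PdfEvalConfig(),
    n_boot: int = 200,
    quantile: float = 0.95,
    bins="fd",
    frame: str = "observed",
    weighting: str = "none",
) -> SelectionResult:
    """Decide between one and two migration states.

    One state is preferred when the one-state fit's SSE does not exceed the
    bootstrap-calibrated threshold (sampling noise alone explains the
    residual); otherwise two states are needed.  Both fits are returned so a
    degenerate two-state solution can be inspected.
    """
    from .steps import build_histogram

    hist = build_histogram(steps.dx_par, bins=bins)
    fit1 = fit_mixture(hist, 1, acfg, pcfg, dt=steps.dt, frame=frame, weighting=weighting)
    fit2 = fit_mixture(hist, 2, acfg, pcfg, dt=steps.dt, frame=frame, weighting=weighting)
    threshold = bootstrap_sse_threshold(
        steps, fit1, n_boot=n_boot, quantile=quantile, seed=acfg.seed, pcfg=pcfg,
        hist=hist, frame=frame, weighting=weighting,
    )
    n = 1 if fit1.sse <= threshold else 2
    return SelectionResult(n_states=n, fit1=fit1, fit2=fit2, threshold=threshold)
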