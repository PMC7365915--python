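"""Analytic step-coordinate densities for the persistent random walk.

For one state, a step is ``(r cos(theta), r sin(theta))`` with
``r ~ Normal(mu_r, sigma_r**2 dt)`` and turning angle
``theta ~ Normal(0, sigma_theta**2 dt)`` about the previous direction.  The
density of the parallel component ``dx_par = r cos(theta)`` is

    f_X(x) = int_{-1}^{1} g_r(x / h) / |h| * f_H(h) dh,      h = cos(theta),

where ``f_H`` carries the wrapped-Gaussian angle density through the
``arccos`` change of variables, with the usual ``(1 - h**2)**-1/2`` factor
and a sum over wrap offsets ``2 pi k``.  Substituting ``h = cos(u)`` with
``u in (0, pi)`` cancels the endpoint singularity:

    f_X(x) = int_0^pi g_r(x / cos u) / |cos u| * A(u) du,
    A(u)   = sum_k [ g_theta(u + 2 pi k) + g_theta(-u + 2 pi k) ].

The perpendicular component ``dy_perp = r sin(theta)`` has the same form
with the angular weight shifted by ``pi/2``:
``B(u) = sum_k [ g_theta(pi/2 - u + 2 pi k) + g_theta(pi/2 + u + 2 pi k) ]``.
``f_Y`` is symmetric about zero (evaluated at ``|y|``, so exactly so).

The product density has an integrable logarithmic singularity at ``x = 0``
whenever ``g_r(0) > 0``.  All histogram comparisons therefore use
*bin-averaged* densities, which this module computes exactly: integrating
``g_r(x / cos u) / |cos u|`` over a bin in ``x`` gives a difference of normal
CDFs, so the bin average needs only the single angular quadrature and is
finite everywhere.  Pointwise evaluation at exactly ``x = 0`` falls back to a
narrow-bin average.

Multi-state mixtures are convex combinations of the per-state densities with
the occupancy fractions as weights.

Polarity frame versus observed frame
------------------------------------
The analytic solution above describes steps relative to the cell's
*polarity* axis.  A track transform, however, can only orient each step by
the previous *displacement*, and whenever the previous step had ``r < 0``
(rearward motion of a still-polarized cell) that observed reference is the
polarity axis rotated by pi.  Because step draws are i.i.d., the density of
the observed parallel component is the reflection mixture

    f_obs(x) = q f(x) + (1 - q) f(-x),
    q = P(r >= 0) = sum_i alpha_i * Phi(mu_ri / (sigma_ri sqrt(dt))),

while the perpendicular density is unaffected (it is symmetric).  The
correction is negligible when every state has ``mu_r >> sigma_r`` but large
when a state hovers near zero net motion.  Mixture-level functions
(the data-facing surface) accept ``frame="observed"`` (default) or
``frame="polarity"``; single-state functions always evaluate the
polarity-frame analytic solution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.special import ndtr

from .model import MixtureModel, StateParams

__all__ = [
    "PdfEvalConfig",
    "PdfNormalizationError",
    "pdf_parallel",
    "pdf_perpendicular",
    "bin_averaged_parallel",
    "bin_averaged_perpendicular",
    "mixture_pdf_parallel",
    "mixture_pdf_perpendicular",
    "reference_flip_probability",
    "mixture_bin_averaged_parallel",
    "mixture_bin_averaged_perpendicular",
]


class PdfNormalizationError(ValueError):
    """The angular quadrature failed its normalization self-check."""


@dataclass(frozen=True)
class PdfEvalConfig:
    """Numerical settings for density evaluation.

    ``k_max = None`` truncates the wrap sum adaptively at
    ``ceil(6 sigma_theta sqrt(dt) / (2 pi)) + 1``, which leaves wrapped-tail
    mass below ~1e-8.  ``n_quad`` Gauss-Legendre nodes are allocated over
    ``(0, pi)``, concentrated around the angular-weight peak when the
    turning dispersion is small.  Every evaluation checks that the angular
    weight integrates to 1 within ``rel_tol`` and raises
    :class:`PdfNormalizationError` otherwise.
    """

    k_max: int | None = None
    n_quad: int = 400
    rel_tol: float = 1e-6
    zero_bin_width: float | None = None  # um; default 1e-3 * sigma_r * sqrt(dt)

    def __post_init__(self) -> None:
        if self.k_max is not None and self.k_max < 1:
            raise ValueError("k_max must be >= 1")
        if self.n_quad < 8:
            raise ValueError("n_quad must be >= 8")
        if not (self.rel_tol > 0):
            raise ValueError("rel_tol must be > 0")


@lru_cache(maxsize=32)
def _leggauss(n: int) -> tuple[np.ndarray, np.ndarray]:
    return np.polynomial.legendre.leggauss(n)


#: half-width (rad) of the band around u = pi/2 that gets dedicated
#: transition panels when a saturation scale is supplied
_MID_BAND = 0.35


def _quad_nodes(
    peaks: tuple[float, ...], sig: float, n_quad: int, eps0: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Gauss-Legendre nodes/weights on (0, pi), concentrated near ``peaks``.

    When the angular weight is a narrow Gaussian of scale ``sig``, a single
    panel over (0, pi) under-resolves it; core panels of half-width
    ``8 sig`` around each peak take most of the nodes and the gaps share the
    rest.

    ``eps0`` marks a saturation scale around ``u = pi/2`` (where ``cos u``
    changes sign): bin masses and near-zero densities switch sharply between
    their limiting values once ``|cos u|`` drops below the smallest
    ``|x| / (|mu| + 9 sigma)`` in play.  The band ``pi/2 +- _MID_BAND`` is
    then tiled with geometrically shrinking panels down to ``eps0`` (inside
    which the integrand is flat), so every transition scale is resolved.
    """
    mid = 0.5 * math.pi
    cores: list[tuple[float, float]] = []
    for p in sorted(peaks):
        lo, hi = max(0.0, p - 8.0 * sig), min(math.pi, p + 8.0 * sig)
        if cores and lo <= cores[-1][1]:
            cores[-1] = (cores[-1][0], hi)
        else:
            cores.append((lo, hi))
    if len(cores) == 1 and cores[0][1] - cores[0][0] >= math.pi - 1e-12:
        panels = [(0.0, math.pi, n_quad)]
    else:
        gaps = []
        prev = 0.0
        for lo, hi in cores:
            if lo - prev > 1e-12:
                gaps.append((prev, lo))
            prev = hi
        if math.pi - prev > 1e-12:
            gaps.append((prev, math.pi))
        n_gap = n_quad // (4 * max(len(gaps), 1))
        n_core = (n_quad - n_gap * len(gaps)) // len(cores)
        panels = [(a, b, n_core) for a, b in cores] + [(a, b, n_gap) for a, b in gaps]

    if eps0 is not None:
        if any(abs(p - mid) < _MID_BAND for p in peaks):
            # an angular-weight peak sits inside the carved band (the
            # perpendicular case): the ladder must also resolve its scale
            eps0 = min(eps0, sig / 2.0)
        eps0 = min(max(eps0, 1e-8), _MID_BAND / 4)
        # carve the mid band out of the base panels
        lo_b, hi_b = mid - _MID_BAND, mid + _MID_BAND
        carved: list[tuple[float, float, int]] = []
        for a, b, n in panels:
            pieces = []
            if a < lo_b:
                pieces.append((a, min(b, lo_b)))
            if b > hi_b:
                pieces.append((max(a, hi_b), b))
            total = sum(q - p for p, q in pieces)
            for p, q in pieces:
                if q - p > 1e-12:
                    carved.append((p, q, max(8, int(n * (q - p) / max(b - a, 1e-12)))))
        panels = carved
        # geometric transition panels from the band edge down to eps0,
        # mirrored about pi/2, plus a small flat inner panel
        edges = [_MID_BAND]
        while edges[-1] / 4.0 > eps0:
            edges.append(edges[-1] / 4.0)
        edges.append(eps0)
        for outer, inner in zip(edges[:-1], edges[1:]):
            panels.append((mid - outer, mid - inner, 8))
            panels.append((mid + inner, mid + outer, 8))
        panels.append((mid - eps0, mid + eps0, 8))

    us, ws = [], []
    for a, b, n in panels:
        x, w = _leggauss(max(n, 8))
        us.append(0.5 * (b - a) * x + 0.5 * (a + b))
        ws.append(0.5 * (b - a) * w)
    u = np.concatenate(us)
    w = np.concatenate(ws)
    order = np.argsort(u)
    return u[order], w[order]


def _wrap_k(sig: float, k_max: int | None) -> int:
    if k_max is not None:
        return k_max
    return math.ceil(6.0 * sig / (2.0 * math.pi)) + 1


def _angular_weight(u: np.ndarray, sig: float, shift: float, k_max: int) -> np.ndarray:
    """sum_k g(shift - u + 2 pi k) + g(shift + u + 2 pi k) for g = Normal(0, sig**2)."""
    out = np.zeros_like(u)
    norm = 1.0 / (sig * math.sqrt(2.0 * math.pi))
    for k in range(-k_max, k_max + 1):
        off = shift + 2.0 * math.pi * k
        out += np.exp(-0.5 * ((off - u) / sig) ** 2)
        out += np.exp(-0.5 * ((off + u) / sig) ** 2)
    return norm * out


@lru_cache(maxsize=4096)
def _angular_parts(
    sig_t: float,
    shift: float,
    n_quad: int,
    k_max: int | None,
    with_flip: bool,
    eps0: float | None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray | None, float]:
    """Cached angular quadrature: nodes, weights, weight function, its flip.

    Caching pays off during fitting, where most proposals leave the angular
    dispersion (the only parameter entering here) untouched.
    """
    peaks = (shift,) if not with_flip else (shift, math.pi - shift)
    u, w = _quad_nodes(peaks, sig_t, n_quad, eps0)
    k = _wrap_k(sig_t, k_max)
    a = _angular_weight(u, sig_t, shift, k)
    a_flip = _angular_weight(math.pi - u, sig_t, shift, k) if with_flip else None
    total = float((w * a).sum())
    return u, w, a, a_flip, total


def _saturation_scale(xs: np.ndarray, mu: float, sig: float) -> float | None:
    """Below ``|cos u| = min|x| / (|mu| + 9 sigma)`` every CDF argument is
    past 9 sigma and the integrand sits at its limiting value; round to one
    significant figure so the quadrature cache stays hot."""
    ax = np.abs(xs[xs != 0.0])
    if len(ax) == 0:
        return 1e-8
    c0 = float(ax.min() / (abs(mu) + 9.0 * sig))
    c0 = min(max(c0, 1e-8), 0.99)
    eps0 = math.asin(c0)
    return float(f"{eps0:.0e}")


def _prepare(
    state: StateParams,
    dt: float,
    cfg: PdfEvalConfig,
    perpendicular: bool,
    flip_prob: float = 0.0,
    eps0: float | None = None,
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Angular quadrature (nodes, weight*A, mu, sigma_eff) with self-check.

    ``flip_prob > 0`` blends in the angular weight evaluated at ``pi - u``,
    which is exactly the reflection ``x -> -x`` of the resulting density
    (mirroring the step is the same as rotating the reference by pi).
    """
    sig_t = state.sigma_theta * math.sqrt(dt)
    sig_r = state.sigma_r * math.sqrt(dt)
    shift = 0.5 * math.pi if perpendicular else 0.0
    u, w, a, a_flip, total = _angular_parts(
        sig_t, shift, cfg.n_quad, cfg.k_max, flip_prob > 0.0, eps0
    )
    if abs(total - 1.0) > cfg.rel_tol:
        raise PdfNormalizationError(
            f"angular weight integrates to {total!r} (tolerance {cfg.rel_tol}) for "
            f"sigma_theta*sqrt(dt)={sig_t!r}; increase n_quad or k_max"
        )
    if flip_prob > 0.0:
        a = (1.0 - flip_prob) * a + flip_prob * a_flip
    return u, w * a, state.mu_r, sig_r


def _bin_averaged(
    edges: np.ndarray,
    state: StateParams,
    dt: float,
    cfg: PdfEvalConfig,
    perpendicular: bool,
    flip_prob: float = 0.0,
) -> np.ndarray:
    """Exact per-bin average of the analytic density (one angular quadrature).

    For each angular node the x-integral over a bin is
    ``|Phi((b/cos u - mu)/sigma) - Phi((a/cos u - mu)/sigma)|``.
    """
    edges = np.asarray(edges, dtype=float)
    if edges.ndim != 1 or len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("edges must be a 1-D increasing array of length >= 2")
    sig_r = state.sigma_r * math.sqrt(dt)
    eps0 = _saturation_scale(edges, state.mu_r, sig_r)
    u, wa, mu, sig = _prepare(state, dt, cfg, perpendicular, flip_prob, eps0)
    c = np.cos(u)
    c = np.where(np.abs(c) < 1e-300, 1e-300, c)  # nodes never sit at u = pi/2 exactly
    z = (edges[:, None] / c[None, :] - mu) / sig
    cdf = ndtr(z)
    mass = np.abs(np.diff(cdf, axis=0))  # (n_bins, n_nodes)
    return (mass @ wa) / np.diff(edges)


def _pointwise(
    x: np.ndarray,
    state: StateParams,
    dt: float,
    cfg: PdfEvalConfig,
    perpendicular: bool,
    flip_prob: float = 0.0,
) -> np.ndarray:
    x = np.atleast_1d(np.asarray(x, dtype=float))
    sig_r = state.sigma_r * math.sqrt(dt)
    eps0 = _saturation_scale(x, state.mu_r, sig_r)
    u, wa, mu, sig = _prepare(state, dt, cfg, perpendicular, flip_prob, eps0)
    c = np.cos(u)
    c = np.where(np.abs(c) < 1e-300, 1e-300, c)
    with np.errstate(under="ignore"):
        z = (x[:, None] / c[None, :] - mu) / sig
        g = np.exp(-0.5 * z**2) / (sig * math.sqrt(2.0 * math.pi))
        out = (g / np.abs(c)[None, :]) @ wa
    # the product density diverges logarithmically at exactly x = 0; report
    # the narrow-bin average there instead
    zero = x == 0.0
    if np.any(zero):
        w0 = cfg.zero_bin_width or 1e-3 * sig
        avg = _bin_averaged(
            np.array([-0.5 * w0, 0.5 * w0]), state, dt, cfg, perpendicular, flip_prob
        )
        out[zero] = avg[0]
    return out


def pdf_parallel(
    x, state: StateParams, dt: float = 1.0, cfg: PdfEvalConfig = PdfEvalConfig()
) -> np.ndarray | float:
    """Density (per um) of the step component parallel to the previous step."""
    out = _pointwise(x, state, dt, cfg, perpendicular=False)
    return float(out[0]) if np.isscalar(x) or np.ndim(x) == 0 else out


def pdf_perpendicular(
    y, state: StateParams, dt: float = 1.0, cfg: PdfEvalConfig = PdfEvalConfig()
) -> np.ndarray | float:
    """Density (per um) of the perpendicular step component.

    Symmetric about zero by construction: evaluated at ``|y|``.
    """
    out = _pointwise(np.abs(y), state, dt, cfg, perpendicular=True)
    return float(out[0]) if np.isscalar(y) or np.ndim(y) == 0 else out


def bin_averaged_parallel(
    edges, state: StateParams, dt: float = 1.0, cfg: PdfEvalConfig = PdfEvalConfig()
) -> np.ndarray:
    """Analytic parallel density averaged over each bin (per um)."""
    return _bin_averaged(np.asarray(edges), state, dt, cfg, perpendicular=False)


def bin_averaged_perpendicular(
    edges, state: StateParams, dt: float = 1.0, cfg: PdfEvalConfig = PdfEvalConfig()
) -> np.ndarray:
    """Analytic perpendicular density averaged over each bin (per um)."""
    return _bin_averaged(np.asarray(edges), state, dt, cfg, perpendicular=True)


def reference_flip_probability(model: MixtureModel) -> float:
    """Probability that a step's observed reference direction is flipped.

    Equals ``P(r < 0)`` for a random (previous) step of the mixture:
    ``sum_i alpha_i Phi(-mu_ri / (sigma_ri sqrt(dt)))``.
    """
    sqrt_dt = math.sqrt(model.dt)
    return float(
        sum(a * ndtr(-s.mu_r / (s.sigma_r * sqrt_dt)) for s, a in zip(model.states, model.alphas))
    )


def _check_frame(frame: str) -> None:
    if frame not in ("observed", "polarity"):
        raise ValueError(f"frame must be 'observed' or 'polarity', got {frame!r}")


def _mixture(fn, arg, model: MixtureModel, cfg: PdfEvalConfig, perpendicular: bool, frame: str):
    _check_frame(frame)
    flip = 0.0
    if frame == "observed" and not perpendicular:
        flip = reference_flip_probability(model)
    parts = [
        a * fn(arg, s, model.dt, cfg, perpendicular, flip)
        for s, a in zip(model.states, model.alphas)
    ]
    return sum(parts)


def mixture_pdf_parallel(
    x, model: MixtureModel, cfg: PdfEvalConfig = PdfEvalConfig(), frame: str = "observed"
):
    """Occupancy-weighted mixture density of the parallel step component.

    ``frame="observed"`` (default) applies the reflection mixture that
    accounts for reference flips from negative previous steps; it is the
    density of what a track transform actually measures.
    """
    out = _mixture(_pointwise, x, model, cfg, perpendicular=False, frame=frame)
    return float(out[0]) if np.ndim(x) == 0 else out


def mixture_pdf_perpendicular(y, model: MixtureModel, cfg: PdfEvalConfig = PdfEvalConfig()):
    """Occupancy-weighted mixture density of the perpendicular component.

    Identical in both frames: the perpendicular density is symmetric.
    """
    out = _mixture(_pointwise, np.abs(y), model, cfg, perpendicular=True, frame="polarity")
    return float(out[0]) if np.ndim(y) == 0 else out


def mixture_bin_averaged_parallel(
    edges, model: MixtureModel, cfg: PdfEvalConfig = PdfEvalConfig(), frame: str = "observed"
) -> np.ndarray:
    """Bin-averaged mixture density for Δx∥ — the fitting surface."""
    return _mixture(
        _bin_averaged, np.asarray(edges, dtype=float), model, cfg,
        perpendicular=False, frame=frame,
    )


def mixture_bin_averaged_perpendicular(
    edges, model: MixtureModel, cfg: PdfEvalConfig = PdfEvalConfig()
) -> np.ndarray:
    """Bin-averaged mixture density for Δy⊥ (held-out consistency checks)."""
    return _mixture(
        _bin_averaged, np.asarray(edges, dtype=float), model, cfg,
        perpendicular=True, frame="polarity",
    )
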