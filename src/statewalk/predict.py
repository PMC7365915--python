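"""Windowed Bayesian classification of migration states along a track.

Given a fitted mixture model, each step is assigned the state with the
largest posterior probability.  The likelihood of an odd-length window of
steps centered on the step of interest is the product of per-step analytic
densities (the steps are conditionally independent given the state under
the i.i.d.-mixture assumption), and Bayes' theorem with the occupancy
fractions as priors gives

    P(s_i | X) = P(X | s_i) alpha_i / sum_j P(X | s_j) alpha_j .

The posterior of the non-assigned state doubles as a per-step false-positive
probability.  All products are computed in log space.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .model import CellTrack, MixtureModel, StateParams
from .pdf import PdfEvalConfig, _pointwise, reference_flip_probability
from .steps import StepSample, track_to_steps

__all__ = [
    "StatePosterior",
    "window_likelihood",
    "posterior",
    "classify_track",
    "classification_accuracy",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class StatePosterior:
    """Per-step state posteriors; ``assigned_state`` is the argmax."""

    step_index: int
    posteriors: tuple[float, ...]
    assigned_state: int
    window_length: int


def _log_likelihood_terms(
    samples: list[StepSample],
    state: StateParams,
    dt: float,
    pcfg: PdfEvalConfig,
    use_perpendicular: bool,
    flip_prob: float = 0.0,
) -> float:
    dx = np.array([s.dx_par for s in samples])
    if not np.all(np.isfinite(dx)):
        raise ValueError("non-finite step components in window")
    with np.errstate(divide="ignore"):
        ll = float(np.sum(np.log(_pointwise(dx, state, dt, pcfg, False, flip_prob))))
        if use_perpendicular:
            dy = np.abs(np.array([s.dy_perp for s in samples]))
            ll += float(np.sum(np.log(_pointwise(dy, state, dt, pcfg, True))))
    return ll


def window_likelihood(
    window: list[StepSample],
    state: StateParams,
    dt: float = 1.0,
    pcfg: PdfEvalConfig = PdfEvalConfig(),
    use_perpendicular: bool = False,
) -> float:
    """Likelihood of an odd-length step window under one state.

    Product over the window of the parallel-component density (optionally
    times the perpendicular one).  Use :func:`posterior` for numerically
    safe classification; this returns the plain product and can underflow
    for long windows.
    """
    n = len(window)
    if n < 1 or n % 2 == 0:
        raise ValueError(f"window length must be odd and >= 1, got {n}")
    return float(np.exp(_log_likelihood_terms(window, state, dt, pcfg, use_perpendicular)))


def posterior(
    window: list[StepSample],
    model: MixtureModel,
    pcfg: PdfEvalConfig = PdfEvalConfig(),
    use_perpendicular: bool = False,
    frame: str = "observed",
    step_index: int | None = None,
) -> StatePosterior:
    """State posteriors for one window via Bayes' theorem, priors = alphas.

    Computed in log space; if every state's likelihood underflows to zero
    the priors are returned.  Ties are broken toward the larger-occupancy
    state.  ``frame="observed"`` evaluates per-state densities with the
    reference-flip correction so they describe transformed track data.
    """
    n = len(window)
    if n < 1 or n % 2 == 0:
        raise ValueError(f"window length must be odd and >= 1, got {n}")
    if step_index is None:
        step_index = window[n // 2].step_index

    alphas = np.asarray(model.alphas)
    if model.n_states == 1:
        return StatePosterior(step_index, (1.0,), 0, n)

    flip = reference_flip_probability(model) if frame == "observed" else 0.0
    ll = np.array(
        [
            _log_likelihood_terms(window, s, model.dt, pcfg, use_perpendicular, flip)
            for s in model.states
        ]
    )
    with np.errstate(divide="ignore"):
        logpost = ll + np.log(alphas)
    if np.all(np.isneginf(logpost)):  # all likelihoods underflowed
        post = alphas.copy()
    else:
        logpost -= np.max(logpost[np.isfinite(logpost)])
        post = np.exp(logpost)
        post /= post.sum()
    # argmax with ties broken toward the larger-alpha state
    best = max(range(model.n_states), key=lambda i: (post[i], alphas[i]))
    return StatePosterior(step_index, tuple(float(p) for p in post), int(best), n)


def classify_track(
    track: CellTrack,
    model: MixtureModel,
    window_length: int = 1,
    pcfg: PdfEvalConfig = PdfEvalConfig(),
    use_perpendicular: bool = False,
    frame: str = "observed",
) -> list[StatePosterior]:
    """Classify every step of a track; one :class:`StatePosterior` per step.

    Steps too close to the track ends for the requested window get the
    largest centered odd window that fits (always >= 1).  A sample's
    ``step_index`` refers to the current displacement, so it aligns with the
    simulator's ``true_states[step_index]``.
    """
    if window_length < 1 or window_length % 2 == 0:
        raise ValueError("window_length must be odd and >= 1")
    if window_length not in (1, 3, 5):
        warnings.warn(
            f"window length {window_length} is untested territory; 1, 3 and 5 "
            "are the validated choices",
            stacklevel=2,
        )
    ds = track_to_steps(track)
    samples = ds.samples
    if not samples:
        raise ValueError(f"track {track.cell_id!r} is too short to classify any step")
    out: list[StatePosterior] = []
    m = len(samples)
    for i in range(m):
        half = min(window_length // 2, i, m - 1 - i)
        window = samples[i - half : i + half + 1]
        out.append(
            posterior(
                window, model, pcfg, use_perpendicular, frame,
                step_index=samples[i].step_index,
            )
        )
    return out


def classification_accuracy(
    tracks, model: MixtureModel, window_length: int = 1,
    pcfg: PdfEvalConfig = PdfEvalConfig(), use_perpendicular: bool = False,
) -> float:
    """Fraction of classified steps whose assigned state matches ground truth.

    Only usable on simulated tracks carrying ``true_states``.
    """
    n_correct = 0
    n_total = 0
    for track in tracks:
        if track.true_states is None:
            raise ValueError(f"track {track.cell_id!r} has no ground-truth states")
        for sp in classify_track(track, model, window_length, pcfg, use_perpendicular):
            n_correct += int(sp.assigned_state == track.true_states[sp.step_index])
            n_total += 1
    if n_total == 0:
        raise ValueError("no classifiable steps")
    return n_correct / n_total
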