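"""Domain types and stochastic simulator for multi-state persistent random walks.

A migrating cell is modeled as a 2-D random walk with directional persistence:
during each sampling interval the cell advances a distance ``r`` drawn from
``Normal(mu_r, sigma_r**2 * dt)`` along a polarity angle ``theta`` drawn from
``Normal(theta_prev, sigma_theta**2 * dt)``.  Negative ``r`` is allowed and
means the centroid moves rearward while the cell keeps its polarization; the
next turning draw is still centered on the stored (unwrapped) polarity angle.

A cell may occupy one of ``n`` migration states, each with its own
``(mu_r, sigma_r, sigma_theta)``; the state of every step is an independent
categorical draw with occupancy fractions ``alpha`` (an i.i.d. mixture, the
degenerate limit of a hidden Markov model).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StateParams",
    "MixtureModel",
    "CellTrack",
    "sample_state",
    "simulate_track",
    "sample_steps",
]

_ALPHA_TOL = 1e-12


@dataclass(frozen=True)
class StateParams:
    """Parameters of one migration state.

    Parameters
    ----------
    mu_r : float
        Mean step magnitude (um per sampling interval).
    sigma_r : float
        Step-magnitude dispersion (um * interval**-0.5); the effective step
        distribution is ``Normal(mu_r, sigma_r**2 * dt)``.
    sigma_theta : float
        Turning-angle dispersion (rad * interval**-0.5); the effective turning
        distribution is ``Normal(0, sigma_theta**2 * dt)`` about the previous
        polarity angle.
    label : str
        Human-readable state name.
    """

    mu_r: float
    sigma_r: float
    sigma_theta: float
    label: str = ""

    def __post_init__(self) -> None:
        if not (self.sigma_r > 0):
            raise ValueError(f"sigma_r must be > 0, got {self.sigma_r}")
        if not (self.sigma_theta > 0):
            raise ValueError(f"sigma_theta must be > 0, got {self.sigma_theta}")


@dataclass(frozen=True)
class MixtureModel:
    """An n-state i.i.d. mixture of migration states.

    ``alphas[i]`` is the fraction of time spent in ``states[i]``; with the
    default ``dt = 1`` sampling-interval convention all state parameters are
    per-interval values.
    """

    states: tuple[StateParams, ...]
    alphas: tuple[float, ...]
    dt: float = 1.0

    def __init__(self, states, alphas=None, dt: float = 1.0):
        states = tuple(states)
        if len(states) < 1:
            raise ValueError("need at least one state")
        if alphas is None:
            if len(states) != 1:
                raise ValueError("alphas required for multi-state models")
            alphas = (1.0,)
        alphas = tuple(float(a) for a in alphas)
        if len(alphas) != len(states):
            raise ValueError("one occupancy fraction per state required")
        if any(a < -_ALPHA_TOL or a > 1 + _ALPHA_TOL for a in alphas):
            raise ValueError(f"alphas must lie in [0, 1], got {alphas}")
        if abs(sum(alphas) - 1.0) > _ALPHA_TOL:
            raise ValueError(f"alphas must sum to 1, got sum {sum(alphas)!r}")
        if not (dt > 0):
            raise ValueError("dt must be > 0")
        object.__setattr__(self, "states", states)
        object.__setattr__(self, "alphas", alphas)
        object.__setattr__(self, "dt", float(dt))

    @property
    def n_states(self) -> int:
        return len(self.states)


@dataclass
class CellTrack:
    """Time-ordered centroid positions for one cell.

    ``true_states`` (one index per displacement, so ``len(times) - 1``
    entries) is only present for simulated tracks.
    """

    cell_id: str
    times: np.ndarray
    xs: np.ndarray
    ys: np.ndarray
    true_states: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.xs = np.asarray(self.xs, dtype=float)
        self.ys = np.asarray(self.ys, dtype=float)
        n = len(self.times)
        if n < 2:
            raise ValueError("a track needs at least two observations")
        if len(self.xs) != n or len(self.ys) != n:
            raise ValueError("times, xs, ys must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.true_states is not None:
            self.true_states = np.asarray(self.true_states, dtype=int)
            if len(self.true_states) != n - 1:
                raise ValueError("true_states needs one entry per displacement")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def n_steps(self) -> int:
        return len(self.times) - 1

    def sampling_interval(self, rtol: float = 1e-6) -> float:
        """Uniform sampling interval; raises if spacing is non-uniform."""
        dts = np.diff(self.times)
        if not np.allclose(dts, dts[0], rtol=rtol):
            raise ValueError(
                f"track {self.cell_id!r} has non-uniform time spacing; "
                "model fitting requires a fixed sampling interval"
            )
        return float(dts[0])


def sample_state(model: MixtureModel, rng: np.random.Generator) -> int:
    """Draw one state index with probability ``alphas[i]`` (i.i.d. mixture)."""
    return int(rng.choice(model.n_states, p=model.alphas))


def simulate_track(
    model: MixtureModel,
    n_steps: int,
    start: tuple[float, float] = (0.0, 0.0),
    start_angle: float = 0.0,
    rng: np.random.Generator | int | None = None,
    cell_id: str = "sim",
    t0: float = 0.0,
) -> CellTrack:
    """Simulate a persistent-random-walk track of ``n_steps`` displacements.

    For each step a state is chosen i.i.d. with the occupancy fractions, a
    step magnitude ``r ~ Normal(mu_r, sigma_r**2 dt)`` and a turning increment
    ``delta ~ Normal(0, sigma_theta**2 dt)`` are drawn, the polarity angle is
    advanced by ``delta`` (kept unwrapped on the real line), and the position
    advances by ``(r cos(theta), r sin(theta))``.  Ground-truth state labels
    are recorded.  Passing the same seeded ``rng`` yields bit-identical
    tracks.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    rng = np.random.default_rng(rng)

    alphas = np.asarray(model.alphas)
    states = rng.choice(model.n_states, size=n_steps, p=alphas)
    mu = np.array([s.mu_r for s in model.states])[states]
    s_r = np.array([s.sigma_r for s in model.states])[states]
    s_t = np.array([s.sigma_theta for s in model.states])[states]
    sqrt_dt = np.sqrt(model.dt)

    r = rng.normal(mu, s_r * sqrt_dt)
    dtheta = rng.normal(0.0, s_t * sqrt_dt)
    theta = start_angle + np.cumsum(dtheta)

    xs = np.empty(n_steps + 1)
    ys = np.empty(n_steps + 1)
    xs[0], ys[0] = start
    xs[1:] = start[0] + np.cumsum(r * np.cos(theta))
    ys[1:] = start[1] + np.cumsum(r * np.sin(theta))

    times = t0 + model.dt * np.arange(n_steps + 1)
    return CellTrack(cell_id=cell_id, times=times, xs=xs, ys=ys, true_states=states)


def sample_steps(
    model: MixtureModel, n: int, rng: np.random.Generator | int | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw ``n`` i.i.d. steps ``(r, turn, state)`` in the polarity frame.

    Returns step magnitudes ``r ~ Normal(mu_r, sigma_r**2 dt)``, turning
    increments ``turn ~ Normal(0, sigma_theta**2 dt)`` relative to the cell's
    polarity axis, and the state index of each draw.  The polarity-frame step
    components are ``(r cos(turn), r sin(turn))``; note that the components
    a track transform observes are mirrored whenever the *previous* step had
    ``r < 0`` (the observed reference direction flips while polarity does
    not).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(rng)
    states = rng.choice(model.n_states, size=n, p=np.asarray(model.alphas))
    mu = np.array([s.mu_r for s in model.states])[states]
    s_r = np.array([s.sigma_r for s in model.states])[states]
    s_t = np.array([s.sigma_theta for s in model.states])[states]
    sqrt_dt = np.sqrt(model.dt)
    r = rng.normal(mu, s_r * sqrt_dt)
    turn = rng.normal(0.0, s_t * sqrt_dt)
    return r, turn, states
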