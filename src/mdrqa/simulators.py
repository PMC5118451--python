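"""Deterministic and seeded signal generators used throughout the package.

Two dynamical benchmarks — the Lorenz system and a pair of coupled van der
Pol oscillators — exercise the recurrence machinery on signals with known
structure; the stochastic generators (noisy sine, z-scored uniform
dimensions, coupled group signals) provide seeded fixtures for the
statistical and group-level analyses.  Every generator is reproducible:
identical parameters (and seed, where one applies) give bit-identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .datatypes import TimeSeriesSet
from .embedding import zscore_channels

__all__ = [
    "LorenzParams",
    "VdpParams",
    "GroupSignalParams",
    "simulate_lorenz",
    "simulate_vdp_pair",
    "gen_noisy_sine",
    "gen_random_dims",
    "gen_group_signals",
    "gen_team_study",
]

_ODE_TOL = 1e-9  # rtol = atol for both benchmark systems


@dataclass(frozen=True)
class LorenzParams:
    """Parameters of the Lorenz system

        dx/dt = sigma (y - x)
        dy/dt = x (rho - z) - y
        dz/dt = x y - beta z

    with the classical chaotic regime ``sigma=10, rho=28, beta=8/3`` as
    default.  The trajectory is integrated over ``[0, t_max]`` (after an
    optional transient of length ``discard`` that is integrated but not
    returned) and resampled on a uniform grid with step ``dt_sample``.

    The default initial state ``(10, 10, 10)`` lies near the attractor, so
    the sampled window is dominated by on-attractor dynamics rather than
    the approach transient.
    """

    sigma: float = 10.0
    rho: float = 28.0
    beta: float = 8.0 / 3.0
    t_max: float = 20.0
    dt_sample: float = 0.0162
    initial_state: tuple[float, float, float] = (10.0, 10.0, 10.0)
    discard: float = 0.0

    def __post_init__(self) -> None:
        if min(self.sigma, self.rho, self.beta) <= 0:
            raise ValueError("sigma, rho, beta must be positive")
        if self.dt_sample <= 0 or self.t_max <= self.dt_sample:
            raise ValueError("need t_max > dt_sample > 0")
        if self.discard < 0:
            raise ValueError("discard must be >= 0")


@dataclass(frozen=True)
class VdpParams:
    """Two coupled van der Pol oscillators

        x'' = mu (1 - x^2) x' - x + eps1 (x - y)
        y'' = mu (1 - y^2) y' - y + eps2 (y - x)

    ``mu`` sets the relaxation character (default 100, strongly stiff);
    ``eps1``/``eps2`` the asymmetric coupling (conventionally
    ``eps2 = 5 * eps1``).  Default initial state ``(x, x', y, y') =
    (2, 0, -2, 0)``: on-limit-cycle amplitudes in opposite phase.
    """

    mu: float = 100.0
    eps1: float = 0.01
    eps2: float | None = None  # None -> 5 * eps1
    t_max: float = 4000.0
    dt_sample: float = 2.0
    initial_state: tuple[float, float, float, float] = (2.0, 0.0, -2.0, 0.0)

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ValueError("mu must be positive")
        if self.dt_sample <= 0 or self.t_max <= self.dt_sample:
            raise ValueError("need t_max > dt_sample > 0")

    @property
    def eps2_value(self) -> float:
        return 5.0 * self.eps1 if self.eps2 is None else self.eps2


@dataclass(frozen=True)
class GroupSignalParams:
    """Synthetic coupled group signals (a skin-conductance-like stand-in).

    Each member's channel is a correlated slow latent drift plus member
    specific measurement noise.  The latent drifts are unit-variance AR(1)
    processes (a discretized Ornstein-Uhlenbeck drift, autocorrelation
    time ``drift_timescale`` samples) mixed through a matrix square root of
    ``pairwise_coupling``, so the latent inter-channel correlation matrix
    equals the requested coupling matrix.  ``pairwise_coupling`` must be
    symmetric with unit diagonal; an identity matrix gives independent
    members, an all-ones matrix identical ones.
    """

    n_members: int = 3
    n_samples: int = 2000
    pairwise_coupling: np.ndarray | None = None
    noise_sd: float = 0.1
    seed: int = 0
    drift_timescale: float = 50.0

    def __post_init__(self) -> None:
        if self.n_members < 1:
            raise ValueError("n_members must be >= 1")
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        C = self.pairwise_coupling
        if C is None:
            C = np.eye(self.n_members)
        C = np.asarray(C, dtype=float)
        if C.shape != (self.n_members, self.n_members):
            raise ValueError("coupling matrix shape must be (n_members, n_members)")
        if not np.allclose(C, C.T, atol=1e-12):
            raise ValueError("coupling matrix must be symmetric")
        if not np.allclose(np.diag(C), 1.0, atol=1e-12):
            raise ValueError("coupling matrix must have unit diagonal")
        object.__setattr__(self, "pairwise_coupling", C)


def _integrate(fun, t_span, y0, t_eval, method, name):
    sol = solve_ivp(
        fun,
        t_span,
        y0,
        method=method,
        rtol=_ODE_TOL,
        atol=_ODE_TOL,
        t_eval=t_eval,
        dense_output=False,
    )
    if not sol.success or not np.isfinite(sol.y).all():
        t_bad = sol.t[-1] if sol.t.size else t_span[0]
        raise RuntimeError(f"{name} integration failed (non-finite state near t={t_bad:.4g})")
    return sol.y


def simulate_lorenz(params: LorenzParams = LorenzParams(), zscore: bool = False) -> TimeSeriesSet:
    """Integrate the Lorenz system and resample it on a uniform grid.

    The grid is ``t = discard + k * dt_sample`` for
    ``k = 0 .. floor(t_max / dt_sample) - 1`` (so the canonical window
    ``t_max=20, dt_sample=0.0162`` yields 1234 samples per channel).
    Integration uses an adaptive Runge-Kutta scheme at rtol=atol=1e-9 with
    the solver's dense interpolant evaluated on the grid.  With
    ``zscore=True`` each channel is normalized to mean 0 / sd 1 after
    sampling.
    """
    p = params

    def rhs(t, s):
        x, y, z = s
        return (p.sigma * (y - x), x * (p.rho - z) - y, x * y - p.beta * z)

    n = int(np.floor(p.t_max / p.dt_sample))
    grid = p.discard + np.arange(n) * p.dt_sample
    y = _integrate(rhs, (0.0, p.discard + p.t_max), p.initial_state, grid, "RK45", "Lorenz")
    ts = TimeSeriesSet(y.T, ("x", "y", "z"), dt=p.dt_sample, t0=0.0)
    return zscore_channels(ts) if zscore else ts


def simulate_vdp_pair(params: VdpParams = VdpParams(), zscore: bool = False) -> TimeSeriesSet:
    """Integrate a pair of coupled van der Pol oscillators.

    The second-order equations are reduced to four first-order states
    ``(x, x', y, y')`` and integrated with LSODA (the system is stiff for
    large ``mu``); the returned channels are the positions ``x`` and ``y``
    on the uniform sampling grid.
    """
    p = params
    e1, e2 = p.eps1, p.eps2_value

    def rhs(t, s):
        x, xd, y, yd = s
        return (
            xd,
            p.mu * (1 - x * x) * xd - x + e1 * (x - y),
            yd,
            p.mu * (1 - y * y) * yd - y + e2 * (y - x),
        )

    n = int(np.floor(p.t_max / p.dt_sample))
    grid = np.arange(n) * p.dt_sample
    y = _integrate(rhs, (0.0, p.t_max), p.initial_state, grid, "LSODA", "van der Pol")
    ts = TimeSeriesSet(y[[0, 2]].T, ("x", "y"), dt=p.dt_sample, t0=0.0)
    return zscore_channels(ts) if zscore else ts


def gen_noisy_sine(
    n: int, period: float, noise_sd: float = 0.0, seed: int = 0
) -> TimeSeriesSet:
    """``sin(2 pi t / period)`` over ``t = 0..n-1`` plus seeded Gaussian noise."""
    if not n > period or period < 2:
        raise ValueError("need n > period >= 2")
    rng = np.random.default_rng(seed)
    t = np.arange(n)
    x = np.sin(2 * np.pi * t / period)
    if noise_sd > 0:
        x = x + rng.normal(0.0, noise_sd, size=n)
    return TimeSeriesSet(x[:, None], ("sine",), dt=1.0)


def gen_random_dims(n: int, D: int, seed: int = 0) -> TimeSeriesSet:
    """``D`` independent uniform[0, 1] channels of length ``n``, each z-scored.

    The z-scoring uses the sample standard deviation, so every channel has
    mean exactly 0 and sd (ddof=1) exactly 1 — the construction used to
    study how phase-space distance scales with dimensionality.
    """
    if n < 2 or D < 1:
        raise ValueError("need n >= 2 and D >= 1")
    rng = np.random.default_rng(seed)
    u = rng.uniform(0.0, 1.0, size=(n, D))
    names = tuple(f"u{j + 1}" for j in range(D))
    return zscore_channels(TimeSeriesSet(u, names, dt=1.0))


def _coupling_sqrt(C: np.ndarray) -> np.ndarray:
    # symmetric PSD square root; eigenvalue clipping tolerates the singular
    # all-ones (perfect coupling) case that Cholesky cannot factor
    w, V = np.linalg.eigh(C)
    w = np.clip(w, 0.0, None)
    return V * np.sqrt(w) @ V.T


def gen_group_signals(params: GroupSignalParams) -> TimeSeriesSet:
    """Generate coupled "skin-conductance-like" channels for a group.

    Independent unit-variance AR(1) drifts (one per member) are mixed
    through the matrix square root of the coupling matrix and white
    measurement noise of sd ``noise_sd`` is added per member.  Higher
    pairwise coupling therefore yields higher inter-channel correlation,
    exactly ``C_ij`` in the noise-free latents.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    phi = float(np.exp(-1.0 / p.drift_timescale))
    innov_sd = np.sqrt(1.0 - phi * phi)
    # stationary unit-variance AR(1) latents, one per member
    eps = rng.normal(size=(p.n_samples, p.n_members))
    lat = np.empty_like(eps)
    lat[0] = eps[0]
    for t in range(1, p.n_samples):
        lat[t] = phi * lat[t - 1] + innov_sd * eps[t]
    mixed = lat @ _coupling_sqrt(p.pairwise_coupling).T
    if p.noise_sd > 0:
        mixed = mixed + rng.normal(0.0, p.noise_sd, size=mixed.shape)
    names = tuple(f"member{j + 1}" for j in range(p.n_members))
    return TimeSeriesSet(mixed, names, dt=1.0)


def gen_team_study(
    n_teams: int,
    seed: int,
    design: str = "group",
    n_members: int = 3,
    n_samples: int = 300,
    outcome_noise_sd: float = 0.5,
) -> tuple[list[TimeSeriesSet], np.ndarray]:
    """Synthetic multi-team study with a known locus of outcome-relevant dynamics.

    Each team is an independent draw from :func:`gen_group_signals`; the
    per-team outcome is tied to a designed property of the team's dynamics:

    ``design="group"``
        The shared coupling of the whole team varies between teams
        (uniform off-diagonal coupling c ~ U(0.05, 0.95)) and drives the
        outcome.  Individual channel marginals are identical across
        teams, so only multi-member analyses carry outcome information.
    ``design="individual"``
        Members are uncoupled; the members' common drift timescale varies
        between teams and drives the outcome, so the information already
        lives in the single-channel dynamics.

    Returns the list of team signal sets and the outcome vector.
    """
    if design not in ("group", "individual"):
        raise ValueError("design must be 'group' or 'individual'")
    rng = np.random.default_rng(seed)
    teams: list[TimeSeriesSet] = []
    outcome = np.empty(n_teams)
    for t in range(n_teams):
        member_seed = int(rng.integers(2**31))
        if design == "group":
            c = rng.uniform(0.05, 0.95)
            C = np.full((n_members, n_members), c)
            np.fill_diagonal(C, 1.0)
            params = GroupSignalParams(n_members, n_samples, C, 0.1, member_seed)
            outcome[t] = 10.0 * c + rng.normal(0.0, outcome_noise_sd)
        else:
            timescale = rng.uniform(5.0, 80.0)
            params = GroupSignalParams(
                n_members, n_samples, np.eye(n_members), 0.1, member_seed,
                drift_timescale=timescale,
            )
            outcome[t] = 0.1 * timescale + rng.normal(0.0, outcome_noise_sd)
        teams.append(gen_group_signals(params))
    return teams, outcome
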