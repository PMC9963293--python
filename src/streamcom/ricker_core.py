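"""Multi-species Ricker dynamics with intentional release.

The model tracks densities :math:`N_{i,t}` of ``S`` competing species, one of
which (species 1, index 0) is "enhanced" by an externally controlled release
of ``R`` captive-bred individuals per time step:

.. math::

   N_{i,t+1} = (N_{i,t} + \\phi_i R_t)
       \\exp\\Big[r_i\\Big(1 - \\frac{\\alpha_{i1} R_t
           + \\sum_j \\alpha_{ij} N_{j,t}}{K_i}\\Big)\\Big] e^{\\epsilon_{i,t}}

where :math:`\\phi_i = f_R` for the enhanced species and 0 otherwise, so the
release enters both reproduction (released fish breed with relative fitness
``f_R``) and competition (released fish consume resources in their release
year regardless of fitness).  :math:`\\epsilon_{i,t}` is i.i.d.
``Normal(0, sigma_eps**2)`` environmental noise, independent across species.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CommunityParams",
    "ReleaseSchedule",
    "SimProtocol",
    "Trajectory",
    "SummaryStats",
    "step_community",
    "simulate",
    "summarize_window",
    "PERSISTENCE_THRESHOLD",
    "DIVERGENCE_LIMIT",
]

#: density below which a species counts as non-persistent in summaries
PERSISTENCE_THRESHOLD = 0.01

#: density above which a replicate is flagged as numerically diverged
DIVERGENCE_LIMIT = 1e12


# --------------------------------------------------------------------------
# parameter containers
# --------------------------------------------------------------------------


@dataclass
class CommunityParams:
    """Full parameterization of the S-species Ricker community.

    Parameters
    ----------
    r : array of shape (S,)
        Intrinsic growth rates :math:`r_i`.
    alpha : array of shape (S, S)
        Competition matrix; ``alpha[i, j]`` is the per-capita effect of
        species ``j`` on species ``i``.  The diagonal is fixed at 1
        (intraspecific competition sets the density scale).
    K : array of shape (S,)
        Carrying capacities :math:`K_i > 0`.
    sigma_eps : float
        SD of the environmental log-noise, ``>= 0``.
    f_R : float
        Relative fitness of captive-bred individuals, ``>= 0``.
    enhanced_index : int
        Index of the enhanced species (0 by convention).
    """

    r: np.ndarray
    alpha: np.ndarray
    K: np.ndarray
    sigma_eps: float = 0.0
    f_R: float = 1.0
    enhanced_index: int = 0

    def __post_init__(self) -> None:
        self.r = np.atleast_1d(np.asarray(self.r, dtype=float))
        self.K = np.broadcast_to(
            np.asarray(self.K, dtype=float), self.r.shape
        ).copy()
        self.alpha = np.atleast_2d(np.asarray(self.alpha, dtype=float))
        S = self.S
        if self.alpha.shape != (S, S):
            raise ValueError(
                f"alpha must be ({S}, {S}), got {self.alpha.shape}"
            )
        if not np.allclose(np.diag(self.alpha), 1.0):
            raise ValueError("diagonal of alpha must equal 1")
        if np.any(self.alpha < 0):
            raise ValueError("competition coefficients must be >= 0")
        if np.any(self.K <= 0):
            raise ValueError("carrying capacities must be > 0")
        if self.sigma_eps < 0:
            raise ValueError("sigma_eps must be >= 0")
        if self.f_R < 0:
            raise ValueError("f_R must be >= 0")
        if not 0 <= self.enhanced_index < S:
            raise ValueError("enhanced_index out of range")

    @property
    def S(self) -> int:
        return self.r.shape[0]

    @property
    def phi(self) -> np.ndarray:
        """Reproductive contribution of releases: f_R for the enhanced
        species, 0 for everyone else."""
        phi = np.zeros(self.S)
        phi[self.enhanced_index] = self.f_R
        return phi


@dataclass
class ReleaseSchedule:
    """Per-timestep release counts ``R_t >= 0``."""

    R_t: np.ndarray

    def __post_init__(self) -> None:
        self.R_t = np.asarray(self.R_t, dtype=float)
        if np.any(self.R_t < 0) or not np.all(np.isfinite(self.R_t)):
            raise ValueError("release counts must be finite and >= 0")

    @classmethod
    def constant(cls, R: float, protocol: "SimProtocol") -> "ReleaseSchedule":
        """Constant release ``R`` after the initialization window, zero
        before (the standard design: no release for the first ``T_init``
        steps, then ``R`` every step)."""
        R_t = np.zeros(protocol.T_total)
        R_t[protocol.T_init:] = R
        return cls(R_t)


@dataclass
class SimProtocol:
    """Timing and bookkeeping of a simulation run.

    Default windows: 100 initialization steps without release, 400 burn-in
    steps with release, and a saved window of the final 1,000 steps.
    ``reseed_every`` / ``extinction_threshold`` are switched on only for
    the N-species design (Poisson reseeding during initialization; an
    absorbing threshold below which a species is recorded extinct).
    """

    T_total: int = 1500
    T_init: int = 100
    T_burn: int = 400
    T_save: int = 1000
    init_density: float = 50.0
    reseed_every: int | None = None
    extinction_threshold: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.T_init + self.T_burn + self.T_save != self.T_total:
            raise ValueError("T_init + T_burn + T_save must equal T_total")
        if self.extinction_threshold is not None and self.extinction_threshold < 0:
            raise ValueError("extinction_threshold must be >= 0")

    @property
    def save_slice(self) -> slice:
        return slice(self.T_total - self.T_save, self.T_total)


@dataclass
class Trajectory:
    """Simulated densities, S x (T_total + 1) including the initial state."""

    density: np.ndarray
    extinct: np.ndarray
    extinction_time: np.ndarray
    diverged: bool
    params: CommunityParams
    protocol: SimProtocol

    @property
    def saved(self) -> np.ndarray:
        """Densities over the saved window (S x T_save).  Time index t of
        the model maps to column t of ``density``; the saved window is the
        final ``T_save`` states."""
        return self.density[:, -self.protocol.T_save:]


@dataclass
class SummaryStats:
    """Temporal summary statistics of the saved window, per species group.

    ``cv``, ``mu``, ``sd`` are dicts keyed by ``"whole"``, ``"enhanced"``,
    ``"unenhanced"``; a CV is ``None`` when the group mean is zero.
    ``n_persist`` counts species strictly above the persistence threshold
    at every saved step.
    """

    cv: dict = field(default_factory=dict)
    mu: dict = field(default_factory=dict)
    sd: dict = field(default_factory=dict)
    n_persist: int = 0


# --------------------------------------------------------------------------
# dynamics
# --------------------------------------------------------------------------


def step_community(
    state: np.ndarray,
    params: CommunityParams,
    R: float = 0.0,
    eps: np.ndarray | float = 0.0,
) -> np.ndarray:
    """One step of the release-augmented Ricker map.

    With ``eps = 0`` the map is deterministic.  The release ``R`` enters the
    reproduction prefactor through ``phi`` and the competition term through
    the enhanced species' column of ``alpha``.
    """
    state = np.asarray(state, dtype=float)
    if state.shape != (params.S,):
        raise ValueError(f"state must have shape ({params.S},)")
    if not np.all(np.isfinite(state)) or np.any(state < 0):
        raise ValueError("state must be finite and nonnegative")
    if not np.isfinite(R) or R < 0:
        raise ValueError("release count must be finite and >= 0")
    eps = np.broadcast_to(np.asarray(eps, dtype=float), state.shape)
    if not np.all(np.isfinite(eps)):
        raise ValueError("eps must be finite")

    crowding = params.alpha @ state + params.alpha[:, params.enhanced_index] * R
    growth = params.r * (1.0 - crowding / params.K)
    with np.errstate(over="ignore"):
        out = (state + params.phi * R) * np.exp(growth) * np.exp(eps)
    return out


def simulate(
    params: CommunityParams,
    schedule: ReleaseSchedule,
    protocol: SimProtocol,
    rng: np.random.Generator | None = None,
) -> Trajectory:
    """Run ``T_total`` steps of community dynamics.

    Environmental noise is drawn i.i.d. ``Normal(0, sigma_eps**2)`` per
    species per step.  When ``protocol.reseed_every`` is set, Poisson
    reintroductions with mean ``init_density`` are added on that cadence
    during the initialization window.  When ``protocol.extinction_threshold``
    is set, a species dropping below it is absorbed at 0 and flagged extinct.
    Densities exceeding ``DIVERGENCE_LIMIT`` mark the run as diverged and
    stop the integration (remaining states repeat the last value).
    """
    if rng is None:
        rng = np.random.default_rng(protocol.seed)
    S = params.S
    T = protocol.T_total
    if schedule.R_t.shape != (T,):
        raise ValueError(f"schedule must provide {T} release values")

    dens = np.zeros((S, T + 1))
    dens[:, 0] = protocol.init_density
    extinct = np.zeros(S, dtype=bool)
    ext_time = np.full(S, -1, dtype=int)
    diverged = False

    state = dens[:, 0].copy()
    for t in range(T):
        eps = rng.normal(0.0, params.sigma_eps, S) if params.sigma_eps > 0 else 0.0
        state = step_community(state, params, schedule.R_t[t], eps)
        state[extinct] = 0.0
        if protocol.extinction_threshold is not None:
            newly = (~extinct) & (state < protocol.extinction_threshold)
            state[newly] = 0.0
            ext_time[newly] = t + 1
            extinct |= newly
        if protocol.reseed_every and t + 1 < protocol.T_init and (
            (t + 1) % protocol.reseed_every == 0
        ):
            reseed = rng.poisson(protocol.init_density, S).astype(float)
            state = state + reseed
            revived = extinct & (state > 0)
            extinct[revived] = False
            ext_time[revived] = -1
        if not np.all(np.isfinite(state)) or np.any(state > DIVERGENCE_LIMIT):
            diverged = True
            state = np.where(np.isfinite(state), state, DIVERGENCE_LIMIT)
            dens[:, t + 1:] = state[:, None]
            break
        dens[:, t + 1] = state

    return Trajectory(
        density=dens,
        extinct=extinct,
        extinction_time=ext_time,
        diverged=diverged,
        params=params,
        protocol=protocol,
    )


# --------------------------------------------------------------------------
# summaries
# --------------------------------------------------------------------------


def _series_stats(series: np.ndarray) -> tuple[float | None, float, float]:
    mu = float(np.mean(series))
    sd = float(np.std(series, ddof=1)) if series.size > 1 else 0.0
    cv = sd / mu if mu > 0 else None
    return cv, mu, sd


def summarize_window(
    traj: Trajectory, window: slice | None = None
) -> SummaryStats:
    """Temporal CV / mean / SD of summed density over the saved window.

    Statistics are computed for the whole community, the enhanced species
    alone, and the summed unenhanced species.  SDs use the sample (n-1)
    denominator.  ``n_persist`` counts species strictly above
    ``PERSISTENCE_THRESHOLD`` at every step of the window.
    """
    if window is None:
        window = traj.protocol.save_slice
        # density has T_total + 1 columns; shift model-time slice by one
        window = slice(window.start + 1, window.stop + 1)
    saved = traj.density[:, window]
    if saved.size == 0:
        raise ValueError("summary window is empty")

    idx = traj.params.enhanced_index
    groups = {
        "whole": saved.sum(axis=0),
        "enhanced": saved[idx],
        "unenhanced": np.delete(saved, idx, axis=0).sum(axis=0),
    }
    stats = SummaryStats()
    for name, series in groups.items():
        cv, mu, sd = _series_stats(series)
        stats.cv[name] = cv
        stats.mu[name] = mu
        stats.sd[name] = sd
    stats.n_persist = int(np.sum(np.all(saved > PERSISTENCE_THRESHOLD, axis=1)))
    return stats
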