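"""Time integration of the overdamped alignment–repulsion dynamics.

The model: each of N agents advances at constant speed ``v0`` along its
heading ``n_hat_i = (cos theta_i, sin theta_i)`` while being displaced
by soft-core pair repulsion, and relaxes its heading toward the mean
heading of its contact neighbors on a timescale ``tau`` under angular
white noise of intensity ``sigma``:

    dr_i/dt     = v0 n_hat_i + F_i
    dtheta_i/dt = (1/tau) < mod*(theta_j - theta_i) >_{j in S_i} + sigma xi
    F_i         = sum_{j in S_i} ((r_int - |r_ji|)/r_int) r_ji/|r_ji|

with ``S_i`` the set of agents within ``r_int`` of i (excluding i) and
``mod*`` wrapping angle differences into [-pi, pi). Integration is
explicit Euler–Maruyama with synchronous updates from the pre-step
state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import _kernels
from .model_core import (
    ContactGraph,
    ModelParams,
    ParticleState,
    build_contact_graph,
    minimum_image,
    wrap_angle,
)

__all__ = [
    "IntegratorConfig",
    "StationarityCriterion",
    "BurnInResult",
    "alignment_rate",
    "repulsion_force",
    "step",
    "run_steps",
    "run_burn_in",
]


@dataclass(frozen=True)
class IntegratorConfig:
    """Integration settings.

    ``dt`` defaults (when None) to the ModelParams step. The config is
    validated against the model: ``dt <= tau/10`` for alignment
    stability, and the worst-case deterministic displacement
    ``(v0 + max_force_step) dt`` must stay below ``r_int/2`` so agents
    cannot tunnel through the interaction shell in one step.
    """

    dt: Optional[float] = None
    rng_seed: int = 0
    max_force_step: float = 4.0  # assumed bound on |F| (units of speed)

    def resolve_dt(self, mp: ModelParams) -> float:
        dt = self.dt if self.dt is not None else mp.dt
        if not dt > 0:
            raise ValueError(f"dt must be > 0, got {dt}")
        if dt > mp.tau / 10.0 + 1e-15:
            raise ValueError(f"dt={dt} exceeds tau/10={mp.tau / 10}: alignment unstable")
        if (mp.v0 + self.max_force_step) * dt >= mp.r_int / 2.0:
            raise ValueError(
                f"(v0 + max_force_step) * dt = {(mp.v0 + self.max_force_step) * dt} "
                f">= r_int/2: step too large"
            )
        return dt


def alignment_rate(theta_i: float, neighbor_thetas: Sequence[float], tau: float) -> float:
    """Angular drift (1/tau) <mod*(theta_j - theta_i)> over the neighbors.

    Zero for an empty neighbor list (an isolated agent keeps its
    heading, up to noise).
    """
    if tau <= 0:
        raise ValueError(f"tau must be > 0, got {tau}")
    nb = np.asarray(neighbor_thetas, dtype=float)
    if nb.size == 0:
        return 0.0
    return float(np.mean(wrap_angle(nb - theta_i))) / tau


def repulsion_force(
    i: int,
    state: ParticleState,
    graph: ContactGraph,
    r_int: float,
    L: float,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Soft-core repulsion on agent i from its contact neighbors.

    Each neighbor j contributes ``((r_int - |r_ji|)/r_int) r_ji/|r_ji|``
    with ``r_ji`` the minimum-image displacement from j to i: magnitude
    1 at contact, decaying linearly to 0 at separation r_int. For
    coincident particles (|r_ji| = 0, where the unit vector is
    undefined) the contribution is a uniformly random unit vector.
    """
    f = np.zeros(2)
    for j in graph.neighbors(i):
        d = minimum_image(state.positions[i], state.positions[j], L)
        r = float(np.hypot(d[0], d[1]))
        if r > 1e-12:
            f += (r_int - r) / r_int * d / r
        else:
            if rng is None:
                rng = np.random.default_rng()
            ang = rng.random() * 2.0 * np.pi
            f += np.array([np.cos(ang), np.sin(ang)])
    return f


def step(
    state: ParticleState,
    mp: ModelParams,
    cfg: IntegratorConfig,
    rng: np.random.Generator,
) -> ParticleState:
    """One Euler–Maruyama step; forces and alignment from the pre-step state."""
    if not np.all(np.isfinite(state.positions)) or not np.all(np.isfinite(state.headings)):
        raise FloatingPointError("NaN/Inf in particle state before step")
    dt = cfg.resolve_dt(mp)
    graph = build_contact_graph(state, mp.r_int, mp.L)
    new_pos, new_theta = _kernels.spatial_update(
        state.positions, state.headings, graph.indptr, graph.indices,
        mp.L, mp.v0, mp.r_int, mp.sigma, mp.tau, dt, rng,
    )
    return ParticleState(new_pos, new_theta, state.time + dt)


def run_steps(
    state: ParticleState,
    mp: ModelParams,
    n_steps: int,
    rng: np.random.Generator,
    dt: Optional[float] = None,
    record_every: Optional[int] = None,
):
    """Integrate ``n_steps`` spatial steps (no contagion).

    Returns ``(state, phi_series, lam_series)`` where the order
    parameters are sampled after every ``record_every``-th step
    (default: once per simulated time unit).
    """
    dt = dt if dt is not None else mp.dt
    if record_every is None:
        record_every = max(1, round(1.0 / dt))
    n_rec = n_steps // record_every + 1
    rec_phi = np.empty(n_rec)
    rec_lam = np.empty(n_rec)
    pos = state.positions.copy()
    theta = state.headings.copy()
    nrec = _kernels.run_spatial(
        pos, theta, mp.L, mp.v0, mp.r_int, mp.sigma, mp.tau, dt,
        n_steps, record_every, rng, rec_phi, rec_lam,
    )
    out = ParticleState(pos, theta, state.time + n_steps * dt)
    return out, rec_phi[:nrec], rec_lam[:nrec]


@dataclass(frozen=True)
class StationarityCriterion:
    """Sliding-window stationarity rule for the burn-in.

    The run is considered stationary when the means of both order
    parameters (polarization Phi, largest-cluster fraction Lambda) over
    two consecutive windows of ``window`` time units differ by less
    than ``eps``, subject to a minimum burn-in time ``t_min`` (ordered
    states coarsen slowly and can look window-stationary while still
    climbing) and a hard cap ``t_max``.
    """

    window: float = 200.0
    eps: float = 0.05
    t_max: float = 5000.0
    t_min: float = 1500.0


@dataclass
class BurnInResult:
    state: ParticleState
    converged: bool
    t: np.ndarray          # sample times of the order-parameter series
    phi: np.ndarray
    lam: np.ndarray

    @property
    def phi_bar(self) -> float:
        """Mean polarization over the last window of samples."""
        return float(np.mean(self.phi[-min(len(self.phi), 200):]))

    @property
    def lam_bar(self) -> float:
        return float(np.mean(self.lam[-min(len(self.lam), 200):]))

    def write_series(self, path) -> None:
        """Write the order-parameter time series as CSV (t, phi, lam)."""
        import pandas as pd

        pd.DataFrame({"t": self.t, "phi": self.phi, "lam": self.lam}).to_csv(
            path, index=False
        )


def run_burn_in(
    initial: ParticleState,
    mp: ModelParams,
    cfg: Optional[IntegratorConfig] = None,
    criterion: Optional[StationarityCriterion] = None,
    rng: Optional[np.random.Generator] = None,
) -> BurnInResult:
    """Integrate until the spatial dynamics is statistically stationary.

    Phi and Lambda are sampled once per time unit; after each window of
    ``criterion.window`` time units the means of the last two windows
    are compared. If the cap ``t_max`` is reached without meeting the
    criterion the final state is still returned with
    ``converged=False`` (not an exception).
    """
    cfg = cfg if cfg is not None else IntegratorConfig()
    criterion = criterion if criterion is not None else StationarityCriterion()
    if rng is None:
        rng = np.random.default_rng(cfg.rng_seed)
    dt = cfg.resolve_dt(mp)
    record_every = max(1, round(1.0 / dt))
    sample_dt = record_every * dt
    steps_per_window = max(1, round(criterion.window / sample_dt))

    state = initial
    phi_hist: list = []
    lam_hist: list = []
    t_hist: list = []
    converged = False
    elapsed = 0.0
    while elapsed < criterion.t_max - 1e-9:
        block_steps = steps_per_window * record_every
        state, phis, lams = run_steps(state, mp, block_steps, rng, dt=dt,
                                      record_every=record_every)
        t_hist.extend(elapsed + sample_dt * (np.arange(len(phis)) + 1))
        phi_hist.extend(phis)
        lam_hist.extend(lams)
        elapsed += block_steps * dt
        if len(phi_hist) >= 2 * steps_per_window and elapsed >= criterion.t_min:
            w2 = slice(-steps_per_window, None)
            w1 = slice(-2 * steps_per_window, -steps_per_window)
            dphi = abs(np.mean(phi_hist[w2]) - np.mean(phi_hist[w1]))
            dlam = abs(np.mean(lam_hist[w2]) - np.mean(lam_hist[w1]))
            if dphi < criterion.eps and dlam < criterion.eps:
                converged = True
                break
    return BurnInResult(
        state=state,
        converged=converged,
        t=np.asarray(t_hist),
        phi=np.asarray(phi_hist),
        lam=np.asarray(lam_hist),
    )
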