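"""Synchronous SIR dynamics on the evolving proximity graph.

Each agent carries a ternary label S (susceptible), I (infected), or
R (recovered, absorbing). Per integration step of length dt, a
susceptible agent in contact with k infected agents is infected with
probability ``min(1, k beta_b dt)`` (pairwise transmissions treated as
independent and summed, valid for small steps) and each infected agent
recovers with probability ``gamma dt``. All transitions are evaluated
against the pre-step state and applied simultaneously; an agent
infected in a step can neither transmit nor recover within that step.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import _kernels
from .model_core import (
    ContactGraph,
    EpidemicParams,
    ModelParams,
    ParticleState,
    minimum_image,
)

__all__ = [
    "S", "I", "R",
    "EpidemicState",
    "OutbreakResult",
    "infection_probability",
    "contagion_step",
    "seed_infections",
    "run_outbreak",
    "epidemic_params_from_theta",
    "contagion_dt",
    "spawn_streams",
]

S, I, R = 0, 1, 2


@dataclass
class EpidemicState:
    """Per-agent SIR labels plus aggregate counts/fractions."""

    labels: np.ndarray  # int8, values in {0=S, 1=I, 2=R}

    def __post_init__(self):
        self.labels = np.ascontiguousarray(self.labels, dtype=np.int8)
        if self.labels.ndim != 1:
            raise ValueError("labels must be one-dimensional")
        if self.labels.size and (self.labels.min() < 0 or self.labels.max() > 2):
            raise ValueError("labels must take values in {0, 1, 2}")

    @classmethod
    def all_susceptible(cls, N: int) -> "EpidemicState":
        return cls(np.zeros(N, dtype=np.int8))

    @property
    def N(self) -> int:
        return self.labels.size

    @property
    def n_S(self) -> int:
        return int(np.count_nonzero(self.labels == S))

    @property
    def n_I(self) -> int:
        return int(np.count_nonzero(self.labels == I))

    @property
    def n_R(self) -> int:
        return int(np.count_nonzero(self.labels == R))

    @property
    def rho_S(self) -> float:
        return self.n_S / self.N

    @property
    def rho_I(self) -> float:
        return self.n_I / self.N

    @property
    def rho_R(self) -> float:
        return self.n_R / self.N

    def copy(self) -> "EpidemicState":
        return EpidemicState(self.labels.copy())


@dataclass
class OutbreakResult:
    """Summary of a single outbreak run.

    ``rho_R_final`` is the recovered fraction when the infected count
    first hits zero (the outbreak's final size); if the time cap was hit
    first, ``finished`` is False and the values describe the truncated
    run. ``time_series`` has columns (t, n_S, n_I, n_R, phi, lam).
    """

    rho_R_final: float
    rho_I_peak: float
    duration: float
    finished: bool
    time_series: pd.DataFrame
    n_strained: int = 0
    final_particle_state: Optional[ParticleState] = None
    final_epidemic_state: Optional[EpidemicState] = None

    def to_json_record(self, mp=None, ep=None, seeds=None) -> dict:
        rec = {
            "rho_R_final": self.rho_R_final,
            "rho_I_peak": self.rho_I_peak,
            "duration": self.duration,
            "finished": self.finished,
            "n_strained": self.n_strained,
        }
        if mp is not None:
            rec["model_params"] = mp.to_dict()
        if ep is not None:
            rec["epidemic_params"] = ep.to_dict()
        if seeds is not None:
            rec["seeds"] = seeds
        return rec


def infection_probability(k: int, beta_b: float, dt: float) -> float:
    """Per-step infection probability with k infected contacts.

    The linear sum rule ``k beta_b dt`` (independent pairwise channels),
    capped at 1 as a guardrail. A warning is emitted when the
    uncapped value exceeds 0.1, where the linearization of the
    continuous-time rate is strained.
    """
    if k < 0:
        raise ValueError(f"k must be >= 0, got {k}")
    if beta_b < 0:
        raise ValueError(f"beta_b must be >= 0, got {beta_b}")
    if not dt > 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    p = k * beta_b * dt
    if p > 0.1:
        warnings.warn(
            f"step infection probability {p:.3g} > 0.1: linear sum rule strained",
            RuntimeWarning,
            stacklevel=2,
        )
    return min(1.0, p)


def contagion_step(
    es: EpidemicState,
    graph: ContactGraph,
    ep: EpidemicParams,
    dt: float,
    rng: np.random.Generator,
    rng_recovery: Optional[np.random.Generator] = None,
) -> EpidemicState:
    """One synchronous SIR step on a fixed contact graph.

    ``rng`` drives the infection draws; recoveries come from
    ``rng_recovery`` when given (keeping the two streams independent)
    and from ``rng`` otherwise.
    """
    if es.N != graph.n:
        raise ValueError("epidemic state and graph sizes differ")
    if ep.gamma * dt >= 1.0:
        raise ValueError(
            f"gamma*dt = {ep.gamma * dt} >= 1: step too coarse for the recovery process"
        )
    labels = es.labels.copy()
    _kernels.sir_update(
        labels, graph.indptr, graph.indices,
        ep.beta_b * dt, ep.gamma * dt,
        rng, rng_recovery if rng_recovery is not None else rng,
    )
    return EpidemicState(labels)


def seed_infections(
    es: EpidemicState,
    mode: str = "random",
    n_seed: int = 1,
    rng: Optional[np.random.Generator] = None,
    state: Optional[ParticleState] = None,
    anchor=None,
    L: Optional[float] = None,
) -> EpidemicState:
    """Infect the initial seeds in an all-susceptible population.

    ``random`` mode infects ``n_seed`` distinct agents uniformly at
    random; ``localized`` mode infects the ``n_seed`` agents nearest
    (minimum image) to ``anchor`` — the box center when anchor is None.
    """
    if n_seed > es.N:
        raise ValueError(f"n_seed={n_seed} exceeds N={es.N}")
    if es.n_S != es.N:
        raise ValueError("seed_infections requires an all-susceptible state")
    labels = es.labels.copy()
    if mode == "random":
        if rng is None:
            raise ValueError("random seeding requires an rng")
        idx = rng.choice(es.N, size=n_seed, replace=False)
    elif mode == "localized":
        if state is None or L is None:
            raise ValueError("localized seeding requires the particle state and L")
        if anchor is None:
            anchor = np.array([L / 2.0, L / 2.0])
        d = minimum_image(state.positions, np.asarray(anchor, dtype=float), L)
        idx = np.argsort(np.hypot(d[:, 0], d[:, 1]), kind="stable")[:n_seed]
    else:
        raise ValueError(f"unknown seeding mode {mode!r}")
    labels[idx] = I
    return EpidemicState(labels)


def epidemic_params_from_theta(Theta: float, T_inf: float) -> EpidemicParams:
    """(Theta, T_inf) -> EpidemicParams: gamma = 1/T_inf, beta_b = Theta/T_inf."""
    return EpidemicParams.from_theta(Theta, T_inf)


def contagion_dt(mp: ModelParams, ep: EpidemicParams, max_step_prob: float = 0.1) -> float:
    """Largest epidemic step honoring the contagion constraints.

    At most the spatial step, reduced so that ``gamma dt <=
    max_step_prob`` and the per-contact probability ``beta_b dt <=
    max_step_prob`` (needed e.g. in the short-infectious-duration
    regime where beta_b is large). :func:`run_outbreak` uses this as
    the epidemic subclock step.
    """
    dt = mp.dt
    dt = min(dt, max_step_prob / ep.gamma)
    if ep.beta_b > 0:
        dt = min(dt, max_step_prob / ep.beta_b)
    return dt


def spawn_streams(seed) -> dict:
    """Four named independent generators from one seed.

    Streams: ``spatial`` (angular noise), ``infection``, ``recovery``,
    ``seeding``. Accepts an int or a ``numpy.random.SeedSequence``.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(4)
    names = ("spatial", "infection", "recovery", "seeding")
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def run_outbreak(
    state: ParticleState,
    es: EpidemicState,
    mp: ModelParams,
    ep: EpidemicParams,
    rng_spatial: np.random.Generator,
    rng_infection: np.random.Generator,
    rng_recovery: np.random.Generator,
    dt: Optional[float] = None,
    time_cap: Optional[float] = None,
    record_dt: float = 1.0,
    keep_final_state: bool = False,
) -> OutbreakResult:
    """Run the coupled spatial + SIR dynamics until the outbreak ends.

    Each spatial step (of length ``dt``, default the model step) builds
    the contact graph from the current positions; both processes are
    advanced synchronously from that pre-step state. When the contagion
    rates are too fast for the spatial step (``gamma dt`` or
    ``beta_b dt`` above 0.1), the SIR transitions run on an epidemic
    subclock: ``n_sub`` substeps per spatial step on the same frame's
    graph, keeping per-substep probabilities small. Positions move only
    ``v0 dt`` per frame, so the graph is effectively constant across
    the substeps; for very short infectious durations this is the
    quasi-static-network limit.

    The run stops when no infected agents remain, or at ``time_cap``
    (default ``50 T_inf + 5000`` time units) with ``finished=False``.
    """
    if es.n_I < 1:
        raise ValueError("run_outbreak requires at least one infected agent")
    if es.N != state.N:
        raise ValueError("particle and epidemic state sizes differ")
    if dt is None:
        dt = mp.dt
    dt_epi_max = contagion_dt(mp, ep)
    n_sub = max(1, int(math.ceil(dt / dt_epi_max - 1e-9)))
    dt_epi = dt / n_sub
    if ep.gamma * dt_epi >= 1.0:
        raise ValueError(f"gamma*dt = {ep.gamma * dt_epi} >= 1: step too coarse")
    if time_cap is None:
        time_cap = 50.0 * ep.T_inf + 5000.0
    max_steps = int(math.ceil(time_cap / dt))
    record_every = max(1, round(record_dt / dt))
    n_rec_max = max_steps // record_every + 3

    rec_t = np.empty(n_rec_max)
    rec_S = np.empty(n_rec_max, np.int64)
    rec_I = np.empty(n_rec_max, np.int64)
    rec_R = np.empty(n_rec_max, np.int64)
    rec_phi = np.empty(n_rec_max)
    rec_lam = np.empty(n_rec_max)

    pos = state.positions.copy()
    theta = state.headings.copy()
    labels = es.labels.copy()

    nrec, substeps, finished, peak_I, strained = _kernels.run_coupled(
        pos, theta, labels, mp.L, mp.v0, mp.r_int, mp.sigma, mp.tau, dt,
        ep.beta_b, ep.gamma, n_sub, max_steps, record_every,
        rng_spatial, rng_infection, rng_recovery,
        rec_t, rec_S, rec_I, rec_R, rec_phi, rec_lam, state.time,
    )
    ts = pd.DataFrame(
        {
            "t": rec_t[:nrec],
            "n_S": rec_S[:nrec],
            "n_I": rec_I[:nrec],
            "n_R": rec_R[:nrec],
            "phi": rec_phi[:nrec],
            "lam": rec_lam[:nrec],
        }
    )
    N = state.N
    duration = substeps * dt_epi
    result = OutbreakResult(
        rho_R_final=int(rec_R[nrec - 1]) / N,
        rho_I_peak=peak_I / N,
        duration=duration,
        finished=bool(finished),
        time_series=ts,
        n_strained=int(strained),
    )
    if keep_final_state:
        result.final_particle_state = ParticleState(pos, theta, state.time + duration)
        result.final_epidemic_state = EpidemicState(labels)
    return result
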