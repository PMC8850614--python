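"""Measurement protocol: burn-in ensembles, parameter sweeps, onset estimation.

The protocol mirrors how phase-diagram measurements are done for this
model: for each spatial parameter point, burn in several independent
stationary states of the spatial dynamics, then launch several
outbreaks per stationary state (random 1% seeding by default) with
fresh epidemic randomness, and summarize the final recovered fraction
rho_R(infinity) by its ensemble mean and standard deviation.

Everything is a pure function of (configuration, master seed): seeds
for every stream of every run are derived from the master seed through
``numpy.random.SeedSequence`` spawn keys and recorded in the outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .model_core import EpidemicParams, ModelParams, ParticleState, random_particle_state
from .spatial_dynamics import (
    BurnInResult,
    IntegratorConfig,
    StationarityCriterion,
    run_burn_in,
)
from .contagion import (
    EpidemicState,
    run_outbreak,
    seed_infections,
    spawn_streams,
)

__all__ = [
    "REFERENCE_STATES",
    "EnsembleSpec",
    "EnsembleResult",
    "SweepResult",
    "burn_in_states",
    "run_ensemble",
    "theta_sweep",
    "tinf_sweep",
    "estimate_onset",
    "add_meanfield_prediction",
]

#: The five reference (Pe, g) points of the collective-state phase diagram.
REFERENCE_STATES = {
    "D": (32.0, 1.0),
    "OB": (32.0, 2.0),
    "OH1": (512.0, 16.0),
    "OC": (32.0, 128.0),
    "OH2": (32.0, 1024.0),
}


def _ss(seed: int, *key: int) -> np.random.SeedSequence:
    """Deterministic child seed sequence for a namespaced key."""
    return np.random.SeedSequence(seed, spawn_key=key)


@dataclass(frozen=True)
class EnsembleSpec:
    """Replicate structure of an outbreak ensemble.

    ``n_stationary_states`` independently burned-in spatial states x
    ``n_outbreaks_per_state`` contagion processes each, seeded with a
    fraction ``seed_fraction`` of agents infected uniformly at random.
    All randomness derives from ``seed``. Outbreaks that hit the time
    cap are flagged unfinished and, when ``exclude_unfinished`` is set,
    excluded from the reported mean (with a count).
    """

    n_stationary_states: int = 5
    n_outbreaks_per_state: int = 10
    seed: int = 0
    seed_fraction: float = 0.01
    exclude_unfinished: bool = True
    time_cap: Optional[float] = None
    record_dt: float = 5.0

    @property
    def n_runs(self) -> int:
        return self.n_stationary_states * self.n_outbreaks_per_state


@dataclass
class EnsembleResult:
    """Outbreak ensemble at one parameter point."""

    runs: pd.DataFrame
    mean_rhoR: float
    sd_rhoR: float
    n_runs: int
    n_unfinished: int
    config: dict

    def to_json_record(self) -> dict:
        return {
            "mean_rhoR": self.mean_rhoR,
            "sd_rhoR": self.sd_rhoR,
            "n_runs": self.n_runs,
            "n_unfinished": self.n_unfinished,
            "config": self.config,
            "version": __version__,
        }


def burn_in_states(
    mp: ModelParams,
    n_states: int,
    seed: int,
    cfg: Optional[IntegratorConfig] = None,
    criterion: Optional[StationarityCriterion] = None,
) -> list[BurnInResult]:
    """Burn in ``n_states`` independent stationary spatial states.

    Each replicate starts from its own uniformly random configuration
    and uses its own spatial-noise stream, both derived from ``seed``
    and the replicate index.
    """
    out = []
    for i in range(n_states):
        streams = spawn_streams(_ss(seed, 0, i))
        initial = random_particle_state(mp, streams["seeding"])
        out.append(run_burn_in(initial, mp, cfg=cfg, criterion=criterion,
                               rng=streams["spatial"]))
    return out


def run_ensemble(
    mp: ModelParams,
    ep: EpidemicParams,
    spec: EnsembleSpec,
    states: Optional[Sequence[ParticleState]] = None,
    cfg: Optional[IntegratorConfig] = None,
    criterion: Optional[StationarityCriterion] = None,
    axis_key: int = 0,
) -> EnsembleResult:
    """Burn in (or reuse) stationary states and run the outbreak ensemble.

    ``states`` lets a caller reuse already burned-in spatial states
    (e.g. across the points of a sweep, where the spatial parameters do
    not change). ``axis_key`` namespaces the epidemic seeds so sweep
    points reusing the same states draw fresh epidemic randomness.
    """
    n_seed = max(1, round(spec.seed_fraction * mp.N))
    if states is None:
        burns = burn_in_states(mp, spec.n_stationary_states, spec.seed,
                               cfg=cfg, criterion=criterion)
        states = [b.state for b in burns]
    if len(states) < spec.n_stationary_states:
        raise ValueError(
            f"need {spec.n_stationary_states} stationary states, got {len(states)}"
        )
    rows = []
    for s_idx in range(spec.n_stationary_states):
        base = states[s_idx]
        for o_idx in range(spec.n_outbreaks_per_state):
            key = _ss(spec.seed, 1, axis_key, s_idx, o_idx)
            streams = spawn_streams(key)
            es = seed_infections(
                EpidemicState.all_susceptible(mp.N),
                mode="random",
                n_seed=n_seed,
                rng=streams["seeding"],
            )
            res = run_outbreak(
                base, es, mp, ep,
                rng_spatial=streams["spatial"],
                rng_infection=streams["infection"],
                rng_recovery=streams["recovery"],
                time_cap=spec.time_cap,
                record_dt=spec.record_dt,
            )
            rows.append(
                {
                    "state_idx": s_idx,
                    "outbreak_idx": o_idx,
                    "rho_R_final": res.rho_R_final,
                    "rho_I_peak": res.rho_I_peak,
                    "duration": res.duration,
                    "finished": res.finished,
                    "n_strained": res.n_strained,
                    "seed_key": str(key.spawn_key),
                }
            )
    runs = pd.DataFrame(rows)
    used = runs[runs["finished"]] if spec.exclude_unfinished else runs
    n_unfinished = int((~runs["finished"]).sum())
    config = {
        "model_params": mp.to_dict(),
        "epidemic_params": ep.to_dict(),
        "spec": asdict(spec),
        "n_seed": n_seed,
    }
    return EnsembleResult(
        runs=runs,
        mean_rhoR=float(used["rho_R_final"].mean()) if len(used) else float("nan"),
        sd_rhoR=float(used["rho_R_final"].std(ddof=0)) if len(used) else float("nan"),
        n_runs=len(runs),
        n_unfinished=n_unfinished,
        config=config,
    )


@dataclass
class SweepResult:
    """Ensemble results along one epidemic-parameter axis.

    ``summary`` has one row per parameter point with columns
    (pe, g, theta, tinf, mean_rhoR, sd_rhoR, n_runs, n_unfinished);
    ``runs`` holds the per-run records. ``axis`` names the swept column
    ("theta" or "tinf"); rows are ordered along it as given.
    """

    axis: str
    summary: pd.DataFrame
    runs: pd.DataFrame
    seed_fraction: float
    config: dict = field(default_factory=dict)

    def write_csv(self, summary_path, runs_path=None):
        with open(summary_path, "w") as fh:
            fh.write(f"# flocksir {__version__} sweep axis={self.axis} "
                     f"config={self.config}\n")
            self.summary.to_csv(fh, index=False)
        if runs_path is not None:
            self.runs.to_csv(runs_path, index=False)


def _sweep(
    mp: ModelParams,
    axis: str,
    axis_values: Sequence[float],
    fixed_value: float,
    spec: EnsembleSpec,
    states: Optional[Sequence[ParticleState]] = None,
    cfg: Optional[IntegratorConfig] = None,
    criterion: Optional[StationarityCriterion] = None,
) -> SweepResult:
    if states is None:
        burns = burn_in_states(mp, spec.n_stationary_states, spec.seed,
                               cfg=cfg, criterion=criterion)
        states = [b.state for b in burns]
    sum_rows = []
    run_frames = []
    for a_idx, val in enumerate(axis_values):
        if axis == "theta":
            theta, tinf = val, fixed_value
        else:
            theta, tinf = fixed_value, val
        ep = EpidemicParams.from_theta(theta, tinf)
        ens = run_ensemble(mp, ep, spec, states=states, axis_key=a_idx)
        sum_rows.append(
            {
                "pe": mp.Pe,
                "g": mp.g,
                "theta": theta,
                "tinf": tinf,
                "mean_rhoR": ens.mean_rhoR,
                "sd_rhoR": ens.sd_rhoR,
                "n_runs": ens.n_runs,
                "n_unfinished": ens.n_unfinished,
            }
        )
        rf = ens.runs.copy()
        rf["theta"] = theta
        rf["tinf"] = tinf
        run_frames.append(rf)
    return SweepResult(
        axis=axis,
        summary=pd.DataFrame(sum_rows),
        runs=pd.concat(run_frames, ignore_index=True),
        seed_fraction=spec.seed_fraction,
        config={"model_params": mp.to_dict(), "spec": asdict(spec)},
    )


def theta_sweep(
    mp: ModelParams,
    theta_values: Sequence[float],
    T_inf: float,
    spec: EnsembleSpec,
    states: Optional[Sequence[ParticleState]] = None,
    **kw,
) -> SweepResult:
    """Outbreak ensembles over a list of Theta values at fixed T_inf."""
    if any(t < 0 for t in theta_values):
        raise ValueError("Theta values must be >= 0")
    return _sweep(mp, "theta", list(theta_values), T_inf, spec, states=states, **kw)


def tinf_sweep(
    mp: ModelParams,
    tinf_values: Sequence[float],
    Theta: float,
    spec: EnsembleSpec,
    states: Optional[Sequence[ParticleState]] = None,
    **kw,
) -> SweepResult:
    """Outbreak ensembles over a list of T_inf values at fixed Theta.

    The integration step is auto-reduced per point (inside
    ``run_outbreak``) so that the per-contact step probability stays
    small even in the short-infectious-duration regime where beta_b =
    Theta / T_inf is large.
    """
    if any(t <= 0 for t in tinf_values):
        raise ValueError("T_inf values must be > 0")
    return _sweep(mp, "tinf", list(tinf_values), Theta, spec, states=states, **kw)


def estimate_onset(sweep: SweepResult, threshold_multiple: float = 5.0):
    """Smallest axis value whose mean final size exceeds the seed level.

    Scans the sweep in axis order for the first point with
    ``mean_rhoR > threshold_multiple * seed_fraction``; returns None if
    no point exceeds it. The sweep must be ordered ascending along its
    axis.
    """
    if threshold_multiple <= 1:
        raise ValueError(f"threshold_multiple must be > 1, got {threshold_multiple}")
    ax = sweep.summary[sweep.axis].to_numpy()
    if ax.size > 1 and np.any(np.diff(ax) <= 0):
        raise ValueError("sweep is not strictly increasing along its axis")
    thresh = threshold_multiple * sweep.seed_fraction
    for val, mean in zip(ax, sweep.summary["mean_rhoR"]):
        if mean > thresh:
            return float(val)
    return None


def add_meanfield_prediction(sweep: SweepResult, stats) -> SweepResult:
    """Append a homogeneous-mixing final-size prediction column.

    Uses the measured contact statistics ``stats`` (from a stationary
    run of the same spatial parameters) to compute an effective R0 at
    each sweep point and the corresponding final-size-relation
    prediction, stored as ``meanfield_prediction``.
    """
    from .meanfield import MeanFieldParams, effective_R0, final_size

    preds = []
    for _, row in sweep.summary.iterrows():
        ep = EpidemicParams.from_theta(row["theta"], row["tinf"])
        r0 = effective_R0(ep.beta_b, ep.gamma, stats)
        preds.append(
            final_size(
                MeanFieldParams(
                    R0=r0, s0=1.0 - sweep.seed_fraction, i0=sweep.seed_fraction
                )
            )
        )
    sweep.summary = sweep.summary.assign(meanfield_prediction=preds)
    return sweep
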