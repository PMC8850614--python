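"""Parameters, periodic geometry, and proximity graphs.

This module holds the bookkeeping shared by the rest of the package: the
physical and epidemic parameter containers (with their dimensionless
views), angle arithmetic on the circle, the minimum-image convention for
the periodic square arena, and exact contact-graph construction via a
cell-list search.

Conventions
-----------
* Positions live in the half-open box ``[0, L) x [0, L)``.
* Heading angles live in ``[-pi, pi)`` and are wrapped with
  :func:`wrap_angle` (``mod(x + pi, 2 pi) - pi``).
* Two agents are *in contact* when their minimum-image distance is
  ``<= r_int`` (inclusive); the contact set of an agent excludes the
  agent itself.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np

from . import _kernels

__all__ = [
    "ModelParams",
    "EpidemicParams",
    "ParticleState",
    "ContactGraph",
    "dimensionless_to_physical",
    "physical_to_dimensionless",
    "arena_side_from_packing",
    "wrap_angle",
    "minimum_image",
    "build_contact_graph",
    "random_particle_state",
    "write_snapshot",
    "read_snapshot",
]


# ---------------------------------------------------------------------------
# parameter conversions
# ---------------------------------------------------------------------------

def dimensionless_to_physical(Pe: float, g: float, v0: float, r_int: float):
    """Invert the (Pe, g) definitions to recover (sigma, tau).

    The Peclet number ``Pe = v0 / (r_int sigma^2)`` measures persistence
    of individual motion against angular diffusion; the coupling strength
    ``g = 1 / (tau sigma^2)`` measures alignment against angular noise.

    Parameters
    ----------
    Pe, g : float
        Target dimensionless parameters, both strictly positive.
    v0, r_int : float
        Self-propulsion speed and interaction range, strictly positive.

    Returns
    -------
    (sigma, tau) : tuple of float
        Angular noise intensity (rad / sqrt(time)) and alignment
        relaxation time such that the forward definitions reproduce
        (Pe, g) exactly.
    """
    for name, val in (("Pe", Pe), ("g", g), ("v0", v0), ("r_int", r_int)):
        if not (val > 0 and math.isfinite(val)):
            raise ValueError(f"{name} must be finite and > 0, got {val!r}")
    sigma2 = v0 / (r_int * Pe)
    sigma = math.sqrt(sigma2)
    tau = 1.0 / (g * sigma2)
    return sigma, tau


def physical_to_dimensionless(sigma: float, tau: float, v0: float, r_int: float):
    """Forward map: (sigma, tau) -> (Pe, g)."""
    for name, val in (("sigma", sigma), ("tau", tau), ("v0", v0), ("r_int", r_int)):
        if not (val > 0 and math.isfinite(val)):
            raise ValueError(f"{name} must be finite and > 0, got {val!r}")
    Pe = v0 / (r_int * sigma**2)
    g = 1.0 / (tau * sigma**2)
    return Pe, g


def arena_side_from_packing(N: int, r_int: float, phi_pack: float) -> float:
    """Arena side length for a given packing fraction.

    The packing fraction is ``N pi r_int^2 / (4 L^2)`` (agents seen as
    disks of diameter ``r_int``), so ``L = sqrt(N pi r_int^2 / (4 phi))``.
    """
    if N < 1:
        raise ValueError(f"N must be >= 1, got {N}")
    if not (0.0 < phi_pack < 1.0):
        raise ValueError(f"phi_pack must lie in (0, 1), got {phi_pack}")
    if r_int <= 0:
        raise ValueError(f"r_int must be > 0, got {r_int}")
    return math.sqrt(N * math.pi * r_int**2 / (4.0 * phi_pack))


def wrap_angle(x):
    """Wrap angles into ``[-pi, pi)`` (the mod* map).

    Computes ``mod(x + pi, 2 pi) - pi`` elementwise; the result is
    congruent to ``x`` modulo ``2 pi``.
    """
    return np.mod(np.asarray(x) + np.pi, 2.0 * np.pi) - np.pi


def minimum_image(r_i, r_j, L: float):
    """Displacement ``r_i - r_j`` under the minimum-image convention.

    Each component is shifted by a multiple of ``L`` into
    ``[-L/2, L/2)``; the Euclidean norm of the result is the true
    periodic distance.
    """
    d = np.asarray(r_i, dtype=float) - np.asarray(r_j, dtype=float)
    return d - L * np.floor(d / L + 0.5)


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelParams:
    """Physical parameters of the self-propelled-particle model.

    Attributes
    ----------
    N : int
        Number of agents.
    v0 : float
        Self-propulsion speed (length / time).
    r_int : float
        Interaction range shared by alignment and repulsion (length).
    sigma : float
        Angular noise intensity (rad / sqrt(time)).
    tau : float
        Alignment relaxation time (time).
    L : float
        Arena side length (length); periodic square box.
    dt : float
        Integration time step (time).
    """

    N: int
    v0: float
    r_int: float
    sigma: float
    tau: float
    L: float
    dt: float

    def __post_init__(self):
        if self.N < 1 or self.N != int(self.N):
            raise ValueError(f"N must be an integer >= 1, got {self.N}")
        for name in ("v0", "r_int", "tau", "L", "dt"):
            val = getattr(self, name)
            if not (val > 0 and math.isfinite(val)):
                raise ValueError(f"{name} must be finite and > 0, got {val!r}")
        # sigma = 0 is the deterministic (noise-free) limit, useful for
        # exact tests; Pe and g are then infinite
        if not (self.sigma >= 0 and math.isfinite(self.sigma)):
            raise ValueError(f"sigma must be finite and >= 0, got {self.sigma!r}")
        if self.r_int >= self.L / 2.0:
            raise ValueError(
                f"r_int={self.r_int} >= L/2={self.L / 2}: minimum-image "
                "distances are ambiguous at this size"
            )

    # -- dimensionless views -------------------------------------------------
    @property
    def Pe(self) -> float:
        """Peclet number v0 / (r_int sigma^2); infinite in the noise-free limit."""
        if self.sigma == 0.0:
            return math.inf
        return self.v0 / (self.r_int * self.sigma**2)

    @property
    def g(self) -> float:
        """Alignment coupling strength 1 / (tau sigma^2); infinite at sigma=0."""
        if self.sigma == 0.0:
            return math.inf
        return 1.0 / (self.tau * self.sigma**2)

    @property
    def packing_fraction(self) -> float:
        """N pi r_int^2 / (4 L^2)."""
        return self.N * math.pi * self.r_int**2 / (4.0 * self.L**2)

    @classmethod
    def from_dimensionless(
        cls,
        Pe: float,
        g: float,
        N: int = 2500,
        v0: float = 0.2,
        r_int: float = 1.0,
        phi_pack: float = 0.3,
        dt: Optional[float] = None,
    ) -> "ModelParams":
        """Build parameters from the (Pe, g) phase-space coordinates.

        ``sigma`` and ``tau`` come from inverting the dimensionless
        definitions; ``L`` fixes the packing fraction. When ``dt`` is
        not given it defaults to ``min(0.1, tau/10, 0.02 r_int / v0)``:
        small enough to resolve the alignment relaxation (stiff at large
        g) and to keep the deterministic displacement well below the
        interaction range.
        """
        sigma, tau = dimensionless_to_physical(Pe, g, v0, r_int)
        L = arena_side_from_packing(N, r_int, phi_pack)
        if dt is None:
            dt = min(0.1, tau / 10.0, 0.02 * r_int / v0)
        return cls(N=N, v0=v0, r_int=r_int, sigma=sigma, tau=tau, L=L, dt=dt)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class EpidemicParams:
    """SIR contagion parameters.

    ``beta_b`` is the *base* transmission rate per infected contact
    (1/time): a susceptible agent in contact with one infected agent for
    a short step ``dt`` is infected with probability ``beta_b * dt``.
    ``gamma`` is the spontaneous recovery rate (1/time). Derived views:
    the infection-lifetime transmissibility ``Theta = beta_b / gamma``
    and the mean infectious duration ``T_inf = 1 / gamma``.
    """

    beta_b: float
    gamma: float

    def __post_init__(self):
        if self.beta_b < 0:
            raise ValueError(f"beta_b must be >= 0, got {self.beta_b}")
        if not self.gamma > 0:
            raise ValueError(f"gamma must be > 0, got {self.gamma}")

    @property
    def Theta(self) -> float:
        return self.beta_b / self.gamma

    @property
    def T_inf(self) -> float:
        return 1.0 / self.gamma

    @classmethod
    def from_theta(cls, Theta: float, T_inf: float) -> "EpidemicParams":
        """Construct from (Theta, T_inf): gamma = 1/T_inf, beta_b = Theta/T_inf."""
        if Theta < 0:
            raise ValueError(f"Theta must be >= 0, got {Theta}")
        if not T_inf > 0:
            raise ValueError(f"T_inf must be > 0, got {T_inf}")
        gamma = 1.0 / T_inf
        return cls(beta_b=Theta * gamma, gamma=gamma)

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# state containers
# ---------------------------------------------------------------------------

@dataclass
class ParticleState:
    """Spatial microstate: positions and headings of N agents at one time.

    ``positions`` has shape (N, 2) with entries in [0, L); ``headings``
    has shape (N,) with entries in [-pi, pi); ``time`` is the elapsed
    simulation time.
    """

    positions: np.ndarray
    headings: np.ndarray
    time: float = 0.0

    def __post_init__(self):
        self.positions = np.ascontiguousarray(self.positions, dtype=np.float64)
        self.headings = np.ascontiguousarray(self.headings, dtype=np.float64)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValueError("positions must have shape (N, 2)")
        if self.headings.shape != (self.positions.shape[0],):
            raise ValueError("headings must have shape (N,)")

    @property
    def N(self) -> int:
        return self.positions.shape[0]

    def copy(self) -> "ParticleState":
        return ParticleState(self.positions.copy(), self.headings.copy(), self.time)

    def validate(self, L: float) -> None:
        """Raise if positions/headings violate the box/wrap invariants."""
        if not np.all(np.isfinite(self.positions)) or not np.all(np.isfinite(self.headings)):
            raise ValueError("non-finite entries in particle state")
        if np.any(self.positions < 0) or np.any(self.positions >= L):
            raise ValueError("positions outside [0, L)")
        if np.any(self.headings < -np.pi) or np.any(self.headings >= np.pi):
            raise ValueError("headings outside [-pi, pi)")


def random_particle_state(mp: ModelParams, rng: np.random.Generator) -> ParticleState:
    """Uniformly random initial condition: positions in the box, headings on the circle."""
    pos = rng.random((mp.N, 2)) * mp.L
    theta = rng.random(mp.N) * 2.0 * np.pi - np.pi
    return ParticleState(pos, theta, 0.0)


class ContactGraph:
    """Undirected proximity graph over agent indices (CSR adjacency).

    An edge (i, j) exists iff the minimum-image distance between agents
    i and j is <= r_int; there are no self-loops.
    """

    def __init__(self, n: int, indptr: np.ndarray, indices: np.ndarray):
        self.n = int(n)
        self.indptr = indptr
        self.indices = indices

    @property
    def n_edges(self) -> int:
        return self.indices.size // 2

    def neighbors(self, i: int) -> np.ndarray:
        return self.indices[self.indptr[i]:self.indptr[i + 1]]

    def degree(self) -> np.ndarray:
        return np.diff(self.indptr)

    def edges(self) -> set:
        """Set of undirected edges as (i, j) tuples with i < j."""
        out = set()
        for i in range(self.n):
            for j in self.neighbors(i):
                if i < j:
                    out.add((i, int(j)))
        return out

    def edge_arrays(self):
        """Edge list as two arrays (i, j) with i < j."""
        deg = self.degree()
        src = np.repeat(np.arange(self.n), deg)
        mask = src < self.indices
        return src[mask], self.indices[mask]


def build_contact_graph(state: ParticleState, r_int: float, L: float) -> ContactGraph:
    """Exact contact graph at range ``r_int`` (inclusive) under minimum image.

    Uses a cell-list search with cell size >= r_int; the output is
    set-identical to the all-pairs brute force. Refuses ``r_int >= L/2``
    where the minimum image is ambiguous.
    """
    if r_int >= L / 2.0:
        raise ValueError(f"r_int={r_int} >= L/2={L / 2}: refuse ambiguous minimum image")
    ii, jj = _kernels.pair_list(state.positions, L, r_int)
    indptr, indices = _kernels.csr_from_pairs(state.N, ii, jj)
    return ContactGraph(state.N, indptr, indices)


# ---------------------------------------------------------------------------
# snapshot files
# ---------------------------------------------------------------------------

_SIR_CODE = {0: "S", 1: "I", 2: "R"}
_SIR_DECODE = {"S": 0, "I": 1, "R": 2}


def write_snapshot(
    path,
    state: ParticleState,
    mp: ModelParams,
    ep: Optional[EpidemicParams] = None,
    sir_labels: Optional[np.ndarray] = None,
):
    """Write a one-record-per-agent snapshot (CSV or .npz).

    The CSV variant carries a ``# {json}`` metadata header with the full
    parameter set; columns are (id, x, y, theta, sir_state). The binary
    variant (suffix ``.npz``) stores the same arrays plus the metadata
    JSON string.
    """
    path = Path(path)
    from . import __version__

    meta = {
        "flocksir_version": __version__,
        "model_params": mp.to_dict(),
        "epidemic_params": ep.to_dict() if ep is not None else None,
        "time": state.time,
    }
    labels = sir_labels if sir_labels is not None else np.zeros(state.N, dtype=np.int8)
    if path.suffix == ".npz":
        np.savez(
            path,
            positions=state.positions,
            headings=state.headings,
            sir_labels=np.asarray(labels, dtype=np.int8),
            meta=np.array(json.dumps(meta)),
        )
        return
    with open(path, "w") as fh:
        fh.write("# " + json.dumps(meta) + "\n")
        fh.write("id,x,y,theta,sir_state\n")
        for i in range(state.N):
            fh.write(
                f"{i},{float(state.positions[i, 0])!r},{float(state.positions[i, 1])!r},"
                f"{float(state.headings[i])!r},{_SIR_CODE[int(labels[i])]}\n"
            )


def read_snapshot(path):
    """Read a snapshot written by :func:`write_snapshot`.

    Returns
    -------
    (state, mp, ep, sir_labels)
        ``ep`` is None when no epidemic parameters were stored.
    """
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["meta"]))
            pos = z["positions"]
            theta = z["headings"]
            labels = z["sir_labels"]
    else:
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("#"):
                raise ValueError(f"{path}: missing metadata header")
            meta = json.loads(header[1:].strip())
            body = fh.read()
        rec = np.genfromtxt(
            io.StringIO(body),
            delimiter=",",
            names=True,
            dtype=None,
            encoding="utf-8",
        )
        rec = np.atleast_1d(rec)
        pos = np.column_stack([rec["x"], rec["y"]])
        theta = np.asarray(rec["theta"], dtype=float)
        labels = np.array([_SIR_DECODE[s] for s in rec["sir_state"]], dtype=np.int8)
    mp = ModelParams(**meta["model_params"])
    ep = (
        EpidemicParams(**meta["epidemic_params"])
        if meta.get("epidemic_params") is not None
        else None
    )
    state = ParticleState(pos, theta, float(meta.get("time", 0.0)))
    return state, mp, ep, labels
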