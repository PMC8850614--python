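"""Order parameters, cluster analysis, density rendering, contact statistics.

Two scalar order parameters characterize the collective state: the
polarization ``Phi = |sum_i n_hat_i| / N`` (1 for perfect common
heading, ~0 for random headings) and the clustering ``Lambda``, the
fraction of agents in the largest connected component of the contact
graph. Time averages of (Phi, Lambda) over a stationary window, plus
the shape of the largest cluster relative to the mean heading,
classify a run into one of four collective states:

* ``D``  — disordered (low Phi),
* ``OH`` — ordered homogeneous (high Phi, low Lambda),
* ``OB`` — ordered with bands: dense stripes perpendicular to the
  collective heading,
* ``OC`` — ordered with clusters elongated along the heading.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from . import _kernels
from .model_core import ContactGraph, ParticleState
from .contagion import EpidemicState, I as STATE_I

__all__ = [
    "OrderParameters",
    "DensityGrid",
    "ContactStats",
    "polarization",
    "largest_cluster_fraction",
    "largest_cluster_members",
    "cluster_anisotropy",
    "render_density_grid",
    "contact_statistics",
    "classify_state",
    "classify_run",
]


@dataclass(frozen=True)
class OrderParameters:
    """Instantaneous (phi, lam) pair."""

    phi: float
    lam: float


def polarization(headings) -> float:
    """Modulus of the mean heading unit vector, in [0, 1].

    Rotation-invariant: adding a constant to every heading leaves the
    value unchanged.
    """
    theta = np.asarray(headings, dtype=float)
    if theta.size == 0:
        raise ValueError("polarization of an empty heading list is undefined")
    return float(np.hypot(np.cos(theta).sum(), np.sin(theta).sum()) / theta.size)


def largest_cluster_fraction(graph: ContactGraph, N: Optional[int] = None) -> float:
    """Fraction of agents in the largest connected component.

    Components use transitive-closure semantics: a chain of agents each
    within r_int of the next forms one cluster. 1/N for a fully
    dispersed configuration, 1 when all agents form one cluster.
    """
    n = N if N is not None else graph.n
    ii, jj = graph.edge_arrays()
    return _kernels.largest_component_size(n, ii, jj) / n


def largest_cluster_members(graph: ContactGraph) -> np.ndarray:
    """Indices of the agents in the largest connected component."""
    import scipy.sparse as sp
    from scipy.sparse.csgraph import connected_components

    n = graph.n
    data = np.ones(graph.indices.size, dtype=np.int8)
    adj = sp.csr_matrix((data, graph.indices, graph.indptr), shape=(n, n))
    ncomp, lab = connected_components(adj, directed=False)
    sizes = np.bincount(lab, minlength=ncomp)
    return np.flatnonzero(lab == np.argmax(sizes))


def cluster_anisotropy(
    state: ParticleState,
    graph: ContactGraph,
    L: float,
    members: Optional[np.ndarray] = None,
) -> float:
    """Signed elongation of the largest cluster relative to its mean heading.

    The cluster's gyration tensor is computed on minimum-image
    displacements about the cluster's circular-mean center (well
    defined on the torus even for arena-spanning structures). The
    result is ``e * (2 cos^2 psi - 1)`` where ``e`` in [0, 1] is the
    eigenvalue elongation ``(l1 - l2)/(l1 + l2)`` and ``psi`` the angle
    between the principal axis and the cluster's mean heading: positive
    for a cluster elongated along the heading (OC-like), negative for
    one elongated perpendicular to it (band-like).
    """
    if members is None:
        members = largest_cluster_members(graph)
    if members.size < 2:
        return 0.0
    pos = state.positions[members]
    # circular-mean center per coordinate
    center = np.empty(2)
    for d in range(2):
        ang = pos[:, d] * (2.0 * np.pi / L)
        center[d] = math.atan2(np.sin(ang).mean(), np.cos(ang).mean()) * L / (2.0 * np.pi) % L
    disp = pos - center
    disp -= L * np.floor(disp / L + 0.5)
    gyr = disp.T @ disp / members.size
    evals, evecs = np.linalg.eigh(gyr)
    l1, l2 = evals[1], evals[0]
    if l1 + l2 <= 0:
        return 0.0
    elong = (l1 - l2) / (l1 + l2)
    axis = evecs[:, 1]
    th = state.headings[members]
    mean_head = np.array([np.cos(th).sum(), np.sin(th).sum()])
    norm = np.hypot(*mean_head)
    if norm < 1e-12:
        return 0.0
    cos_psi = float(axis @ mean_head) / norm
    return float(elong * (2.0 * cos_psi**2 - 1.0))


@dataclass
class DensityGrid:
    """Binned agent density with a periodically smoothed total layer.

    ``raw_counts`` holds the per-bin agent counts (summing to N);
    ``density`` is the Gaussian-smoothed count field (periodic
    boundary, mass-conserving); ``infected_counts`` is the raw count of
    infected agents per bin, meaningful only where positive.
    """

    edges: np.ndarray
    raw_counts: np.ndarray
    density: np.ndarray
    infected_counts: np.ndarray
    smooth_width: float

    @property
    def infected_masked(self) -> np.ma.MaskedArray:
        """Infected layer masked to bins that contain infected agents."""
        return np.ma.masked_where(self.infected_counts <= 0, self.infected_counts)

    def save(self, path) -> None:
        """Write the grid to disk: ``.npz`` container, or plain matrix
        text (smoothed density; bin edges and smoothing width in the
        header) for any other suffix."""
        from pathlib import Path

        path = Path(path)
        if path.suffix == ".npz":
            np.savez(
                path,
                edges=self.edges,
                raw_counts=self.raw_counts,
                density=self.density,
                infected_counts=self.infected_counts,
                smooth_width=np.array(self.smooth_width),
            )
        else:
            header = (
                f"smooth_width={self.smooth_width!r} "
                f"edges={self.edges[0]!r}:{self.edges[-1]!r}:{self.edges.size}"
            )
            np.savetxt(path, self.density, header=header)

    @classmethod
    def load(cls, path) -> "DensityGrid":
        """Read a grid saved by :meth:`save` (``.npz`` variant only)."""
        with np.load(path) as z:
            return cls(
                edges=z["edges"],
                raw_counts=z["raw_counts"],
                density=z["density"],
                infected_counts=z["infected_counts"],
                smooth_width=float(z["smooth_width"]),
            )


def render_density_grid(
    state: ParticleState,
    es: Optional[EpidemicState],
    n_bins: int,
    L: float,
    smooth_width: Optional[float] = None,
) -> DensityGrid:
    """Histogram the agents on an n_bins x n_bins grid over the arena.

    The total layer is smoothed with a periodic Gaussian kernel of
    standard deviation ``smooth_width`` (length units; default two bin
    widths). Smoothing conserves total mass. The infected layer is the
    raw count of agents in state I per bin.
    """
    if n_bins < 2:
        raise ValueError(f"n_bins must be >= 2, got {n_bins}")
    edges = np.linspace(0.0, L, n_bins + 1)
    counts, _, _ = np.histogram2d(
        state.positions[:, 0], state.positions[:, 1], bins=[edges, edges]
    )
    bin_w = L / n_bins
    if smooth_width is None:
        smooth_width = 2.0 * bin_w
    sigma_bins = smooth_width / bin_w
    density = ndimage.gaussian_filter(counts, sigma=sigma_bins, mode="wrap")
    if es is not None:
        inf = state.positions[es.labels == STATE_I]
        inf_counts, _, _ = np.histogram2d(inf[:, 0], inf[:, 1], bins=[edges, edges])
    else:
        inf_counts = np.zeros_like(counts)
    return DensityGrid(
        edges=edges,
        raw_counts=counts,
        density=density,
        infected_counts=inf_counts,
        smooth_width=smooth_width,
    )


@dataclass(frozen=True)
class ContactStats:
    """Mean rate of new contacts per agent per unit time, and mean contact duration."""

    mean_contact_rate: float
    mean_contact_duration: float


def contact_statistics(graph_sequence: Sequence[ContactGraph], dt: float) -> ContactStats:
    """Contact-event statistics from a time-ordered sequence of graphs.

    A contact event is a maximal run of consecutive frames over which a
    given pair stays an edge. The mean duration is the mean run length
    times ``dt`` (runs still open at the last frame count at their
    observed length). The contact rate counts event onsets — edges
    present now but absent in the previous frame — per agent per unit
    time over the observation window; the first frame defines the
    initial condition and contributes no onsets.
    """
    frames = list(graph_sequence)
    if len(frames) < 2:
        raise ValueError("contact_statistics needs at least two frames")
    n_agents = frames[0].n
    open_runs: dict = {}
    durations: list = []
    n_onsets = 0
    prev = frames[0].edges()
    for e in prev:
        open_runs[e] = 1
    for g in frames[1:]:
        cur = g.edges()
        for e in prev - cur:
            durations.append(open_runs.pop(e))
        for e in cur & prev:
            open_runs[e] += 1
        for e in cur - prev:
            open_runs[e] = 1
            n_onsets += 1
        prev = cur
    durations.extend(open_runs.values())
    window = (len(frames) - 1) * dt
    mean_dur = float(np.mean(durations)) * dt if durations else 0.0
    # each onset is a new contact for both members of the pair
    rate = 2.0 * n_onsets / (n_agents * window)
    return ContactStats(mean_contact_rate=rate, mean_contact_duration=mean_dur)


def classify_state(
    phi_bar: float,
    lam_bar: float,
    anisotropy: float = 0.0,
    phi_c: float = 0.5,
    lam_c: float = 0.2,
) -> str:
    """Label a stationary run as D, OH, OB, or OC.

    ``phi_bar`` and ``lam_bar`` are time averages over a stationary
    window; ``anisotropy`` is the signed cluster elongation from
    :func:`cluster_anisotropy`. Disordered below the polarization
    threshold; ordered homogeneous when polar but unclustered; among
    clustered ordered states, bands (OB) have their long axis closer to
    perpendicular to the mean heading and clusters (OC) closer to
    parallel. The thresholds are tunable surrogates for visually drawn
    phase boundaries.
    """
    for name, v in (("phi_bar", phi_bar), ("lam_bar", lam_bar)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    if phi_bar < phi_c:
        return "D"
    if lam_bar < lam_c:
        return "OH"
    return "OC" if anisotropy >= 0 else "OB"


def classify_run(
    states: Sequence[ParticleState],
    graphs: Sequence[ContactGraph],
    L: float,
    phi_c: float = 0.5,
    lam_c: float = 0.2,
):
    """Classify from a set of stationary snapshots.

    Averages Phi and Lambda over the snapshots and the cluster
    anisotropy over the snapshots whose largest cluster passes the
    clustering threshold. Returns (label, phi_bar, lam_bar, aniso_bar).
    """
    phis = [polarization(s.headings) for s in states]
    lams = [largest_cluster_fraction(g) for g in graphs]
    anisos = [
        cluster_anisotropy(s, g, L)
        for s, g, lam in zip(states, graphs, lams)
        if lam >= lam_c
    ]
    phi_bar = float(np.mean(phis))
    lam_bar = float(np.mean(lams))
    aniso_bar = float(np.mean(anisos)) if anisos else 0.0
    return classify_state(phi_bar, lam_bar, aniso_bar, phi_c, lam_c), phi_bar, lam_bar, aniso_bar
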