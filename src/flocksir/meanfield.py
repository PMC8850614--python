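"""Homogeneous-mixing SIR baseline.

For the disordered collective state — where agents mix continuously
with near-uniform density — the outbreak can be approximated by a
well-mixed SIR process. The effective basic reproduction number is
built from the measured contact statistics of the stationary spatial
dynamics, and the final outbreak size follows the classical
Kermack–McKendrick final-size relation

    r_inf = 1 - s0 exp(-R0 r_inf).

This is a baseline for comparison with the spatially explicit
simulations, valid when per-contact transmission is weak
(beta_b * contact_duration << 1) and mixing is fast.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from scipy.optimize import brentq

from .observables import ContactStats

__all__ = ["MeanFieldParams", "effective_R0", "final_size"]


@dataclass(frozen=True)
class MeanFieldParams:
    """R0 plus the initial susceptible/infected fractions."""

    R0: float
    s0: float = 1.0
    i0: float = 0.0

    def __post_init__(self):
        if self.R0 < 0:
            raise ValueError(f"R0 must be >= 0, got {self.R0}")
        if self.s0 < 0 or self.i0 < 0 or self.s0 + self.i0 > 1.0 + 1e-12:
            raise ValueError(f"need s0, i0 >= 0 and s0 + i0 <= 1, got {self.s0}, {self.i0}")


def effective_R0(beta_b: float, gamma: float, stats: ContactStats) -> float:
    """Effective reproduction number from measured contact statistics.

    R0 = (beta_b * mean contact duration) * (mean contact rate / gamma):
    the linearized per-contact transmission probability times the
    expected number of contacts made during one infectious period.
    An approximation valid when ``beta_b * duration << 1``; a warning
    is emitted past 0.5 where the linearization is clearly invalid.
    """
    if beta_b < 0 or gamma <= 0:
        raise ValueError("need beta_b >= 0 and gamma > 0")
    p_contact = beta_b * stats.mean_contact_duration
    if p_contact > 0.5:
        warnings.warn(
            f"beta_b * contact duration = {p_contact:.3g} > 0.5: "
            "linearized per-contact probability invalid",
            RuntimeWarning,
            stacklevel=2,
        )
    return p_contact * stats.mean_contact_rate / gamma


def final_size(p: MeanFieldParams, tol: float = 1e-10) -> float:
    """Final recovered fraction of the homogeneous-mixing SIR model.

    Solves ``r = 1 - s0 exp(-R0 r)`` for the largest root in
    ``[i0, 1]`` by bracketed root-finding. Continuous and
    non-decreasing in R0; equals ``1 - s0`` at R0 = 0 (only the initial
    non-susceptibles end up recovered) and tends to 1 as R0 grows.
    """
    R0, s0, i0 = p.R0, p.s0, p.i0
    if s0 == 0.0:
        return 1.0

    def f(r):
        return r - 1.0 + s0 * math.exp(-R0 * r)

    lo = 1.0 - s0  # = i0 when s0 + i0 = 1; always a lower bound for r_inf
    f_lo = f(lo)
    if abs(f_lo) < tol:
        # lo itself solves the relation (vanishing seed). Supercritical
        # curves re-descend past lo: take the larger root, bracketing
        # from the minimum of f at ln(s0 R0)/R0.
        if R0 * s0 <= 1.0:
            return lo
        r_star = math.log(s0 * R0) / R0
        if f(r_star) >= 0:
            return lo
        return float(brentq(f, r_star, 1.0, xtol=tol))
    if f_lo > 0:
        raise RuntimeError(
            f"no bracket for the final-size root: f({lo}) = {f_lo} > 0 "
            f"(R0={R0}, s0={s0}, i0={i0})"
        )
    if f(1.0) <= 0:
        return 1.0
    return float(brentq(f, lo, 1.0, xtol=tol))
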