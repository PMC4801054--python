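"""Deterministic mean model of mRNA over the cell cycle.

The mean copy number R(t) of a species produced at rate g(t)*kini and
eliminated at rate kd, with gene dosage g = 1 before the replication time
trep and 2 after, obeys dR/dt = g(t)*kini - kd*R subject to the
cyclostationary boundary condition R(tdiv) = 2 R(0) (division halves the
mean).  The closed-form solution is piecewise exponential and continuous
at trep.  For nascent mRNA the elimination rate is 1/tres (residence at
the gene); for mature mRNA it is the degradation rate.

The G2/G1 window ratio RM = <R over [t2, tdiv)> / <R over [0, t1)>
approaches 2 when the mRNA lifetime is short compared to the cycle and
falls below 2 when it is comparable, which is why nascent mRNA doubles
between G1 and G2 while mature mRNA does not.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["DeterministicParams", "mean_trajectory", "window_ratio", "rm_sweep"]


@dataclass
class DeterministicParams:
    """Effective parameters of the mean model (rates in 1/min, times in min)."""

    kini_eff: float  # ON/OFF-averaged initiation rate
    kd_eff: float    # elimination rate; 1/tres for nascent mRNA
    trep: float
    tdiv: float
    t1: float        # end of the early observation window (in G1)
    t2: float        # start of the late observation window (in G2)

    def __post_init__(self) -> None:
        if self.kd_eff == 0:
            raise ValueError("kd_eff must be nonzero (solution is singular at 0)")
        if not 0 < self.t1 <= self.trep <= self.t2 < self.tdiv:
            raise ValueError(
                "windows must satisfy 0 < t1 <= trep <= t2 < tdiv, got "
                f"t1={self.t1}, trep={self.trep}, t2={self.t2}, tdiv={self.tdiv}")


def mean_trajectory(p: DeterministicParams, t) -> np.ndarray:
    """Cyclostationary mean R(t); continuous at trep, R(tdiv) = 2 R(0).

    Exponentials are evaluated on shifted arguments so that large kd*t
    never overflows.
    """
    t = np.asarray(t, dtype=float)
    K = p.kini_eff / p.kd_eff
    D = 2.0 - math.exp(-p.kd_eff * p.tdiv)
    pre = K * (1.0 - np.exp(-p.kd_eff * (p.tdiv - p.trep + t)) / D)
    post = K * (2.0 - 2.0 * np.exp(-p.kd_eff * (t - p.trep)) / D)
    return np.where(t < p.trep, pre, post)


def window_ratio(p: DeterministicParams) -> float:
    """RM: mean of R over the late window divided by the early window (analytic)."""
    if p.t1 <= 0 or p.t2 >= p.tdiv:
        raise ValueError("empty observation window")
    kd = p.kd_eff
    K = p.kini_eff / kd
    D = 2.0 - math.exp(-kd * p.tdiv)
    # integral of R over [0, t1)
    i_early = K * (p.t1 - math.exp(-kd * (p.tdiv - p.trep))
                   * (1.0 - math.exp(-kd * p.t1)) / (kd * D))
    # integral of R over [t2, tdiv)
    i_late = K * (2.0 * (p.tdiv - p.t2)
                  - 2.0 * (math.exp(-kd * (p.t2 - p.trep))
                           - math.exp(-kd * (p.tdiv - p.trep))) / (kd * D))
    return (i_late / (p.tdiv - p.t2)) / (i_early / p.t1)


def rm_sweep(p: DeterministicParams, kd_tdiv_grid) -> np.ndarray:
    """RM as a function of kd*tdiv (lifetime sweep at fixed windows)."""
    out = []
    for kt in np.asarray(kd_tdiv_grid, dtype=float):
        q = DeterministicParams(kini_eff=p.kini_eff, kd_eff=kt / p.tdiv,
                                trep=p.trep, tdiv=p.tdiv, t1=p.t1, t2=p.t2)
        out.append(window_ratio(q))
    return np.asarray(out)
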