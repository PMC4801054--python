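"""Parameter containers for the cell-cycle-aware telegraph model.

The model: each gene copy switches OFF->ON at rate ``kon`` and ON->OFF at
``koff``; an ON copy initiates transcripts at rate ``kini``.  A nascent
transcript elongates at constant speed and leaves the transcription site
after a deterministic residence time ``tres``, becoming a mature mRNA that
is degraded at rate ``kd``.  The locus replicates at time ``trep`` within a
cell cycle of length ``tdiv``; after replication the activation rate is
``alpha * kon`` (dosage compensation).  At division, mature mRNA are
binomially partitioned.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

__all__ = [
    "KineticParams",
    "CellCycleParams",
    "phase_boundary_ages",
    "age_density",
    "age_cdf",
    "sample_ages",
    "load_config",
    "dump_config",
]


@dataclass
class KineticParams:
    """Kinetic parameters of the two-state model (rates in 1/min, times in min).

    ``lam`` is the mean signal weight of one nascent transcript under the
    uniform-probe approximation (a transcript elongated a fraction f of the
    gene contributes f full-transcript equivalents; averaged over a uniform
    age this gives 1/2).
    """

    kon: float = 0.009
    koff: float = 0.02
    kini: float = 2.2
    tres: float = 3.5
    kd: float = math.log(2) / 426.0
    trep: float = 390.0
    tdiv: float = 780.0
    alpha: float = 1.0
    lam: float = 0.5

    def __post_init__(self) -> None:
        for name in ("kon", "koff", "kini", "tres", "kd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if not self.tdiv > 0:
            raise ValueError(f"tdiv must be positive, got {self.tdiv}")
        if not 0 < self.trep < self.tdiv:
            raise ValueError(
                f"trep must lie strictly inside the cell cycle: 0 < {self.trep} < {self.tdiv}"
            )
        if self.alpha <= 0:
            raise ValueError(f"alpha must be positive, got {self.alpha}")
        if self.alpha > 1:
            import warnings

            warnings.warn(
                f"alpha={self.alpha} > 1 implies enhanced activation after "
                "replication (negative dosage compensation)",
                stacklevel=2,
            )
        if not 0 < self.lam <= 1:
            raise ValueError(f"lam must be in (0, 1], got {self.lam}")

    @property
    def duty_pre(self) -> float:
        """Fraction of time a copy is ON before replication, kon/(kon+koff)."""
        return self.kon / (self.kon + self.koff)

    @property
    def duty_post(self) -> float:
        """ON fraction after replication, alpha*kon/(alpha*kon+koff)."""
        a = self.alpha * self.kon
        return a / (a + self.koff)

    def replace(self, **kwargs) -> "KineticParams":
        d = asdict(self)
        d.update(kwargs)
        return KineticParams(**d)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class CellCycleParams:
    """Observation model for DNA content of an asynchronous population."""

    mu: float = 100.0
    cv: float = 0.05
    phase_fractions: tuple = field(default=(0.43, 0.29, 0.28))
    tdiv: float = 780.0

    def __post_init__(self) -> None:
        if self.cv <= 0 and self.cv != 0.0:
            raise ValueError(f"cv must be >= 0, got {self.cv}")
        f = tuple(float(x) for x in self.phase_fractions)
        if len(f) != 3 or any(x < 0 for x in f):
            raise ValueError("phase_fractions must be 3 nonnegative numbers")
        if abs(sum(f) - 1.0) > 1e-9:
            raise ValueError(f"phase_fractions must sum to 1, got {sum(f)}")
        self.phase_fractions = f
        if self.mu <= 0 or self.tdiv <= 0:
            raise ValueError("mu and tdiv must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["phase_fractions"] = list(self.phase_fractions)
        return d


def age_density(a, tdiv: float):
    """Age density of an exponentially growing asynchronous population.

    p(a) = (2 ln 2 / tdiv) * 2**(-a/tdiv) on [0, tdiv): newborn cells are
    twice as frequent as dividing ones.
    """
    a = np.asarray(a, dtype=float)
    out = (2.0 * math.log(2.0) / tdiv) * np.exp2(-a / tdiv)
    return np.where((a >= 0) & (a < tdiv), out, 0.0)


def age_cdf(a, tdiv: float):
    """CDF of the exponential-growth age density, F(a) = 2(1 - 2**(-a/tdiv))."""
    a = np.clip(np.asarray(a, dtype=float), 0.0, tdiv)
    return 2.0 * (1.0 - np.exp2(-a / tdiv))


def sample_ages(n: int, tdiv: float, rng: np.random.Generator) -> np.ndarray:
    """Draw cell ages by inverting the age CDF."""
    u = rng.random(n)
    return -tdiv * np.log2(1.0 - u / 2.0)


def phase_boundary_ages(phase_fractions, tdiv: float) -> tuple:
    """Ages (t1, t2) at which G1 ends and G2/M begins.

    Solves F(t1) = fG1 and F(t2) = fG1 + fS under the exponential-growth age
    density, so that the population fractions of cells younger than t1 /
    older than t2 equal the requested G1 / G2M fractions.
    """
    f_g1, f_s, f_g2m = phase_fractions
    t1 = -tdiv * math.log2(1.0 - f_g1 / 2.0)
    t2 = -tdiv * math.log2(1.0 - (f_g1 + f_s) / 2.0)
    return t1, t2


def load_config(path) -> dict:
    """Read a YAML config into {'kinetics': KineticParams, 'cellcycle': CellCycleParams, ...}."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    out = dict(raw)
    if "kinetics" in raw:
        out["kinetics"] = KineticParams(**raw["kinetics"])
    if "cellcycle" in raw:
        cc = dict(raw["cellcycle"])
        if "phase_fractions" in cc:
            cc["phase_fractions"] = tuple(cc["phase_fractions"])
        out["cellcycle"] = CellCycleParams(**cc)
    return out


def dump_config(path, kinetics: KineticParams | None = None,
                cellcycle: CellCycleParams | None = None, **extra) -> None:
    doc = dict(extra)
    if kinetics is not None:
        doc["kinetics"] = kinetics.to_dict()
    if cellcycle is not None:
        doc["cellcycle"] = cellcycle.to_dict()
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
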