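"""Model parameters, cell-state algebra and pointwise rate formulas.

Two species compete on a lattice (or in a well-mixed vessel).  Species 1
carries an evolvable antibiotic production rate ``a`` (``a == 0`` is the
non-producing cheater N); species 2 is either sensitive (S, inhibited by
the antibiotic) or resistant (R, paying a fixed growth cost).  The
antibiotic is bacteriostatic: it lowers birth rates, never death rates.

Growth rates:

* producer:      ``r_P = r1 - a * c``
* non-producer:  ``r_N = r1``
* sensitive:     ``r_S = r2 - A_loc``
* resistant:     ``r_R = r2 - c_R``

where ``A_loc`` is the quasi-steady-state antibiotic concentration of
the 9-site Moore neighbourhood, ``sum(a_i) / (9 b)``.
"""
from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

__all__ = [
    "Kind",
    "CellState",
    "ModelParams",
    "producer_growth_rate",
    "sensitive_growth_rate",
    "resistant_growth_rate",
    "local_antibiotic",
    "NEIGHBORHOOD_SIZE",
]

#: sites in the Moore neighbourhood, centre included
NEIGHBORHOOD_SIZE = 9


class Kind(enum.Enum):
    """What occupies a lattice site."""

    VACANT = "vacant"
    SPECIES1 = "species1"  # producer lineage (P / N strains)
    SPECIES2 = "species2"  # sensitive lineage (S / R)


@dataclass(frozen=True)
class CellState:
    """One lattice site: vacant, a species-1 strain, or a species-2 cell.

    ``a`` is meaningful only for species 1 (``a == 0`` means
    non-producer); ``resistant`` only for species 2.
    """

    kind: Kind
    a: float = 0.0
    resistant: bool = False

    # -- constructors ------------------------------------------------
    @staticmethod
    def vacant() -> "CellState":
        return CellState(Kind.VACANT)

    @staticmethod
    def producer(a: float) -> "CellState":
        if not math.isfinite(a) or a < 0:
            raise ValueError(f"production rate must be finite and >= 0, got {a}")
        return CellState(Kind.SPECIES1, a=float(a))

    @staticmethod
    def nonproducer() -> "CellState":
        return CellState(Kind.SPECIES1, a=0.0)

    @staticmethod
    def sensitive() -> "CellState":
        return CellState(Kind.SPECIES2, resistant=False)

    @staticmethod
    def resistant_cell() -> "CellState":
        return CellState(Kind.SPECIES2, resistant=True)

    # -- predicates --------------------------------------------------
    @property
    def is_vacant(self) -> bool:
        return self.kind is Kind.VACANT

    @property
    def is_producer(self) -> bool:
        return self.kind is Kind.SPECIES1 and self.a > 0

    @property
    def is_nonproducer(self) -> bool:
        return self.kind is Kind.SPECIES1 and self.a == 0

    @property
    def is_sensitive(self) -> bool:
        return self.kind is Kind.SPECIES2 and not self.resistant

    @property
    def is_resistant(self) -> bool:
        return self.kind is Kind.SPECIES2 and self.resistant

    def label(self) -> str:
        """Short display label: 'vacant', 'N', 'P110', 'S' or 'R'."""
        if self.kind is Kind.VACANT:
            return "vacant"
        if self.kind is Kind.SPECIES1:
            return "N" if self.a == 0 else f"P{self.a:g}"
        return "R" if self.resistant else "S"


def _check_finite(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value}")
    return value


@dataclass(frozen=True)
class ModelParams:
    """All rate constants and simulation controls.

    Invariants are enforced at construction: rates positive, mutation
    probability in [0, 1], ``max(r1, r2) * dt <= 1`` and ``v * dt <= 1``
    so per-step event probabilities stay valid, and ``allowed_a`` sorted,
    non-negative and duplicate-free.
    """

    r1: float = 2.0  # intrinsic growth rate, species 1
    r2: float = 2.5  # intrinsic growth rate, species 2
    b: float = 10.0  # antibiotic decay rate
    c: float = 0.001  # metabolic cost per unit production
    v: float = 1.0  # death rate (all cell types)
    u: float = 0.0  # mutation probability per birth
    c_R: float = 0.0  # growth-rate cost of resistance
    dt: float = 0.01  # time step
    L: int = 256  # lattice side length
    allowed_a: tuple[float, ...] = (0.0,)  # permitted production rates
    init_fractions: Mapping[str, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("r1", "r2", "b", "v", "dt"):
            if _check_finite(name, getattr(self, name)) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        for name in ("c", "c_R"):
            if _check_finite(name, getattr(self, name)) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if not 0.0 <= self.u <= 1.0:
            raise ValueError(f"u must be in [0, 1], got {self.u}")
        if max(self.r1, self.r2) * self.dt > 1.0 or self.v * self.dt > 1.0:
            raise ValueError(
                "dt too large: birth/death probabilities r*dt and v*dt "
                "must not exceed 1"
            )
        if self.L < 3:
            raise ValueError(f"L must be >= 3, got {self.L}")
        a = tuple(float(x) for x in self.allowed_a)
        if len(a) == 0:
            raise ValueError("allowed_a must be non-empty")
        if any(x < 0 or not math.isfinite(x) for x in a):
            raise ValueError(f"allowed_a must be finite and >= 0, got {a}")
        if sorted(set(a)) != list(a):
            raise ValueError(f"allowed_a must be sorted and duplicate-free, got {a}")
        object.__setattr__(self, "allowed_a", a)
        if self.init_fractions is not None:
            fr = dict(self.init_fractions)
            if any(f < 0 for f in fr.values()) or sum(fr.values()) > 1 + 1e-12:
                raise ValueError("init_fractions must be >= 0 and sum to <= 1")
            object.__setattr__(self, "init_fractions", fr)

    def with_(self, **changes) -> "ModelParams":
        """Return a copy with the given fields replaced (revalidated)."""
        return replace(self, **changes)

    @property
    def r_R(self) -> float:
        """Growth rate of resistant cells, ``r2 - c_R``."""
        return resistant_growth_rate(self.r2, self.c_R)

    def strain_code(self, a: float) -> int:
        """Snapshot/lattice code of the species-1 strain with rate ``a``."""
        try:
            return 1 + self.allowed_a.index(float(a))
        except ValueError:
            raise ValueError(
                f"production rate {a} not in allowed_a={self.allowed_a}"
            ) from None


def producer_growth_rate(r1: float, a: float, c: float) -> float:
    """Growth rate of a producer strain, ``r1 - a * c``.

    May be negative; clamping to a valid birth probability happens in
    the sweep.  ``a == 0`` recovers the non-producer rate ``r1``.
    """
    r1 = _check_finite("r1", r1)
    a = _check_finite("a", a)
    c = _check_finite("c", c)
    if r1 <= 0 or a < 0 or c < 0:
        raise ValueError(f"need r1 > 0, a >= 0, c >= 0; got {r1=}, {a=}, {c=}")
    return r1 - a * c


def sensitive_growth_rate(r2: float, A_loc: float) -> float:
    """Growth rate of a sensitive cell, ``r2 - A_loc`` (may be negative)."""
    r2 = _check_finite("r2", r2)
    A_loc = _check_finite("A_loc", A_loc)
    if A_loc < 0:
        raise ValueError(f"A_loc must be >= 0, got {A_loc}")
    return r2 - A_loc


def resistant_growth_rate(r2: float, c_R: float) -> float:
    """Growth rate of a resistant cell, ``r2 - c_R`` (antibiotic-free)."""
    r2 = _check_finite("r2", r2)
    c_R = _check_finite("c_R", c_R)
    if c_R < 0:
        raise ValueError(f"c_R must be >= 0, got {c_R}")
    return r2 - c_R


def local_antibiotic(neighborhood_rates: Sequence[float], b: float) -> float:
    """Quasi-steady-state antibiotic concentration of one neighbourhood.

    ``neighborhood_rates`` lists the production rate at each of the 9
    Moore-neighbourhood sites (centre included); vacant and species-2
    sites contribute 0.  Each producer contributes additively, so the
    result is ``sum(a_i) / (9 b)`` -- for a uniform strain this is the
    familiar ``a * n_P / (9 b)``.
    """
    b = _check_finite("b", b)
    if b <= 0:
        raise ValueError(f"b must be > 0, got {b}")
    rates = [_check_finite("rate", r) for r in neighborhood_rates]
    if len(rates) != NEIGHBORHOOD_SIZE:
        raise ValueError(
            f"neighbourhood must have exactly {NEIGHBORHOOD_SIZE} sites, "
            f"got {len(rates)}"
        )
    if any(r < 0 for r in rates):
        raise ValueError("production rates must be >= 0")
    return sum(rates) / (NEIGHBORHOOD_SIZE * b)
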