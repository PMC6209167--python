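"""Well-mixed ODE counterparts of the lattice model.

Two systems are provided:

* the bactericidal *colicin* system, where producers kill sensitive
  cells through a ``sigma * P * S`` term, and
* the *bacteriostatic* system studied throughout this package, where
  the antibiotic (at quasi-steady state ``A = a P / b``) lowers the
  sensitive birth rate instead.

Both share the logistic-with-death structure
``dX/dt = r_X X (1 - T) - X`` with ``T = P + N + S``.  Closed-form
single-species equilibria, the unstable producer/sensitive coexistence
point ``(P0, S0)`` and the production-rate window where it exists
(``S0 > 0``) are exposed alongside a generic integrator.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .core import ModelParams, producer_growth_rate

__all__ = [
    "ColicinParams",
    "CoexistencePoint",
    "ProductionRateWindow",
    "Trajectory",
    "rhs_bacteriostatic",
    "rhs_colicin",
    "integrate",
    "single_species_equilibrium",
    "unstable_coexistence_point",
    "production_rate_window",
    "classify_ode_outcome",
]

#: densities below this are treated as extinct when classifying outcomes
EXTINCTION_THRESHOLD = 1e-6
#: ``max |dX/dt|`` below this counts as converged
CONVERGENCE_TOL = 1e-9


@dataclass(frozen=True)
class ColicinParams:
    """Rates of the bactericidal colicin system.

    The rock-paper-scissors regime requires ``rP < rN < rS``.
    """

    rP: float
    rN: float
    rS: float
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")


@dataclass(frozen=True)
class CoexistencePoint:
    """The unstable producer/sensitive fixed point ``(P0, 0, S0)``."""

    P0: float
    S0: float
    exists: bool  # S0 > 0 (and producer viable)


@dataclass(frozen=True)
class ProductionRateWindow:
    """Roots of ``S0(a) = 0`` bracketing the region ``S0 > 0``.

    ``empty`` means no sign change was found; ``anomalous`` flags more
    than two roots (not expected for this family of parameters and left
    to the caller to interpret).
    """

    a_min: float | None
    a_max: float | None
    roots: tuple[float, ...] = ()
    empty: bool = False
    anomalous: bool = False


@dataclass(frozen=True)
class Trajectory:
    """Sampled ODE solution with the final right-hand-side residual."""

    t: np.ndarray
    y: np.ndarray  # shape (n_times, 3), columns P, N, S
    final_rhs_norm: float

    @property
    def final(self) -> np.ndarray:
        return self.y[-1]

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {"t": self.t, "P": self.y[:, 0], "N": self.y[:, 1], "S": self.y[:, 2]}
        ).to_csv(path, index=False)


def rhs_bacteriostatic(
    state: Sequence[float], params: ModelParams, a: float
) -> np.ndarray:
    """Time derivative of (P, N, S) for the bacteriostatic system.

    dP/dt = (r1 - a c) P (1 - T) - P
    dN/dt = r1 N (1 - T) - N
    dS/dt = (r2 - a P / b) S (1 - T) - S
    """
    P, N, S = state
    T = P + N + S
    rP = producer_growth_rate(params.r1, a, params.c)
    return np.array(
        [
            rP * P * (1.0 - T) - P,
            params.r1 * N * (1.0 - T) - N,
            (params.r2 - a * P / params.b) * S * (1.0 - T) - S,
        ]
    )


def rhs_colicin(state: Sequence[float], params: ColicinParams) -> np.ndarray:
    """Time derivative of (P, N, S) for the colicin (bactericidal) system."""
    P, N, S = state
    T = P + N + S
    return np.array(
        [
            params.rP * P * (1.0 - T) - P,
            params.rN * N * (1.0 - T) - N,
            params.rS * S * (1.0 - T) - S - params.sigma * P * S,
        ]
    )


def integrate(
    rhs: Callable[[np.ndarray], np.ndarray],
    init: Sequence[float],
    t_end: float,
    n_points: int = 500,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Integrate ``dy/dt = rhs(y)`` from ``init`` to ``t_end``.

    Uses an adaptive stiff-capable solver; densities are clipped at 0
    in the sampled output (solver undershoot is bounded by ``atol``).
    Raises ``RuntimeError`` with solver diagnostics on failure.
    """
    init = np.asarray(init, dtype=float)
    if t_end <= 0:
        raise ValueError(f"t_end must be > 0, got {t_end}")
    if np.any(init < 0):
        raise ValueError(f"initial state must be >= 0, got {init}")
    sol = solve_ivp(
        lambda _t, y: rhs(y),
        (0.0, float(t_end)),
        init,
        method="LSODA",
        t_eval=np.linspace(0.0, float(t_end), n_points),
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:  # pragma: no cover - solver failure is exceptional
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    y = np.clip(sol.y.T, 0.0, None)
    final_norm = float(np.max(np.abs(rhs(y[-1]))))
    return Trajectory(t=sol.t, y=y, final_rhs_norm=final_norm)


def single_species_equilibrium(r: float) -> float:
    """Equilibrium density ``max(0, 1 - 1/r)`` of a species alone.

    ``r`` is the net intrinsic growth rate (production cost already
    deducted); ``r <= 1`` means extinction since the death rate is 1.
    """
    if not np.isfinite(r) or r <= 0:
        raise ValueError(f"growth rate must be > 0, got {r}")
    return max(0.0, 1.0 - 1.0 / r)


def unstable_coexistence_point(params: ModelParams, a: float) -> CoexistencePoint:
    """The unstable P/S fixed point where producer and sensitive growth
    rates coincide: ``r1 - a c = r2 - a P0 / b`` gives
    ``P0 = b ((r2 - r1)/a + c)`` and ``S0 = 1 - 1/(r1 - a c) - P0``.

    ``exists`` requires both ``S0 > 0`` and a viable producer
    (``r1 - a c > 1``); outside that regime P0/S0 are still reported.
    """
    if a <= 0:
        raise ValueError(f"a must be > 0 for a P/S coexistence point, got {a}")
    rP = producer_growth_rate(params.r1, a, params.c)
    P0 = params.b * ((params.r2 - params.r1) / a + params.c)
    if rP <= 1.0:
        # producer cannot persist at all; S0 via the formula anyway
        S0 = -np.inf if rP <= 0 else 1.0 - 1.0 / rP - P0
        return CoexistencePoint(P0=P0, S0=S0, exists=False)
    S0 = 1.0 - 1.0 / rP - P0
    return CoexistencePoint(P0=P0, S0=S0, exists=bool(S0 > 0))


def _s0_of_a(params: ModelParams):
    def s0(a: float) -> float:
        rP = params.r1 - a * params.c
        return (
            1.0
            - 1.0 / rP
            - params.b * ((params.r2 - params.r1) / a + params.c)
        )

    return s0


def production_rate_window(
    params: ModelParams, n_scan: int = 2000, rel_tol: float = 1e-9
) -> ProductionRateWindow:
    """Production-rate window ``(a_min, a_max)`` where ``S0(a) > 0``.

    Scans ``S0(a)`` on a logarithmic grid over ``a`` in
    ``[1e-3, (r1 - 1)/c)`` (the producer-viability range; ``a_max``
    sits near its upper pole), then polishes every sign change with a
    bracketing root finder to relative tolerance ``rel_tol``.  No sign
    change yields an empty-window result, not an exception; more than
    two roots is flagged as anomalous.
    """
    if params.c <= 0:
        # costless production: S0 > 0 for all large enough a; scan up to
        # an arbitrary large bound rather than guessing a pole.
        a_hi = 1e6
    else:
        a_hi = (params.r1 - 1.0) / params.c
    s0 = _s0_of_a(params)
    grid = np.geomspace(1e-3, a_hi * (1.0 - 1e-12), n_scan)
    vals = np.array([s0(a) for a in grid])
    roots: list[float] = []
    for lo, hi, vlo, vhi in zip(grid[:-1], grid[1:], vals[:-1], vals[1:]):
        if vlo == 0.0:
            roots.append(float(lo))
        elif vlo * vhi < 0:
            roots.append(float(brentq(s0, lo, hi, rtol=rel_tol)))
    if vals[-1] == 0.0:
        roots.append(float(grid[-1]))
    if not roots:
        return ProductionRateWindow(a_min=None, a_max=None, empty=True)
    anomalous = len(roots) > 2
    a_min = roots[0]
    a_max = roots[-1] if len(roots) > 1 else None
    return ProductionRateWindow(
        a_min=a_min, a_max=a_max, roots=tuple(roots), anomalous=anomalous
    )


def classify_ode_outcome(trajectory: Trajectory) -> str:
    """Label the surviving species at the end of a converged trajectory.

    Returns ``"indeterminate"`` when the final right-hand-side residual
    exceeds the convergence tolerance -- never a false winner.  Species
    with final density above ``EXTINCTION_THRESHOLD`` survive; the label
    is ``P_only`` / ``N_only`` / ``S_only``, ``extinct``, or a
    ``coexist_*`` combination such as ``coexist_PS``.
    """
    if trajectory.final_rhs_norm >= CONVERGENCE_TOL:
        return "indeterminate"
    names = np.array(["P", "N", "S"])
    alive = trajectory.final > EXTINCTION_THRESHOLD
    survivors = names[alive]
    if len(survivors) == 0:
        return "extinct"
    if len(survivors) == 1:
        return f"{survivors[0]}_only"
    return "coexist_" + "".join(survivors)
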