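"""Reproducible experiment drivers: outcome classification, replicate
ensembles, the a-c phase diagram, staged protocols (mutation switched on
mid-run), multi-strain production-rate evolution, and the resistance
sweep.

Defaults are scaled down relative to the full-scale reference settings
(L = 256, t = 2000, modest replicate counts) so experiments run at desk
scale; pass larger values for full-scale reproductions.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from ._kernels import CODE_R, CODE_S
from .core import CellState, ModelParams
from .lattice import Lattice, RunResult, TimeSeries, code_label, run

__all__ = [
    "OutcomeClass",
    "ReplicateSummary",
    "OUTCOME_LABELS",
    "classify_outcome",
    "replicate_outcomes",
    "phase_diagram",
    "time_averaged_concentrations",
    "staged_protocol",
    "evolve_production_rates",
    "resistance_sweep",
    "standard_composition",
]

#: fixed label order; also the deterministic tie-break order
OUTCOME_LABELS = (
    "S_only",
    "P_only",
    "N_only",
    "coexist_PNS",
    "coexist_SP",
    "coexist_other",
    "four_type",
    "extinct",
)


@dataclass(frozen=True)
class OutcomeClass:
    """Categorical end-state of a run, a pure function of the survivors."""

    label: str
    surviving_types: frozenset[str]


@dataclass
class ReplicateSummary:
    """Aggregate of an ensemble of independent runs at fixed parameters."""

    n_runs: int
    outcome_counts: dict[str, int]
    majority: str
    majority_tied: bool
    mean_concentrations: dict[str, dict[str, float]]  # per outcome label
    seeds: tuple[int, ...] = ()

    def frequency(self, label: str) -> float:
        return self.outcome_counts.get(label, 0) / self.n_runs


def standard_composition(
    a: float, fraction: float = 0.05
) -> list[tuple[CellState, float]]:
    """The usual P/N/S starting mix at 5% each (rest vacant)."""
    return [
        (CellState.producer(a), fraction),
        (CellState.nonproducer(), fraction),
        (CellState.sensitive(), fraction),
    ]


def _category_sets(lattice: Lattice) -> frozenset[str]:
    """Surviving categories among {P, N, S, R} (strains collapsed)."""
    cats = set()
    for code in lattice.surviving_codes():
        if code == CODE_S:
            cats.add("S")
        elif code == CODE_R:
            cats.add("R")
        elif lattice.allowed_a[code - 1] == 0:
            cats.add("N")
        else:
            cats.add("P")
    return frozenset(cats)


def classify_outcome(final_lattice: Lattice, params: ModelParams | None = None) -> OutcomeClass:
    """Label a finished run by its surviving cell-type set.

    Species-1 survivors split into P (any ``a > 0`` strain) and N
    (``a == 0``).  The labels mirror the phase-diagram legend: S only,
    P only, N only, P+N+S, S+P, four-type, other mixtures, extinct.
    """
    cats = _category_sets(final_lattice)
    if not cats:
        label = "extinct"
    elif cats == {"S"}:
        label = "S_only"
    elif cats == {"P"}:
        label = "P_only"
    elif cats == {"N"}:
        label = "N_only"
    elif cats == {"P", "N", "S"}:
        label = "coexist_PNS"
    elif cats == {"P", "S"}:
        label = "coexist_SP"
    elif cats >= {"P", "N", "S", "R"}:
        label = "four_type"
    else:
        label = "coexist_other"
    return OutcomeClass(label=label, surviving_types=cats)


def time_averaged_concentrations(
    series: TimeSeries, window: float = 0.5
) -> dict[str, float]:
    """Mean fraction per type over the trailing ``window`` of the run.

    ``window`` is the fraction of the recorded time span to average
    over (0.5 = second half, the convention used for reported averages).
    """
    if not 0.0 < window <= 1.0:
        raise ValueError(f"window must be in (0, 1], got {window}")
    t0 = series.times[-1] - window * (series.times[-1] - series.times[0])
    mask = series.times >= t0 - 1e-9
    if not mask.any():
        raise ValueError("empty averaging window")
    mean = series.counts[mask].mean(axis=0) / float(series.side**2)
    out = {"vacant": float(mean[0])}
    for code in range(1, len(series.allowed_a) + 1):
        out[code_label(code, series.allowed_a)] = float(mean[code])
    out["S"] = float(mean[CODE_S])
    out["R"] = float(mean[CODE_R])
    return out


def replicate_outcomes(
    params: ModelParams,
    composition: Sequence[tuple[CellState, float]],
    n_runs: int,
    t_end: float,
    seed_base: int | None = None,
    record_every: float = 10.0,
    hooks: Sequence[tuple[float, Mapping]] = (),
) -> ReplicateSummary:
    """Run ``n_runs`` independent simulations (seeds ``seed_base + i``)
    and aggregate outcome frequencies plus trailing-half concentrations
    conditioned on outcome.

    The majority label is the modal outcome; ties break to the first
    label in :data:`OUTCOME_LABELS` and are flagged.
    """
    if n_runs < 1:
        raise ValueError(f"n_runs must be >= 1, got {n_runs}")
    seed_base = params.seed if seed_base is None else int(seed_base)
    counts: dict[str, int] = {}
    conc_acc: dict[str, list[dict[str, float]]] = {}
    seeds = tuple(seed_base + i for i in range(n_runs))
    for seed in seeds:
        result = run(
            params,
            composition,
            t_end,
            record_every=record_every,
            hooks=hooks,
            seed=seed,
        )
        label = classify_outcome(result.lattice, params).label
        counts[label] = counts.get(label, 0) + 1
        conc_acc.setdefault(label, []).append(
            time_averaged_concentrations(result.series)
        )
    best = max(counts.values())
    leaders = [lab for lab in OUTCOME_LABELS if counts.get(lab, 0) == best]
    mean_conc = {
        lab: {
            key: float(np.mean([c[key] for c in rows]))
            for key in rows[0]
        }
        for lab, rows in conc_acc.items()
    }
    return ReplicateSummary(
        n_runs=n_runs,
        outcome_counts=counts,
        majority=leaders[0],
        majority_tied=len(leaders) > 1,
        mean_concentrations=mean_conc,
        seeds=seeds,
    )


def phase_diagram(
    a_values: Sequence[float],
    c_values: Sequence[float],
    n_runs: int,
    params: ModelParams,
    t_end: float = 2000.0,
    seed_base: int | None = None,
) -> list[dict]:
    """Majority outcome over an (a, c) grid, one ensemble per cell.

    Returns a list of records ``{"a", "c", "majority", "counts"}`` in
    row-major (c outer, a inner) order.
    """
    if len(a_values) == 0 or len(c_values) == 0:
        raise ValueError("a_values and c_values must be non-empty")
    seed_base = params.seed if seed_base is None else int(seed_base)
    out = []
    stride = 1000003  # distinct seed block per grid cell
    for i, c in enumerate(c_values):
        for k, a in enumerate(a_values):
            cell_params = params.with_(c=float(c), allowed_a=_strains_for(a))
            summary = replicate_outcomes(
                cell_params,
                standard_composition(a),
                n_runs,
                t_end,
                seed_base=seed_base + (i * len(a_values) + k) * stride,
            )
            out.append(
                {
                    "a": float(a),
                    "c": float(c),
                    "majority": summary.majority,
                    "counts": summary.outcome_counts,
                }
            )
    return out


def _strains_for(a: float) -> tuple[float, ...]:
    return (0.0, float(a)) if a > 0 else (0.0,)


def staged_protocol(
    params: ModelParams,
    composition: Sequence[tuple[CellState, float]],
    t_end: float,
    stages: Sequence[tuple[float, Mapping]] = (),
    record_every: float = 10.0,
    seed: int | None = None,
) -> RunResult:
    """Single run whose parameters change at scheduled times.

    Thin veneer over :func:`abxlattice.lattice.run`'s hook mechanism;
    with no stages it is identical to ``run``.  Stage times must be
    increasing and lie inside the run.
    """
    times = [t for t, _ in stages]
    if times != sorted(times):
        raise ValueError("stage times must be increasing")
    return run(
        params,
        composition,
        t_end,
        record_every=record_every,
        hooks=stages,
        seed=seed,
    )


def evolve_production_rates(
    initial_strains: Sequence[tuple[CellState, float]],
    params: ModelParams,
    burn_in: float = 1000.0,
    t_end: float = 10_000.0,
    mutation_rate: float = 1e-4,
    record_every: float = 10.0,
    seed: int | None = None,
    burn_in_retries: int = 0,
) -> tuple[dict[str, float], RunResult]:
    """Multi-strain production-rate evolution.

    Runs ``burn_in`` time units without mutation to let spatial
    structure establish, then switches mutation on among all strains in
    ``params.allowed_a`` at ``mutation_rate``.  Returns the per-type
    time-averaged frequency over the trailing half of the full
    (burn-in + evolution) timeline, plus the mutation-phase run result.

    On lattices well below the reference scale the burn-in transient
    occasionally loses S or the producers outright; such a collapsed
    burn-in carries no information about the evolved state.  With
    ``burn_in_retries > 0`` a burn-in missing either species is
    re-seeded (seed + attempt) up to that many extra times before the
    expensive mutation phase runs.
    """
    if not 0 < burn_in < t_end:
        raise ValueError(f"need 0 < burn_in < t_end, got {burn_in}, {t_end}")
    seed = params.seed if seed is None else int(seed)
    base = params.with_(u=0.0)
    burn = None
    for attempt in range(1 + max(0, burn_in_retries)):
        candidate = run(
            base,
            initial_strains,
            burn_in,
            record_every=record_every,
            seed=seed + attempt,
            early_stop=False,
        )
        counts = candidate.lattice.counts()
        producer_codes = [
            1 + k for k, a in enumerate(params.allowed_a) if a > 0
        ]
        if (
            burn_in_retries == 0
            or (counts[CODE_S] > 0 and sum(counts[c] for c in producer_codes) > 0)
        ):
            burn = candidate
            break
    if burn is None:
        burn = candidate  # all retries collapsed; proceed and let the
        # caller see the degenerate concentrations
    result = run(
        base.with_(u=mutation_rate),
        None,
        t_end - burn_in,
        record_every=record_every,
        lattice=burn.lattice,
        seed=seed + 100 + attempt,
    )
    window = (t_end / 2) / (t_end - burn_in)
    return time_averaged_concentrations(result.series, window=window), result


def resistance_sweep(
    r_R_values: Sequence[float],
    params: ModelParams,
    a: float = 110.0,
    burn_in: float = 5000.0,
    t_end: float = 15_000.0,
    mutation_rate: float = 1e-4,
    n_runs: int = 1,
    seed_base: int | None = None,
) -> list[dict]:
    """Equilibrium concentrations of P, N, S, R versus resistant growth rate.

    For each ``r_R``: start from the standard P/N/S mix, burn in without
    mutation, then enable mutation both within species 1 (P <-> N) and
    within species 2 (S <-> R).  Reports trailing-half mean
    concentrations averaged over ``n_runs`` replicates, plus how many
    replicates ended with species 1 extinct.
    """
    seed_base = params.seed if seed_base is None else int(seed_base)
    out = []
    stride = 1000003
    for i, r_R in enumerate(r_R_values):
        if not 0.0 < r_R <= params.r2:
            raise ValueError(f"r_R must lie in (0, r2], got {r_R}")
        p = params.with_(
            c_R=params.r2 - float(r_R), u=0.0, allowed_a=_strains_for(a)
        )
        acc: list[dict[str, float]] = []
        species1_extinct = 0
        for rep in range(n_runs):
            result = staged_protocol(
                p,
                standard_composition(a),
                t_end,
                stages=[(burn_in, {"u": mutation_rate, "sr_mutation": True})],
                seed=seed_base + i * stride + rep,
            )
            acc.append(time_averaged_concentrations(result.series))
            if result.series.species1_fraction()[-1] == 0.0:
                species1_extinct += 1
        mean = {
            key: float(np.mean([row[key] for row in acc])) for key in acc[0]
        }
        mean["P"] = mean.pop(code_label(2, p.allowed_a)) if a > 0 else 0.0
        out.append(
            {
                "r_R": float(r_R),
                "c_R": p.c_R,
                "concentrations": mean,
                "species1_extinct_runs": species1_extinct,
                "n_runs": n_runs,
            }
        )
    return out
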