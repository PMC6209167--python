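"""Stochastic spatial engine: L x L torus, per-dt sweeps, antibiotic
coupling through the Moore neighbourhood, multi-strain producers and
resistant cells.

The lattice is stored as a flat int8 code array (see
:mod:`abxlattice._kernels` for the code scheme).  All randomness flows
through :class:`abxlattice._rng.SweepRng`: identical (seed, params,
composition) give a bit-identical trajectory.
"""
from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import _kernels
from ._kernels import (
    CODE_R,
    CODE_S,
    CODE_VACANT,
    N_CODES,
    birth_thresholds,
    event_bounds,
)
from ._rng import SweepRng, splitmix64
from .core import CellState, Kind, ModelParams

__all__ = [
    "Lattice",
    "TimeSeries",
    "RunResult",
    "SweepRng",
    "initialize_lattice",
    "antibiotic_field",
    "mutate_offspring",
    "sweep",
    "run",
    "concentrations",
    "code_label",
    "write_snapshot",
    "read_snapshot",
    "lattice_to_rgb",
]


def code_label(code: int, allowed_a: Sequence[float]) -> str:
    """Display label for a site code ('vacant', 'N', 'P110', 'S', 'R')."""
    if code == CODE_VACANT:
        return "vacant"
    if code == CODE_S:
        return "S"
    if code == CODE_R:
        return "R"
    a = allowed_a[code - 1]
    return "N" if a == 0 else f"P{a:g}"


@dataclass
class Lattice:
    """L x L grid of cell codes on a torus.

    ``codes`` is the flattened int8 array; dimensions are immutable for
    the duration of a run.
    """

    side: int
    codes: np.ndarray  # flat, length side**2, dtype int8
    allowed_a: tuple[float, ...]

    def __post_init__(self) -> None:
        self.codes = np.ascontiguousarray(self.codes, dtype=np.int8).ravel()
        if self.codes.size != self.side * self.side:
            raise ValueError(
                f"codes has {self.codes.size} entries, expected {self.side}^2"
            )
        valid = (
            (self.codes == CODE_VACANT)
            | (self.codes == CODE_S)
            | (self.codes == CODE_R)
            | ((self.codes >= 1) & (self.codes <= len(self.allowed_a)))
        )
        if not valid.all():
            bad = np.unique(self.codes[~valid])
            raise ValueError(f"invalid site codes {bad.tolist()}")

    @property
    def grid(self) -> np.ndarray:
        """2-D view of the codes."""
        return self.codes.reshape(self.side, self.side)

    def counts(self) -> np.ndarray:
        """Per-code site counts, length ``N_CODES``."""
        return np.bincount(self.codes, minlength=N_CODES).astype(np.int64)

    def cell_at(self, x: int, y: int) -> CellState:
        return self._cell_of_code(int(self.grid[x, y]))

    def _cell_of_code(self, code: int) -> CellState:
        if code == CODE_VACANT:
            return CellState.vacant()
        if code == CODE_S:
            return CellState.sensitive()
        if code == CODE_R:
            return CellState.resistant_cell()
        return CellState.producer(self.allowed_a[code - 1])

    def surviving_codes(self) -> list[int]:
        """Codes of the non-vacant types currently present."""
        counts = self.counts()
        return [c for c in np.nonzero(counts)[0].tolist() if c != CODE_VACANT]

    def copy(self) -> "Lattice":
        return Lattice(self.side, self.codes.copy(), self.allowed_a)


@dataclass
class TimeSeries:
    """Occupancy counts per cell type at each recording instant.

    ``counts[i, code]`` is the number of sites with the given code at
    ``times[i]``; fractions are counts / L^2 and vacancy is implied.
    """

    times: np.ndarray
    counts: np.ndarray  # shape (n_times, N_CODES)
    side: int
    allowed_a: tuple[float, ...]

    def fractions(self) -> np.ndarray:
        return self.counts / float(self.side * self.side)

    def fraction_of(self, label: str) -> np.ndarray:
        """Fraction time series for one type label (see `code_label`)."""
        for code in range(N_CODES):
            if self._has_code(code) and code_label(code, self.allowed_a) == label:
                return self.counts[:, code] / float(self.side * self.side)
        raise KeyError(f"unknown type label {label!r}")

    def _has_code(self, code: int) -> bool:
        return (
            code in (CODE_S, CODE_R)
            or 1 <= code <= len(self.allowed_a)
        )

    def species1_fraction(self) -> np.ndarray:
        n = len(self.allowed_a)
        return self.counts[:, 1 : n + 1].sum(axis=1) / float(self.side**2)

    def to_frame(self):
        """Time series as a pandas DataFrame (t + one column per type)."""
        import pandas as pd

        data = {"t": self.times}
        for code in range(1, len(self.allowed_a) + 1):
            data[code_label(code, self.allowed_a)] = self.counts[:, code]
        data["S"] = self.counts[:, CODE_S]
        data["R"] = self.counts[:, CODE_R]
        data["vacant"] = self.counts[:, CODE_VACANT]
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class RunResult:
    series: TimeSeries
    lattice: Lattice
    stopped_early: bool = False


# ----------------------------------------------------------------------
# construction


def initialize_lattice(
    params: ModelParams,
    composition: Iterable[tuple[CellState, float]],
    rng: np.random.Generator | int | None = None,
) -> Lattice:
    """Random lattice with each site independently assigned by fractions.

    ``composition`` lists (cell state, fraction) pairs; the remaining
    probability is vacancy.  Realized counts are binomial around the
    expectation.
    """
    comp = list(composition)
    fracs = np.array([f for _, f in comp], dtype=float)
    if np.any(fracs < 0):
        raise ValueError("fractions must be >= 0")
    if fracs.sum() > 1.0 + 1e-12:
        raise ValueError(f"composition fractions sum to {fracs.sum()} > 1")
    codes = []
    for cell, _f in comp:
        if cell.kind is Kind.VACANT:
            raise ValueError("composition must not contain vacant entries")
        if cell.kind is Kind.SPECIES1:
            codes.append(params.strain_code(cell.a))
        else:
            codes.append(CODE_R if cell.resistant else CODE_S)
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(params.seed if rng is None else rng)
    n = params.L * params.L
    draw = rng.random(n)
    flat = np.zeros(n, dtype=np.int8)
    lo = 0.0
    for code, f in zip(codes, fracs):
        flat[(draw >= lo) & (draw < lo + f)] = code
        lo += f
    return Lattice(params.L, flat, params.allowed_a)


# ----------------------------------------------------------------------
# fields and reference single-step operations


def _arate_table(params: ModelParams) -> np.ndarray:
    arate = np.zeros(N_CODES)
    for k, a in enumerate(params.allowed_a):
        arate[1 + k] = a
    return arate


def _rate_table(params: ModelParams) -> np.ndarray:
    """Growth rate per code (S handled dynamically in the kernel)."""
    rates = np.zeros(N_CODES)
    for k, a in enumerate(params.allowed_a):
        rates[1 + k] = params.r1 - a * params.c
    rates[CODE_R] = params.r2 - params.c_R
    return rates


def antibiotic_field(lattice: Lattice, b: float) -> np.ndarray:
    """L x L quasi-steady-state antibiotic concentration field.

    ``field[x, y]`` is the summed production rate of the 9-site Moore
    neighbourhood of (x, y), torus-wrapped, divided by ``9 b``.
    """
    if b <= 0:
        raise ValueError(f"b must be > 0, got {b}")
    arate = _arate_table(ModelParams(allowed_a=lattice.allowed_a, L=lattice.side))
    agrid = arate[lattice.grid]
    total = np.zeros_like(agrid)
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            total += np.roll(np.roll(agrid, dx, axis=0), dy, axis=1)
    return total / (9.0 * b)


def _neighbor_production_sum(lattice: Lattice, params: ModelParams) -> np.ndarray:
    """Flat float32 per-site neighbourhood production sum for the kernel."""
    field = antibiotic_field(lattice, params.b) * (9.0 * params.b)
    return np.ascontiguousarray(field.ravel(), dtype=np.float32)


def mutate_offspring(
    parent: CellState, params: ModelParams, rng: SweepRng,
    sr_mutation: bool = False,
) -> CellState:
    """Offspring type of a reproducing cell (reference implementation).

    With probability ``1 - u`` the offspring copies the parent.  A
    species-1 mutant redraws ``a`` uniformly from the other allowed
    values (for two strains this is the P/N flip); a species-2 mutant
    toggles S/R when ``sr_mutation`` is enabled.  Species never changes.
    The jitted sweep kernel implements the same rule inline.
    """
    if parent.kind is Kind.VACANT:
        raise ValueError("vacant sites do not reproduce")
    if params.u == 0.0 or rng.random(2) >= params.u:
        return parent
    if parent.kind is Kind.SPECIES1:
        n = len(params.allowed_a)
        if n <= 1:
            return parent
        k = rng.randint(n - 1, 2)
        idx = params.allowed_a.index(parent.a)
        if k >= idx:
            k += 1
        return CellState.producer(params.allowed_a[k])
    if sr_mutation:
        return (
            CellState.sensitive() if parent.resistant else CellState.resistant_cell()
        )
    return parent


# ----------------------------------------------------------------------
# sweeps


class _KernelState:
    """Persistent scratch buffers shared across kernel calls of one run."""

    def __init__(self, lattice: Lattice, params: ModelParams, rng: SweepRng):
        self.lattice = lattice
        self.rng = rng
        self.perm = np.arange(lattice.side**2, dtype=np.int32)
        side = lattice.side
        self.xp = np.roll(np.arange(side, dtype=np.int32), -1)
        self.xm = np.roll(np.arange(side, dtype=np.int32), 1)
        self.afield = _neighbor_production_sum(lattice, params)
        self.set_params(params)

    def set_params(self, params: ModelParams) -> None:
        self.params = params
        self.arate = _arate_table(params)
        rates = _rate_table(params)
        self.t_both, self.t_birth, self.t_dall = birth_thresholds(
            rates, params.v, params.dt
        )
        self.bound_u = event_bounds(self.t_dall, params.r2, params.v, params.dt)

    def advance(self, n_sweeps: int, sr_mutation: bool, global_dispersal: bool):
        p = self.params
        _kernels.run_sweeps(
            self.lattice.codes,
            self.afield,
            self.perm,
            self.rng.state,
            self.xp,
            self.xm,
            self.arate,
            self.t_both,
            self.t_birth,
            self.t_dall,
            self.bound_u,
            p.r2,
            1.0 / (9.0 * p.b),
            p.v * p.dt,
            p.dt,
            p.u,
            len(p.allowed_a),
            1 if sr_mutation else 0,
            1 if global_dispersal else 0,
            n_sweeps,
        )


def sweep(
    lattice: Lattice,
    params: ModelParams,
    rng: SweepRng,
    n_sweeps: int = 1,
    sr_mutation: bool = False,
    global_dispersal: bool = False,
) -> Lattice:
    """Advance ``lattice`` in place by ``n_sweeps`` time steps of ``dt``."""
    ks = _KernelState(lattice, params, rng)
    ks.advance(n_sweeps, sr_mutation, global_dispersal)
    return lattice


# ----------------------------------------------------------------------
# full runs


def _absorbed(counts: np.ndarray, u: float) -> bool:
    """True when no further compositional change is possible.

    An all-vacant lattice is absorbing regardless of mutation; with
    ``u == 0`` so is any single-type configuration.
    """
    occupied = [c for c in np.nonzero(counts)[0].tolist() if c != CODE_VACANT]
    if len(occupied) == 0:
        return True
    return u == 0.0 and len(occupied) == 1


def run(
    params: ModelParams,
    composition: Iterable[tuple[CellState, float]] | None,
    t_end: float,
    record_every: float = 10.0,
    hooks: Sequence[tuple[float, Mapping]] = (),
    global_dispersal: bool = False,
    lattice: Lattice | None = None,
    seed: int | None = None,
    early_stop: bool = True,
) -> RunResult:
    """Run the spatial model for ``t_end`` time units.

    ``hooks`` is a time-sorted schedule of parameter changes, each a
    ``(time, changes)`` pair where ``changes`` maps a subset of
    ``{"u", "c_R", "sr_mutation"}`` to new values (e.g. switching
    mutation on mid-run).  Occupancy is recorded every ``record_every``
    time units.  The run stops early once the configuration is
    absorbing: all-vacant, or a single cell type with mutation off.

    Pass ``lattice`` to resume from a snapshot instead of initializing
    from ``composition``.
    """
    if t_end <= 0:
        raise ValueError(f"t_end must be > 0, got {t_end}")
    hooks = sorted(hooks, key=lambda h: h[0])
    if hooks and hooks[-1][0] >= t_end:
        raise ValueError("hook schedule extends beyond t_end")
    run_seed = params.seed if seed is None else int(seed)
    if lattice is None:
        if composition is None:
            raise ValueError("need either composition or a lattice to resume")
        init_rng = np.random.default_rng(splitmix64(run_seed))
        lattice = initialize_lattice(params, composition, init_rng)
    elif lattice.allowed_a != params.allowed_a or lattice.side != params.L:
        raise ValueError("lattice does not match params (L / allowed_a)")
    rng = SweepRng(run_seed)

    n_total = round(t_end / params.dt)
    n_record = max(1, round(record_every / params.dt))
    sr_mutation = False
    ks = _KernelState(lattice, params, rng)

    hook_sweeps = [(round(ht / params.dt), dict(hc)) for ht, hc in hooks]
    times = [0.0]
    counts = [lattice.counts()]
    done = 0
    stopped_early = False
    while done < n_total:
        chunk = min(n_record - done % n_record, n_total - done)
        if hook_sweeps and hook_sweeps[0][0] > done:
            chunk = min(chunk, hook_sweeps[0][0] - done)
        ks.advance(chunk, sr_mutation, global_dispersal)
        done += chunk
        while hook_sweeps and hook_sweeps[0][0] <= done:
            _ht, changes = hook_sweeps.pop(0)
            changes = dict(changes)
            if "sr_mutation" in changes:
                sr_mutation = bool(changes.pop("sr_mutation"))
            if changes:
                ks.set_params(ks.params.with_(**changes))
        if done % n_record == 0 or done == n_total:
            snap = lattice.counts()
            times.append(done * params.dt)
            counts.append(snap)
            if early_stop and _absorbed(snap, ks.params.u):
                stopped_early = True
                break
    series = TimeSeries(
        times=np.array(times),
        counts=np.vstack(counts),
        side=params.L,
        allowed_a=params.allowed_a,
    )
    return RunResult(series=series, lattice=lattice, stopped_early=stopped_early)


def concentrations(lattice: Lattice) -> dict[str, float]:
    """Occupancy fraction of every type present, plus vacancy.

    Fractions sum to 1 exactly (integer counts over L^2).
    """
    n = lattice.side * lattice.side
    counts = lattice.counts()
    out = {"vacant": counts[CODE_VACANT] / n}
    for code in np.nonzero(counts)[0]:
        if code != CODE_VACANT:
            out[code_label(int(code), lattice.allowed_a)] = counts[code] / n
    return out


# ----------------------------------------------------------------------
# snapshot I/O (plain text, round-trips bit-exactly)


def write_snapshot(
    path,
    lattice: Lattice,
    params: ModelParams,
    time: float = 0.0,
    seed: int | None = None,
) -> None:
    """Plain-text snapshot: key=value header then L rows of site codes."""
    header = {
        "L": lattice.side,
        "time": repr(float(time)),
        "seed": params.seed if seed is None else int(seed),
        "allowed_a": ",".join(repr(a) for a in lattice.allowed_a),
        "r1": repr(params.r1),
        "r2": repr(params.r2),
        "b": repr(params.b),
        "c": repr(params.c),
        "v": repr(params.v),
        "u": repr(params.u),
        "c_R": repr(params.c_R),
        "dt": repr(params.dt),
    }
    buf = io.StringIO()
    for key, value in header.items():
        buf.write(f"# {key}={value}\n")
    np.savetxt(buf, lattice.grid, fmt="%d")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_snapshot(path) -> tuple[Lattice, ModelParams, float]:
    """Read a snapshot written by :func:`write_snapshot`.

    Returns (lattice, params, time); the code array round-trips
    bit-exactly.
    """
    meta: dict[str, str] = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                key, _, value = line[1:].strip().partition("=")
                meta[key.strip()] = value
            elif line.strip():
                rows.append(np.array(line.split(), dtype=np.int8))
    allowed_a = tuple(float(x) for x in meta["allowed_a"].split(","))
    params = ModelParams(
        r1=float(meta["r1"]),
        r2=float(meta["r2"]),
        b=float(meta["b"]),
        c=float(meta["c"]),
        v=float(meta["v"]),
        u=float(meta["u"]),
        c_R=float(meta["c_R"]),
        dt=float(meta["dt"]),
        L=int(meta["L"]),
        allowed_a=allowed_a,
        seed=int(meta["seed"]),
    )
    lattice = Lattice(params.L, np.vstack(rows), allowed_a)
    return lattice, params, float(meta["time"])


# ----------------------------------------------------------------------
# rendering

#: role colours: vacant white, P red, N blue, S green, R violet
_PALETTE = {
    "vacant": (255, 255, 255),
    "P": (220, 40, 40),
    "N": (50, 80, 220),
    "S": (40, 170, 60),
    "R": (150, 60, 200),
}


def lattice_to_rgb(lattice: Lattice) -> np.ndarray:
    """L x L x 3 uint8 image of the lattice (one pixel per site).

    Producers are shaded from light to full red with increasing ``a``.
    """
    a_max = max([a for a in lattice.allowed_a if a > 0], default=1.0)
    lut = np.zeros((N_CODES, 3), dtype=np.uint8)
    lut[CODE_VACANT] = _PALETTE["vacant"]
    lut[CODE_S] = _PALETTE["S"]
    lut[CODE_R] = _PALETTE["R"]
    for k, a in enumerate(lattice.allowed_a):
        if a == 0:
            lut[1 + k] = _PALETTE["N"]
        else:
            w = 0.35 + 0.65 * (a / a_max)
            base = np.array(_PALETTE["P"], dtype=float)
            white = np.array([255.0, 255.0, 255.0])
            lut[1 + k] = (white * (1 - w) + base * w).astype(np.uint8)
    return lut[lattice.grid]
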