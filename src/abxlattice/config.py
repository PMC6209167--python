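"""Run configuration: TOML loading/saving with strict validation.

A config file has a ``[model]`` table (the :class:`ModelParams` fields),
a ``[run]`` table (experiment selector and run controls), an optional
``[[composition]]`` array of initial cell types, and an optional
``[[stages]]`` array of scheduled parameter changes.  Unknown keys are
rejected so typos fail loudly, and a config round-trips losslessly
through ``save_config``/``load_config``.
"""
from __future__ import annotations

import tomllib
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Any, Mapping, Sequence

from .core import CellState, ModelParams

__all__ = ["RunConfig", "load_config", "save_config"]

_MODEL_KEYS = {
    "r1", "r2", "b", "c", "v", "u", "c_R", "dt", "L", "allowed_a", "seed",
}
_RUN_KEYS = {
    "experiment", "t_end", "record_every", "global_dispersal", "outdir",
    "n_runs", "seed_base", "burn_in", "a", "c", "r_R_values", "a_values",
    "c_values", "mutation_rate",
}
_COMPOSITION_KEYS = {"type", "a", "fraction"}
_STAGE_KEYS = {"time", "u", "c_R", "sr_mutation"}


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration for one experiment invocation."""

    model: ModelParams
    experiment: str = "run"
    t_end: float = 2000.0
    record_every: float = 10.0
    global_dispersal: bool = False
    outdir: str = "out"
    options: dict[str, Any] = field(default_factory=dict)
    composition: tuple[tuple[CellState, float], ...] = ()
    stages: tuple[tuple[float, dict], ...] = ()

    def with_(self, **changes) -> "RunConfig":
        return replace(self, **changes)


def _reject_unknown(table: Mapping, allowed: set[str], where: str) -> None:
    unknown = set(table) - allowed
    if unknown:
        raise ValueError(
            f"unknown key(s) {sorted(unknown)} in [{where}]"
        )


def _parse_composition(entries: Sequence[Mapping]) -> tuple:
    comp = []
    for i, entry in enumerate(entries):
        _reject_unknown(entry, _COMPOSITION_KEYS, f"composition[{i}]")
        kind = entry.get("type")
        frac = float(entry.get("fraction", 0.0))
        if kind == "P":
            cell = CellState.producer(float(entry["a"]))
        elif kind == "N":
            cell = CellState.nonproducer()
        elif kind == "S":
            cell = CellState.sensitive()
        elif kind == "R":
            cell = CellState.resistant_cell()
        else:
            raise ValueError(
                f"composition[{i}].type must be one of P/N/S/R, got {kind!r}"
            )
        comp.append((cell, frac))
    return tuple(comp)


def _parse_stages(entries: Sequence[Mapping]) -> tuple:
    stages = []
    for i, entry in enumerate(entries):
        _reject_unknown(entry, _STAGE_KEYS, f"stages[{i}]")
        if "time" not in entry:
            raise ValueError(f"stages[{i}] is missing 'time'")
        changes = {k: v for k, v in entry.items() if k != "time"}
        stages.append((float(entry["time"]), changes))
    return tuple(stages)


def parse_config(data: Mapping) -> RunConfig:
    """Build a validated RunConfig from a parsed TOML mapping."""
    _reject_unknown(data, {"model", "run", "composition", "stages"}, "<root>")
    model_tbl = dict(data.get("model", {}))
    _reject_unknown(model_tbl, _MODEL_KEYS, "model")
    if "allowed_a" in model_tbl:
        model_tbl["allowed_a"] = tuple(float(x) for x in model_tbl["allowed_a"])
    try:
        model = ModelParams(**model_tbl)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid [model] table: {exc}") from exc
    run_tbl = dict(data.get("run", {}))
    _reject_unknown(run_tbl, _RUN_KEYS, "run")
    known = {
        "experiment": str(run_tbl.pop("experiment", "run")),
        "t_end": float(run_tbl.pop("t_end", 2000.0)),
        "record_every": float(run_tbl.pop("record_every", 10.0)),
        "global_dispersal": bool(run_tbl.pop("global_dispersal", False)),
        "outdir": str(run_tbl.pop("outdir", "out")),
    }
    return RunConfig(
        model=model,
        composition=_parse_composition(data.get("composition", [])),
        stages=_parse_stages(data.get("stages", [])),
        options=run_tbl,
        **known,
    )


def load_config(path) -> RunConfig:
    """Load and validate a TOML config file."""
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    return parse_config(data)


def _toml_value(value) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, (int, float)):
        return repr(value)
    if isinstance(value, str):
        return '"' + value.replace("\\", "\\\\").replace('"', '\\"') + '"'
    if isinstance(value, (list, tuple)):
        return "[" + ", ".join(_toml_value(v) for v in value) + "]"
    raise TypeError(f"cannot serialize {value!r}")


def save_config(config: RunConfig, path) -> None:
    """Write a RunConfig back to TOML (lossless round trip)."""
    lines = ["[model]"]
    model = asdict(config.model)
    model.pop("init_fractions", None)
    for key, value in model.items():
        lines.append(f"{key} = {_toml_value(value)}")
    lines += [
        "",
        "[run]",
        f'experiment = {_toml_value(config.experiment)}',
        f"t_end = {_toml_value(config.t_end)}",
        f"record_every = {_toml_value(config.record_every)}",
        f"global_dispersal = {_toml_value(config.global_dispersal)}",
        f"outdir = {_toml_value(config.outdir)}",
    ]
    for key, value in config.options.items():
        lines.append(f"{key} = {_toml_value(value)}")
    for cell, frac in config.composition:
        lines += ["", "[[composition]]"]
        label = cell.label()
        if label.startswith("P"):
            lines.append('type = "P"')
            lines.append(f"a = {_toml_value(cell.a)}")
        else:
            lines.append(f'type = {_toml_value(label)}')
        lines.append(f"fraction = {_toml_value(frac)}")
    for time, changes in config.stages:
        lines += ["", "[[stages]]", f"time = {_toml_value(time)}"]
        for key, value in changes.items():
            lines.append(f"{key} = {_toml_value(value)}")
    Path(path).write_text("\n".join(lines) + "\n")
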