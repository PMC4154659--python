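"""Flat INI-style run configuration.

Sections: [model] (rate constants and feedback parameters), [population]
(omega, group size), [engine] (method, error control, horizon, recording
grid, seed), [perturbation] (optional schedule) and [output].  Unknown
keys are rejected; every omitted key takes its documented default.
"""

from __future__ import annotations

import configparser
import dataclasses
import io
import json
from dataclasses import dataclass, field, fields

import numpy as np

from .coupling import NicheGrouping
from .engine import LeapControl, HSCSystem, make_grid, simulate, simulate_ssa
from .model import HSCParameters, calibrate_mpcr
from .perturbation import PerturbationSpec

__all__ = ["RunConfig", "load_config", "dump_config", "run_from_config"]

# configparser lowercases option names; map back to field names
_MODEL_FIELDS = {f.name.lower(): f.name for f in fields(HSCParameters)}
_MODEL_KEYS = set(_MODEL_FIELDS)
_ENGINE_KEYS = {
    "engine", "epsilon", "tau_min", "max_halvings",
    "t_end", "record_dt", "dense_window", "dense_dt", "seed",
}
_POP_KEYS = {"omega", "group_size"}
_PERT_KEYS = {
    "kind", "time", "even_fraction", "strong_fraction",
    "hit_probability", "target_species", "seed",
}
_OUT_KEYS = {"prefix", "record_signals"}


@dataclass(frozen=True)
class RunConfig:
    """A fully validated simulation configuration."""

    params: HSCParameters = field(default_factory=HSCParameters)
    omega: int = 1000
    group_size: int = 1
    t_end: float = 5000.0
    record_dt: float = 10.0
    dense_window: tuple[float, float] | None = None
    dense_dt: float | None = None
    engine: str = "tau-leap"
    epsilon: float = 0.03
    tau_min: float = 1e-6
    max_halvings: int = 30
    seed: int = 0
    perturbation: PerturbationSpec | None = None
    output_prefix: str | None = None
    record_signals: bool = True

    def __post_init__(self) -> None:
        problems = []
        if self.engine not in ("tau-leap", "ssa"):
            problems.append(f"engine must be 'tau-leap' or 'ssa', got {self.engine!r}")
        if self.omega < 1:
            problems.append("omega must be >= 1")
        if self.group_size < 1 or self.omega % self.group_size:
            problems.append(
                f"omega={self.omega} must be divisible by group_size={self.group_size}"
            )
        if self.engine == "ssa" and self.group_size != 1:
            problems.append("the exact SSA supports uncoupled lineages only (group_size 1)")
        if self.t_end <= 0:
            problems.append("t_end must be positive")
        if self.perturbation is not None and not (0 < self.perturbation.time < self.t_end):
            problems.append(
                f"perturbation time {self.perturbation.time} must lie inside (0, t_end={self.t_end})"
            )
        if problems:
            raise ValueError("invalid configuration:\n  " + "\n  ".join(problems))

    @property
    def grouping(self) -> NicheGrouping:
        return NicheGrouping(self.omega, self.group_size)

    @property
    def control(self) -> LeapControl:
        return LeapControl(
            epsilon=self.epsilon, tau_min=self.tau_min, max_halvings=self.max_halvings
        )

    @property
    def grid(self) -> np.ndarray:
        return make_grid(self.t_end, self.record_dt, self.dense_window, self.dense_dt)


def _collect_unknown(parser: configparser.ConfigParser) -> list[str]:
    known = {
        "model": _MODEL_KEYS,
        "engine": _ENGINE_KEYS,
        "population": _POP_KEYS,
        "perturbation": _PERT_KEYS,
        "output": _OUT_KEYS,
    }
    problems = []
    for section in parser.sections():
        if section not in known:
            problems.append(f"unknown section [{section}]")
            continue
        for key in parser[section]:
            if key not in known[section]:
                problems.append(f"unknown key {key!r} in section [{section}]")
    return problems


def load_config(path) -> RunConfig:
    """Parse and validate an INI config file; defaults fill omitted keys."""
    parser = configparser.ConfigParser(inline_comment_prefixes=("#", ";"))
    with open(path) as fh:
        parser.read_file(fh)
    problems = _collect_unknown(parser)
    if problems:
        raise ValueError("invalid configuration:\n  " + "\n  ".join(problems))

    kwargs = {}
    model_kwargs = {}
    if parser.has_section("model"):
        sec = parser["model"]
        for key in sec:
            name = _MODEL_FIELDS[key]
            if name == "h1_on_sdiff":
                model_kwargs[name] = sec.getboolean(key)
            elif name == "gamma" and sec[key].strip().lower() == "auto":
                pass  # resolved below from theta and rho
            else:
                model_kwargs[name] = sec.getfloat(key)
        if parser.has_option("model", "gamma") and sec["gamma"].strip().lower() == "auto":
            theta = model_kwargs.get("theta", HSCParameters.theta)
            rho = model_kwargs.get("rho", HSCParameters.rho)
            model_kwargs["gamma"] = calibrate_mpcr(theta, rho)
    kwargs["params"] = HSCParameters(**model_kwargs)

    if parser.has_section("population"):
        sec = parser["population"]
        if "omega" in sec:
            kwargs["omega"] = sec.getint("omega")
        if "group_size" in sec:
            kwargs["group_size"] = sec.getint("group_size")

    if parser.has_section("engine"):
        sec = parser["engine"]
        for key, conv in [
            ("engine", str), ("epsilon", float), ("tau_min", float),
            ("max_halvings", int), ("t_end", float), ("record_dt", float),
            ("dense_dt", float), ("seed", int),
        ]:
            if key in sec:
                kwargs[key] = conv(sec[key])
        if "dense_window" in sec:
            lo, hi = (float(v) for v in sec["dense_window"].split(":"))
            kwargs["dense_window"] = (lo, hi)

    if parser.has_section("perturbation"):
        sec = parser["perturbation"]
        pkw = {}
        for key, conv in [
            ("kind", str), ("time", float), ("even_fraction", float),
            ("strong_fraction", float), ("hit_probability", float),
            ("target_species", str), ("seed", int),
        ]:
            if key in sec:
                pkw[key] = conv(sec[key])
        kwargs["perturbation"] = PerturbationSpec(**pkw)

    if parser.has_section("output"):
        sec = parser["output"]
        if "prefix" in sec:
            kwargs["output_prefix"] = sec["prefix"]
        if "record_signals" in sec:
            kwargs["record_signals"] = sec.getboolean("record_signals")

    return RunConfig(**kwargs)


def dump_config(config: RunConfig) -> str:
    """Canonical INI text; ``load_config`` of the dump round-trips."""
    parser = configparser.ConfigParser()
    parser["model"] = {
        f.name: repr(getattr(config.params, f.name)) for f in fields(HSCParameters)
    }
    parser["population"] = {"omega": str(config.omega), "group_size": str(config.group_size)}
    engine_sec = {
        "engine": config.engine,
        "epsilon": repr(config.epsilon),
        "tau_min": repr(config.tau_min),
        "max_halvings": str(config.max_halvings),
        "t_end": repr(config.t_end),
        "record_dt": repr(config.record_dt),
        "seed": str(config.seed),
    }
    if config.dense_window is not None:
        engine_sec["dense_window"] = f"{config.dense_window[0]}:{config.dense_window[1]}"
        engine_sec["dense_dt"] = repr(config.dense_dt)
    parser["engine"] = engine_sec
    if config.perturbation is not None:
        p = config.perturbation
        sec = {
            "kind": p.kind,
            "time": repr(p.time),
            "even_fraction": repr(p.even_fraction),
            "strong_fraction": repr(p.strong_fraction),
            "hit_probability": repr(p.hit_probability),
            "target_species": p.target_species,
        }
        if p.seed is not None:
            sec["seed"] = str(p.seed)
        parser["perturbation"] = sec
    out = {"record_signals": str(config.record_signals)}
    if config.output_prefix is not None:
        out["prefix"] = config.output_prefix
    parser["output"] = out
    buf = io.StringIO()
    parser.write(buf)
    return buf.getvalue()


def run_from_config(config: RunConfig, seed: int | None = None):
    """Run one simulation described by a config; optionally write outputs.

    Returns the RunResult.  With an output prefix set, writes the tidy
    records CSV and a JSON sidecar carrying the full configuration,
    seed, tau summary, halving counts and removal reports, from which
    the run can be regenerated bit-identically.
    """
    seed = config.seed if seed is None else seed
    system = HSCSystem(config.params, config.grouping)
    initial = system.founding_state()
    if config.engine == "ssa":
        result = simulate_ssa(system, initial, config.grid, seed)
    else:
        perts = [config.perturbation] if config.perturbation is not None else []
        result = simulate(
            system,
            initial,
            config.grid,
            seed,
            control=config.control,
            perturbations=perts,
            record_signals=config.record_signals,
        )
    if config.output_prefix:
        write_outputs(result, config, config.output_prefix)
    return result


def write_outputs(result, config: RunConfig, prefix: str) -> None:
    result.to_dataframe().to_csv(f"{prefix}.csv", index=False)
    sidecar = {
        "config": dump_config(dataclasses.replace(config, seed=result.seed)),
        "seed": result.seed,
        "engine": result.engine,
        "n_steps": result.n_steps,
        "n_halvings": result.n_halvings,
        "tau_summary": {k: float(v) for k, v in result.tau_summary.items()},
        "removals": [
            {
                "kind": r.kind,
                "time": r.time,
                "target_species": r.target_species,
                "total_before": r.total_before,
                "total_removed": r.total_removed,
                "removed_fraction": r.removed_fraction,
                "n_affected": int(r.affected.sum()),
            }
            for r in result.removals
        ],
    }
    with open(f"{prefix}.json", "w") as fh:
        json.dump(sidecar, fh, indent=2)
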