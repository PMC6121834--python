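"""Run configuration: TOML parsing, validation and serialization.

A run is fully described by a ``RunConfig``. Defaults reproduce the
reference setting (lambda = sigma = beta = 1, quality on [0, 5]). A config
file may omit whole sections, in which case built-in defaults apply; a
section that *is* present must be complete, so that archived configs are
self-describing — a missing key raises an error naming the field.
"""

from __future__ import annotations

import dataclasses
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

from .model_core import ModelParams

__all__ = ["RunConfig", "load_config", "ConfigError"]


class ConfigError(ValueError):
    """Raised for malformed or incomplete run configurations."""


@dataclass(frozen=True)
class SolverSettings:
    num_points: int = 2001
    rtol: float = 1e-10
    atol: float = 1e-12


@dataclass(frozen=True)
class VerificationSettings:
    q_points: int = 200
    a_points: int = 2000
    tolerance: float = 1e-6
    n_perturbations: int = 100
    amplitude: float = 0.1
    seed: int = 20180524


@dataclass(frozen=True)
class DynamicsSettings:
    num_points: int = 401
    damping: float = 0.5
    max_iter: int = 500
    change_tol: float = 1e-6
    distance_tol: float = 1e-2
    init_kind: str = "cue"
    magnitude: float = 0.0
    seed: int = 0


@dataclass(frozen=True)
class SweepSettings:
    lambdas: tuple[float, ...] = (1.0,)
    sigmas: tuple[float, ...] = (1.0,)
    betas: tuple[float, ...] = (0.25, 0.5, 1.0, 2.0, 4.0)


@dataclass(frozen=True)
class FigureSettings:
    num: int = 501
    continuum_betas: tuple[float, ...] = (0.25, 0.5, 1.0, 2.0, 4.0)


@dataclass(frozen=True)
class RunConfig:
    params: ModelParams = field(default_factory=ModelParams)
    solver: SolverSettings = field(default_factory=SolverSettings)
    verification: VerificationSettings = field(default_factory=VerificationSettings)
    dynamics: DynamicsSettings = field(default_factory=DynamicsSettings)
    sweep: SweepSettings = field(default_factory=SweepSettings)
    figures: FigureSettings = field(default_factory=FigureSettings)
    output_dir: str = "signalgap_out"

    def to_dict(self) -> dict[str, Any]:
        return {
            "model": dataclasses.asdict(self.params),
            "solver": dataclasses.asdict(self.solver),
            "verification": dataclasses.asdict(self.verification),
            "dynamics": dataclasses.asdict(self.dynamics),
            "sweep": dataclasses.asdict(self.sweep),
            "figures": dataclasses.asdict(self.figures),
            "output": {"directory": self.output_dir},
        }

    def echo(self, out_dir: Path) -> None:
        """Write the exact resolved configuration into the output directory."""
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "config.json").write_text(
            json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n"
        )


_MODEL_FIELDS = ("lambda_pref", "sigma_cost", "beta_slope", "a_min", "q_min", "q_max")

_SECTION_TYPES = {
    "solver": SolverSettings,
    "verification": VerificationSettings,
    "dynamics": DynamicsSettings,
    "sweep": SweepSettings,
    "figures": FigureSettings,
}


def _build_section(name: str, cls, data: dict) -> Any:
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown key(s) in [{name}]: {sorted(unknown)}")
    for key, value in data.items():
        if isinstance(value, list):
            data[key] = tuple(value)
    return cls(**data)


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Build a RunConfig from an optional TOML file plus keyword overrides.

    Overrides use dotted keys flattened to ``section_field`` for
    non-model sections (e.g. ``solver_num_points``) and bare field names
    for model parameters (e.g. ``lambda_pref``); ``None`` values are
    ignored so CLI flags can be passed through directly.
    """
    raw: dict[str, Any] = {}
    if path is not None:
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
    unknown = set(raw) - set(_SECTION_TYPES) - {"model", "output"}
    if unknown:
        raise ConfigError(f"unknown section(s): {sorted(unknown)}")

    overrides = {k: v for k, v in overrides.items() if v is not None}

    model_raw = dict(raw.get("model", {}))
    if "model" in raw:
        missing = [f for f in _MODEL_FIELDS if f not in model_raw]
        if missing:
            raise ConfigError(
                f"[model] section is incomplete: missing {', '.join(missing)}"
            )
        extra = set(model_raw) - set(_MODEL_FIELDS)
        if extra:
            raise ConfigError(f"unknown key(s) in [model]: {sorted(extra)}")
    for name in _MODEL_FIELDS:
        if name in overrides:
            model_raw[name] = overrides.pop(name)
    try:
        params = ModelParams(**{k: float(v) for k, v in model_raw.items()})
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid model parameters: {exc}") from exc

    sections: dict[str, Any] = {}
    for name, cls in _SECTION_TYPES.items():
        data = dict(raw.get(name, {}))
        prefix = name + "_"
        for key in list(overrides):
            if key.startswith(prefix):
                data[key[len(prefix):]] = overrides.pop(key)
        sections[name] = _build_section(name, cls, data)

    output_dir = raw.get("output", {}).get("directory", "signalgap_out")
    output_dir = overrides.pop("output_dir", output_dir)
    if overrides:
        raise ConfigError(f"unknown override(s): {sorted(overrides)}")
    return RunConfig(params=params, output_dir=str(output_dir), **sections)
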