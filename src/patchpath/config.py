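"""Run configuration: YAML/JSON parsing, schema validation, defaults.

The default parameter set is the demonstration configuration the rest of
the package documents: interplanar distance d = 1 mm, maximum spatial step
S = 2.09 mm, repeatability eps = 0.05 mm, benchmark circle diameter
D = 20 mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Optional, Union

import yaml

from .kinematics import ArmModel
from .synthetic import PatchSpec


class ConfigError(ValueError):
    """Schema violation; the message names the offending key."""


_FIXTURE_KEYS = {
    "kind", "cap_diameter", "sphere_radius", "amplitude", "wavelength",
    "extent", "resolution", "seed", "jitter",
}
_ARM_KEYS = {"L1", "L2", "L3", "L4", "repeatability_eps"}
_BENCH_KEYS = {"N_list", "M", "mode", "center"}
_TOP_KEYS = {
    "input_stl", "fixture", "d", "max_step", "eps", "diameter", "arm",
    "benchmark", "output_dir", "log_level", "seed", "workspace_origin",
    "layers", "layer_offset",
}


@dataclass(frozen=True)
class RunConfig:
    d: float = 1.0
    max_step: float = 2.09
    eps: float = 0.05
    diameter: float = 20.0
    input_stl: Optional[str] = None
    fixture: PatchSpec = field(default_factory=PatchSpec)
    arm: ArmModel = field(default_factory=lambda: ArmModel(repeatability_eps=0.05))
    benchmark_N: tuple[int, ...] = (5, 10, 20, 30)
    benchmark_M: int = 200
    benchmark_mode: str = "cartesian_chord"
    benchmark_center: tuple[float, float, float] = (250.0, 0.0, 50.0)
    workspace_origin: tuple[float, float, float] = (250.0, -10.0, 50.0)
    layers: int = 1
    layer_offset: Optional[float] = None
    output_dir: str = "patchpath_run"
    log_level: str = "INFO"
    seed: int = 0


def _reject_unknown(section: dict, allowed: set, where: str) -> None:
    for key in section:
        if key not in allowed:
            raise ConfigError(f"unknown key {key!r} in {where}")


def validate_config(source: Union[str, Path, dict, None]) -> RunConfig:
    """Parse and validate a YAML/JSON config file (or dict).

    An empty file yields the full default parameter set.  Unknown keys are
    rejected by name; numeric parameters must be positive.
    """
    if source is None:
        raw: dict[str, Any] = {}
    elif isinstance(source, dict):
        raw = dict(source)
    else:
        text = Path(source).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError("config root must be a mapping")
        raw = loaded

    _reject_unknown(raw, _TOP_KEYS, "config")

    kwargs: dict[str, Any] = {}
    for key in ("d", "max_step", "eps", "diameter"):
        if key in raw:
            value = float(raw[key])
            if value <= 0:
                raise ConfigError(f"{key} must be positive, got {value}")
            kwargs[key] = value
    if "input_stl" in raw:
        kwargs["input_stl"] = str(raw["input_stl"])
    if "fixture" in raw:
        section = raw["fixture"] or {}
        _reject_unknown(section, _FIXTURE_KEYS, "fixture")
        if "extent" in section:
            section["extent"] = tuple(float(v) for v in section["extent"])
        kwargs["fixture"] = PatchSpec(**section)
    if "arm" in raw:
        section = raw["arm"] or {}
        _reject_unknown(section, _ARM_KEYS, "arm")
        kwargs["arm"] = ArmModel(**{k: float(v) for k, v in section.items()})
    if "benchmark" in raw:
        section = raw["benchmark"] or {}
        _reject_unknown(section, _BENCH_KEYS, "benchmark")
        if "N_list" in section:
            kwargs["benchmark_N"] = tuple(int(n) for n in section["N_list"])
        if "M" in section:
            kwargs["benchmark_M"] = int(section["M"])
        if "mode" in section:
            if section["mode"] not in ("cartesian_chord", "joint_linear"):
                raise ConfigError(f"unknown benchmark mode {section['mode']!r}")
            kwargs["benchmark_mode"] = section["mode"]
        if "center" in section:
            kwargs["benchmark_center"] = tuple(float(v) for v in section["center"])
    if "workspace_origin" in raw:
        kwargs["workspace_origin"] = tuple(float(v) for v in raw["workspace_origin"])
    if "layers" in raw:
        kwargs["layers"] = int(raw["layers"])
    if "layer_offset" in raw and raw["layer_offset"] is not None:
        kwargs["layer_offset"] = float(raw["layer_offset"])
    if "output_dir" in raw:
        kwargs["output_dir"] = str(raw["output_dir"])
    if "log_level" in raw:
        kwargs["log_level"] = str(raw["log_level"])
    if "seed" in raw:
        kwargs["seed"] = int(raw["seed"])
    return RunConfig(**kwargs)
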