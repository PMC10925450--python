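"""Run configuration: YAML/JSON loading with validated defaults."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .parameters import SCENARIOS, DistributionSpec, ModelParameters

__all__ = ["RunConfig", "load_config", "save_config", "DEFAULT_CONFIG_PATH"]

DEFAULT_CONFIG_PATH = Path(__file__).parent / "data" / "default_config.yaml"

_PARAM_FIELDS = {f.name for f in dataclasses.fields(ModelParameters)}
_DIST_FIELDS = ("or_misuse_given_anxiety", "anxiety_prev_post_fire")


@dataclass(frozen=True)
class RunConfig:
    """Validated run settings: model parameters plus output options."""

    parameters: ModelParameters = field(default_factory=ModelParameters)
    output_directory: Path = Path("results")
    export_draws: bool = True
    density_bins: int = 100
    scenarios: tuple[str, ...] = SCENARIOS

    def __post_init__(self) -> None:
        if not self.scenarios:
            raise ValueError("scenarios must be non-empty")
        unknown = set(self.scenarios) - set(SCENARIOS)
        if unknown:
            raise ValueError(f"unknown scenarios: {sorted(unknown)}")
        if self.density_bins < 1:
            raise ValueError("density_bins must be >= 1")


def _dist_from_mapping(name: str, value) -> DistributionSpec:
    if isinstance(value, DistributionSpec):
        return value
    if not isinstance(value, dict):
        raise ValueError(f"{name}: expected a mapping with a 'family' key, got {value!r}")
    try:
        return DistributionSpec(**value)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{name}: {exc}") from exc


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML or JSON run configuration.

    Omitted keys take the published defaults (the shipped
    ``default_config.yaml`` spells them all out).  Validation errors name
    the offending field.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    text = path.read_text()
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"config root must be a mapping, got {type(raw).__name__}")

    param_kwargs = {}
    run_kwargs = {}
    for key, value in raw.items():
        if key in _PARAM_FIELDS:
            if key in _DIST_FIELDS:
                value = _dist_from_mapping(key, value)
            param_kwargs[key] = value
        elif key == "output_directory":
            run_kwargs[key] = Path(value)
        elif key == "scenarios":
            run_kwargs[key] = tuple(value)
        elif key in ("export_draws", "density_bins"):
            run_kwargs[key] = value
        else:
            raise ValueError(f"unknown config key: {key!r}")
    try:
        parameters = ModelParameters(**param_kwargs)
    except ValueError as exc:
        raise ValueError(f"invalid parameter configuration: {exc}") from exc
    return RunConfig(parameters=parameters, **run_kwargs)


def save_config(config: RunConfig, path: str | Path) -> None:
    """Write a config that :func:`load_config` reloads to an equal RunConfig."""
    p = config.parameters
    payload = {
        **{
            f: getattr(p, f)
            for f in _PARAM_FIELDS
            if f not in _DIST_FIELDS
        },
        **{f: dataclasses.asdict(getattr(p, f)) for f in _DIST_FIELDS},
        "output_directory": str(config.output_directory),
        "export_draws": config.export_draws,
        "density_bins": config.density_bins,
        "scenarios": list(config.scenarios),
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))
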