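"""Configuration files and tabular output.

Configs are flat YAML or JSON mappings keyed by the model-parameter names.
At this boundary the values use the units a reader of the parameter table
would write down (conductivities in S/m, permittivities in As/Vm, radii in
micrometres, membrane thicknesses in nanometres, B0 in tesla, frequency in
kilohertz, coil-axis offset in millimetres); everything is converted to SI
on the way in.  Unknown keys are rejected, value errors name the offending
key, and CSV is the canonical tabular format (JSON mirrors it).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .model import MagneticStimulus, TwoShellCell, build_cell, build_stimulus
from .scenarios import SweepResult, SurfaceMap, remove_cell_membrane, remove_organelle

__all__ = [
    "ConfigError",
    "RunConfig",
    "BOUNDARY_UNITS",
    "SCENARIOS",
    "default_config",
    "read_config",
    "write_config",
    "write_sweep",
    "read_sweep",
    "write_map",
]

#: key -> (human-facing unit label, factor converting that unit to SI)
BOUNDARY_UNITS: dict[str, tuple[str, float]] = {
    "sigma_0": ("S/m", 1.0),
    "sigma_1": ("S/m", 1.0),
    "sigma_2": ("S/m", 1.0),
    "sigma_3": ("S/m", 1.0),
    "sigma_4": ("S/m", 1.0),
    "epsilon_0": ("As/Vm", 1.0),
    "epsilon_1": ("As/Vm", 1.0),
    "epsilon_2": ("As/Vm", 1.0),
    "epsilon_3": ("As/Vm", 1.0),
    "epsilon_4": ("As/Vm", 1.0),
    "R": ("um", 1e-6),
    "D": ("nm", 1e-9),
    "r": ("um", 1e-6),
    "d": ("nm", 1e-9),
    "B0": ("T", 1.0),
    "f": ("kHz", 1e3),
    "C": ("mm", 1e-3),
}

SCENARIOS = ("intact", "no-cell-membrane", "no-organelle")


class ConfigError(ValueError):
    """A configuration problem, carrying the offending key when known."""

    def __init__(self, message: str, key: str | None = None):
        super().__init__(message)
        self.key = key


@dataclass
class RunConfig:
    """A resolved run configuration.

    ``values`` holds the 17 model parameters in *boundary* units (exactly as
    written in the config file, defaults filled in), so a written config
    round-trips bit-identically.  SI conversion happens in
    :meth:`to_parameters`.
    """

    values: dict[str, float] = field(default_factory=dict)
    scenario: str = "intact"

    def __post_init__(self) -> None:
        defaults = _default_values()
        unknown = set(self.values) - set(defaults)
        if unknown:
            key = sorted(unknown)[0]
            raise ConfigError(f"unknown configuration key {key!r}", key=key)
        merged = {**defaults, **self.values}
        for key, value in merged.items():
            if isinstance(value, bool) or not isinstance(value, (int, float)):
                raise ConfigError(
                    f"configuration key {key!r} must be a number, got {value!r}",
                    key=key,
                )
        self.values = merged
        if self.scenario not in SCENARIOS:
            raise ConfigError(
                f"unknown scenario {self.scenario!r}; expected one of {SCENARIOS}"
            )
        self._validate()

    def _validate(self) -> None:
        for key in ("sigma_0", "sigma_1", "sigma_2", "sigma_3", "sigma_4", "B0", "f", "C"):
            if self.values[key] < 0:
                raise ConfigError(f"{key} must be >= 0, got {self.values[key]!r}", key=key)
        for key in ("epsilon_0", "epsilon_1", "epsilon_2", "epsilon_3", "epsilon_4",
                    "R", "D", "r", "d"):
            if self.values[key] <= 0:
                raise ConfigError(f"{key} must be > 0, got {self.values[key]!r}", key=key)
        try:
            self.to_cell()
        except ValueError as exc:
            raise ConfigError(f"invalid geometry: {exc}") from exc

    def to_parameters(self) -> dict[str, float]:
        """The parameter set in SI units."""
        return {
            key: float(value) * BOUNDARY_UNITS[key][1]
            for key, value in self.values.items()
        }

    def to_cell(self) -> TwoShellCell:
        cell = build_cell(self.to_parameters())
        if self.scenario == "no-cell-membrane":
            return remove_cell_membrane(cell)
        if self.scenario == "no-organelle":
            return remove_organelle(cell)
        return cell

    def to_stimulus(self) -> MagneticStimulus:
        return build_stimulus(self.to_parameters())


# Standard values expressed directly in boundary units (floating-point
# division of the SI table values would smear the round decimals).
_DEFAULT_BOUNDARY: dict[str, float] = {
    "sigma_0": 1.2, "sigma_1": 3e-7, "sigma_2": 0.3, "sigma_3": 3e-7, "sigma_4": 0.3,
    "epsilon_0": 6.4e-10, "epsilon_1": 4.4e-11, "epsilon_2": 6.4e-10,
    "epsilon_3": 4.4e-11, "epsilon_4": 6.4e-10,
    "R": 10.0, "D": 5.0, "r": 3.0, "d": 5.0,
    "B0": 2.0, "f": 10.0, "C": 10.0,
}


def _default_values() -> dict[str, float]:
    return dict(_DEFAULT_BOUNDARY)


def default_config() -> RunConfig:
    """Standard parameter set, intact cell."""
    return RunConfig(values=_default_values())


def read_config(path) -> RunConfig:
    """Read a YAML or JSON config file (YAML is a superset of JSON here).

    Keys not present fall back to the standard values; unknown keys and
    out-of-range values raise :class:`ConfigError` naming the key.
    """
    text = Path(path).read_text()
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"malformed configuration file {path}: {exc}") from exc
    if doc is None:
        doc = {}
    if not isinstance(doc, dict):
        raise ConfigError(f"configuration root must be a mapping, got {type(doc).__name__}")
    scenario = doc.pop("scenario", "intact")
    return RunConfig(values=doc, scenario=scenario)


def write_config(config: RunConfig, path) -> None:
    """Write a config so that ``read_config(write_config(x)) == x``."""
    doc = dict(config.values)
    if config.scenario != "intact":
        doc["scenario"] = config.scenario
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def write_sweep(result: SweepResult, path) -> None:
    """Write a sweep table; format chosen by extension (.csv or .json)."""
    path = Path(path)
    if path.suffix == ".json":
        result.to_json(path)
    else:
        result.to_csv(path)


def read_sweep(path) -> SweepResult:
    return SweepResult.from_csv(path)


def write_map(surface: SurfaceMap, path) -> None:
    path = Path(path)
    if path.suffix == ".json":
        surface.to_json(path)
    else:
        surface.to_csv(path)
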