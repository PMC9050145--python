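"""YAML configuration loading with strict schema validation.

A config file holds up to five sections -- ``periphery``, ``neuropathy``,
``circuit``, ``sbc``, ``gbc``, ``mso`` -- whose keys are exactly the field
names of the corresponding dataclasses.  Missing keys take the package
defaults (the model's parameter-table values); unknown sections or keys are
rejected with a message naming every offender.  Every override is logged at
INFO level.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import yaml

from .network import CircuitConfig
from .neurons import BushyCellParams, GBC_PARAMS, MSOCellParams, SBC_PARAMS
from .periphery import NeuropathyConfig, PeripheryParams

logger = logging.getLogger("socsim")


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    """Fully resolved configuration of one simulation run."""

    periphery: PeripheryParams = field(default_factory=PeripheryParams)
    neuropathy: NeuropathyConfig = field(default_factory=NeuropathyConfig)
    circuit: CircuitConfig = field(default_factory=CircuitConfig)

    def resolved_circuit(self) -> CircuitConfig:
        return replace(self.circuit, periphery=self.periphery)


_SECTIONS = {
    "periphery": PeripheryParams,
    "neuropathy": NeuropathyConfig,
    "circuit": CircuitConfig,
    "sbc": BushyCellParams,
    "gbc": BushyCellParams,
    "mso": MSOCellParams,
}
# circuit fields that are themselves dataclasses are set via their own sections
_CIRCUIT_EXCLUDED = {"periphery", "sbc_params", "gbc_params", "mso_params"}


def _build_section(cls, data: dict, section: str, errors: list, base=None):
    allowed = {f.name for f in fields(cls)}
    if section == "circuit":
        allowed -= _CIRCUIT_EXCLUDED
    unknown = set(data) - allowed
    for k in sorted(unknown):
        errors.append(f"unknown key '{section}.{k}'")
    kwargs = {k: v for k, v in data.items() if k in allowed}
    if not kwargs and base is not None:
        return base
    for k, v in kwargs.items():
        logger.info("config override: %s.%s = %r", section, k, v)
    try:
        if base is not None:
            return replace(base, **kwargs)
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        errors.append(f"invalid value in section '{section}': {exc}")
        return base if base is not None else cls()


def load_config(path) -> SimulationConfig:
    """Load and validate a YAML config file; empty file = full defaults."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    errors: list = []
    unknown_sections = set(raw) - set(_SECTIONS)
    for s in sorted(unknown_sections):
        errors.append(f"unknown section '{s}'")
    periphery = _build_section(PeripheryParams, raw.get("periphery", {}), "periphery", errors)
    neuropathy = _build_section(NeuropathyConfig, raw.get("neuropathy", {}), "neuropathy", errors)
    sbc = _build_section(BushyCellParams, raw.get("sbc", {}), "sbc", errors, base=SBC_PARAMS)
    gbc = _build_section(BushyCellParams, raw.get("gbc", {}), "gbc", errors, base=GBC_PARAMS)
    mso = _build_section(MSOCellParams, raw.get("mso", {}), "mso", errors, base=MSOCellParams())
    circuit = _build_section(CircuitConfig, raw.get("circuit", {}), "circuit", errors)
    if errors:
        raise ConfigError("; ".join(errors))
    circuit = dataclasses.replace(
        circuit, periphery=periphery, sbc_params=sbc, gbc_params=gbc, mso_params=mso
    )
    return SimulationConfig(periphery=periphery, neuropathy=neuropathy, circuit=circuit)


def default_parameter_file() -> Path:
    """Path of the shipped, versioned parameter file (cell + periphery)."""
    return Path(__file__).parent / "data" / "default_params.yaml"
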