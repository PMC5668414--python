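"""Run configuration: a flat, sectioned, human-editable YAML schema.

Sections mirror the module layout.  Unknown keys (typos) are errors, never
silently defaulted; a config round-trips through serialization losslessly;
every pipeline run echoes its effective config, seed and package version
into the output directory.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .mc import MCSchedule
from .model import EnergyParams
from .units import UnitSystem

__all__ = ["RunConfig"]

_SCHEMA = {
    "units": {"sigma_nm"},
    "sequence_design": {"chain_length", "tau", "f_charged", "taus"},
    "rpm_model": {
        "bjerrum_length",
        "bond_k",
        "bond_r0",
        "angle_k",
        "angle_theta0",
        "ewald_tolerance",
        "bead_radius",
    },
    "mc_engine": {
        "n_equil_sweeps",
        "n_prod_sweeps",
        "sample_interval",
        "move_mix",
        "max_bead_displacement",
        "max_chain_displacement",
    },
    "system": {"box_length", "c_P_mM", "c_S_mM"},
    "analysis": {"r_C", "r_CC", "bin_width", "n_widom", "mu", "n_seeds",
                 "census_sweeps"},
    "output": {"directory"},
}
_TOP_KEYS = set(_SCHEMA) | {"seed"}


@dataclass
class RunConfig:
    """Validated, serializable settings for one pipeline run."""

    seed: int = 0
    units: dict = field(default_factory=dict)
    sequence_design: dict = field(default_factory=dict)
    rpm_model: dict = field(default_factory=dict)
    mc_engine: dict = field(default_factory=dict)
    system: dict = field(default_factory=dict)
    analysis: dict = field(default_factory=dict)
    output: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for section, keys in _SCHEMA.items():
            payload = getattr(self, section)
            unknown = set(payload) - keys
            if unknown:
                raise ValueError(
                    f"unknown key(s) {sorted(unknown)} in config section "
                    f"[{section}]; allowed: {sorted(keys)}"
                )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - _TOP_KEYS
        if unknown:
            raise ValueError(
                f"unknown top-level config section(s) {sorted(unknown)}; "
                f"allowed: {sorted(_TOP_KEYS)}"
            )
        return cls(
            seed=int(raw.get("seed", 0)),
            **{k: dict(raw.get(k, {}) or {}) for k in _SCHEMA},
        )

    def to_yaml(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.as_dict(), sort_keys=True, default_flow_style=False)
        )

    def as_dict(self) -> dict:
        d = {"seed": self.seed}
        for k in _SCHEMA:
            d[k] = dict(getattr(self, k))
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.as_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]

    # -- concrete objects -------------------------------------------------

    def unit_system(self) -> UnitSystem:
        return UnitSystem(**self.units)

    def energy_params(self) -> EnergyParams:
        kw = {k: v for k, v in self.rpm_model.items() if k != "bead_radius"}
        return EnergyParams(**kw)

    @property
    def bead_radius(self) -> float:
        return float(self.rpm_model.get("bead_radius", 0.5))

    def schedule(self, seed_offset: int = 0) -> MCSchedule:
        kw = dict(self.mc_engine)
        if "move_mix" in kw:
            kw["move_mix"] = tuple(kw["move_mix"])
        return MCSchedule(seed=self.seed + seed_offset, **kw)
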