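"""Run configuration: YAML schema, validation, and provenance stamps.

A :class:`RunConfig` fully determines a run: model, conductance scaling,
protocol block (0D pacing or tissue geometry + S1S2), solver settings and
output paths.  Unknown keys are rejected and every violation is reported
at once, so a config file either round-trips exactly or fails loudly.
The provenance stamp (package version + SHA-256 of the canonical JSON
form) is written into run logs and output tables.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .currents import ConductanceScaling, CurrentID

__all__ = ["RunConfig", "ConfigError", "load_config"]

SCHEMA_VERSION = 1


class ConfigError(ValueError):
    """Config validation failure; ``errors`` lists every violation."""

    def __init__(self, errors: list[str]):
        super().__init__("invalid configuration:\n  - " + "\n  - ".join(errors))
        self.errors = errors


_PROTOCOL_0D_KEYS = {"bcl_ms", "n_beats", "stim_amplitude", "stim_duration_ms",
                     "record_last_n", "solver"}
_TISSUE_KEYS = {"nx", "ny", "dx_cm", "diffusion", "dt_ms", "s1s2_interval_ms",
                "duration_ms", "frame_stride_ms", "stim_amplitude"}
_SOLVER_KEYS = {"rtol", "atol", "dt_ms"}


@dataclass
class RunConfig:
    model: str = "courtemanche"
    scaling: dict = field(default_factory=dict)      # CurrentID -> multiplier
    protocol_0d: dict = field(default_factory=dict)
    tissue: dict = field(default_factory=dict)
    solver: dict = field(default_factory=dict)
    output_dir: str = "results"
    schema_version: int = SCHEMA_VERSION

    def validate(self) -> None:
        errors: list[str] = []
        from .models import MODEL_NAMES

        if self.model not in MODEL_NAMES:
            errors.append(f"model: unknown {self.model!r} (one of {MODEL_NAMES})")
        for key, val in self.scaling.items():
            try:
                CurrentID(key)
            except ValueError:
                errors.append(f"scaling: unknown current {key!r}")
                continue
            try:
                ok = float(val) >= 0
            except (TypeError, ValueError):
                ok = False
            if not ok:
                errors.append(f"scaling[{key}]: multiplier must be a number >= 0")
        for name, block, allowed in (("protocol_0d", self.protocol_0d,
                                      _PROTOCOL_0D_KEYS),
                                     ("tissue", self.tissue, _TISSUE_KEYS),
                                     ("solver", self.solver, _SOLVER_KEYS)):
            for key in block:
                if key not in allowed:
                    errors.append(f"{name}: unknown key {key!r} "
                                  f"(allowed: {sorted(allowed)})")
        bcl = self.protocol_0d.get("bcl_ms")
        dur = self.protocol_0d.get("stim_duration_ms", 2.0)
        if bcl is not None and not bcl > dur > 0:
            errors.append("protocol_0d: need bcl_ms > stim_duration_ms > 0")
        if self.protocol_0d.get("n_beats", 1) < 1:
            errors.append("protocol_0d: n_beats must be >= 1")
        for key in ("nx", "ny"):
            if key in self.tissue and self.tissue[key] < 3:
                errors.append(f"tissue: {key} must be >= 3")
        if self.schema_version != SCHEMA_VERSION:
            errors.append(f"schema_version: expected {SCHEMA_VERSION}")
        if errors:
            raise ConfigError(errors)

    # ------------------------------------------------------------------
    def conductance_scaling(self) -> ConductanceScaling:
        return ConductanceScaling(self.scaling)

    def canonical_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, separators=(",", ":"))

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()[:16]

    def provenance(self) -> dict:
        from . import __version__

        return {"package_version": __version__,
                "config_hash": self.config_hash,
                "schema_version": self.schema_version}

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(yaml.safe_dump(asdict(self), sort_keys=True))
        return path


def load_config(path_or_dict, overrides: dict | None = None) -> RunConfig:
    """Load and validate a config from a YAML file or a dict.

    ``overrides`` (flag values) take precedence over file values; unknown
    top-level keys are rejected with the full list of violations.
    """
    if isinstance(path_or_dict, (str, Path)):
        raw = yaml.safe_load(Path(path_or_dict).read_text()) or {}
    else:
        raw = dict(path_or_dict or {})
    errors = []
    allowed = set(RunConfig.__dataclass_fields__)
    for key in raw:
        if key not in allowed:
            errors.append(f"unknown top-level key {key!r} "
                          f"(allowed: {sorted(allowed)})")
    if errors:
        raise ConfigError(errors)
    for key, val in (overrides or {}).items():
        if val is None:
            continue
        if key in ("scaling", "protocol_0d", "tissue", "solver"):
            raw.setdefault(key, {}).update(val)
        else:
            raw[key] = val
    cfg = RunConfig(**raw)
    cfg.validate()
    return cfg
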