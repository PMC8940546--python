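"""Run configuration: one YAML file per run, CLI flags take precedence."""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

import yaml

from kneemech.errors import ValidationError


@dataclass(frozen=True)
class RunConfig:
    """Validated settings for a simulation run."""

    scenario: str = "intact"
    fixation_flexion_deg: float = 0.0
    graft_pretension_N: float = 0.0
    protocol: str = "anterior"               # anterior | rotation
    flexion_angles_deg: tuple = (0.0, 30.0, 60.0, 90.0)
    use_default_pretension: bool = True      # take pretension from the fitted defaults
    solver_tol_force_N: float = 1e-6
    solver_tol_torque_Nmm: float = 1e-6
    seed: int = 0
    verbosity: int = 1

    def __post_init__(self):
        if self.scenario not in ("intact", "deficient", "anatomic"):
            raise ValidationError(f"unknown scenario {self.scenario!r}")
        if self.protocol not in ("anterior", "rotation"):
            raise ValidationError(f"unknown protocol {self.protocol!r}")

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def load_config(path=None, **overrides) -> RunConfig:
    """Build a RunConfig from an optional YAML file plus overrides.

    Unknown keys are rejected with their field path; None-valued overrides
    are ignored so CLI flags only apply when given.
    """
    values = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValidationError(f"config {path} must be a mapping")
        values.update(loaded)
    values.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in fields(RunConfig)}
    unknown = set(values) - known
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    if "flexion_angles_deg" in values:
        values["flexion_angles_deg"] = tuple(float(a) for a in values["flexion_angles_deg"])
    return RunConfig(**values)
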