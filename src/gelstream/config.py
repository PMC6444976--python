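"""Run configuration: validated, serializable experiment descriptions.

All physical quantities carry unit-suffixed key names (``E1_V_per_cm``,
``injection_band_width_um``, ...) so a config file cannot silently mix
units.  Unknown keys are rejected; every materialized default is recorded
so a run can be reproduced from its manifest alone.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .deflection import FieldProtocol
from .mobility import FragmentSpec, MobilityModel, synthetic_mobility_model
from .simulate import ChamberSpec


class ConfigError(ValueError):
    """Schema violation, reported with the offending field path."""


_PROTOCOL_KEYS = {"E1_V_per_cm", "E2_V_per_cm", "theta1_deg", "theta2_deg", "f_Hz", "duty"}
_CHAMBER_KEYS = {"width_cm", "height_cm", "injection_y_cm", "injection_band_width_um"}
_FRAGMENT_KEYS = {"length_bp", "label"}
_MOBILITY_KEYS = {"mode", "table_csv", "mu0", "beta", "gamma", "kuhn_bp", "extrapolate"}
_SIM_KEYS = {"n_particles", "seed", "diffusion_cm2_per_s"}
_TOP_KEYS = {"protocol", "fragments", "chamber", "mobility", "simulation"}

_SIM_DEFAULTS = {"n_particles": 2000, "diffusion_cm2_per_s": 0.0}


def _check_keys(blob: dict, allowed: set, path: str) -> None:
    unknown = set(blob) - allowed
    if unknown:
        raise ConfigError(f"{path}: unknown key(s) {sorted(unknown)}")


@dataclass
class RunConfig:
    protocol: FieldProtocol
    fragments: list[FragmentSpec]
    chamber: ChamberSpec
    mobility_spec: dict
    simulation: dict
    defaults_applied: list[str] = field(default_factory=list)

    def mobility_model(self, base_dir: Path | None = None) -> MobilityModel:
        spec = self.mobility_spec
        mode = spec["mode"]
        if mode == "synthetic":
            return synthetic_mobility_model(extrapolate=spec.get("extrapolate", False))
        if mode == "table":
            path = Path(spec["table_csv"])
            if base_dir is not None and not path.is_absolute():
                path = base_dir / path
            return MobilityModel.from_csv(path, extrapolate=spec.get("extrapolate", False))
        return MobilityModel(
            "parametric",
            mu0=spec["mu0"], beta=spec["beta"], gamma=spec["gamma"],
            kuhn_bp=spec.get("kuhn_bp", 300.0),
        )

    def to_dict(self) -> dict:
        p = self.protocol
        c = self.chamber
        return {
            "protocol": {
                "E1_V_per_cm": p.E1_V_per_cm, "E2_V_per_cm": p.E2_V_per_cm,
                "theta1_deg": p.theta1_deg, "theta2_deg": p.theta2_deg,
                "f_Hz": p.f_Hz, "duty": p.duty,
            },
            "fragments": [
                {"length_bp": f.length_bp, "label": f.label} for f in self.fragments
            ],
            "chamber": {
                "width_cm": c.width_cm, "height_cm": c.height_cm,
                "injection_y_cm": c.injection_y_cm,
                "injection_band_width_um": c.injection_band_width_um,
            },
            "mobility": copy.deepcopy(self.mobility_spec),
            "simulation": copy.deepcopy(self.simulation),
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def parse_config(blob: dict) -> RunConfig:
    """Validate a config mapping and materialize defaults."""
    if not isinstance(blob, dict):
        raise ConfigError("top level: expected a mapping")
    _check_keys(blob, _TOP_KEYS, "top level")
    applied: list[str] = []

    if "protocol" not in blob:
        raise ConfigError("protocol: required section missing")
    pr = dict(blob["protocol"])
    _check_keys(pr, _PROTOCOL_KEYS, "protocol")
    for key in ("E1_V_per_cm", "E2_V_per_cm", "theta1_deg", "theta2_deg", "f_Hz"):
        if key not in pr:
            raise ConfigError(f"protocol.{key}: required field missing")
    if "duty" not in pr:
        pr["duty"] = 0.5
        applied.append("protocol.duty=0.5")
    try:
        protocol = FieldProtocol(**pr)
    except ValueError as exc:
        raise ConfigError(f"protocol: {exc}") from exc

    frags_blob = blob.get("fragments")
    if not frags_blob:
        raise ConfigError("fragments: at least one fragment required")
    fragments = []
    for i, fb in enumerate(frags_blob):
        fb = dict(fb)
        _check_keys(fb, _FRAGMENT_KEYS, f"fragments[{i}]")
        if "length_bp" not in fb:
            raise ConfigError(f"fragments[{i}].length_bp: required field missing")
        try:
            fragments.append(FragmentSpec(int(fb["length_bp"]), fb.get("label", "")))
        except ValueError as exc:
            raise ConfigError(f"fragments[{i}]: {exc}") from exc

    ch = dict(blob.get("chamber", {}))
    _check_keys(ch, _CHAMBER_KEYS, "chamber")
    for key, default in (
        ("width_cm", 1.0), ("height_cm", 1.0),
        ("injection_y_cm", 0.0), ("injection_band_width_um", 110.0),
    ):
        if key not in ch:
            ch[key] = default
            applied.append(f"chamber.{key}={default}")
    try:
        chamber = ChamberSpec(**ch)
    except ValueError as exc:
        raise ConfigError(f"chamber: {exc}") from exc

    mob = dict(blob.get("mobility", {"mode": "synthetic"}))
    if "mobility" not in blob:
        applied.append("mobility.mode=synthetic")
    _check_keys(mob, _MOBILITY_KEYS, "mobility")
    mode = mob.get("mode")
    if mode not in ("synthetic", "table", "parametric"):
        raise ConfigError(f"mobility.mode: expected synthetic|table|parametric, got {mode!r}")
    if mode == "table" and "table_csv" not in mob:
        raise ConfigError("mobility.table_csv: required for table mode")
    if mode == "parametric":
        for key in ("mu0", "beta", "gamma"):
            if key not in mob:
                raise ConfigError(f"mobility.{key}: required for parametric mode")

    sim = dict(blob.get("simulation", {}))
    _check_keys(sim, _SIM_KEYS, "simulation")
    for key, default in _SIM_DEFAULTS.items():
        if key not in sim:
            sim[key] = default
            applied.append(f"simulation.{key}={default}")
    if "seed" not in sim:
        raise ConfigError("simulation.seed: a seed is mandatory for stochastic runs")
    sim["seed"] = int(sim["seed"])
    sim["n_particles"] = int(sim["n_particles"])

    return RunConfig(protocol, fragments, chamber, mob, sim, defaults_applied=applied)


def load_config(path) -> RunConfig:
    """Load and validate a YAML (or JSON; YAML is a superset) config file."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path) as fh:
        blob = yaml.safe_load(fh)
    return parse_config(blob)
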