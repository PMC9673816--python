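"""Configuration loading/validation and run manifests.

Configuration is nested YAML mirroring the model parameter tables: optical
properties per medium (cm^-1), sensor design dimensions (mm), kinetic and
transport parameters (SI), and experiment protocols.  Unspecified keys fall
back to the package defaults (the published parameter tables); every
defaulted key is recorded so a run manifest can state exactly which values
were assumptions.  Units are carried in key names (``*_per_cm``,
``*_mol_per_m3``, ...) to prevent silent unit drift between the optical
(cm^-1) and chemical (SI) halves of the package.
"""

from __future__ import annotations

import difflib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .geometry import NEEDLE_ID_17G_TW
from .kinetics import KineticParams, SternVolmerParams
from .optics import OpticalProperties, default_optical_properties
from .rd_solver import TransportParams

__all__ = ["ConfigError", "Config", "RunManifest", "default_config", "load_config", "save_config"]


class ConfigError(ValueError):
    """Unknown key or invariant violation in a configuration file."""


def default_config() -> dict:
    """Full default configuration (the published parameter tables)."""
    opt = {}
    for name, p in default_optical_properties().items():
        opt[name] = {
            "mua_ex_per_cm": p.mua[0],
            "mua_em_per_cm": p.mua[1],
            "mus_ex_per_cm": p.mus[0],
            "mus_em_per_cm": p.mus[1],
            "g": p.g,
            "n": p.n,
            "quantum_yield": p.quantum_yield,
        }
    return {
        "scene": {
            "extent_mm": [17.0, 17.0, 4.0],
            "voxel_mm": 0.05,
            "layer_depths_mm": [0.1, 1.6],
        },
        "optics": {
            "media": opt,
            "led_side_mm": 1.75,
            "excitation_nm": 680.0,
            "emission_nm": 800.0,
        },
        "designs": {
            "needle_inner_diameter_mm": NEEDLE_ID_17G_TW,
            "design1": {"kind": "rect_barcode", "length_mm": 6.5, "width_mm": 0.7,
                        "height_mm": 0.9, "unit_thickness_mm": 3.25},
            "design2": {"kind": "stacked_cylinder", "length_mm": 6.5,
                        "diameter_mm": NEEDLE_ID_17G_TW, "unit_thickness_mm": 0.65},
            "design3": {"kind": "longitudinal_rods", "length_mm": 6.5,
                        "rod_diameter_mm": NEEDLE_ID_17G_TW / (1 + 2**0.5), "n_rods": 4},
        },
        "kinetics": {
            "k1": 100.0, "k_1": 0.003, "k2": 300.0, "k3": 1000.0,
            "k_3": 150.0, "k4": 50.0, "Et_mol_per_m3": 0.1463,
        },
        "stern_volmer": {"tau0_us": 201.0, "ksv": 0.023, "o2_unit": "uM"},
        "transport": {
            "DG_S_m2_per_s": 2.64e-10, "DO2_S_m2_per_s": 1.5e-9,
            "DG_Assay1_m2_per_s": 4.0e-10, "DO2_Assay1_m2_per_s": 2.45e-9,
        },
        "flowcell": {
            "ICG_mol_per_m3": 2.78, "ICO2_mol_per_m3": 0.009,
            "inlet_velocity_m_per_s": 0.009,
            "channel_mm": [7.6, 2.8], "sensor_mm": [4.0, 0.5],
            "fillet_radius_mm": 0.1, "dx_mm": 0.05, "dt_s": 1.0,
            "protocol_mol_per_m3": [0.0, 2.78, 5.55, 8.34, 11.1],
            "hold_min": 45.0,
        },
        "interstitial": {
            "RG_mol_per_m3_s": 0.027, "RO2_mol_per_m3_s": 1.04e-5,
            "Pw_mol_per_m3": 2.78, "CO2_mol_per_m3": 0.009,
            "height_mm": 1.0, "domain_thickness_mm": 0.36,
            "standoff_mm": 0.05, "end_cap_mm": 0.05,
            "spacer_sweep_mm": [0.01, 1.0], "capillary_ends": True,
        },
        "mc": {"n_photons": 1_000_000, "n_emission": 1_000_000, "repeats": 3, "seed": 0},
    }


def _merge(defaults: dict, user: dict, path: str, defaulted: list, errors: list) -> dict:
    out = {}
    for key, dval in defaults.items():
        here = f"{path}.{key}" if path else key
        if key not in user:
            out[key] = dval
            defaulted.append(here)
        elif isinstance(dval, dict):
            if not isinstance(user[key], dict):
                errors.append(f"{here}: expected a mapping")
            else:
                out[key] = _merge(dval, user[key], here, defaulted, errors)
        else:
            out[key] = user[key]
    for key in user:
        if key not in defaults:
            here = f"{path}.{key}" if path else key
            close = difflib.get_close_matches(key, list(defaults), n=1)
            hint = f" (did you mean {close[0]!r}?)" if close else ""
            errors.append(f"unknown key {here!r}{hint}")
    return out


def _validate(cfg: dict, errors: list) -> None:
    for name, m in cfg["optics"]["media"].items():
        try:
            OpticalProperties(
                mua=(m["mua_ex_per_cm"], m["mua_em_per_cm"]),
                mus=(m["mus_ex_per_cm"], m["mus_em_per_cm"]),
                g=m["g"], n=m["n"], quantum_yield=m["quantum_yield"],
            )
        except ValueError as e:
            errors.append(f"optics.media.{name}: {e}")
    k = cfg["kinetics"]
    try:
        KineticParams(k1=k["k1"], km1=k["k_1"], k2=k["k2"], k3=k["k3"],
                      km3=k["k_3"], k4=k["k4"], Et=k["Et_mol_per_m3"])
    except ValueError as e:
        errors.append(f"kinetics: {e}")
    sv = cfg["stern_volmer"]
    try:
        SternVolmerParams(tau0=sv["tau0_us"], ksv=sv["ksv"], o2_unit=sv["o2_unit"])
    except ValueError as e:
        errors.append(f"stern_volmer: {e}")
    t = cfg["transport"]
    try:
        TransportParams(
            DG=(t["DG_S_m2_per_s"],) + (t["DG_Assay1_m2_per_s"],) * 3 + (t["DG_S_m2_per_s"],),
            DO2=(t["DO2_S_m2_per_s"],) + (t["DO2_Assay1_m2_per_s"],) * 3 + (t["DO2_S_m2_per_s"],),
        )
    except ValueError as e:
        errors.append(f"transport: {e}")
    d1, d2 = cfg["scene"]["layer_depths_mm"]
    if not 0 < d1 < d2 < cfg["scene"]["extent_mm"][2]:
        errors.append("scene.layer_depths_mm must be strictly increasing within the domain")


@dataclass
class Config:
    """Validated full configuration plus provenance of defaulted keys."""

    raw: dict
    defaulted: list = field(default_factory=list)
    source: str | None = None

    # -- typed accessors -------------------------------------------------
    def optical_properties(self) -> dict:
        out = {}
        for name, m in self.raw["optics"]["media"].items():
            out[name] = OpticalProperties(
                mua=(m["mua_ex_per_cm"], m["mua_em_per_cm"]),
                mus=(m["mus_ex_per_cm"], m["mus_em_per_cm"]),
                g=m["g"], n=m["n"], quantum_yield=m["quantum_yield"],
            )
        return out

    def kinetic_params(self) -> KineticParams:
        k = self.raw["kinetics"]
        return KineticParams(k1=k["k1"], km1=k["k_1"], k2=k["k2"], k3=k["k3"],
                             km3=k["k_3"], k4=k["k4"], Et=k["Et_mol_per_m3"])

    def stern_volmer(self) -> SternVolmerParams:
        sv = self.raw["stern_volmer"]
        return SternVolmerParams(tau0=sv["tau0_us"], ksv=sv["ksv"], o2_unit=sv["o2_unit"])

    def transport_params(self) -> TransportParams:
        t = self.raw["transport"]
        return TransportParams(
            DG=(t["DG_S_m2_per_s"],) + (t["DG_Assay1_m2_per_s"],) * 3 + (t["DG_S_m2_per_s"],),
            DO2=(t["DO2_S_m2_per_s"],) + (t["DO2_Assay1_m2_per_s"],) * 3 + (t["DO2_S_m2_per_s"],),
        )


def load_config(path=None, overrides: dict | None = None) -> Config:
    """Load, merge with defaults, and validate a YAML configuration.

    ``path=None`` returns the pure default configuration.  Unknown keys and
    invariant violations raise :class:`ConfigError` listing every problem
    (with nearest-key suggestions).
    """
    user = {}
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(user, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
    if overrides:
        user = _deep_update(user, overrides)
    defaulted, errors = [], []
    cfg = _merge(default_config(), user, "", defaulted, errors)
    if not errors:
        _validate(cfg, errors)
    if errors:
        raise ConfigError("; ".join(errors))
    return Config(raw=cfg, defaulted=defaulted, source=str(path) if path else None)


def _deep_update(base: dict, extra: dict) -> dict:
    out = dict(base)
    for k, v in extra.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_update(out[k], v)
        else:
            out[k] = v
    return out


def save_config(cfg: Config, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.raw, sort_keys=False))


@dataclass
class RunManifest:
    """Append-only provenance record for a set of result files."""

    config: dict
    seed: int
    stages: list = field(default_factory=list)
    version: str = __version__
    created: str = field(default_factory=lambda: time.strftime("%Y-%m-%dT%H:%M:%S"))

    def add_stage(self, name: str, inputs: dict, outputs: list, wall_s: float) -> None:
        self.stages.append(
            {"stage": name, "inputs": inputs, "outputs": list(map(str, outputs)),
             "wall_s": round(wall_s, 3)}
        )

    def append_to(self, path) -> None:
        path = Path(path)
        with path.open("a") as f:
            f.write(json.dumps(self.__dict__, default=str) + "\n")
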