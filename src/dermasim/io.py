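"""Config parsing with unit-suffixed keys, the tidy-CSV dataset dialect, and
run manifests.

One CSV dialect serves simulator output, the fixture generator and
calibration input alike: columns ``group, replicate, time_h, q_ug_per_cm2``
for the time series, plus optional terminal-layer rows carrying
``layer, amount_ug, mass_mg`` with an empty time field.
"""

from __future__ import annotations

import hashlib
import json
import platform
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import DomainError
from .metrics import ExperimentDataset
from .presets import default_config

__version__ = "0.1.0"


class ConfigError(DomainError):
    pass


#: user-facing key -> (resolved SI key, multiplicative factor)
KEY_REGISTRY: dict[str, tuple[str, float]] = {
    "vehicle_thickness_cm": ("vehicle_thickness", 1e-2),
    "initial_mass_ug": ("initial_drug_mass", 1e-9),
    "vehicle_cells": ("vehicle_cells", 1),
    "vehicle_grid_ratio": ("vehicle_grid_ratio", 1),
    "diff_vehicle_m2_s": ("diff_vehicle", 1.0),
    "droplet_size_um": ("droplet_diameter", 1e-6),
    "particle_size_um": ("particle_diameter", 1e-6),
    "kp_cont_disp": ("kp_cont_disp", 1.0),
    "dispersed_volume_fraction": ("dispersed_volume_fraction", 1.0),
    "solubility_mg_ml": ("solubility", 1.0),          # mg/mL == kg/m^3
    "particle_density_kg_m3": ("particle_density", 1.0),
    "shrinking_particles": ("shrinking_particles", 1),
    "kp_vehicle_receptor": ("kp_vehicle_receptor", 1.0),
    "diffusion_area_cm2": ("diffusion_area", 1e-4),
    "receptor_volume_ml": ("receptor_volume", 1e-6),
    "duration_h": ("duration", 3600.0),
    "sampling_times_h": ("sampling_times", 3600.0),
    "sample_volume_ul": ("sample_volume", 1e-9),
    "replacement_concentration_ug_ml": ("replacement_concentration", 1e-3),
    "sampling_mode": ("sampling_mode", 1),
    "membrane_thickness_um": ("membrane_thickness", 1e-6),
    "membrane_porosity": ("membrane_porosity", 1.0),
    "membrane_free_diffusivity_m2_s": ("membrane_free_diffusivity", 1.0),
    "membrane_cells": ("membrane_cells", 1),
    "sc_thickness_um": ("sc_thickness", 1e-6),
    "corneocyte_diameter_um": ("corneocyte_diameter", 1e-6),
    "corneocyte_thickness_um": ("corneocyte_thickness", 1e-6),
    "lipid_thickness_um": ("lipid_thickness", 1e-6),
    "ve_thickness_um": ("ve_thickness", 1e-6),
    "dermis_thickness_mm": ("dermis_thickness", 1e-3),
    "specimen_thickness_um": ("specimen_thickness", 1e-6),
    "brick_offset": ("brick_offset", 1.0),
    "channel_width_um": ("channel_width", 1e-6),
    "sc_lateral_subcells": ("sc_lateral_subcells", 1),
    "ve_cells": ("ve_cells", 1),
    "dermis_cells": ("dermis_cells", 1),
    "skin_grid_ratio": ("skin_grid_ratio", 1),
    "kp_lipid_vehicle": ("kp_lipid_vehicle", 1.0),
    "perm_lc_horizontal_m_s": ("perm_lc_horizontal", 1.0),
    "perm_lc_vertical_m_s": ("perm_lc_vertical", 1.0),
    "diff_ve_m2_s": ("diff_ve", 1.0),
    "diff_dermis_m2_s": ("diff_dermis", 1.0),
    "perm_dermis_receptor_m_s": ("perm_dermis_receptor", 1.0),
    "diff_lipid_m2_s": ("diff_lipid", 1.0),
    "diff_corneocyte_m2_s": ("diff_corneocyte", 1.0),
    "kp_cor_lipid": ("kp_cor_lipid", 1.0),
    "kp_ve_lipid": ("kp_ve_lipid", 1.0),
    "kp_dm_ve": ("kp_dm_ve", 1.0),
    "kp_receptor_dm": ("kp_receptor_dm", 1.0),
    "rtol": ("rtol", 1),
    "atol": ("atol", 1),
}

_NONNEGATIVE_OK = {"replacement_concentration", "specimen_thickness"}
_PASSTHROUGH = {"sampling_mode", "shrinking_particles", "rtol", "atol",
                "vehicle_grid_ratio", "skin_grid_ratio"}


def resolve_user_keys(entries: dict) -> dict:
    """Convert unit-suffixed user keys to resolved SI config overrides."""
    out = {}
    for key, raw in entries.items():
        if key not in KEY_REGISTRY:
            raise ConfigError(f"unknown config key {key!r}")
        si_key, factor = KEY_REGISTRY[key]
        if si_key in _PASSTHROUGH or isinstance(raw, (bool, str)):
            out[si_key] = raw
            continue
        if isinstance(raw, (list, tuple)):
            vals = [float(v) * factor for v in raw]
            if any(not np.isfinite(v) or v < 0 for v in vals):
                raise ConfigError(f"{key}: values must be finite and >= 0")
            out[si_key] = tuple(vals)
            continue
        value = float(raw) * factor
        if not np.isfinite(value):
            raise ConfigError(f"{key}: value must be finite")
        if value <= 0 and si_key not in _NONNEGATIVE_OK:
            raise ConfigError(f"{key}: physical quantity must be positive, "
                              f"got {raw!r}")
        if si_key in ("vehicle_cells", "membrane_cells", "ve_cells",
                      "dermis_cells", "sc_lateral_subcells"):
            out[si_key] = int(round(value))
        else:
            out[si_key] = value
    return out


def load_config(path: str | Path) -> dict:
    """Read a YAML config into a fully resolved SI configuration.

    Recognised structural keys: ``mode``, ``vehicle`` (preset name) and
    ``skin_params`` (preset name); every other key must appear in the
    unit-suffixed registry.  Unknown keys are rejected by name.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("config must be a flat key/value mapping")
    mode = raw.pop("mode", "ivpt")
    vehicle = raw.pop("vehicle", "cream")
    skin_params = raw.pop("skin_params", None)
    vehicle_kind = raw.pop("vehicle_kind", None)   # structural; dump_config emits it
    overrides = resolve_user_keys(raw)
    if vehicle_kind is not None:
        overrides["vehicle_kind"] = vehicle_kind
    return default_config(mode=mode, vehicle=vehicle, skin_params=skin_params,
                          **overrides)


def dump_config(cfg: dict, path: str | Path) -> None:
    """Write a resolved config back as unit-suffixed YAML (round-trips)."""
    inverse = {si: (user, factor) for user, (si, factor) in KEY_REGISTRY.items()}
    out = {"mode": cfg["mode"]}
    for si_key, value in cfg.items():
        if si_key in ("mode",) or value is None:
            continue
        if si_key not in inverse:
            out[si_key] = value
            continue
        user, factor = inverse[si_key]
        if si_key in _PASSTHROUGH or isinstance(value, (bool, str)):
            out[user] = value
        elif isinstance(value, (list, tuple)):
            out[user] = [float(v) / factor for v in value]
        elif isinstance(value, int) and factor == 1:
            out[user] = value
        else:
            out[user] = float(value) / factor
    Path(path).write_text(yaml.safe_dump(out, sort_keys=True))


# ---------------------------------------------------------------------------
# tidy CSV datasets
# ---------------------------------------------------------------------------

_COLUMNS = ["group", "replicate", "time_h", "q_ug_per_cm2",
            "layer", "amount_ug", "mass_mg"]


def write_dataset(dataset: ExperimentDataset, path) -> None:
    rows = []
    for rid in sorted(dataset.replicates):
        for t, q in zip(dataset.times_h, dataset.replicates[rid]):
            rows.append((dataset.group, rid, t, q, "", "", ""))
        for layer, amount in sorted(dataset.layer_amounts.get(rid, {}).items()):
            mass = dataset.layer_masses.get(rid, {}).get(layer, "")
            rows.append((dataset.group, rid, "", "", layer, amount, mass))
    df = pd.DataFrame(rows, columns=_COLUMNS)
    df.to_csv(path, index=False)


def read_dataset(path_or_buf) -> ExperimentDataset:
    """Parse the tidy CSV dialect; malformed rows are reported by line."""
    df = pd.read_csv(path_or_buf, dtype={"replicate": str, "layer": str})
    missing = [c for c in _COLUMNS[:4] if c not in df.columns]
    if missing:
        raise DomainError(f"dataset is missing columns {missing}")
    groups = df["group"].dropna().unique()
    if len(groups) != 1:
        raise DomainError(f"dataset must contain exactly one group, found "
                          f"{list(groups)}")
    has_layer = "layer" in df.columns
    series = df[df["time_h"].notna()] if has_layer else df
    if has_layer:
        series = series[series["layer"].isna() | (series["layer"] == "")]

    replicates: dict[str, np.ndarray] = {}
    times_ref: np.ndarray | None = None
    for rid, sub in series.groupby("replicate", sort=True):
        sub = sub.sort_values("time_h")
        t = sub["time_h"].to_numpy(dtype=float)
        q = sub["q_ug_per_cm2"].to_numpy(dtype=float)
        bad = np.nonzero(~np.isfinite(q) | (q < 0))[0]
        if len(bad):
            line = int(sub.index[bad[0]]) + 2  # header + 1-based
            raise DomainError(f"negative or non-numeric amount at line {line}")
        if np.any(np.diff(t) <= 0):
            raise DomainError(f"replicate {rid!r}: times not strictly increasing")
        if times_ref is None:
            times_ref = t
        elif not np.allclose(times_ref, t):
            raise DomainError(f"replicate {rid!r} uses a different time grid")
        replicates[str(rid)] = q
    if not replicates:
        raise DomainError("dataset contains no time-series rows")

    layer_amounts: dict[str, dict[str, float]] = {}
    layer_masses: dict[str, dict[str, float]] = {}
    if has_layer:
        lrows = df[df["layer"].notna() & (df["layer"] != "")]
        for _, row in lrows.iterrows():
            rid, layer = str(row["replicate"]), str(row["layer"])
            amount = float(row["amount_ug"])
            if amount < 0:
                raise DomainError(f"negative layer amount at line {int(row.name) + 2}")
            layer_amounts.setdefault(rid, {})[layer] = amount
            if pd.notna(row.get("mass_mg", np.nan)) and row.get("mass_mg") != "":
                layer_masses.setdefault(rid, {})[layer] = float(row["mass_mg"])
    return ExperimentDataset(group=str(groups[0]), times_h=times_ref,
                             replicates=replicates,
                             layer_amounts=layer_amounts,
                             layer_masses=layer_masses)


# ---------------------------------------------------------------------------
# run manifests
# ---------------------------------------------------------------------------

@dataclass
class RunManifest:
    """Reproducibility record emitted once per CLI run."""
    command: str
    config: dict
    seeds: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)     # path -> sha256
    outputs: list = field(default_factory=list)
    wall_time_s: float = 0.0
    version: str = __version__
    platform: str = field(default_factory=platform.platform)

    def write(self, path: str | Path) -> None:
        payload = {"tool": "dermasim", "version": self.version,
                   "command": self.command,
                   "config": _jsonable(self.config), "seeds": self.seeds,
                   "inputs": self.inputs, "outputs": self.outputs,
                   "wall_time_s": round(self.wall_time_s, 3),
                   "platform": self.platform}
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def file_digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


class Stopwatch:
    def __enter__(self):
        self.t0 = time.perf_counter()
        return self

    def __exit__(self, *exc):
        self.elapsed = time.perf_counter() - self.t0
        return False
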