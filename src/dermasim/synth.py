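"""Seeded synthetic Franz-cell datasets.

No raw replicate data accompany the reference study, so calibration and the
replicate statistics are exercised against generated datasets: the simulator
is run as ground truth, cumulative permeation is read off at the sampling
schedule, and each replicate receives i.i.d. multiplicative lognormal noise
(median-unbiased) per time point, mimicking error bars that grow with the
mean.  IVPT datasets also carry noisy terminal layer depositions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import units
from .core import DomainError
from .franz import run_ivpt, run_ivrt
from .metrics import ExperimentDataset, cumulative_per_area
from .presets import apply_overrides, build_experiment, default_config

FIXTURE_SEEDS = {"cream-ivrt": 101, "ointment-ivrt": 102,
                 "cream-ivpt": 103, "ointment-ivpt": 104}


@dataclass(frozen=True)
class NoiseModel:
    """Replicate noise: multiplicative lognormal with coefficient of
    variation ``replicate_cv``; the default replicate counts follow the
    reference protocols (n = 6 for IVRT, n = 5 for IVPT)."""
    replicate_cv: float = 0.15
    n_replicates: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicate_cv < 0:
            raise DomainError("replicate_cv must be >= 0")
        if self.n_replicates < 1:
            raise DomainError("need at least one replicate")

    @property
    def sigma(self) -> float:
        return float(np.sqrt(np.log1p(self.replicate_cv ** 2)))


def generate_dataset(config: dict, noise: NoiseModel,
                     truth_overrides: dict | None = None,
                     group: str | None = None) -> ExperimentDataset:
    """Simulate ground truth and wrap it in noisy replicates.

    ``config`` is a resolved experiment config (see :mod:`dermasim.presets`);
    ``truth_overrides`` are calibration-style parameter overrides applied to
    it before simulation.  The truth parameters and seed are recorded in the
    dataset metadata.
    """
    cfg = apply_overrides(config, truth_overrides or {})
    exp = build_experiment(cfg)
    run = run_ivpt if cfg["mode"] == "ivpt" else run_ivrt
    result = run(exp)
    t_s = np.asarray(cfg["sampling_times"])
    q = cumulative_per_area(result, cfg["diffusion_area"])
    # post-event rows share the event time; take the cumulative value there
    # (continuous through the event by construction)
    idx = [np.nonzero(np.isclose(result.times, t))[0][-1] for t in t_s]
    q_true = q[idx]

    rng = np.random.default_rng(noise.seed)
    sigma = noise.sigma
    reps = {}
    for r in range(noise.n_replicates):
        factors = np.exp(sigma * rng.standard_normal(len(t_s))) if sigma > 0 \
            else np.ones(len(t_s))
        reps[f"rep{r + 1}"] = q_true * factors

    layer_amounts: dict[str, dict[str, float]] = {}
    layer_masses: dict[str, dict[str, float]] = {}
    if cfg["mode"] == "ivpt":
        g = exp.stack.geometry
        area = cfg["diffusion_area"]
        truth_layers = {
            "epidermis": units.kg_to_ug(result.layer_amount("epidermis")[-1]),
            "dermis": units.kg_to_ug(result.layer_amount("dermis")[-1]),
        }
        masses = {
            "epidermis": area * (g.sc_thickness + g.ve_thickness) * 1000.0 / units.MG,
            "dermis": area * g.dermis_thickness * 1000.0 / units.MG,
        }
        for rid in reps:
            f = np.exp(sigma * rng.standard_normal(2)) if sigma > 0 else np.ones(2)
            layer_amounts[rid] = {"epidermis": truth_layers["epidermis"] * f[0],
                                  "dermis": truth_layers["dermis"] * f[1]}
            layer_masses[rid] = dict(masses)

    return ExperimentDataset(
        group=group or f"{cfg['vehicle_kind']}-{cfg['mode']}",
        times_h=t_s / units.HOUR,
        replicates=reps,
        layer_amounts=layer_amounts,
        layer_masses=layer_masses,
        meta={"seed": noise.seed, "replicate_cv": noise.replicate_cv,
              "truth_overrides": dict(truth_overrides or {}),
              "mode": cfg["mode"], "vehicle_kind": cfg["vehicle_kind"],
              "noiseless_profile": q_true.tolist()})


def make_paper_fixtures(write_dir: str | Path | None = None
                        ) -> dict[str, ExperimentDataset]:
    """The four canned datasets (cream/ointment x IVRT/IVPT) generated from
    the study presets with documented seeds; optionally written as CSVs plus
    a manifest recording the generating parameters."""
    from .io import write_dataset  # local import to avoid a cycle

    bundle: dict[str, ExperimentDataset] = {}
    for name, seed in FIXTURE_SEEDS.items():
        vehicle, mode = name.split("-")
        n = 5 if mode == "ivpt" else 6
        cfg = default_config(mode, vehicle)
        ds = generate_dataset(cfg, NoiseModel(replicate_cv=0.15,
                                              n_replicates=n, seed=seed),
                              group=name)
        bundle[name] = ds
    if write_dir is not None:
        out = Path(write_dir)
        out.mkdir(parents=True, exist_ok=True)
        manifest = {}
        for name, ds in bundle.items():
            write_dataset(ds, out / f"{name}.csv")
            manifest[name] = {"seed": FIXTURE_SEEDS[name],
                              "replicate_cv": ds.meta["replicate_cv"],
                              "n_replicates": ds.n_replicates,
                              "mode": ds.meta["mode"],
                              "vehicle_kind": ds.meta["vehicle_kind"]}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return bundle


def load_shipped_fixtures() -> dict[str, ExperimentDataset]:
    """Read the fixture bundle shipped inside the package."""
    from importlib.resources import files

    from .io import read_dataset

    root = files("dermasim").joinpath("data/fixtures")
    out = {}
    for name in FIXTURE_SEEDS:
        with (root / f"{name}.csv").open("r") as fh:  # type: ignore[attr-defined]
            out[name] = read_dataset(fh)
    return out
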