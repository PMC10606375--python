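"""Two-stage mechanistic calibration.

Stage 1 (release) fits donor-vehicle / membrane parameters to IVRT data;
stage 2 (skin) fixes the release parameters and fits the five skin transport
parameters to IVPT data.  Splitting the fit keeps each stage low-dimensional
and anchored to the data that actually constrains it.

The objective is the RMSE between the simulated cumulative-permeation-per-
area profile and the replicate-mean observed profile at the data's time
points (optionally pooled over replicates, optionally augmented with terminal
layer-deposition residuals in stage 2).  Minimisation is bounded
Nelder-Mead with log-scaled transport parameters and optional seeded
multi-start; given a seed the whole procedure, including its iteration log,
is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from . import units
from .core import DomainError
from .franz import run_ivpt, run_ivrt
from .metrics import ExperimentDataset, cumulative_per_area, layer_accumulation
from .presets import apply_overrides, build_experiment

RELEASE_PARAMS = {"diff_vehicle", "kp_cont_disp", "kp_vehicle_receptor",
                  "droplet_diameter", "particle_diameter", "solubility",
                  "dispersed_volume_fraction", "membrane_porosity",
                  "membrane_free_diffusivity"}
SKIN_PARAMS = {"kp_lipid_vehicle", "perm_lc_horizontal", "perm_lc_vertical",
               "diff_ve_dm", "diff_ve", "diff_dermis", "perm_dermis_receptor"}

#: the five free skin parameters of the reference calibration
DEFAULT_SKIN_FREE = ("kp_lipid_vehicle", "perm_lc_horizontal",
                     "perm_lc_vertical", "diff_ve_dm", "perm_dermis_receptor")


@dataclass(frozen=True)
class FreeParameter:
    initial: float
    lower: float
    upper: float
    scale: str = "log"          # "log" | "linear"

    def __post_init__(self) -> None:
        if not (self.lower <= self.initial <= self.upper):
            raise DomainError("bounds must bracket the initial value")
        if self.scale not in ("log", "linear"):
            raise DomainError("scale must be 'log' or 'linear'")
        if self.scale == "log" and self.lower <= 0:
            raise DomainError("log-scaled parameters need positive bounds")

    def to_x(self, value: float) -> float:
        return float(np.log10(value)) if self.scale == "log" else float(value)

    def from_x(self, x: float) -> float:
        return float(10.0 ** x) if self.scale == "log" else float(x)


@dataclass
class CalibrationSpec:
    stage: str                                   # "release" | "skin"
    free: dict[str, FreeParameter]
    fixed: dict[str, float] = field(default_factory=dict)
    objective: str = "rmse"                      # "rmse" | "sse"
    weighting: str = "mean-profile"              # "mean-profile" | "pooled"
    seed: int = 0
    restarts: int = 0
    maxiter: int = 400
    layer_weight: float = 0.0                    # stage-2 deposition weight
    compute_sensitivity: bool = True

    def __post_init__(self) -> None:
        if self.stage not in ("release", "skin"):
            raise DomainError("stage must be 'release' or 'skin'")
        allowed = RELEASE_PARAMS if self.stage == "release" else SKIN_PARAMS
        bad = set(self.free) - allowed
        if bad:
            raise DomainError(f"parameters not calibratable in stage "
                              f"{self.stage!r}: {sorted(bad)}")
        if self.objective not in ("rmse", "sse"):
            raise DomainError("objective must be 'rmse' or 'sse'")
        if self.weighting not in ("mean-profile", "pooled"):
            raise DomainError("weighting must be 'mean-profile' or 'pooled'")


@dataclass
class CalibrationResult:
    estimates: dict[str, float]
    objective_value: float
    objective_trace: list[float]                 # best-so-far per evaluation
    converged: bool
    log: list[dict]                              # per-evaluation record
    residuals: np.ndarray                        # at the optimum
    sensitivity: dict[str, float]
    n_evaluations: int
    spec: CalibrationSpec


class _Evaluator:
    def __init__(self, spec: CalibrationSpec, data: ExperimentDataset,
                 template_cfg: dict):
        cfg = apply_overrides(dict(template_cfg), spec.fixed)
        cfg["sampling_times"] = tuple(np.asarray(data.times_h) * units.HOUR)
        cfg["duration"] = max(cfg["duration"], cfg["sampling_times"][-1])
        self.cfg = cfg
        self.spec = spec
        self.data = data
        self.names = list(spec.free)
        self.log: list[dict] = []
        self.trace: list[float] = []
        self._target = (data.mean_profile() if spec.weighting == "mean-profile"
                        else data.matrix())

    def params_from_x(self, x: np.ndarray) -> dict[str, float]:
        return {n: self.spec.free[n].from_x(xi) for n, xi in zip(self.names, x)}

    def simulate(self, params: dict[str, float]):
        cfg = apply_overrides(self.cfg, params)
        exp = build_experiment(cfg)
        run = run_ivpt if cfg["mode"] == "ivpt" else run_ivrt
        result = run(exp)
        q = cumulative_per_area(result, cfg["diffusion_area"])
        idx = [np.nonzero(np.isclose(result.times, t))[0][-1]
               for t in cfg["sampling_times"]]
        return q[idx], result

    def residuals(self, params: dict[str, float]) -> np.ndarray:
        q_sim, result = self.simulate(params)
        if self.spec.weighting == "mean-profile":
            res = q_sim - self._target
        else:
            res = (q_sim[None, :] - self._target).ravel()
        if self.spec.layer_weight > 0 and self.data.layer_amounts:
            res = np.concatenate([res, self._layer_residuals(result)])
        return res

    def _layer_residuals(self, result) -> np.ndarray:
        out = []
        for layer in ("epidermis", "dermis"):
            obs = [self.data.layer_amounts[r][layer] / self.data.layer_masses[r][layer]
                   for r in self.data.layer_amounts
                   if layer in self.data.layer_amounts[r]]
            if obs:
                sim = layer_accumulation(result, layer)
                out.append(self.spec.layer_weight * (sim - float(np.mean(obs))))
        return np.asarray(out)

    def __call__(self, x: np.ndarray) -> float:
        params = self.params_from_x(x)
        try:
            res = self.residuals(params)
            value = (float(np.sqrt(np.mean(res ** 2)))
                     if self.spec.objective == "rmse"
                     else float(np.sum(res ** 2)))
        except Exception as exc:
            raise RuntimeError(
                f"objective not evaluable at {params}: {exc}") from exc
        best = min(value, self.trace[-1]) if self.trace else value
        self.trace.append(best)
        self.log.append({"evaluation": len(self.log) + 1,
                         "params": params, "objective": value})
        return value


def _calibrate(spec: CalibrationSpec, data: ExperimentDataset,
               template_cfg: dict) -> CalibrationResult:
    ev = _Evaluator(spec, data, template_cfg)
    if not spec.free:
        value = ev(np.empty(0))
        return CalibrationResult(estimates=dict(spec.fixed),
                                 objective_value=value, objective_trace=ev.trace,
                                 converged=True, log=ev.log,
                                 residuals=ev.residuals({}), sensitivity={},
                                 n_evaluations=1, spec=spec)

    x0 = np.array([spec.free[n].to_x(spec.free[n].initial) for n in ev.names])
    lo = np.array([spec.free[n].to_x(spec.free[n].lower) for n in ev.names])
    hi = np.array([spec.free[n].to_x(spec.free[n].upper) for n in ev.names])
    f0 = ev(x0)
    if not np.isfinite(f0):
        raise DomainError(f"objective non-finite at the initial point "
                          f"{ev.params_from_x(x0)}")

    rng = np.random.default_rng(spec.seed)
    starts = [x0]
    for _ in range(spec.restarts):
        jitter = rng.uniform(-0.25, 0.25, size=x0.shape) * np.maximum(hi - lo, 1e-12)
        starts.append(np.clip(x0 + jitter, lo, hi))

    best = None
    converged = False
    for xs in starts:
        sol = minimize(ev, xs, method="Nelder-Mead",
                       bounds=list(zip(lo, hi)),
                       options={"maxiter": spec.maxiter, "xatol": 1e-5,
                                "fatol": 1e-12, "adaptive": len(x0) > 2})
        if best is None or sol.fun < best.fun:
            best = sol
            converged = bool(sol.success) or converged
    estimates = ev.params_from_x(best.x)
    for n, p in spec.free.items():
        if not (p.lower * (1 - 1e-12) <= estimates[n] <= p.upper * (1 + 1e-12)):
            raise RuntimeError(f"optimizer left the bounds for {n}")

    sensitivity = {}
    if spec.compute_sensitivity:
        h = 0.01
        for i, n in enumerate(ev.names):
            dx = np.zeros_like(best.x)
            dx[i] = h
            fp = ev(np.clip(best.x + dx, lo, hi))
            fm = ev(np.clip(best.x - dx, lo, hi))
            sensitivity[n] = (fp - fm) / (2 * h)

    return CalibrationResult(estimates={**spec.fixed, **estimates},
                             objective_value=float(best.fun),
                             objective_trace=ev.trace, converged=converged,
                             log=ev.log, residuals=ev.residuals(estimates),
                             sensitivity=sensitivity,
                             n_evaluations=len(ev.log), spec=spec)


def calibrate_release(spec: CalibrationSpec, ivrt_data: ExperimentDataset,
                      template_cfg: dict) -> CalibrationResult:
    """Stage 1: fit release-model parameters to IVRT data."""
    if spec.stage != "release":
        raise DomainError("spec.stage must be 'release'")
    if template_cfg["mode"] != "ivrt":
        raise DomainError("stage-1 template must be an IVRT config")
    return _calibrate(spec, ivrt_data, template_cfg)


def calibrate_skin(spec: CalibrationSpec, ivpt_data: ExperimentDataset,
                   release_result: CalibrationResult | dict | None,
                   template_cfg: dict) -> CalibrationResult:
    """Stage 2: fix the stage-1 release parameters, fit the skin parameters.

    ``release_result`` may be a stage-1 :class:`CalibrationResult`, an
    explicit parameter dict, or None when the template already carries the
    release parameters.
    """
    if spec.stage != "skin":
        raise DomainError("spec.stage must be 'skin'")
    if template_cfg["mode"] != "ivpt":
        raise DomainError("stage-2 template must be an IVPT config")
    release = {}
    if isinstance(release_result, CalibrationResult):
        release = {k: v for k, v in release_result.estimates.items()
                   if k in RELEASE_PARAMS}
    elif isinstance(release_result, dict):
        release = dict(release_result)
    spec = CalibrationSpec(stage=spec.stage, free=spec.free,
                           fixed={**release, **spec.fixed},
                           objective=spec.objective, weighting=spec.weighting,
                           seed=spec.seed, restarts=spec.restarts,
                           maxiter=spec.maxiter, layer_weight=spec.layer_weight,
                           compute_sensitivity=spec.compute_sensitivity)
    return _calibrate(spec, ivpt_data, template_cfg)
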