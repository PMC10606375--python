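"""Derived Franz-cell metrics and replicate statistics.

Works on simulated results and on observed replicate datasets alike:
cumulative permeation per area, steady-state flux and lag time from the
linear regime, permeability coefficient, per-skin-layer deposition per tissue
mass, recovery, and the per-timepoint one-way ANOVA used to compare
formulations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import units
from .core import DomainError
from .franz import SimulationResult

SKIN_DENSITY = 1000.0   # kg/m^3 (1 g/cm^3) unless configured otherwise


@dataclass
class ExperimentDataset:
    """Replicate cumulative-permeation time series for one formulation group.

    ``times_h`` is shared by all replicates; ``replicates`` maps replicate id
    to cumulative amount per area (ug/cm^2).  Terminal layer depositions
    (ug) and layer masses (mg) are optional and keyed the same way.
    """
    group: str
    times_h: np.ndarray
    replicates: dict[str, np.ndarray]
    layer_amounts: dict[str, dict[str, float]] = field(default_factory=dict)
    layer_masses: dict[str, dict[str, float]] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        if np.any(np.diff(self.times_h) <= 0):
            raise DomainError("dataset times must be strictly increasing")
        for rid, q in self.replicates.items():
            q = np.asarray(q, dtype=float)
            if q.shape != self.times_h.shape:
                raise DomainError(f"replicate {rid!r} length mismatch")
            if np.any(q < 0):
                raise DomainError(f"replicate {rid!r} has negative amounts")
            self.replicates[rid] = q

    @property
    def n_replicates(self) -> int:
        return len(self.replicates)

    def matrix(self) -> np.ndarray:
        """(n_replicates, n_times) array in replicate-id order."""
        return np.vstack([self.replicates[k] for k in sorted(self.replicates)])

    def mean_profile(self) -> np.ndarray:
        return self.matrix().mean(axis=0)


# ---------------------------------------------------------------------------
# series metrics
# ---------------------------------------------------------------------------

def cumulative_per_area(result: SimulationResult, area: float) -> np.ndarray:
    """Cumulative receptor amount (content + sampled) per area, ug/cm^2."""
    if area <= 0:
        raise DomainError("area must be positive")
    q_kg = result.cumulative_receptor_amount()
    return units.kg_to_ug(q_kg) / (area / units.CM2)


def steady_state_flux_and_lag(times_h: np.ndarray, q: np.ndarray,
                              fit_window: tuple[float, float] | None = None
                              ) -> tuple[float, float | None, float]:
    """OLS fit of the linear regime of Q(t): (flux, lag time, R^2).

    ``flux`` is the slope in ug/cm^2/h and ``lag`` the x-intercept in h,
    reported only for a positive slope (None otherwise).  The default window
    covers the last 40 % of time points with positive Q.
    """
    t = np.asarray(times_h, dtype=float)
    q = np.asarray(q, dtype=float)
    if fit_window is None:
        pos = np.nonzero(q > 0)[0]
        if len(pos) < 3:
            raise DomainError("not enough positive points to fit a flux")
        start = pos[int(np.ceil(0.6 * (len(pos) - 1)))]
        mask = np.zeros_like(t, dtype=bool)
        mask[start:] = True
        mask &= np.arange(len(t)) >= pos[0]
    else:
        lo, hi = fit_window
        if lo >= hi or lo < t[0] - 1e-12 or hi > t[-1] + 1e-12:
            raise DomainError("fit window must lie inside the data time range")
        mask = (t >= lo) & (t <= hi)
    if mask.sum() < 3:
        raise DomainError("need at least 3 points inside the fit window")
    res = stats.linregress(t[mask], q[mask])
    flux = float(res.slope)
    r2 = float(res.rvalue ** 2) if np.isfinite(res.rvalue) else 1.0
    lag = float(-res.intercept / res.slope) if flux > 0 else None
    return flux, lag, r2


def permeability_coefficient(flux: float, donor_concentration: float) -> float:
    """kp = flux / C_donor in cm/h (flux in ug/cm^2/h, C in ug/mL = ug/cm^3)."""
    if donor_concentration <= 0:
        raise DomainError("donor concentration must be positive")
    if flux < 0:
        raise DomainError("flux must be non-negative")
    return flux / donor_concentration


def layer_accumulation(result: SimulationResult, layer: str,
                       density: float = SKIN_DENSITY,
                       include_sc_in_epidermis: bool = True) -> float:
    """Terminal drug content of a skin layer per tissue mass, ug/mg.

    Forceps separation leaves the SC on the epidermis, so the epidermis
    aggregate includes the SC by default.  The tissue mass is layer volume
    (diffusion area x layer thickness) times ``density``.
    """
    if not result.is_ivpt:
        raise DomainError("layer accumulation requires an IVPT result")
    if density <= 0:
        raise DomainError("density must be positive")
    g = result.experiment.stack.geometry
    area = result.experiment.config.diffusion_area
    if layer == "epidermis":
        amount = (result.layer_amount("epidermis") if include_sc_in_epidermis
                  else result.group_amount("ve"))[-1]
        thickness = g.ve_thickness + (g.sc_thickness if include_sc_in_epidermis else 0.0)
    elif layer == "dermis":
        amount = result.group_amount("dermis")[-1]
        thickness = g.dermis_thickness
    else:
        raise DomainError("layer must be 'epidermis' or 'dermis'")
    tissue_mass_mg = area * thickness * density / units.MG   # kg -> mg
    return units.kg_to_ug(amount) / tissue_mass_mg


def recovery_percent(donor_residual: float, receptor_total: float,
                     layer_amounts, dose: float) -> float:
    """Mass-balance recovery: 100*(donor + receptor + sum(layers))/dose.

    Accepts any consistent mass unit; ``layer_amounts`` is an iterable or
    mapping of per-layer amounts.
    """
    if dose <= 0:
        raise DomainError("dose must be positive")
    layers = (layer_amounts.values() if hasattr(layer_amounts, "values")
              else layer_amounts)
    parts = [donor_residual, receptor_total, *layers]
    if any(p < 0 for p in parts):
        raise DomainError("all mass-balance components must be non-negative")
    return 100.0 * sum(parts) / dose


# ---------------------------------------------------------------------------
# replicate statistics
# ---------------------------------------------------------------------------

def oneway_anova(groups) -> tuple[float, float, int, int]:
    """Classical one-way ANOVA: (F, p, df_between, df_within).

    Degenerate all-equal input returns F = 0, p = 1.
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2 or any(len(a) < 2 for a in arrs):
        raise DomainError("ANOVA needs >= 2 groups with >= 2 values each")
    df_b = len(arrs) - 1
    df_w = sum(len(a) for a in arrs) - len(arrs)
    if all(np.ptp(a) == 0 for a in arrs) and np.ptp([a[0] for a in arrs]) == 0:
        return 0.0, 1.0, df_b, df_w
    f, p = stats.f_oneway(*arrs)
    if not np.isfinite(f):  # zero within-group variance, unequal means
        return float("inf"), 0.0, df_b, df_w
    if f < 0.0 or not np.isfinite(p):  # roundoff at F ~ 0
        f = max(float(f), 0.0)
        p = float(stats.f.sf(f, df_b, df_w))
    return float(f), float(p), df_b, df_w


def compare_groups_per_timepoint(dataset_a: ExperimentDataset,
                                 dataset_b: ExperimentDataset,
                                 alpha: float = 0.05,
                                 holm: bool = False):
    """Per-timepoint one-way ANOVA between two replicate groups.

    Returns a list of dicts (time_h, f_stat, p_value, significant).  Raw
    per-timepoint p-values are reported by default; ``holm`` applies a Holm
    step-down correction across time points.
    """
    if not np.allclose(dataset_a.times_h, dataset_b.times_h):
        raise DomainError("datasets must share the sampling time grid")
    if dataset_a.n_replicates < 2 or dataset_b.n_replicates < 2:
        raise DomainError("each group needs at least 2 replicates")
    a, b = dataset_a.matrix(), dataset_b.matrix()
    rows = []
    for j, t in enumerate(dataset_a.times_h):
        f, p, _, _ = oneway_anova([a[:, j], b[:, j]])
        rows.append({"time_h": float(t), "f_stat": f, "p_value": p})
    ps = np.array([r["p_value"] for r in rows])
    if holm:
        order = np.argsort(ps)
        m = len(ps)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, min(1.0, (m - rank) * ps[idx]))
            adj[idx] = running
        ps = adj
    for r, p in zip(rows, ps):
        r["p_value"] = float(p)
        r["significant"] = bool(p < alpha)
    return rows
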