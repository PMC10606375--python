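# dermasim

A virtual Franz diffusion-cell laboratory for semisolid dermal drug
products.  `dermasim` mechanistically simulates **in vitro release testing
(IVRT)** of creams, ointments and solutions through an inert porous
membrane, and **in vitro permeation testing (IVPT)** through a layered skin
barrier with an explicit brick-and-mortar stratum corneum, then derives the
standard Franz-cell endpoints (cumulative permeation per area, steady-state
flux, lag time, permeability coefficient, skin-layer deposition, recovery)
and calibrates the model in two stages against replicate data.  It is aimed
at formulation and dermal-PBPK modellers who need a transparent, testable
alternative to running every what-if on a diffusion-cell bench.

## The model in brief

All compartments exchange drug by the generalized diffusive interface law

    J(A→B) = P·SA·(C_A − C_B/Kp),   P = 1/(δ_A·Kp/D_A + δ_B/D_B)

with zero flux at partition equilibrium C_B = Kp·C_A.  On top of this:

* **cream** — a two-phase oil-in-water emulsion: dispersed droplets
  (d ≈ 3.37 µm) exchange with the continuous phase through their total
  surface area at the continuous/dispersed partition coefficient;
* **ointment** — a particle suspension releasing drug by the
  Nernst–Brunner form of the Noyes–Whitney law,
  J = N_p·D_p·SA_p·(C_s − C_v)/R_p, with shrinking monodisperse spheres;
* **membrane** — a porous slab whose effective diffusivity carries the
  Mackie–Meares obstruction factor D·(ε/(2−ε))²;
* **skin** — 16 corneocyte and 17 lipid strata (14.075 µm stratum corneum)
  in a periodic, staggered brick-and-mortar unit cell, over discretised
  viable epidermis (56 µm) and dermis (1.2 mm), ending at a
  dermis/receptor film;
* **receptor** — well mixed (4.7 mL), with discrete sample-and-replace
  events (400 µL) that produce the characteristic concentration drops and
  feed the cumulative-permeation ledger.

Calibration splits the problem the way the bench does: stage 1 fits the
release model to IVRT data, stage 2 freezes it and fits the five skin
transport parameters to IVPT data (bounded Nelder–Mead, log-scaled, RMSE on
the replicate-mean profile).  See `docs/methods.md` for assumptions,
defaults and limitations.

## Worked example

```python
from dermasim import presets, franz, metrics, units

cfg = presets.default_config("ivpt", "cream")     # published parameter presets
exp = presets.build_experiment(cfg)
res = franz.run_ivpt(exp)                         # 36 h virtual permeation test

q = metrics.cumulative_per_area(res, cfg["diffusion_area"])
flux, lag, r2 = metrics.steady_state_flux_and_lag(res.times / units.HOUR, q,
                                                  fit_window=(20, 36))
print(q[-1], flux, lag)
print(metrics.layer_accumulation(res, "epidermis"),
      metrics.layer_accumulation(res, "dermis"))
```

prints (cream preset, default grids):

```
Q(36 h)            75.72 ug/cm^2
steady flux         2.42 ug/cm^2/h   lag 4.69 h
epidermis (SC+VE)   4.10 ug/mg
dermis              0.031 ug/mg
```

Q(36 h) is everything that reached (and was sampled from) the receptor per
cm² of dosed skin; the flux and lag come from the linear late-time regime
of Q(t); the last two lines are the drug retained per milligram of skin
layer at the end of the run — the lipophilic permeant concentrates in the
epidermis (stratum corneum included) rather than the dermis, matching the
qualitative pattern seen on the bench.  The mass ledger closes to
100.0000 % recovery on every run.  Runnable scripts for release,
permeation, statistics and calibration live in `examples/`.

A thin CLI mirrors the library: `dermasim simulate|calibrate|metrics|
fixtures|report` (each run writes a JSON manifest of the fully resolved
configuration for reproducibility).

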