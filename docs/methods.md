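# Methods

`dermasim` simulates Franz diffusion-cell experiments on semisolid dermal
products — in vitro release testing (IVRT) through an inert porous membrane
and in vitro permeation testing (IVPT) through excised skin — and calibrates
the underlying mechanistic model in two stages against such data.  This note
records the model, its assumptions, the numerical choices, and the limits of
what the synthetic-data tests demonstrate.

## Transport model

Every experiment is a network of well-mixed compartments.  The flux across
the interface between compartments A and B is

    J(A→B) = P · SA · (C_A − C_B / Kp),     P = 1 / (δ_A·Kp/D_A + δ_B/D_B)

with interface permeability `P`, shared area `SA`, film thicknesses `δ`,
diffusivities `D`, and the link partition coefficient `Kp`.  **Convention:**
zero flux corresponds to `C_B = Kp·C_A`, i.e. `Kp` is the equilibrium
concentration of the receiving phase relative to the donating phase.  A
tabulated coefficient written "Kp (X/Y)" therefore enters a link that
carries drug from Y into X unchanged (e.g. Kp(lipid/vehicle) = 18.8 on the
vehicle→lipid link), and inverted on the reverse orientation (the
vehicle→membrane link uses 1/Kp(vehicle/receptor)).  Some published
compartment codes orient partition coefficients the other way; when
importing coefficients from elsewhere this is the first thing to check.

Amounts (kg) are the state variables, so every link conserves mass exactly
in the continuous problem; concentrations are amounts over phase volumes.

## Donor vehicles

The vehicle film (0.92 cm deep, 1250 µg drug over 0.64 cm² by default) is
discretised into 40 one-dimensional finite volumes geometrically refined
(ratio 1.2) toward the barrier face, because the diffusion depth over
24–36 h (~100 µm at D ≈ 1e-10 m²/s) is far smaller than the film — a
well-mixed donor would be qualitatively wrong.  Three vehicle kinds:

* **solution** — single phase, diffusion only (default D = 1e-9 m²/s,
  aqueous-like control).
* **emulsion (cream)** — oil droplets (diameter 3.37 µm) in a continuous
  aqueous phase.  Each cell carries a lumped dispersed reservoir whose
  exchange with the continuous phase uses the interface law with the total
  droplet surface area in the cell (6φV/d), a droplet-film permeability
  D_cont/r (the Sherwood-number-2 boundary layer), and the
  continuous/dispersed partition coefficient 4.484 oriented so the
  continuous phase is the richer one at equilibrium, as the source table is
  labelled.  The dispersed volume fraction φ is not published; the default
  0.2 is a package choice, announced at WARN level.
* **suspension (ointment)** — solid monodisperse particles dissolving by
  the Nernst–Brunner/Noyes–Whitney law J = N_p·D_p·SA_p·(C_s − C_v)/R_p.
  Particles shrink: N_p is conserved per cell and R_p, SA_p are recomputed
  from the remaining solid mass (switchable to fixed geometry).  R_p is
  clamped below at 1 nm and the solid mass floored at zero to avoid
  stiffness blow-up at exhaustion.  Solubility 0.63 is interpreted as
  mg/mL in the continuous phase (the source prints no units); particle
  density 1300 kg/m³ is a package default.

Initial conditions: solutions dissolve the whole dose; suspensions saturate
the continuous phase (dissolved = min(C_s·V_vehicle, dose)) and hold the
remainder as solid; emulsions split the dose between phases at partition
equilibrium.  All splits close the mass ledger exactly.

## Barriers

**IVRT membrane** — a homogeneous water-filled porous slab (default 50 µm,
10 cells; thickness and porosity are not published — defaults are announced
loudly).  The in-membrane diffusivity applies the Mackie–Meares obstruction
factor D_eff = D·(ε/(2−ε))² (named but not printed by the source; this is
the standard form).  The vehicle/receptor partition coefficient (223.872)
acts at the vehicle→membrane interface, which is what makes release
partition-limited for these lipophilic-vehicle products.

**IVPT skin stack** — explicit brick-and-mortar stratum corneum (SC) over
1-D viable epidermis (VE, 56 µm, 10 cells) and dermis (DM, 1.2 mm, 20
cells), both refined toward their interfaces.  The SC geometry (14.075 µm
total, 0.8 µm corneocytes, 0.075 µm lipid layers) admits exactly 16
corneocyte and 17 lipid strata.  The 2-D unit cell spans one corneocyte
(40 µm) plus one vertical lipid channel (width = lipid thickness by
default), wraps periodically in the lateral direction, and staggers the
channel by `brick_offset` (default 0.5) between successive corneocyte
strata; corneocytes are subdivided laterally (2 subcells per span by
default, convergence-tested).  Lipid↔corneocyte interfaces carry the
direction-specific calibrated permeabilities (vertical for depth links,
horizontal for lateral links); same-phase links use the two-film series
formula with intraphase diffusivities D_lipid = D_corneocyte = 1e-13 m²/s —
lamellar SC lipid transport is orders of magnitude slower than aqueous, and
at this scale the calibrated interface permeabilities dominate the SC
resistance, which is the structure the published calibration implies.
Partition coefficients the source does not print (corneocyte/lipid,
lipid/VE, VE/DM, DM/receptor) default to 1.0.  A steady-state
homogenisation (`homogenized_sc_resistance`) reports the effective SC
permeability for diagnostics and limit tests.

The dermis/receptor interface uses the calibrated permeability directly.  A
`specimen_thickness` override rescales the dermis to a dermatomed specimen
and is logged whenever used; the published layer table's 1.2 mm dermis is
the default.

## Receptor sampling

The receptor (4.7 mL) is well mixed.  Sampling is a discrete replace event
by default: at each scheduled time an aliquot (400 µL) moves its drug mass
to a removed-mass ledger and fresh medium restores the volume, so the
receptor concentration drops — the behaviour visible in measured receptor
traces.  A continuous-withdrawal mode (V_R dC/dt = J_in − Q̇C) is retained;
the discrete scheme converges to it in the many-small-samples limit (tested
at 1 % on 36 hourly 40 µL events).  Cumulative permeation Q(t) is receptor
content plus everything sampled, per dosing area.  Note that sampling is
*not* exactly neutral for Q when the receptor exerts back-pressure (the
vehicle/receptor partition makes it do so in IVRT); the telescoping
invariance of Q holds only in the sink regime, and that is where the test
asserts it.

## Numerics

Stiff integration uses BDF (`scipy.integrate.solve_ivp`) with an assembled
Jacobian sparsity pattern, restarted at every sampling event so events are
never interpolated across.  Tolerances default to rtol 1e-9, atol 1e-15 kg,
at which the mass ledger closes to better than 1e-6 relative over a full
36 h run (the closure is asserted by the tests; looser tolerances
measurably drift).  Sub-picogram negative amounts from solver truncation
are clipped to zero on output.  Typical problem sizes: ~90 states for IVRT,
~310 for IVPT; a full 36 h IVPT run takes well under a second on one CPU.

## Two-stage calibration

Stage 1 fits release parameters (vehicle diffusivity, partition
coefficients, particle/droplet size, solubility, membrane porosity) to IVRT
data; stage 2 fixes those and fits the five skin parameters
(Kp lipid/vehicle, horizontal and vertical lipid/corneocyte permeabilities,
the tied VE = DM diffusivity, dermis/receptor permeability) to IVPT data.
The objective is the RMSE between the simulated cumulative-per-area profile
and the replicate-mean observed profile at the data's time points (pooled
residuals and terminal layer-deposition residuals are options).  The source
names neither objective nor optimizer; bounded Nelder–Mead on
log10-transformed transport parameters with optional seeded multi-start was
chosen because it is derivative-free (robust to solver noise) and the
calibrated corrections span decades.  A finite-difference sensitivity of
the objective at the optimum is always available, because a five-parameter
fit to a single mean curve is plausibly under-determined; the VE/DM tie
(identical published values) removes one such direction by default.

## Synthetic data

No raw replicate data accompany the reference study, so the generator runs
the simulator as ground truth, evaluates Q at the sampling schedule
(IVPT grid 12–36 h, IVRT grid 0.5–24 h), and applies i.i.d. multiplicative
lognormal noise per replicate and time point, median-unbiased, with
cv = 0.15 and n = 6 (IVRT) / n = 5 (IVPT) replicates mirroring the
reference protocols; terminal layer amounts get independent noise of the
same cv.  Lognormal was chosen because measured amounts are positive and
reported error bars grow with the mean.  What passing recovery tests show:
the pipeline is self-consistent and identifiable under the stated noise.
What they do not show: robustness to structure the generator lacks —
inter-donor skin variability, assay error correlated across time points,
vehicle metamorphosis (evaporation), or model misspecification.

## Known limitations

* Formulation viscosity, polydisperse particle sizes, co-solvent and
  surfactant effects are not modelled.
* No ionisation/pH-partition correction (pKa and pH are carried as
  metadata only) and no temperature dependence.
* Appendageal routes, skin metabolism and hydration dynamics are absent.
* The unprinted SC partition coefficients default to 1.0.  With the
  published optimized parameter sets this makes the simulated SC store
  more cream-borne drug, and pass less ointment-borne drug to the dermis,
  than the reference model evidently did: the printed cream and ointment
  depositions imply effective SC/vehicle concentration ratios that differ
  by a factor of ~5 between formulations, which no single neutral
  parameter set can reproduce.  The affected end-to-end deposition and
  cream/ointment-comparability checks in the acceptance suite document
  this gap rather than hide it; all structural, conservation and recovery
  properties pass independently of it.
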