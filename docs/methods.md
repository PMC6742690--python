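# Model and methods

## The disease model

`t1dsim` integrates a twelve-compartment nonlinear ODE model of type-1-
diabetes (T1D) initiation in a single well-mixed pancreatic compartment.
The compartments are resting and activated macrophages (M, Ma, cells/ml),
healthy β-cell mass (B, mg), apoptotic and necrotic β-cells (Ba, Bn,
cells/ml), glucose (G, mg/dl), insulin (I, μU), immunogenic and tolerogenic
dendritic cells (D, tD, cells/ml) drawn from a resident pool of fixed
capacity Dss, and effector, regulatory and memory T cells (E, R, Em,
cells/ml).

The causal chain encoded by the equations is the Copenhagen hypothesis:

1. β-cells die at a basal rate δB, through a transient neonatal *apoptotic
   wave* W(B,t) = 0.1·w·B·exp(−((t−9)/9)²) peaking at day 9, and through
   effector-T-cell killing ηe(t)·K2(E,R)·B, where
   K2 = (sE·E)²/(1+(sE·E)²+(sR·R)²) saturates in E and is damped by R, and
   ηe(t) = η + 2η(1+tanh(αe(t−βe))) ramps from η to 5η as effector avidity
   matures.
2. Apoptotic cells that are not cleared in time (rate d) become necrotic.
   Clearance is by resting/activated macrophages (fM, fMa — the only
   strain-specific parameters) and by dendritic cells (ftD for the
   immature/tolerogenic pool, fD for mature immunogenic DCs).
3. Resident immature DCs that engulf an apoptotic cell become tolerogenic
   (tD) and expand regulatory T cells; DCs that engulf a necrotic cell
   become immunogenic (D) and expand effector T cells.  Slow macrophage
   clearance (the NOD strain) therefore tilts the DC signal toward the
   immunogenic side.
4. Effector and regulatory T cells mutually suppress each other (μE, μR)
   and are replenished from a naive pool (aE, aR, Tnaive), DC-driven
   proliferation (bP, half-saturation θD) and memory reactivation
   (bE·D·Em, bR·tD·Em).
5. Glucose and insulin follow the classic two-compartment feedback
   (production R0, uptake G0 + SI·I, secretion σI·K1(G,GI)·B, decay δI)
   with the saturating response K1(G, Gh) = G²/(G²+Gh²).

Both strains share every parameter except the macrophage clearance pair:
NOD (fM = fMa = 1e-5 ml/cell/day) versus Balb/c (fM = 2e-5,
fMa = 5e-5).  DC engulfment rates are tied to the Balb/c activated-
macrophage rate through the assay-derived ratios fD = 0.0549·fMa and
ftD = 0.382·fMa and are identical across strains.

## Unit conventions

β-cell mass is tracked in mg; every β-sourced flux into the apoptotic pool
is converted to cells/ml with the factor Bconv/Qpanc.  Time is integrated
in days; all user-facing interfaces report weeks (conversion factor exactly
7).  Injected doses are whole-animal cell counts and are converted to
concentrations by dividing by Qpanc.

`Qpanc` deserves a caveat.  Treating it simultaneously as (i) the volume
that converts β-cell mass fluxes to concentrations, (ii) the dilution
volume of an intravenous dose that reaches the compartment in full, and
(iii) a literal mouse pancreas volume (~0.2 ml) is not possible: with a
0.2 ml volume any dose above ~3×10⁴ cells would saturate the resident DC
pool and all studied doses would act identically.  We therefore interpret
the compartment as the effective distribution volume of the model's cell
populations and set Qpanc = 5 ml, which preserves a graded response over
the studied dose range (10⁴–5×10⁶ cells) while keeping DC-mediated
clearance subordinate to macrophage clearance.  Doses large enough to
overflow the resident pool are truncated at injection time (the overflow is
logged on the trajectory), so the very top of the dose range saturates.

## Parameter provenance and calibration

The macrophage block (J, k, b, c, e1, e2 and the strain clearance pairs)
uses the standard NOD/Balb-c phagocytosis kinetics from the macrophage-
clearance modeling literature.  The glucose–insulin block is the classic
Topp parameterization (R0 = 864 mg/dl/day, G0 = 1.44/day,
SI = 0.72 ml/μU/day, δI = 432/day, GI² = 20,000 mg²/dl²), with the
secretion scale σI set so that the healthy equilibrium carries ~2 mg of
β-cell mass.  β-cell growth uses the saturating glucose response with
half-max Ghb and maximal rate αB chosen so the healthy glucose equilibrium
sits at 89 mg/dl; δB = 1/60 per day corresponds to a 60-day β-cell
lifespan.

The immune couplings (DC pool capacity and turnover, T-cell homeostasis,
proliferation, suppression and memory rates, and the kill-saturation
scalings sE, sR) are not individually measurable and were calibrated
jointly, as one set, against the model's documented natural histories and
treatment behaviors:

* healthy steady-state glucose ≈ 89 mg/dl (all non-diseased scenarios);
* diseased steady-state glucose ≈ 539 mg/dl (NOD with wave);
* first crossing of the 250 mg/dl diabetic threshold at ≈ 24.3 weeks for
  the NOD mouse with the wave, and no crossing within 40 weeks for the
  NOD mouse without the wave or Balb/c with or without it;
* the asymmetric ±5% clearance-rate sensitivity pattern at week 40;
* the tolerogenic-DC dose/timing window structure (early injections fail;
  a high 2×10⁶-cell dose first becomes effective at 6.57 weeks; a low
  2×10⁵-cell dose only from 24.86 weeks, just after overt onset; a
  3×10⁴-cell dose has no window in the low-dose region).

Calibration proceeded in that order; the steady states pin the metabolic
and kill-saturation scales, the onset time pins the avidity ramp (αe, βe),
and the treatment windows pin the DC-turnover asymmetry (see below).  The
registry records a provenance string per parameter in the preset files.
Two documented behaviors of this class of model are *not* met by the
shipped registry and are stated here as known calibration deficits rather
than smoothed over: (i) the NOD fate in this registry is decided by the
suppression/memory couplings rather than sitting critically in clearance
space, so a +5% change of fM and fMa delays onset by under a week and
moves week-40 glucose by under 1% instead of producing a large glucose
reduction; (ii) the low-dose window opens on time but does not close again
within the 45-week sweep — late low-dose injections keep rescuing the
model mouse because the memory-powered regulatory reactivation that drives
late rescue does not decay fast enough after onset.

## Dynamical structure worth knowing about

The model is bistable between a regulatory-dominated healthy state and an
effector-dominated diseased state with ~0.6% of the healthy β-cell mass
(the 539 mg/dl equilibrium).  Three design points shape the dynamics:

* **Tolerogenic DCs turn over much faster than immunogenic DCs.**  tD is
  removed by regulatory cells (bIR·R·tD) and by necrotic-debris conversion
  on top of the shared death rate μD, so the natural tD pool stays well
  below the proliferation half-saturation θD while an injected bolus
  transiently saturates it.  This is what gives injections leverage beyond
  the natural tolerogenic signal, and its decay is what closes treatment
  windows.
* **The avidity ramp, not the wave, sets the onset time.**  The wave
  decides *whether* the NOD system tips (by loading the memory pool and
  depressing β-mass while clearance is marginal); the tanh ramp ηe(t)
  decides *when* glucose escapes, which is why the crossing time is
  controlled by βe.
* **The NOD preset sits close to the healthy/diseased boundary in
  clearance space; Balb/c sits far from it.**  This reproduces the strong
  and asymmetric NOD sensitivity to ±5% clearance changes and the <1%
  Balb/c response.  A side effect of the regulatory cells' dependence on
  apoptotic supply is that extremely fast clearance (fM near the top of
  the sampled interval, beyond any strain preset) starves the tolerogenic
  signal and can re-enter a diseased region; the region maps therefore
  march from low fM and report the first diabetic→healthy transition as
  the healthy boundary.

## Initial conditions

Runs start from a 50-day wave-free equilibration with the β-cell mass
clamped at its full 2 mg: macrophages, glucose, insulin, DC pools and
T cells settle to strain-specific quasi-steady levels (the NOD preset
starts with visibly more immunogenic DCs than Balb/c).  The equilibrated
state is stored in each preset file so production runs are reproducible
byte-for-byte; loaders fall back to re-equilibration whenever any
parameter differs from the stored registry.

## Numerics

LSODA with relative tolerance 1e-8 and per-state absolute tolerances
(states span mg to 10⁵ cells/ml).  Injections halt and restart the
integrator with an exact impulse on tD.  Threshold crossings are refined
with a root finder on the dense output; halving tolerances moves reported
crossing times by well under 0.1 day.  States are never clamped: a
component below −10⁻⁶ of its scale aborts the run as an integration
failure, and trajectories carry warning flags rather than silently
repairing anything.  Long sweeps use rtol 1e-6 and weekly output samples;
the classification outcomes are unchanged at tighter tolerance.

The phagocytosis-assay fit uses a log-scale random-walk Metropolis chain
(default 20,000 steps, step size tuned to ~20–40% acceptance) on a
Gaussian likelihood on the percent-phagocytosis scale, restricted to the
≤1 h transient where the rate is identifiable; the closed-form solution is
used for the likelihood and is property-tested against direct integration
of the assay ODEs.

## Synthetic assay data

The real engulfment assay is human-derived and external, so the fitting
path ships with a generator: percent phagocytosis from the closed form at
the canonical rate ratios (gMa = 5e-6 ml/cell/h; gD/gMa = 0.0549;
gtD/gMa = 0.382), 1:1 phagocyte:apoptotic seeding at P = 1e5, eight sample
times from 5 min to 4 h, and i.i.d. Gaussian observation noise
(σ = 2 percentage points), clipped to [0, 100].  The generator reproduces
the saturation plateau (1−1/e)·100 ≈ 63.2% that makes late samples
uninformative about the rate.  What passing the recovery tests shows is
that the estimator is consistent and roughly calibrated under this noise
model; it does not validate the Gaussian error assumption against the real
assay, nor multi-cargo engulfment effects, which the reduced model ignores
by design.

## Scope of validation and known limitations

Everything the tests assert is a property of this model with this
registry, not of mice: the synthetic generator emulates the model's own
kinetics, so parameter-recovery tests validate the estimation machinery
only.  The registry is a calibrated point, not a measured one — the
treatment-window boundaries in particular are emergent properties of a
stiff nonlinear system and should be read as qualitative structure (an
early dead zone, a broad high-dose window, a narrow late low-dose window)
rather than as biological predictions with day-level accuracy.  The model
omits β-cell regeneration in the growing pancreas (so the wave's mass
loss is overstated), spatial islet structure, ER-stress death, viral
triggers, and any delay in DC-driven T-cell activation.  Two further
quirks of the shipped registry: the high-dose effectiveness region has a
gap between ~13 and ~21 weeks (the destruction phase briefly overwhelms
even a pool-filling injection), and very small doses acquire a faint
window very late (after ~35 weeks) once the effector pool has relaxed
toward its diseased equilibrium.  Related, and important when reading the
treatment maps: effectiveness is defined by the evaluation protocol
(glucose below 250 mg/dl at 85 weeks).  Early high-dose rescues are true
basin changes (regulatory cells take over, log(R/E) > 0, glucose returns
to ~90 mg/dl); the late low-dose "rescues", however, are transient dips —
glucose re-escapes the threshold on a ~year timescale and the effector
population stays dominant.  The two effectiveness readings therefore
disagree on those cells; `TreatmentMap.criteria_disagreement()` reports
every such cell rather than reconciling the criteria.  Sweeps at the
full published resolution (2,500 clearance pairs × 6 wave/η settings;
500 doses × 315 start days) are supported by the API but the shipped
defaults and tests use strided or targeted sub-grids around the features
of interest; the CLI exposes the full grids.
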