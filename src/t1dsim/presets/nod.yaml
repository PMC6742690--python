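# Parameter preset (flat keys = model symbols); the init block
# stores the 50-day wave-free equilibration used to start runs.
name: NOD
wave_on: true
w: 0.75
params:
  J: 50000.0
  k: 0.4
  b: 0.09
  c: 0.1
  e1: 1.0e-08
  e2: 1.0e-08
  fM: 1.0e-05
  fMa: 1.0e-05
  alphaB: 0.0587
  deltaB: 0.016666666666666666
  Ghb: 141.421356
  eta: 0.01
  alphaE: 0.039247
  betaE: 104.83
  sE: 0.00010982
  sR: 2.4233e-05
  w: 0.75
  d: 0.5
  Bconv: 870000.0
  Qpanc: 5.0
  Dss: 205760.0
  ftD: 1.91e-05
  fD: 2.745e-06
  bDE: 1.9087e-07
  bIR: 7.6207e-05
  muD: 0.014617
  R0: 864.0
  G0: 1.44
  SI: 0.72
  sigmaI: 8743.7
  GI: 141.421356
  deltaI: 432.0
  aE: 0.0031271
  aR: 0.0020508
  Tnaive: 8806.5
  bP: 0.63799
  thetaD: 20422.0
  ram: 0.01706
  bE: 1.9131e-05
  bR: 1.9216e-06
  muE: 3.2024e-05
  muR: 4.44e-05
  aEm: 0.0055865
init:
  M: 482909.9079800595
  Ma: 7912.049545685171
  B: 2.0
  Ba: 627.929959848423
  Bn: 35.84646403771979
  G: 88.99766883020467
  I: 11.48349923961958
  D: 4887.339774890159
  tD: 1668.8160563510557
  E: 611.6627737016236
  R: 18637.672835083777
  Em: 3051.3895878124517
provenance:
  J: macrophage influx; resident-macrophage turnover literature (Maree-type estimate)
  k: Ma->M deactivation; Maree-type macrophage kinetics
  b: Ma-driven recruitment; Maree-type macrophage kinetics
  c: macrophage egress; Maree-type macrophage kinetics
  e1: macrophage crowding; Maree-type macrophage kinetics
  e2: activated-macrophage crowding; Maree-type macrophage kinetics
  fM: 'strain preset: resting-macrophage clearance of dying beta cells'
  fMa: 'strain preset: activated-macrophage clearance of dying beta cells'
  alphaB: calibrated so the healthy equilibrium glucose is 89 mg/dl
  deltaB: beta-cell turnover, ~60-day lifespan
  Ghb: half-max glucose for beta-cell growth (Topp-type half-saturation)
  eta: basal effector kill strength; sweep values 0.01/0.025
  alphaE: avidity-ramp steepness; calibrated to the disease time course
  betaE: avidity-ramp midpoint; calibrated to 24.3-week onset
  sE: effector scaling in the kill saturation; calibrated to the 539 mg/dl diseased
    equilibrium
  sR: regulatory scaling in the kill saturation; calibrated
  w: apoptotic-wave scale (default study condition 0.75)
  d: apoptotic->necrotic decay; Maree-type estimate
  Bconv: beta cells per mg islet mass (beta-cell volume ~1.1 pl)
  Qpanc: effective distribution volume of the compartment; see docs/methods.md
  Dss: resident DC pool capacity; calibrated
  ftD: '0.382 x fMa(Balb/c): immature/tolerogenic DC engulfment (assay-derived ratio)'
  fD: '0.0549 x fMa(Balb/c): immunogenic DC engulfment (assay-derived ratio)'
  bDE: DC removal by effector T cells; calibrated
  bIR: tDC removal by regulatory T cells; calibrated
  muD: DC death rate; calibrated (days-to-weeks DC residence)
  R0: hepatic glucose production (Topp)
  G0: insulin-independent glucose uptake (Topp)
  SI: insulin sensitivity (Topp)
  sigmaI: max insulin secretion per mg beta cells; scaled to ~2 mg healthy beta mass
  GI: half-max glucose for insulin secretion (Topp, alpha^2 = 20,000)
  deltaI: insulin clearance (Topp)
  aE: effector naive homeostasis; calibrated
  aR: regulatory naive homeostasis; calibrated
  Tnaive: naive T-cell reference level; calibrated
  bP: DC-driven T-cell proliferation (Ludewig-type saturating term); calibrated
  thetaD: DC half-saturation for proliferation; calibrated
  ram: memory conversion rate; calibrated
  bE: memory reactivation by immunogenic DCs; calibrated
  bR: memory reactivation by tolerogenic DCs; calibrated
  muE: suppression of effectors by regulatory cells; calibrated
  muR: suppression of regulatory cells by effectors; calibrated
  aEm: memory T-cell death rate; calibrated
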