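"""Core single-compartment ODE model of type-1-diabetes initiation.

The model couples five interacting subsystems inside one well-mixed
pancreatic compartment:

* resting/activated macrophages (``M``, ``Ma``) that clear dying β-cells,
* healthy/apoptotic/necrotic β-cells (``B``, ``Ba``, ``Bn``),
* glucose and insulin (``G``, ``I``; Topp-style kinetics),
* immunogenic and tolerogenic dendritic cells (``D``, ``tD``) drawn from a
  fixed resident pool of capacity ``Dss``,
* effector, regulatory and memory T cells (``E``, ``R``, ``Em``).

Healthy β-cell mass is measured in mg; every cell population is a
concentration in cells/ml, glucose in mg/dl, insulin in μU.  The factor
``Bconv/Qpanc`` converts β-cell mass fluxes (mg/day) into cells/ml/day when
they feed the apoptotic pool.

Disease initiation follows the Copenhagen hypothesis: strains differ only
in their macrophage clearance rates ``fM``/``fMa``; slow clearance lets
apoptotic cells become necrotic, necrotic debris matures dendritic cells,
mature DCs expand effector T cells, and effector T cells kill more β-cells.
A transient developmental apoptotic wave around day 9 provides the trigger.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "STATE_NAMES",
    "ParameterSet",
    "StateVector",
    "MousePreset",
    "NOD",
    "BALBC",
    "k1",
    "k2",
    "eta_e",
    "apoptotic_wave",
    "rhs",
    "make_rhs",
    "macrophage_resting_equilibrium",
    "topp_glucose_equilibrium",
]

#: Canonical state ordering used by every array-based interface.
STATE_NAMES = ("M", "Ma", "B", "Ba", "Bn", "G", "I", "D", "tD", "E", "R", "Em")


# ---------------------------------------------------------------------------
# auxiliary response functions
# ---------------------------------------------------------------------------

def k1(G: float, Ghalf: float):
    """Saturating glucose response G²/(G² + Ghalf²), in [0, 1).

    Used both for glucose-dependent β-cell growth (half-max ``Ghb``) and for
    glucose-dependent insulin secretion (half-max ``GI``).
    """
    G = np.asarray(G, dtype=float)
    if np.any(G < 0):
        raise ValueError("glucose must be nonnegative")
    if Ghalf <= 0:
        raise ValueError("half-max glucose must be positive")
    out = G * G / (G * G + Ghalf * Ghalf)
    return float(out) if out.ndim == 0 else out


def k2(E: float, R: float, sE: float, sR: float):
    """Effector-driven β-cell apoptosis fraction, damped by regulatory cells.

    (sE·E)² / (1 + (sE·E)² + (sR·R)²): increasing in E, decreasing in R,
    bounded in [0, 1).
    """
    E = np.asarray(E, dtype=float)
    R = np.asarray(R, dtype=float)
    if np.any(E < 0) or np.any(R < 0):
        raise ValueError("T-cell concentrations must be nonnegative")
    e2 = (sE * E) ** 2
    r2 = (sR * R) ** 2
    out = e2 / (1.0 + e2 + r2)
    return float(out) if out.ndim == 0 else out


def eta_e(t, eta: float, alphaE: float, betaE: float):
    """Time-ramped effector kill strength η + 2η(1 + tanh(αe(t − βe))).

    Monotone nondecreasing in t, rising from η (t → −∞) through 3η at
    t = βe to 5η (t → +∞); models increasing effector T-cell avidity as the
    autoreactive repertoire matures.
    """
    t = np.asarray(t, dtype=float)
    out = eta + 2.0 * eta * (1.0 + np.tanh(alphaE * (t - betaE)))
    return float(out) if out.ndim == 0 else out


def apoptotic_wave(B, t, w: float):
    """Developmental β-cell apoptosis wave 0.1·w·B·exp(−((t−9)/9)²), mg/day.

    Peaks at day 9 at 10% of the β-cell mass per day (for w = 1) and decays
    on a ~9-day scale, emulating the neonatal remodeling wave in rodents.
    """
    B = np.asarray(B, dtype=float)
    t = np.asarray(t, dtype=float)
    if np.any(B < 0):
        raise ValueError("beta-cell mass must be nonnegative")
    z = (t - 9.0) / 9.0
    out = 0.1 * w * B * np.exp(-z * z)
    if out.ndim == 0:
        return float(out)
    return out


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

_POSITIVE = ("Qpanc", "Bconv", "Dss", "thetaD", "Ghb", "GI")


@dataclass(frozen=True)
class ParameterSet:
    """All rate constants and scaling factors of the full model.

    Default values form the packaged registry: macrophage kinetics follow
    Marée et al.'s NOD/Balb/c phagocytosis work, the glucose–insulin block
    follows Topp et al., T-cell terms follow Ludewig-type DC-driven kinetics,
    and the remaining immune couplings are calibrated so that the packaged
    presets reproduce the documented natural histories (see docs/methods.md).
    Clearance presets live in :class:`MousePreset`, not here.
    """

    # macrophages (ml-based concentrations, rates per day)
    J: float = 5.0e4        # resting macrophage influx, cells/ml/day
    k: float = 0.4          # Ma -> M deactivation, 1/day
    b: float = 0.09         # Ma-driven recruitment of M, 1/day
    c: float = 0.1          # macrophage egress, 1/day
    e1: float = 1.0e-8      # crowding of M, ml/cell/day
    e2: float = 1.0e-8      # crowding of Ma, ml/cell/day
    fM: float = 1.0e-5      # resting-macrophage clearance, ml/cell/day (NOD)
    fMa: float = 1.0e-5     # activated-macrophage clearance, ml/cell/day (NOD)

    # healthy beta cells
    alphaB: float = 0.0587  # max glucose-driven growth, 1/day
    deltaB: float = 1.0 / 60.0  # natural turnover, 1/day
    Ghb: float = 141.421356  # half-max glucose for growth, mg/dl
    eta: float = 0.01       # basal effector kill strength, 1/day
    alphaE: float = 0.039247    # avidity ramp steepness, 1/day
    betaE: float = 104.83    # avidity ramp midpoint, days
    sE: float = 1.0982e-4      # effector scaling inside K2, ml/cell
    sR: float = 2.4233e-5      # regulatory scaling inside K2, ml/cell
    w: float = 0.75         # apoptotic wave scale, dimensionless
    d: float = 0.5          # apoptotic -> necrotic decay, 1/day
    Bconv: float = 8.7e5    # beta cells per mg of islet mass, cells/mg
    Qpanc: float = 5.0      # compartment distribution volume, ml

    # dendritic cells
    Dss: float = 2.0576e5      # resident DC pool capacity, cells/ml
    ftD: float = 1.9100e-5  # immature/tolerogenic DC engulfment, ml/cell/day
    fD: float = 2.7450e-6   # immunogenic DC engulfment, ml/cell/day
    bDE: float = 1.9087e-7     # DC removal by effector T cells, ml/cell/day
    bIR: float = 7.6207e-5     # tDC removal by regulatory T cells, ml/cell/day
    muD: float = 0.014617       # DC death, 1/day

    # glucose / insulin (Topp)
    R0: float = 864.0       # hepatic glucose production, mg/dl/day
    G0: float = 1.44        # insulin-independent uptake, 1/day
    SI: float = 0.72        # insulin sensitivity, ml/μU/day
    sigmaI: float = 8743.7  # max secretion per mg beta cells, μU/mg/day
    GI: float = 141.421356  # half-max glucose for secretion, mg/dl
    deltaI: float = 432.0   # insulin decay, 1/day

    # T cells
    aE: float = 3.1271e-3        # effector naive homeostasis, 1/day
    aR: float = 2.0508e-3        # regulatory naive homeostasis, 1/day
    Tnaive: float = 8806.5   # naive reference level, cells/ml
    bP: float = 0.63799        # DC-driven proliferation, 1/day
    thetaD: float = 2.0422e4   # DC half-saturation, cells/ml
    ram: float = 0.017060       # memory conversion, 1/day
    bE: float = 1.9131e-5      # memory reactivation by D, ml/cell/day
    bR: float = 1.9216e-6      # memory reactivation by tD, ml/cell/day
    muE: float = 3.2024e-5     # suppression of E by R, ml/cell/day
    muR: float = 4.4400e-5     # suppression of R by E, ml/cell/day
    aEm: float = 5.5865e-3       # memory death, 1/day

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v):
                raise ValueError(f"parameter {f.name} must be finite")
            if v < 0:
                raise ValueError(f"parameter {f.name} must be nonnegative")
        for name in _POSITIVE:
            if getattr(self, name) <= 0:
                raise ValueError(f"parameter {name} must be positive")

    def with_preset(self, preset: "MousePreset") -> "ParameterSet":
        """Return a copy with the preset's clearance rates and wave scale."""
        return replace(self, fM=preset.fM, fMa=preset.fMa, w=preset.w)

    def replace(self, **kwargs) -> "ParameterSet":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True)
class MousePreset:
    """Strain preset: the two macrophage clearance rates plus wave settings.

    NOD and Balb/c differ only in fM and fMa; DC/tDC clearance is shared.
    """

    name: str
    fM: float
    fMa: float
    wave_on: bool = True
    w: float = 0.75

    def __post_init__(self) -> None:
        if self.fM < 0 or self.fMa < 0:
            raise ValueError("clearance rates must be nonnegative")
        if self.w < 0:
            raise ValueError("wave scale must be nonnegative")
        if not self.wave_on:
            object.__setattr__(self, "w", 0.0)


#: Diabetes-prone strain: impaired clearance by both macrophage classes.
NOD = MousePreset(name="NOD", fM=1.0e-5, fMa=1.0e-5)
#: Non-diabetes-prone control strain.
BALBC = MousePreset(name="Balbc", fM=2.0e-5, fMa=5.0e-5)


# ---------------------------------------------------------------------------
# state vector
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StateVector:
    """The twelve model compartments.

    All populations in cells/ml except B (mg), G (mg/dl) and I (μU).
    """

    M: float = 0.0
    Ma: float = 0.0
    B: float = 0.0
    Ba: float = 0.0
    Bn: float = 0.0
    G: float = 0.0
    I: float = 0.0
    D: float = 0.0
    tD: float = 0.0
    E: float = 0.0
    R: float = 0.0
    Em: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in STATE_NAMES], dtype=float)

    @classmethod
    def from_array(cls, y: Sequence[float]) -> "StateVector":
        y = np.asarray(y, dtype=float)
        if y.shape != (12,):
            raise ValueError("state array must have 12 components")
        return cls(**dict(zip(STATE_NAMES, map(float, y))))

    def validate(self, Dss: float, tol: float = 0.0) -> None:
        """Raise if any component is negative or the DC pool overflows."""
        for n in STATE_NAMES:
            if getattr(self, n) < -tol:
                raise ValueError(f"state component {n} is negative")
        if self.D + self.tD > Dss + tol:
            raise ValueError("D + tD exceeds the resident DC capacity Dss")


# ---------------------------------------------------------------------------
# right-hand side
# ---------------------------------------------------------------------------

def make_rhs(p: ParameterSet, wave_scale: float | None = None) -> Callable:
    """Build a fast ``f(t, y) -> dy/dt`` closure for the 12-D system.

    ``wave_scale`` overrides ``p.w`` (pass 0.0 to disable the wave).
    """
    J, k, b, c = p.J, p.k, p.b, p.c
    e1, e2 = p.e1, p.e2
    fM, fMa = p.fM, p.fMa
    alphaB, deltaB = p.alphaB, p.deltaB
    Ghb2 = p.Ghb * p.Ghb
    eta, alphaE, betaE = p.eta, p.alphaE, p.betaE
    sE, sR = p.sE, p.sR
    w = p.w if wave_scale is None else float(wave_scale)
    d = p.d
    S = p.Bconv / p.Qpanc  # mg -> cells/ml conversion for B-sourced fluxes
    Dss, ftD, fD = p.Dss, p.ftD, p.fD
    bDE, bIR, muD = p.bDE, p.bIR, p.muD
    R0, G0, SI = p.R0, p.G0, p.SI
    sigmaI, GI2, deltaI = p.sigmaI, p.GI * p.GI, p.deltaI
    aE, aR, Tnaive = p.aE, p.aR, p.Tnaive
    bP, thetaD, ram = p.bP, p.thetaD, p.ram
    bE, bR, muE, muR, aEm = p.bE, p.bR, p.muE, p.muR, p.aEm
    tanh, exp = math.tanh, math.exp

    def f(t, y):
        M, Ma, B, Ba, Bn, G, I, D, tD, E, R, Em = y

        G2 = G * G
        k1b = G2 / (G2 + Ghb2)          # growth response
        k1i = G2 / (G2 + GI2)           # secretion response
        sEE2 = (sE * E) ** 2
        kill = (eta + 2.0 * eta * (1.0 + tanh(alphaE * (t - betaE)))) * (
            sEE2 / (1.0 + sEE2 + (sR * R) ** 2)
        )
        z = (t - 9.0) / 9.0
        wave = 0.1 * w * B * exp(-z * z)

        crowd = M + Ma
        engulf_M = fM * M * (Ba + Bn)
        dM = J + (k + b) * Ma - c * M - engulf_M - e1 * M * crowd
        dMa = engulf_M - k * Ma - e2 * Ma * crowd

        dB = alphaB * k1b * B - deltaB * B - kill * B - wave

        clear_a = d + fM * M + fMa * Ma + ftD * (Dss - D) + fD * D
        dBa = (deltaB * B + kill * B + wave) * S - clear_a * Ba
        clear_n = fM * M + fMa * Ma + ftD * (Dss - D) + fD * D
        dBn = d * Ba - clear_n * Bn

        dG = R0 - (G0 + SI * I) * G
        dI = sigmaI * k1i * B - deltaI * I

        iD = Dss - D - tD
        dD = ftD * Bn * (iD + tD) - bDE * E * D - muD * D
        dtD = ftD * Ba * iD - ftD * Bn * tD - bIR * R * tD - muD * tD

        dE = (aE * (Tnaive - E) + bP * D * E / (thetaD + D) - ram * E
              + bE * D * Em - muE * E * R)
        dR = (aR * (Tnaive - R) + bP * tD * R / (thetaD + tD) - ram * R
              + bR * tD * Em - muR * E * R)
        dEm = ram * (E + R) - (aEm + bE * D + bR * tD) * Em

        return (dM, dMa, dB, dBa, dBn, dG, dI, dD, dtD, dE, dR, dEm)

    return f


def rhs(t: float, state, p: ParameterSet, wave_scale: float | None = None):
    """Time-derivative of the full system at one point.

    ``state`` may be a :class:`StateVector` or a 12-array in ``STATE_NAMES``
    order; the return type mirrors the input.
    """
    is_sv = isinstance(state, StateVector)
    y = state.as_array() if is_sv else np.asarray(state, dtype=float)
    if y.shape != (12,):
        raise ValueError("state must have 12 components")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite state passed to rhs")
    dy = np.array(make_rhs(p, wave_scale)(float(t), y))
    return StateVector.from_array(dy) if is_sv else dy


# ---------------------------------------------------------------------------
# closed-form anchors used for initialisation and testing
# ---------------------------------------------------------------------------

def macrophage_resting_equilibrium(p: ParameterSet) -> float:
    """Resting-macrophage level with no dying cells: J = c·M + e1·M²."""
    return float((-p.c + math.sqrt(p.c * p.c + 4.0 * p.e1 * p.J)) / (2.0 * p.e1))


def topp_glucose_equilibrium(p: ParameterSet, B: float) -> tuple[float, float]:
    """Glucose/insulin steady state for a frozen β-cell mass ``B``.

    Solves R0 = (G0 + SI·I*)·G* with I* = σI·K1(G*, GI)·B/δI.  Returns
    (G*, I*).  Used as the algebraic oracle for the metabolic subsystem.
    """
    from scipy.optimize import brentq

    def resid(G):
        I = p.sigmaI * k1(G, p.GI) * B / p.deltaI
        return p.R0 - (p.G0 + p.SI * I) * G

    G_hi = p.R0 / p.G0  # insulin-free ceiling
    G = brentq(resid, 1e-6, G_hi, xtol=1e-10, rtol=1e-12)
    I = p.sigmaI * k1(G, p.GI) * B / p.deltaI
    return float(G), float(I)
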