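"""Stiff integration of the disease model with impulse tDC dosing.

The simulator integrates the 12-compartment system with LSODA at tight
tolerances, restarts the integrator at every injection time (adding the
dose to the tolerogenic-DC compartment), exposes dense output for event
refinement, and classifies runs against the 250 mg/dl diabetic glucose
threshold.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .core_model import (
    STATE_NAMES,
    BALBC,
    NOD,
    MousePreset,
    ParameterSet,
    StateVector,
    macrophage_resting_equilibrium,
    make_rhs,
    topp_glucose_equilibrium,
)

__all__ = [
    "DoseSchedule",
    "Trajectory",
    "OutcomeRecord",
    "SimulationError",
    "DIABETIC_THRESHOLD",
    "RATIO_FLOOR",
    "simulate",
    "detect_threshold_crossing",
    "classify_outcome",
    "steady_state",
    "equilibrate_initial_state",
    "default_initial_state",
]

#: Glucose level marking entry into a full diabetic state, mg/dl.
DIABETIC_THRESHOLD = 250.0

#: Denominator floor used when reporting cell ratios (never in dynamics).
RATIO_FLOOR = 1e-9

#: Dose range (cells) studied by the treatment experiments; schedules
#: outside it trigger a warning, not an error.
STUDIED_DOSE_RANGE = (1e4, 5e6)

# Per-state absolute tolerance scales (same order as STATE_NAMES).  B is in
# mg while cell pools are in cells/ml, so a single scalar atol is wrong by
# many orders of magnitude.
_ATOL_SCALE = np.array(
    [1e5, 1e5, 1.0, 1e3, 1e2, 1e2, 10.0, 1e4, 1e4, 1e4, 1e4, 1e4]
)

_NEG_GUARD = 1e-6  # relative negativity treated as integration failure


class SimulationError(RuntimeError):
    """Solver failure, NaN state or tolerance breach during a run."""


@dataclass(frozen=True)
class DoseSchedule:
    """Timed impulse additions of tolerogenic DCs.

    ``events`` is a sequence of (time_days, dose_cells) with strictly
    increasing times and positive doses; the dose is a whole-animal cell
    count that the simulator converts to cells/ml via ``Qpanc``.
    """

    events: tuple[tuple[float, float], ...]
    target: str = "tD"

    def __init__(self, events: Iterable[Sequence[float]], target: str = "tD"):
        ev = tuple((float(t), float(dose)) for t, dose in events)
        if any(dose <= 0 for _, dose in ev):
            raise ValueError("doses must be positive")
        times = [t for t, _ in ev]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("dose times must be strictly increasing")
        if target != "tD":
            raise ValueError("only tolerogenic-DC dosing is supported")
        lo, hi = STUDIED_DOSE_RANGE
        for _, dose in ev:
            if not (lo <= dose <= hi):
                warnings.warn(
                    f"dose {dose:g} cells is outside the studied range "
                    f"[{lo:g}, {hi:g}]", stacklevel=2)
        object.__setattr__(self, "events", ev)
        object.__setattr__(self, "target", target)

    @classmethod
    def single(cls, time_days: float, dose_cells: float) -> "DoseSchedule":
        return cls([(time_days, dose_cells)])

    @classmethod
    def weekly(cls, start_days: float, total_dose_cells: float,
               n_doses: int = 4) -> "DoseSchedule":
        """Total dose split into ``n_doses`` equal weekly injections."""
        per = total_dose_cells / n_doses
        return cls([(start_days + 7.0 * i, per) for i in range(n_doses)])


@dataclass
class Trajectory:
    """Time-indexed solution plus dense interpolants per dose segment."""

    times: np.ndarray                 # days
    states: np.ndarray                # (n_times, 12) in STATE_NAMES order
    params: ParameterSet
    preset: MousePreset | None = None
    flags: list = field(default_factory=list)
    _segments: list = field(default_factory=list, repr=False)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.states[:, STATE_NAMES.index(name)]

    def ratio(self, num: str, den: str) -> np.ndarray:
        """Reported cell ratio with a denominator floor (plotting only)."""
        return self[num] / np.maximum(self[den], RATIO_FLOOR)

    @property
    def derived(self) -> dict:
        return {
            "R/E": self.ratio("R", "E"),
            "tD/D": self.ratio("tD", "D"),
            "Ba/Bn": self.ratio("Ba", "Bn"),
        }

    def glucose_dense(self, t: float) -> float:
        """Glucose from the dense solver output at arbitrary ``t`` (days)."""
        g_idx = STATE_NAMES.index("G")
        for t0, t1, sol in self._segments:
            if t0 <= t <= t1:
                return float(sol(t)[g_idx])
        raise ValueError(f"t={t} outside the integrated horizon")

    def state_at(self, t: float) -> StateVector:
        for t0, t1, sol in self._segments:
            if t0 <= t <= t1:
                return StateVector.from_array(np.asarray(sol(t), dtype=float))
        raise ValueError(f"t={t} outside the integrated horizon")

    def to_frame(self):
        """Long trajectory table: time_days, 12 states, 3 reported ratios."""
        import pandas as pd

        data = {"time_days": self.times}
        for i, n in enumerate(STATE_NAMES):
            data[n] = self.states[:, i]
        for key, val in self.derived.items():
            data[key.replace("/", "_over_")] = val
        return pd.DataFrame(data)


@dataclass(frozen=True)
class OutcomeRecord:
    """Long-run classification of a single simulated mouse.

    Region I: never crossed the diabetic threshold.  Region II: crossed at
    some point but recovered below it by the evaluation time.  Region III:
    glucose at or above threshold at evaluation (diabetic).
    """

    region: str
    first_crossing_weeks: float | None
    terminal_glucose: float
    eval_time_weeks: float

    def __post_init__(self):
        if self.region not in ("I", "II", "III"):
            raise ValueError("region must be one of I, II, III")


def _resolve(p: ParameterSet | None, preset: MousePreset | None,
             wave_scale: float | None) -> tuple[ParameterSet, float]:
    if p is None:
        p = ParameterSet()
    if preset is not None:
        p = p.with_preset(preset)
    w = p.w if wave_scale is None else float(wave_scale)
    return p, w


def _check_segment(y: np.ndarray, p: ParameterSet, flags: list) -> None:
    if not np.all(np.isfinite(y)):
        raise SimulationError("non-finite state encountered")
    neg = y < -_NEG_GUARD * _ATOL_SCALE
    if np.any(neg):
        bad = [STATE_NAMES[i] for i in np.nonzero(neg.any(axis=0))[0]] \
            if y.ndim == 2 else [STATE_NAMES[i] for i in np.nonzero(neg)[0]]
        raise SimulationError(f"negative state beyond tolerance: {bad}")
    pool = y[..., 7] + y[..., 8] - p.Dss
    if np.any(pool > _NEG_GUARD * p.Dss):
        flags.append("DC pool exceeded capacity beyond tolerance")


def simulate(
    p: ParameterSet | None = None,
    preset: MousePreset | None = None,
    schedule: DoseSchedule | None = None,
    horizon: float = 280.0,
    init: StateVector | None = None,
    wave_scale: float | None = None,
    rtol: float = 1e-8,
    t_eval_step: float = 1.0,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate the model for ``horizon`` days with optional impulse dosing.

    At each dose time the integration halts, ``dose/Qpanc`` is added to the
    tolerogenic-DC compartment (truncated so D + tD never exceeds the
    resident capacity ``Dss``; any spill is recorded in ``flags``), and
    integration restarts.  Daily samples are returned along with dense
    interpolants for event refinement.
    """
    p, w = _resolve(p, preset, wave_scale)
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    if init is None:
        init = default_initial_state(p, wave_scale=w, preset=preset)
    y = init.as_array().copy()
    init.validate(p.Dss, tol=1e-9)

    events = list(schedule.events) if schedule is not None else []
    if any(t >= horizon for t, _ in events):
        raise ValueError("dose times must precede the horizon")
    breaks = [0.0] + [t for t, _ in events] + [float(horizon)]
    doses = {t: dose for t, dose in events}

    f = make_rhs(p, wave_scale=w)
    atol = _ATOL_SCALE * rtol
    flags: list = []
    all_t, all_y, segments = [], [], []

    for t0, t1 in zip(breaks, breaks[1:]):
        if t0 in doses:
            y[8] += doses[t0] / p.Qpanc
            spill = y[7] + y[8] - p.Dss
            if spill > 0:
                flags.append(
                    f"dose at day {t0:g} truncated: {spill:.3g} cells/ml "
                    "spilled over the DC capacity")
                y[8] = p.Dss - y[7]
        if t1 <= t0:
            continue
        n = max(2, int(math.ceil((t1 - t0) / t_eval_step)) + 1)
        t_eval = np.linspace(t0, t1, n)
        sol = solve_ivp(f, (t0, t1), y, method=method, rtol=rtol, atol=atol,
                        t_eval=t_eval, dense_output=True)
        if not sol.success:
            raise SimulationError(f"solver failed on [{t0}, {t1}]: {sol.message}")
        _check_segment(sol.y.T, p, flags)
        segments.append((t0, t1, sol.sol))
        skip = 1 if all_t else 0  # avoid duplicating the segment join
        all_t.append(sol.t[skip:])
        all_y.append(sol.y.T[skip:])
        y = sol.y[:, -1].copy()

    return Trajectory(
        times=np.concatenate(all_t),
        states=np.concatenate(all_y),
        params=p,
        preset=preset,
        flags=flags,
        _segments=segments,
    )


def detect_threshold_crossing(
    traj: Trajectory, threshold: float = DIABETIC_THRESHOLD
) -> float | None:
    """First upward crossing of glucose through ``threshold``, in weeks.

    Located between samples by root refinement on the dense output;
    ``None`` if glucose never rises through the threshold.
    """
    G = traj["G"]
    t = traj.times
    below = G < threshold
    for i in range(len(t) - 1):
        if below[i] and G[i + 1] >= threshold:
            if traj._segments:
                t_star = brentq(
                    lambda x: traj.glucose_dense(x) - threshold,
                    t[i], t[i + 1], xtol=1e-8)
            else:  # pure sampled trajectory: linear interpolation
                frac = (threshold - G[i]) / (G[i + 1] - G[i])
                t_star = t[i] + frac * (t[i + 1] - t[i])
            return float(t_star) / 7.0
    if G[0] >= threshold:
        return 0.0
    return None


def classify_outcome(
    traj: Trajectory,
    threshold: float = DIABETIC_THRESHOLD,
    eval_time_weeks: float | None = None,
) -> OutcomeRecord:
    """Assign the run to outcome region I, II or III at ``eval_time_weeks``.

    A terminal glucose at or above the threshold counts as diabetic (III);
    otherwise a past crossing yields II (recovered hyperglycemic episode)
    and no crossing yields I.
    """
    if eval_time_weeks is None:
        eval_time_weeks = traj.times[-1] / 7.0
    t_eval = eval_time_weeks * 7.0
    if t_eval > traj.times[-1] + 1e-9:
        raise ValueError("trajectory horizon shorter than evaluation time")
    terminal = (traj.glucose_dense(t_eval) if traj._segments
                else float(np.interp(t_eval, traj.times, traj["G"])))
    crossing = detect_threshold_crossing(traj, threshold)
    if crossing is not None and crossing > eval_time_weeks:
        crossing = None
    if terminal >= threshold:
        region = "III"
    elif crossing is not None:
        region = "II"
    else:
        region = "I"
    return OutcomeRecord(
        region=region,
        first_crossing_weeks=crossing,
        terminal_glucose=float(terminal),
        eval_time_weeks=float(eval_time_weeks),
    )


def steady_state(
    p: ParameterSet | None = None,
    preset: MousePreset | None = None,
    horizon: float = 2000.0,
    init: StateVector | None = None,
    wave_scale: float | None = None,
    rel_tol: float = 1e-8,
    chunk: float = 250.0,
) -> tuple[StateVector, bool]:
    """Integrate until the state stops moving; returns (state, converged).

    Convergence: max over components of |dy/dt| / max(|y|, scale) below
    ``rel_tol`` at the end of an integration chunk.
    """
    p, w = _resolve(p, preset, wave_scale)
    if init is None:
        init = default_initial_state(p, wave_scale=w, preset=preset)
    f = make_rhs(p, wave_scale=w)
    y = init.as_array().copy()
    atol = _ATOL_SCALE * 1e-8
    t = 0.0
    converged = False
    while t < horizon:
        t1 = min(t + chunk, horizon)
        sol = solve_ivp(f, (t, t1), y, method="LSODA", rtol=1e-8, atol=atol)
        if not sol.success:
            raise SimulationError(f"solver failed in steady_state: {sol.message}")
        y = sol.y[:, -1]
        t = t1
        dy = np.abs(np.array(f(t, y)))
        rel = dy / np.maximum(np.abs(y), _ATOL_SCALE)
        if float(rel.max()) < rel_tol:
            converged = True
            break
    return StateVector.from_array(y), converged


# ---------------------------------------------------------------------------
# initial conditions
# ---------------------------------------------------------------------------

#: Healthy (full) β-cell mass used to seed simulations, mg.
FULL_BETA_MASS = 2.0


def equilibrate_initial_state(
    p: ParameterSet,
    B0: float = FULL_BETA_MASS,
    days: float = 50.0,
    wave_scale: float = 0.0,
) -> StateVector:
    """Default initial condition: short wave-free equilibration at fixed B.

    Starting from the macrophage/metabolic resting levels with no immune
    engagement, the system is integrated for ``days`` with the β-cell mass
    clamped at ``B0`` and the wave off; the terminal state (with B released
    at ``B0``) seeds production runs, so D(0)/tD(0)/T-cell levels reflect
    each strain's basal clearance burden.
    """
    M0 = macrophage_resting_equilibrium(p)
    G0, I0 = topp_glucose_equilibrium(p, B0)
    y = np.zeros(12)
    y[0], y[2], y[5], y[6] = M0, B0, G0, I0

    base = make_rhs(p, wave_scale=wave_scale)
    iB = STATE_NAMES.index("B")

    def clamped(t, y):
        dy = list(base(t, y))
        dy[iB] = 0.0
        return dy

    sol = solve_ivp(clamped, (0.0, days), y, method="LSODA",
                    rtol=1e-8, atol=_ATOL_SCALE * 1e-8)
    if not sol.success:
        raise SimulationError("equilibration failed: " + sol.message)
    out = sol.y[:, -1].copy()
    out[iB] = B0
    return StateVector.from_array(out)


_INIT_CACHE: dict = {}


def default_initial_state(
    p: ParameterSet,
    wave_scale: float = 0.0,
    preset: MousePreset | None = None,
) -> StateVector:
    """Preset initial condition (stored in the preset file when available).

    Falls back to :func:`equilibrate_initial_state`; results are cached on
    the parameter values so sweeps do not re-equilibrate.
    """
    if preset is not None:
        from .io_cli import stored_initial_state

        stored = stored_initial_state(preset.name, p)
        if stored is not None:
            return stored
    key = tuple(sorted(p.to_dict().items()))
    if key not in _INIT_CACHE:
        _INIT_CACHE[key] = equilibrate_initial_state(p)
    return _INIT_CACHE[key]
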