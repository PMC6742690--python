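"""In-silico studies: local sensitivity, clearance-rate maps, dosing sweeps.

Three experiment families drive the model:

* one-at-a-time ±5% perturbations of the macrophage clearance rates, scored
  as percent glucose change at a set of evaluation weeks;
* Latin-hypercube sweeps over the (fM, fMa) plane, classified at 1,000 days
  into outcome regions I/II/III with extraction of the "healthy boundary"
  between recovered (II) and diabetic (III) outcomes;
* tolerogenic-DC treatment sweeps over dose × start-time grids evaluated at
  85 weeks, yielding windows of opportunity and critical transition times.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .core_model import MousePreset, NOD, ParameterSet, StateVector
from .simulator import (
    DIABETIC_THRESHOLD,
    DoseSchedule,
    OutcomeRecord,
    SimulationError,
    classify_outcome,
    default_initial_state,
    detect_threshold_crossing,
    simulate,
)

__all__ = [
    "SensitivityResult",
    "RegionMap",
    "TreatmentMap",
    "LHS_BOUNDS",
    "oat_sensitivity",
    "lhs_sample",
    "clearance_heatmap",
    "treatment_sweep",
    "window_report",
]

#: Default clearance-rate sampling bounds (ml/cell/day).
LHS_BOUNDS = {"fM": (0.062e-4, 3.1e-4), "fMa": (0.062e-4, 1.2e-4)}

#: Alternate reading of the sampling bounds with the two intervals swapped;
#: selectable because the source ranges are stated inconsistently.
LHS_BOUNDS_SWAPPED = {"fM": (0.062e-4, 1.2e-4), "fMa": (0.062e-4, 3.1e-4)}

SENSITIVITY_WEEKS = (20, 25, 30, 35, 40)


# ---------------------------------------------------------------------------
# one-at-a-time sensitivity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SensitivityResult:
    """Percent glucose change for one parameter perturbation at one week."""

    parameter: str
    direction: str          # "+5%" or "-5%"
    eval_week: float
    percent_change: float | None   # None marks a failed perturbed run


def _glucose_at_weeks(traj, weeks):
    return np.array([traj.glucose_dense(wk * 7.0) for wk in weeks])


def oat_sensitivity(
    p: ParameterSet | None = None,
    preset: MousePreset = NOD,
    parameters: Sequence = (("fM", "fMa"), "fM", "fMa"),
    fraction: float = 0.05,
    weeks: Sequence[float] = SENSITIVITY_WEEKS,
    wave_scale: float | None = None,
) -> list[SensitivityResult]:
    """One-at-a-time local sensitivity of glucose to parameter changes.

    Each entry of ``parameters`` (a name, or a tuple of names perturbed
    jointly) is scaled by 1 ± ``fraction`` with everything else fixed; the
    result is 100·(G_perturbed − G_base)/G_base at each requested week.
    Both presets run with the apoptotic wave by default (the perturbation
    study conditions).  Failed perturbed runs yield ``None`` entries.
    """
    if p is None:
        p = ParameterSet()
    p = p.with_preset(preset)
    w = p.w if wave_scale is None else wave_scale
    horizon = max(weeks) * 7.0 + 1.0
    init = default_initial_state(p, preset=preset)
    base = simulate(p, horizon=horizon, init=init, wave_scale=w)
    g_base = _glucose_at_weeks(base, weeks)

    out: list[SensitivityResult] = []
    for group in parameters:
        names = (group,) if isinstance(group, str) else tuple(group)
        label = "+".join(names)
        for sign, tag in ((+1, f"+{fraction:.0%}"), (-1, f"-{fraction:.0%}")):
            factor = 1.0 + sign * fraction
            pert = p.replace(**{n: getattr(p, n) * factor for n in names})
            try:
                # perturbed clearance changes the pre-natal equilibration too
                init_p = default_initial_state(pert)
                traj = simulate(pert, horizon=horizon, init=init_p,
                                wave_scale=w)
                g_pert = _glucose_at_weeks(traj, weeks)
                changes = 100.0 * (g_pert - g_base) / g_base
            except SimulationError:
                changes = [None] * len(weeks)
            for wk, ch in zip(weeks, changes):
                out.append(SensitivityResult(
                    parameter=label, direction=tag, eval_week=float(wk),
                    percent_change=None if ch is None else float(ch)))
    return out


def sensitivity_table(results: list[SensitivityResult]):
    import pandas as pd
    return pd.DataFrame([r.__dict__ for r in results])


# ---------------------------------------------------------------------------
# Latin hypercube clearance sweep
# ---------------------------------------------------------------------------

def lhs_sample(
    bounds: dict | None = None,
    n_bins: int = 50,
    seed: int | None = None,
) -> np.ndarray:
    """Stratified clearance-rate pairs: full cross of two LHS marginals.

    Each marginal interval is split into ``n_bins`` equal-probability bins
    with one uniform draw per bin; the two stratified samples are then fully
    crossed, giving ``n_bins²`` (fM, fMa) pairs (2,500 at the default 50).
    """
    if bounds is None:
        bounds = LHS_BOUNDS
    if n_bins < 1:
        raise ValueError("n_bins must be at least 1")
    rng = np.random.default_rng(seed)
    marginals = {}
    for name in ("fM", "fMa"):
        lo, hi = bounds[name]
        edges = np.linspace(lo, hi, n_bins + 1)
        draws = rng.uniform(edges[:-1], edges[1:])
        marginals[name] = rng.permutation(draws)
    fM, fMa = np.meshgrid(marginals["fM"], marginals["fMa"], indexing="ij")
    return np.column_stack([fM.ravel(), fMa.ravel()])


@dataclass
class RegionMap:
    """Outcome classification over the (fM, fMa) plane at one (w, eta)."""

    pairs: np.ndarray               # (n, 2) clearance-rate pairs
    outcomes: list                  # OutcomeRecord or None (failed run)
    w: float
    eta: float
    eval_days: float

    @property
    def regions(self) -> np.ndarray:
        return np.array([o.region if o is not None else "failed"
                         for o in self.outcomes])

    def to_frame(self):
        import pandas as pd
        rec = []
        for (fM, fMa), o in zip(self.pairs, self.outcomes):
            rec.append({
                "fM": fM, "fMa": fMa, "w": self.w, "eta": self.eta,
                "region": o.region if o else "failed",
                "terminal_glucose": o.terminal_glucose if o else np.nan,
                "first_crossing_weeks":
                    (o.first_crossing_weeks if o else np.nan),
            })
        return pd.DataFrame(rec)

    def healthy_boundary(self) -> np.ndarray:
        """Approximate II/III ("healthy") boundary as (fM, fMa) midpoints.

        Marches each unique fMa row in increasing fM and records the
        midpoint of the first diabetic→non-diabetic transition.
        """
        pts = []
        regions = self.regions
        for fMa in np.unique(self.pairs[:, 1]):
            mask = self.pairs[:, 1] == fMa
            fMs = self.pairs[mask, 0]
            order = np.argsort(fMs)
            fMs, regs = fMs[order], regions[mask][order]
            for a, b, fa, fb in zip(regs[:-1], regs[1:], fMs[:-1], fMs[1:]):
                if a == "III" and b in ("I", "II"):
                    pts.append(((fa + fb) / 2.0, fMa))
                    break
        return np.array(pts) if pts else np.empty((0, 2))


def clearance_heatmap(
    pairs: np.ndarray,
    w_values: Sequence[float] = (0.0, 0.5, 1.0),
    eta_values: Sequence[float] = (0.01, 0.025),
    eval_days: float = 1000.0,
    p: ParameterSet | None = None,
    progress: bool = False,
) -> list[RegionMap]:
    """Classify every clearance pair at 1,000 days per (wave, eta) setting."""
    if p is None:
        p = ParameterSet()
    maps = []
    pairs = np.asarray(pairs, dtype=float)
    for w in w_values:
        for eta in eta_values:
            outcomes = []
            for i, (fM, fMa) in enumerate(pairs):
                pp = p.replace(fM=float(fM), fMa=float(fMa), eta=float(eta))
                try:
                    init = default_initial_state(pp)
                    traj = simulate(pp, horizon=eval_days, init=init,
                                    wave_scale=w, rtol=1e-6, t_eval_step=2.0)
                    outcomes.append(classify_outcome(
                        traj, eval_time_weeks=eval_days / 7.0))
                except SimulationError as err:
                    warnings.warn(f"run failed at fM={fM:g}, fMa={fMa:g}: {err}")
                    outcomes.append(None)
                if progress and i % 100 == 0:
                    print(f"  w={w} eta={eta}: {i}/{len(pairs)}", flush=True)
            maps.append(RegionMap(pairs=pairs, outcomes=outcomes, w=float(w),
                                  eta=float(eta), eval_days=float(eval_days)))
    return maps


# ---------------------------------------------------------------------------
# treatment sweeps
# ---------------------------------------------------------------------------

@dataclass
class TreatmentMap:
    """Effectiveness of tDC dosing over a dose × start-time grid.

    ``effective[i, j]`` is True when dose i started at day j leaves glucose
    below the diabetic threshold at the evaluation week; ``log_re[i, j]``
    is log10 of the regulatory-to-effector ratio at evaluation.
    """

    doses: np.ndarray               # cells
    start_days: np.ndarray
    effective: np.ndarray           # bool (n_doses, n_starts)
    log_re: np.ndarray              # float, same shape
    terminal_glucose: np.ndarray
    schedule_kind: str
    eval_weeks: float

    def windows(self, dose_index: int) -> list[tuple[float, float]]:
        """Maximal runs of consecutive effective start days for one dose."""
        eff = self.effective[dose_index]
        out, start = [], None
        for t, ok in zip(self.start_days, eff):
            if ok and start is None:
                start = t
            elif not ok and start is not None:
                out.append((start, prev))
                start = None
            prev = t
        if start is not None:
            out.append((start, self.start_days[-1]))
        return out

    def critical_transitions(self, dose_index: int) -> dict:
        """First effective start and first later ineffective start, weeks."""
        eff = self.effective[dose_index]
        days = self.start_days
        first_eff = next((d for d, ok in zip(days, eff) if ok), None)
        first_fail_after = None
        if first_eff is not None:
            seen = False
            for d, ok in zip(days, eff):
                if ok:
                    seen = True
                elif seen:
                    first_fail_after = d
                    break
        return {
            "first_effective_weeks":
                None if first_eff is None else first_eff / 7.0,
            "first_ineffective_after_weeks":
                None if first_fail_after is None else first_fail_after / 7.0,
        }

    def to_frame(self):
        import pandas as pd
        rec = []
        for i, dose in enumerate(self.doses):
            for j, day in enumerate(self.start_days):
                rec.append({"dose_cells": dose, "start_day": day,
                            "effective": bool(self.effective[i, j]),
                            "log10_RE": self.log_re[i, j],
                            "terminal_glucose": self.terminal_glucose[i, j]})
        return pd.DataFrame(rec)

    def criteria_disagreement(self) -> dict:
        """Cells where the glucose criterion and log10(R/E) > 0 disagree.

        The two effectiveness readings are near-equivalent for clear-cut
        rescues and failures but can part ways on slow-transit cells whose
        glucose dips below threshold at evaluation without a regulatory
        takeover; such cells are reported here rather than reconciled.
        """
        ratio_call = self.log_re > 0.0
        mask = ratio_call != self.effective
        cells = [
            {"dose_cells": float(self.doses[i]),
             "start_day": float(self.start_days[j]),
             "terminal_glucose": float(self.terminal_glucose[i, j]),
             "log10_RE": float(self.log_re[i, j])}
            for i, j in zip(*np.nonzero(mask))
        ]
        return {"fraction": float(mask.mean()), "cells": cells}


def _make_schedule(kind: str, start_day: float, dose: float) -> DoseSchedule:
    if kind == "single":
        return DoseSchedule.single(start_day, dose)
    if kind == "weekly4":
        return DoseSchedule.weekly(start_day, dose, n_doses=4)
    raise ValueError("schedule_kind must be 'single' or 'weekly4'")


def treatment_sweep(
    doses: Sequence[float],
    start_days: Sequence[float],
    schedule_kind: str = "single",
    eval_weeks: float = 85.0,
    p: ParameterSet | None = None,
    preset: MousePreset = NOD,
    wave_scale: float | None = None,
    progress: bool = False,
) -> TreatmentMap:
    """Simulate every (dose, start-day) cell and score effectiveness.

    Effectiveness is glucose below the 250 mg/dl threshold at ``eval_weeks``;
    log10(R/E) at evaluation is recorded alongside as the T-cell-ratio
    cross-check.  The NOD preset with the wave is the study condition.
    """
    if p is None:
        p = ParameterSet()
    p = p.with_preset(preset)
    w = p.w if wave_scale is None else wave_scale
    doses = np.asarray(list(doses), dtype=float)
    start_days = np.asarray(list(start_days), dtype=float)
    horizon = eval_weeks * 7.0 + 1.0
    init = default_initial_state(p, preset=preset)

    shape = (len(doses), len(start_days))
    eff = np.zeros(shape, dtype=bool)
    log_re = np.full(shape, np.nan)
    gterm = np.full(shape, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # out-of-range doses in wide sweeps
        for i, dose in enumerate(doses):
            for j, day in enumerate(start_days):
                sched = _make_schedule(schedule_kind, float(day), float(dose))
                try:
                    traj = simulate(p, schedule=sched, horizon=horizon,
                                    init=init, wave_scale=w, rtol=1e-6,
                                    t_eval_step=7.0)
                    s = traj.state_at(eval_weeks * 7.0)
                    gterm[i, j] = s.G
                    eff[i, j] = s.G < DIABETIC_THRESHOLD
                    log_re[i, j] = np.log10(max(s.R, 1e-9) / max(s.E, 1e-9))
                except SimulationError:
                    pass
            if progress:
                print(f"  dose {dose:g}: {i + 1}/{len(doses)}", flush=True)
    return TreatmentMap(doses=doses, start_days=start_days, effective=eff,
                        log_re=log_re, terminal_glucose=gterm,
                        schedule_kind=schedule_kind, eval_weeks=eval_weeks)


def window_report(tmap: TreatmentMap, p: ParameterSet | None = None,
                  preset: MousePreset = NOD) -> dict:
    """Per-dose windows of opportunity plus the untreated R/E overlay.

    Each dose row is labelled by its window count and placement:
    ``no-window``, ``single-late``, ``double`` or ``single-long``.
    """
    if p is None:
        p = ParameterSet()
    rows = []
    span = tmap.start_days[-1] - tmap.start_days[0]
    for i, dose in enumerate(tmap.doses):
        wins = tmap.windows(i)
        if not wins:
            label = "no-window"
        elif len(wins) >= 2:
            label = "double"
        else:
            w0, w1 = wins[0]
            frac = (w1 - w0) / max(span, 1.0)
            label = "single-long" if frac > 0.5 else "single-late"
        rows.append({
            "dose_cells": float(dose),
            "windows_weeks": [(a / 7.0, b / 7.0) for a, b in wins],
            "n_windows": len(wins),
            "label": label,
            **tmap.critical_transitions(i),
        })

    pp = p.with_preset(preset)
    init = default_initial_state(pp, preset=preset)
    untreated = simulate(pp, horizon=tmap.eval_weeks * 7.0 + 1.0, init=init)
    re = untreated.ratio("R", "E")
    return {
        "doses": rows,
        "untreated_RE": {"weeks": (untreated.times / 7.0).tolist(),
                         "ratio": re.tolist()},
    }
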