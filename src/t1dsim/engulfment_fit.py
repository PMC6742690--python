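"""Reduced phagocytosis-assay model and engulfment-rate estimation.

In the in-vitro assay emulated here, a phagocyte population (macrophages,
mature DCs or immature DCs, count ``P``) is co-cultured 1:1 with apoptotic
cells (``C(0) = P``) and the percentage of phagocytes that have engulfed at
least one cell is tracked over a few hours.  Mass-action kinetics

    dC/dt  = -gP * P * C,
    dPe/dt =  gP * (P - Pe) * C,

admit the closed forms  C(t) = P·exp(-gP·P·t)  and
Pe(t) = P·(1 - exp(exp(-gP·P·t) - 1)),  so percent phagocytosis saturates at
(1 - 1/e)·100 ≈ 63.2% regardless of the rate ``gP`` — which is why fitting
is restricted to the early (≤ 1 h) transient.

A single rate ``gP`` (ml/cell/hour) is estimated per cell type by maximum
likelihood under i.i.d. Gaussian observation noise on the percent scale,
sampled with a log-scale random-walk Metropolis chain.  Only the dimension-
less rate ratios gD/gMa and gtD/gMa are exported to the mouse disease model,
scaled by the activated-macrophage clearance rate fMa.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "AssayData",
    "SingleCellFit",
    "EngulfmentFit",
    "CELL_TYPES",
    "DEFAULT_RATIO_D",
    "DEFAULT_RATIO_TD",
    "assay_closed_form",
    "percent_phagocytosis",
    "assay_percent",
    "fit_mcmc",
    "fit_single",
    "scale_rates",
    "generate_synthetic_assay",
    "default_assay_suite",
]

CELL_TYPES = ("macrophage", "matureDC", "immatureDC")

#: Canonical human-derived engulfment-rate ratios (gD/gMa, gtD/gMa) used to
#: scale mouse DC clearance rates from the activated-macrophage rate.
DEFAULT_RATIO_D = 5.49e-2
DEFAULT_RATIO_TD = 3.82e-1

#: Fitting window, hours: beyond ~1 h percent phagocytosis saturates and the
#: likelihood becomes flat in the rate.
FIT_WINDOW_H = 1.0


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

def assay_closed_form(t, gP: float, P: float):
    """Closed-form (C, Pe) of the assay kinetics at time ``t`` (hours)."""
    t = np.asarray(t, dtype=float)
    if gP < 0 or P < 0 or np.any(t < 0):
        raise ValueError("t, gP and P must be nonnegative")
    u = np.exp(-gP * P * t)
    C = P * u
    Pe = P * (1.0 - np.exp(u - 1.0))
    if C.ndim == 0:
        return float(C), float(Pe)
    return C, Pe


def percent_phagocytosis(Pe, P: float):
    """ρ = Pe/P × 100%."""
    if P <= 0:
        raise ValueError("P must be positive")
    out = np.asarray(Pe, dtype=float) / P * 100.0
    return float(out) if out.ndim == 0 else out


def assay_percent(t, gP: float, P: float):
    """Percent phagocytosis predicted by the closed form."""
    _, Pe = assay_closed_form(t, gP, P)
    return percent_phagocytosis(Pe, P)


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AssayData:
    """One phagocytosis time course: times (h) and percent engulfed."""

    cell_type: str
    times: tuple
    percent: tuple
    P: float = 1.0e5  # phagocyte count; apoptotic cells seeded 1:1

    def __post_init__(self):
        if self.cell_type not in CELL_TYPES:
            raise ValueError(f"cell_type must be one of {CELL_TYPES}")
        t = np.asarray(self.times, dtype=float)
        rho = np.asarray(self.percent, dtype=float)
        if t.shape != rho.shape or t.ndim != 1:
            raise ValueError("times and percent must be 1-D and equal length")
        if np.any(t < 0):
            raise ValueError("times must be nonnegative")
        if np.any((rho < 0) | (rho > 100)):
            raise ValueError("percent phagocytosis must lie in [0, 100]")
        if self.P <= 0:
            raise ValueError("P must be positive")
        object.__setattr__(self, "times", tuple(map(float, t)))
        object.__setattr__(self, "percent", tuple(map(float, rho)))

    def window(self, max_hours: float = FIT_WINDOW_H) -> "AssayData":
        """Restrict to the early transient used for fitting."""
        keep = [(t, r) for t, r in zip(self.times, self.percent)
                if t <= max_hours]
        return AssayData(self.cell_type, tuple(t for t, _ in keep),
                         tuple(r for _, r in keep), self.P)

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({"cell_type": self.cell_type,
                             "time_h": self.times,
                             "percent": self.percent})


@dataclass(frozen=True)
class SingleCellFit:
    """Posterior summary for one cell type's engulfment rate."""

    cell_type: str
    g: float                  # MLE / max-posterior rate, ml/cell/hour
    sigma: float              # fitted observation noise, percent
    chain: np.ndarray = field(repr=False)  # (n, 2): log g, log sigma
    acceptance_rate: float = float("nan")
    seed: int | None = None
    flat_likelihood: bool = False

    def credible_interval(self, level: float = 0.90) -> tuple[float, float]:
        lo = (1.0 - level) / 2.0
        g = np.exp(self.chain[:, 0])
        return tuple(np.quantile(g, [lo, 1.0 - lo]))


@dataclass(frozen=True)
class EngulfmentFit:
    """Joint fit across cell types with the exported rate ratios."""

    gMa: float | None
    gD: float | None
    gtD: float | None
    fits: dict
    seed: int | None = None

    @property
    def ratio_D(self) -> float:
        if self.gMa is None or self.gD is None:
            return DEFAULT_RATIO_D
        return self.gD / self.gMa

    @property
    def ratio_tD(self) -> float:
        if self.gMa is None or self.gtD is None:
            return DEFAULT_RATIO_TD
        return self.gtD / self.gMa

    def to_dict(self) -> dict:
        return {
            "gMa": self.gMa, "gD": self.gD, "gtD": self.gtD,
            "ratio_D": self.ratio_D, "ratio_tD": self.ratio_tD,
            "seed": self.seed,
            "acceptance_rates": {c: f.acceptance_rate
                                 for c, f in self.fits.items()},
        }


# ---------------------------------------------------------------------------
# likelihood and Metropolis sampler
# ---------------------------------------------------------------------------

def _log_posterior(theta, t, rho, P, bounds):
    lg, ls = theta
    if not (bounds[0][0] <= lg <= bounds[0][1]
            and bounds[1][0] <= ls <= bounds[1][1]):
        return -np.inf
    g, sigma = math.exp(lg), math.exp(ls)
    pred = assay_percent(t, g, P)
    resid = rho - pred
    n = rho.size
    return float(-0.5 * np.sum(resid * resid) / (sigma * sigma)
                 - n * ls - 0.5 * n * math.log(2.0 * math.pi))


def fit_single(
    data: AssayData,
    prior_bounds: tuple | None = None,
    n_steps: int = 20_000,
    seed: int | None = None,
    step: float = 0.25,
    n_grid: int = 200,
) -> SingleCellFit:
    """Metropolis MCMC fit of one engulfment rate on the ≤1 h window.

    Flat prior on (log g, log σ) within ``prior_bounds`` (default: four
    orders of magnitude around a coarse grid-search initializer).  Returns
    the max-posterior sample; warns when acceptance falls below 5%.
    """
    win = data.window()
    t = np.asarray(win.times)
    rho = np.asarray(win.percent)
    if t.size < 3:
        raise ValueError("need at least 3 time points within the 1 h window")
    if np.allclose(rho, 0.0):
        raise ValueError("degenerate assay data: all percents are zero")

    plateau = (1.0 - math.exp(-1.0)) * 100.0
    flat = bool(np.all(np.abs(rho - plateau) < 1.0))
    if flat:
        warnings.warn(
            "assay data sit on the saturation plateau; the likelihood is "
            "flat in the rate and the fit is unidentifiable", stacklevel=2)

    rng = np.random.default_rng(seed)

    # coarse grid-search initializer for g
    g_grid = np.logspace(-10, -2, n_grid)
    sse = [np.sum((rho - assay_percent(t, g, win.P)) ** 2) for g in g_grid]
    g0 = float(g_grid[int(np.argmin(sse))])
    s0 = max(math.sqrt(min(sse) / t.size), 1e-3)
    if prior_bounds is None:
        prior_bounds = ((math.log(g0) - 2 * math.log(10),
                         math.log(g0) + 2 * math.log(10)),
                        (math.log(1e-3), math.log(50.0)))

    theta = np.array([math.log(g0), math.log(s0)])
    lp = _log_posterior(theta, t, rho, win.P, prior_bounds)
    chain = np.empty((n_steps, 2))
    n_acc = 0
    best_theta, best_lp = theta.copy(), lp
    for i in range(n_steps):
        prop = theta + step * rng.standard_normal(2)
        lp_prop = _log_posterior(prop, t, rho, win.P, prior_bounds)
        if math.log(rng.uniform()) < lp_prop - lp:
            theta, lp = prop, lp_prop
            n_acc += 1
            if lp > best_lp:
                best_theta, best_lp = theta.copy(), lp
        chain[i] = theta
    acc = n_acc / n_steps
    if acc < 0.05:
        warnings.warn(f"Metropolis acceptance rate {acc:.1%} below 5%: "
                      "chain may not be mixing", stacklevel=2)

    return SingleCellFit(
        cell_type=data.cell_type,
        g=float(math.exp(best_theta[0])),
        sigma=float(math.exp(best_theta[1])),
        chain=chain,
        acceptance_rate=acc,
        seed=seed,
        flat_likelihood=flat,
    )


_CELL_TO_RATE = {"macrophage": "gMa", "matureDC": "gD", "immatureDC": "gtD"}


def fit_mcmc(
    data: AssayData | Iterable[AssayData],
    prior_bounds: tuple | None = None,
    n_steps: int = 20_000,
    seed: int | None = None,
) -> EngulfmentFit:
    """Fit engulfment rates for one or several assay time courses.

    Per-cell-type chains get independent sub-seeds derived from ``seed``.
    """
    datasets = [data] if isinstance(data, AssayData) else list(data)
    if not datasets:
        raise ValueError("no assay data supplied")
    rates: dict = {"gMa": None, "gD": None, "gtD": None}
    fits = {}
    for j, ds in enumerate(datasets):
        sub = None if seed is None else seed + 1000 * j
        f = fit_single(ds, prior_bounds=prior_bounds, n_steps=n_steps,
                       seed=sub)
        fits[ds.cell_type] = f
        rates[_CELL_TO_RATE[ds.cell_type]] = f.g
    return EngulfmentFit(gMa=rates["gMa"], gD=rates["gD"], gtD=rates["gtD"],
                         fits=fits, seed=seed)


def scale_rates(fMa_mouse: float,
                fit: EngulfmentFit | None = None) -> tuple[float, float]:
    """Mouse DC clearance rates (fD, ftD) from the activated-macrophage rate.

    fD = (gD/gMa)·fMa and ftD = (gtD/gMa)·fMa; with no fit supplied the
    canonical human-derived ratios 5.49e-2 and 3.82e-1 are used.
    """
    if fMa_mouse <= 0:
        raise ValueError("fMa must be positive")
    rD = fit.ratio_D if fit is not None else DEFAULT_RATIO_D
    rtD = fit.ratio_tD if fit is not None else DEFAULT_RATIO_TD
    return rD * fMa_mouse, rtD * fMa_mouse


# ---------------------------------------------------------------------------
# synthetic assay generator
# ---------------------------------------------------------------------------

#: Default assay conditions: phagocyte count with 1:1 apoptotic seeding, a
#: macrophage rate giving a realistic early transient (~1/3 engulfed by 1 h),
#: and DC rates at the canonical ratios.
DEFAULT_P = 1.0e5
DEFAULT_GMA = 5.0e-6          # ml/cell/hour
DEFAULT_TIMES_H = (0.083, 0.167, 0.25, 0.5, 0.75, 1.0, 2.0, 4.0)
DEFAULT_NOISE_SD = 2.0        # percent-scale observation noise


def generate_synthetic_assay(
    gP: float = DEFAULT_GMA,
    P: float = DEFAULT_P,
    times: Sequence[float] = DEFAULT_TIMES_H,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int | None = None,
    cell_type: str = "macrophage",
) -> AssayData:
    """Synthetic phagocytosis time course: closed form plus Gaussian noise.

    Percents are clipped to [0, 100].  This generator stands in for the
    human-derived assay measurements the rate ratios were estimated from.
    """
    rng = np.random.default_rng(seed)
    t = np.asarray(times, dtype=float)
    rho = assay_percent(t, gP, P)
    rho = rho + rng.normal(0.0, noise_sd, size=t.shape) if noise_sd > 0 else rho
    rho = np.clip(rho, 0.0, 100.0)
    return AssayData(cell_type=cell_type, times=tuple(t),
                     percent=tuple(rho), P=P)


def default_assay_suite(seed: int | None = None,
                        noise_sd: float = DEFAULT_NOISE_SD) -> list[AssayData]:
    """Three synthetic time courses at the canonical rate ratios."""
    rates = {"macrophage": DEFAULT_GMA,
             "matureDC": DEFAULT_GMA * DEFAULT_RATIO_D,
             "immatureDC": DEFAULT_GMA * DEFAULT_RATIO_TD}
    out = []
    for j, (cell, g) in enumerate(rates.items()):
        sub = None if seed is None else seed + 17 * (j + 1)
        out.append(generate_synthetic_assay(gP=g, noise_sd=noise_sd,
                                            seed=sub, cell_type=cell))
    return out
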