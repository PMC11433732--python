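"""PK summary statistics: trapezoidal and integrated AUC, interval
half-lives, dose normalization, naive pooling, fold changes and average
absolute percent error.

Censoring conventions (configurable): below-LLOQ points are excluded from
pooled means and half-life regressions; for trapezoidal AUC a censored
point between quantifiable points is imputed at LLOQ/2, while leading and
trailing censored runs count as zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .engine import SimulationResult
from .parameters import ANALYTES

__all__ = [
    "CtSeries",
    "PKSummary",
    "auc_trapezoid",
    "auc_model",
    "auc_to_inf",
    "interval_half_life",
    "dose_normalize",
    "naive_pool",
    "aape",
    "fold_change",
    "summarize",
]


@dataclass
class CtSeries:
    """One analyte's concentration-time series for one subject (or pool)."""

    analyte: str
    t: np.ndarray  #: h, strictly increasing
    conc: np.ndarray  #: ug/L
    dose_mg: float
    group: str = ""
    subject: str = ""
    lloq: float = 0.0  #: ug/L
    censored: np.ndarray | None = None  #: True where below LLOQ

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.conc = np.asarray(self.conc, dtype=float)
        if self.analyte not in ANALYTES:
            raise ValueError(f"unknown analyte {self.analyte!r}")
        if self.t.ndim != 1 or self.t.shape != self.conc.shape:
            raise ValueError("t and conc must be 1-D arrays of equal length")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.censored is None:
            self.censored = np.zeros_like(self.t, dtype=bool)
        else:
            self.censored = np.asarray(self.censored, dtype=bool)
        if np.any(self.conc[~self.censored] < 0):
            raise ValueError("uncensored concentrations must be >= 0")

    def usable(self) -> np.ndarray:
        """Mask of uncensored, strictly positive points."""
        return (~self.censored) & (self.conc > 0)


@dataclass(frozen=True)
class PKSummary:
    analyte: str
    group: str
    auc: float  #: ug*h/L over the stated interval
    auc_interval: tuple[float, float]
    c_max: float
    t_max: float
    t_half_12_24: float  #: h; NaN when not computable
    t_half_24_36: float


def _effective_conc(series: CtSeries) -> np.ndarray:
    """Concentrations with the censoring convention applied (for AUC)."""
    c = series.conc.copy()
    cen = series.censored
    if not cen.any():
        return c
    usable_idx = np.flatnonzero(~cen)
    for i in np.flatnonzero(cen):
        interior = usable_idx.size > 0 and usable_idx[0] < i < usable_idx[-1]
        c[i] = series.lloq / 2.0 if interior else 0.0
    return c


def auc_trapezoid(series: CtSeries, t0: float, t1: float) -> float:
    """Linear trapezoidal AUC (ug*h/L) over [t0, t1] on the observed points."""
    if t1 <= t0:
        raise ValueError("t1 must exceed t0")
    if t0 < series.t[0] - 1e-9 or t1 > series.t[-1] + 1e-9:
        raise ValueError(
            f"interval [{t0}, {t1}] outside sampled range "
            f"[{series.t[0]}, {series.t[-1]}]"
        )
    c = _effective_conc(series)
    ts = np.unique(np.clip(np.concatenate([series.t, [t0, t1]]), t0, t1))
    cs = np.interp(ts, series.t, c)
    return float(np.trapezoid(cs, ts))


def auc_model(
    result: SimulationResult, analyte: str, t0: float, t1: float
) -> float:
    """Integrated AUC of the model output on its dense time grid."""
    if analyte not in result.conc:
        raise ValueError(f"unknown analyte {analyte!r}")
    t, c = result.t, result.conc[analyte]
    if t0 < t[0] - 1e-9 or t1 > t[-1] + 1e-9:
        raise ValueError("interval outside simulated range")
    ts = np.unique(np.clip(np.concatenate([t, [t0, t1]]), t0, t1))
    cs = np.interp(ts, t, c)
    return float(np.trapezoid(cs, ts))


def auc_to_inf(series: CtSeries, tail_window: float = 36.0) -> float:
    """AUC extrapolated to infinity with a log-linear tail.

    The terminal slope is regressed over the last `tail_window` hours of
    usable data; the extrapolated area ``C_last / lambda_z`` is added to the
    trapezoidal AUC over the sampled range.
    """
    auc = auc_trapezoid(series, series.t[0], series.t[-1])
    t_half = interval_half_life(series, series.t[-1] - tail_window, series.t[-1])
    if not math.isfinite(t_half):
        return auc
    lam = math.log(2.0) / t_half
    usable = series.usable()
    c_last = series.conc[usable][-1] if usable.any() else 0.0
    return auc + float(c_last) / lam


def interval_half_life(
    series: CtSeries, t0: float, t1: float, method: str = "regression"
) -> float:
    """Half-life (h) from the log-concentration slope within [t0, t1].

    Returns NaN when fewer than two usable points fall in the window or the
    slope is non-negative (not computable).  ``method='two-point'`` uses the
    first and last usable points only.
    """
    mask = (series.t >= t0 - 1e-9) & (series.t <= t1 + 1e-9) & series.usable()
    if mask.sum() < 2:
        return math.nan
    x = series.t[mask]
    y = np.log(series.conc[mask])
    if method == "two-point":
        slope = (y[-1] - y[0]) / (x[-1] - x[0])
    elif method == "regression":
        slope = np.polyfit(x, y, 1)[0]
    else:
        raise ValueError(f"unknown method {method!r}")
    if slope >= -1e-12:  # flat or rising: no terminal decline
        return math.nan
    return math.log(2.0) / -slope


def dose_normalize(series: CtSeries, ref_dose_mg: float) -> CtSeries:
    """Scale concentrations (and LLOQ) to a reference dose."""
    if ref_dose_mg <= 0:
        raise ValueError("reference dose must be > 0")
    if series.dose_mg <= 0:
        raise ValueError("series has no positive dose to normalize from")
    f = ref_dose_mg / series.dose_mg
    return replace(
        series,
        conc=series.conc * f,
        lloq=series.lloq * f,
        dose_mg=ref_dose_mg,
        censored=series.censored.copy(),
    )


def naive_pool(cohort: Sequence[CtSeries]) -> tuple[CtSeries, np.ndarray]:
    """Pointwise mean and sample SD over subjects on a common schedule.

    Censored points are excluded from the mean; a pooled point is flagged
    censored unless a strict majority of subjects are quantifiable there
    (a pooled mean over only the high tail of a censored distribution is
    biased upward, so minority-quantifiable points are not trusted).
    Returns ``(mean series, SD array)``.
    """
    if not cohort:
        raise ValueError("empty cohort")
    ref = cohort[0]
    for s in cohort[1:]:
        if s.analyte != ref.analyte or not np.array_equal(s.t, ref.t):
            raise ValueError("cohort series must share analyte and schedule")
    conc = np.stack([s.conc for s in cohort])
    cen = np.stack([s.censored for s in cohort])
    counts = (~cen).sum(axis=0)
    summed = np.where(cen, 0.0, conc).sum(axis=0)
    mean = np.divide(summed, counts, out=np.zeros_like(summed), where=counts > 0)
    with np.errstate(invalid="ignore"):
        dev = np.where(cen, 0.0, (conc - mean) ** 2).sum(axis=0)
        sd = np.sqrt(np.divide(dev, counts - 1, out=np.zeros_like(dev),
                               where=counts > 1))
    pooled = CtSeries(
        analyte=ref.analyte,
        t=ref.t.copy(),
        conc=mean,
        dose_mg=ref.dose_mg,
        group=ref.group,
        subject="pooled",
        lloq=ref.lloq,
        censored=2 * counts <= len(cohort),
    )
    return pooled, sd


def aape(pred_aucs: Iterable[float], obs_aucs: Iterable[float]) -> float:
    """Average absolute percent error, mean of 100*|pred-obs|/obs."""
    pred = np.asarray(list(pred_aucs), dtype=float)
    obs = np.asarray(list(obs_aucs), dtype=float)
    if pred.shape != obs.shape or pred.size == 0:
        raise ValueError("pred and obs must be equal-length, non-empty")
    if np.any(obs <= 0):
        raise ValueError("observed AUCs must be > 0")
    return float(np.mean(100.0 * np.abs(pred - obs) / obs))


def fold_change(auc_a: float, auc_b: float) -> float:
    """Ratio a/b."""
    if auc_b <= 0:
        raise ValueError("denominator AUC must be > 0")
    return auc_a / auc_b


def summarize(series: CtSeries, t0: float = 0.0, t1: float | None = None) -> PKSummary:
    """Standard panel summary: interval AUC, C_max/T_max, window half-lives."""
    t1 = series.t[-1] if t1 is None else t1
    usable = series.usable()
    if usable.any():
        i = int(np.argmax(np.where(usable, series.conc, -np.inf)))
        c_max, t_max = float(series.conc[i]), float(series.t[i])
    else:
        c_max, t_max = 0.0, math.nan
    return PKSummary(
        analyte=series.analyte,
        group=series.group,
        auc=auc_trapezoid(series, t0, t1),
        auc_interval=(t0, t1),
        c_max=c_max,
        t_max=t_max,
        t_half_12_24=interval_half_life(series, 12.0, 24.0),
        t_half_24_36=interval_half_life(series, 24.0, 36.0),
    )
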