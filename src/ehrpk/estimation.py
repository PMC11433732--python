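"""Parameter estimation against pooled concentration-time data.

The loss is least squares on log residuals over uncensored points, with a
one-sided penalty when the model predicts above the LLOQ at a censored
point.  Fitting proceeds stage by stage, mirroring the model-building
order: parent first, then the glucuronide, then each oxidative metabolite,
with earlier estimates carried forward as fixed values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

from .engine import SimulationResult, assemble, simulate, DoseRegimen, make_grid
from .hepatobiliary import MealSchedule
from .metrics import CtSeries
from .parameters import ParameterSet

__all__ = [
    "FitSpec",
    "FitStage",
    "FitResult",
    "ModelFactory",
    "loss",
    "residuals",
    "fit",
    "fit_stepwise",
    "default_stages",
]

_PENALTY = 20.0  # log-residual assigned to a non-positive prediction


@dataclass(frozen=True)
class FitStage:
    """One step of the stepwise workflow: free parameters and analytes used."""

    name: str
    free: Mapping[str, tuple[float, float]]  #: name -> (lo, hi) bounds
    analytes: tuple[str, ...]


@dataclass
class FitSpec:
    """Free parameters with bounds/transforms plus optimizer settings."""

    free: Mapping[str, tuple[float, float]]
    fixed: Mapping[str, float] = field(default_factory=dict)
    analytes: tuple[str, ...] = ("NAL", "M1", "M3", "M4", "M5")
    log_scale: frozenset[str] | None = None  #: default: all but fractions
    n_starts: int = 1
    seed: int = 0
    max_nfev: int = 60
    xtol: float = 1e-10
    ftol: float = 1e-10

    def __post_init__(self) -> None:
        overlap = set(self.free) & set(self.fixed)
        if overlap:
            raise ValueError(f"parameters both free and fixed: {sorted(overlap)}")
        for name, (lo, hi) in self.free.items():
            if not (math.isfinite(lo) and math.isfinite(hi) and lo < hi):
                raise ValueError(f"bounds for {name} must be finite with lo < hi")
            if self._is_log(name) and lo <= 0:
                raise ValueError(f"log-scale parameter {name} needs positive bounds")

    def _is_log(self, name: str) -> bool:
        if self.log_scale is not None:
            return name in self.log_scale
        return not name.startswith("f_")


@dataclass
class FitResult:
    estimates: dict[str, float]
    cost: float  #: sum of squared residuals at the optimum
    n_evaluations: int
    converged: bool
    message: str
    per_analyte_rmse: dict[str, float]
    manifest: dict


class ModelFactory:
    """Builds and simulates the model for a given set of parameter overrides.

    A lighter grid and looser tolerances than the production defaults keep a
    single loss evaluation well under a second; both are recorded in the fit
    manifest.
    """

    def __init__(
        self,
        base_params: ParameterSet,
        dose_mg: float | None = None,
        t_end: float = 120.0,
        n_nodes: int = 24,
        rtol: float = 1e-5,
        atol: float = 1e-8,
        dt_out: float = 0.5,
    ):
        self.base_params = base_params
        self.dose_mg = dose_mg if dose_mg is not None else base_params.dose_mg
        self.t_end = t_end
        self.n_nodes = n_nodes
        self.rtol = rtol
        self.atol = atol
        self.dt_out = dt_out

    def __call__(self, overrides: Mapping[str, float]) -> SimulationResult:
        params = self.base_params.with_overrides(**overrides)
        model = assemble(
            params,
            DoseRegimen(dose_mg=self.dose_mg),
            meals=MealSchedule.daily(self.t_end),
            grid=make_grid(self.n_nodes),
        )
        return simulate(model, t_end=self.t_end, rtol=self.rtol,
                        atol=self.atol, dt_out=self.dt_out)

    def settings(self) -> dict:
        return {
            "dose_mg": self.dose_mg, "t_end": self.t_end,
            "n_nodes": self.n_nodes, "rtol": self.rtol, "atol": self.atol,
        }


def residuals(
    overrides: Mapping[str, float],
    data: Sequence[CtSeries],
    factory: Callable[[Mapping[str, float]], SimulationResult],
) -> np.ndarray:
    """Log-residual vector of the model against the data series."""
    if not data:
        raise ValueError("no data series provided")
    result = factory(overrides)
    out: list[np.ndarray] = []
    for series in data:
        pred = np.interp(series.t, result.t, result.conc[series.analyte])
        res = np.zeros_like(series.t)
        usable = series.usable()
        ok = usable & (pred > 0)
        res[ok] = np.log(pred[ok]) - np.log(series.conc[ok])
        res[usable & (pred <= 0)] = _PENALTY
        if series.lloq > 0:
            over = series.censored & (pred > series.lloq)
            res[over] = np.log(pred[over] / series.lloq)
        out.append(res)
    return np.concatenate(out)


def loss(
    overrides: Mapping[str, float],
    data: Sequence[CtSeries],
    factory: Callable[[Mapping[str, float]], SimulationResult],
) -> float:
    """Scalar objective: sum of squared log residuals."""
    r = residuals(overrides, data, factory)
    return float(np.dot(r, r))


def fit(
    spec: FitSpec,
    data: Sequence[CtSeries],
    factory: Callable[[Mapping[str, float]], SimulationResult],
    start: Mapping[str, float] | None = None,
) -> FitResult:
    """Bounded local least-squares fit, optionally multistart.

    Deterministic given ``spec.seed``.  Log-scale parameters are optimized
    in log space; estimates are therefore invariant to concentration unit
    changes because the loss acts on log residuals.
    """
    names = list(spec.free)
    data = [s for s in data if s.analyte in spec.analytes]
    if not data:
        raise ValueError("no data series match the requested analytes")

    def to_x(values: Mapping[str, float]) -> np.ndarray:
        return np.array([
            math.log(values[n]) if spec._is_log(n) else values[n] for n in names
        ])

    def from_x(x: np.ndarray) -> dict[str, float]:
        out = dict(spec.fixed)
        for n, v in zip(names, x):
            out[n] = math.exp(v) if spec._is_log(n) else v
        return out

    lo = np.array([math.log(spec.free[n][0]) if spec._is_log(n) else spec.free[n][0]
                   for n in names])
    hi = np.array([math.log(spec.free[n][1]) if spec._is_log(n) else spec.free[n][1]
                   for n in names])

    def fun(x: np.ndarray) -> np.ndarray:
        return residuals(from_x(x), data, factory)

    rng = np.random.default_rng(spec.seed)
    starts: list[np.ndarray] = [
        np.clip(to_x(start), lo, hi) if start is not None else (lo + hi) / 2.0
    ]
    while len(starts) < spec.n_starts:
        starts.append(lo + (hi - lo) * rng.random(len(names)))

    best = None
    nfev = 0
    for x0 in starts:
        sol = least_squares(
            fun, x0, bounds=(lo, hi), max_nfev=spec.max_nfev,
            xtol=spec.xtol, ftol=spec.ftol, gtol=1e-12,
            diff_step=1e-4,
        )
        nfev += sol.nfev
        if best is None or sol.cost < best.cost:
            best = sol

    estimates = from_x(best.x)
    per_analyte: dict[str, float] = {}
    result = factory(estimates)
    for series in data:
        pred = np.interp(series.t, result.t, result.conc[series.analyte])
        usable = series.usable() & (pred > 0)
        if usable.any():
            r = np.log(pred[usable]) - np.log(series.conc[usable])
            per_analyte[series.analyte] = float(np.sqrt(np.mean(r**2)))
    return FitResult(
        estimates={n: estimates[n] for n in names},
        cost=float(2.0 * best.cost),  # least_squares cost is 0.5 * sum r^2
        n_evaluations=nfev,
        converged=bool(best.status > 0),
        message=str(best.message),
        per_analyte_rmse=per_analyte,
        manifest={
            "free": {n: spec.free[n] for n in names},
            "fixed": dict(spec.fixed),
            "analytes": spec.analytes,
            "seed": spec.seed,
            "max_nfev": spec.max_nfev,
        },
    )


def default_stages(base: ParameterSet) -> list[FitStage]:
    """The stepwise build order: parent, then M5, M3, M1, M4 components."""

    def around(x: float, lo_f: float = 0.1, hi_f: float = 10.0) -> tuple[float, float]:
        return (x * lo_f, x * hi_f)

    return [
        FitStage("parent", {
            "cl_int_h": around(base.cl_int_h),
            "k_rel": around(base.k_rel),
        }, ("NAL",)),
        FitStage("m5", {
            "f_m5": (0.05, 0.9),
            "cl_elim_m5": around(base.cl_elim_m5),
        }, ("NAL", "M5")),
        FitStage("m3", {
            "f_m3": (0.02, 0.9),
            "v_m3": around(base.v_m3, 0.2, 5.0),
        }, ("NAL", "M5", "M3")),
        FitStage("m1", {
            "cl_int_m3_to_m1": around(base.cl_int_m3_to_m1),
        }, ("NAL", "M5", "M3", "M1")),
        FitStage("m4", {
            "cl_elim_m4": around(base.cl_elim_m4),
        }, ("NAL", "M5", "M3", "M1", "M4")),
        # Final joint refinement: with f_m3 pinned, the M4 profile anchors
        # f_m4 = 1 - f_m3 - f_m5 and thereby breaks the f_m5 / cl_elim_m5
        # ridge left by the M5-only stage.
        FitStage("refine", {
            "f_m5": (0.05, 0.9),
            "cl_elim_m5": around(base.cl_elim_m5),
        }, ("NAL", "M5", "M3", "M1", "M4")),
    ]


def fit_stepwise(
    data: Sequence[CtSeries],
    base_params: ParameterSet,
    factory: Callable[[Mapping[str, float]], SimulationResult],
    stages: Sequence[FitStage] | None = None,
    starts: Mapping[str, float] | None = None,
    seed: int = 0,
    max_nfev: int = 40,
) -> tuple[dict[str, float], list[FitResult]]:
    """Run the staged fit; returns accumulated estimates and per-stage results.

    ``starts`` optionally supplies perturbed starting values per free
    parameter (defaults to the base parameter values).  Free fractions are
    kept feasible: when ``f_m3`` is fitted with ``f_m5`` already fixed, its
    upper bound is capped so the remainder fraction stays positive.
    """
    stages = list(stages) if stages is not None else default_stages(base_params)
    fixed: dict[str, float] = {}
    stage_results: list[FitResult] = []
    for stage in stages:
        free = dict(stage.free)
        stage_fixed = {k: v for k, v in fixed.items() if k not in free}
        # keep the fraction simplex feasible against already-fixed fractions
        for this, other in (("f_m3", "f_m5"), ("f_m5", "f_m3")):
            if this in free and other in stage_fixed:
                lo, hi = free[this]
                free[this] = (lo, min(hi, 1.0 - stage_fixed[other] - 0.02))
        spec = FitSpec(
            free=free, fixed=stage_fixed, analytes=stage.analytes,
            seed=seed, max_nfev=max_nfev,
        )
        start = {}
        for name in free:
            if name in fixed:  # refit of an earlier estimate: resume from it
                start[name] = float(np.clip(fixed[name], *free[name]))
            elif starts and name in starts:
                start[name] = float(np.clip(starts[name], *free[name]))
            else:
                start[name] = float(np.clip(
                    getattr(base_params, name), *free[name]))
        res = fit(spec, data, factory, start=start)
        stage_results.append(res)
        fixed.update(res.estimates)
    return fixed, stage_results
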