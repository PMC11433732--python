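"""Well-stirred liver with metabolic partitioning, biliary secretion and a
meal-driven gallbladder.

The liver receives portal absorption from the intestine and exchanges with
the systemic compartments: the parent by hepatic blood flow (flow-limited),
metabolites by a fast reversible exchange clearance.  Parent intrinsic
clearance is split into formation of the two hydroxy metabolites and the
3-glucuronide; sequential metabolism converts M3 to M1 and M4 to its
glucuronide.  Parent, M5 and M4-G are secreted into the gallbladder, which
empties into the duodenal inlet during meal windows.

Formation fluxes are mass-rate scaled by molecular-weight ratios so that
molar balance is exact while all state is kept in mg.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .parameters import ParameterSet, Physiology

__all__ = [
    "LIVER_SPECIES",
    "GB_SPECIES",
    "MealSchedule",
    "HepaticFluxes",
    "meal_signal",
    "hepatic_rhs",
    "gallbladder_rhs",
]

#: Species tracked in the liver, in state order.
LIVER_SPECIES = ("NAL", "M1", "M3", "M4", "M5", "M4G")

#: Species secreted into the gallbladder, in state order.
GB_SPECIES = ("NAL", "M5", "M4G")


@dataclass(frozen=True)
class MealSchedule:
    """Meal times (h post-dose) with fixed-width gallbladder-emptying windows."""

    times: tuple[float, ...] = (3.0, 9.0, 14.0, 27.0, 33.0, 38.0, 51.0, 57.0,
                                62.0, 75.0, 81.0, 86.0, 99.0, 105.0, 110.0)
    window_h: float = 0.5
    k_empty: float = 6.0  #: first-order ejection rate during a window, 1/h

    def __post_init__(self) -> None:
        if self.window_h <= 0 or self.k_empty < 0:
            raise ValueError("window_h must be > 0 and k_empty >= 0")
        times = self.times
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("meal times must be strictly increasing")
        if any(b < a + self.window_h for a, b in zip(times, times[1:])):
            raise ValueError("meal windows overlap")

    @classmethod
    def daily(
        cls,
        t_end: float,
        offsets: tuple[float, ...] = (3.0, 9.0, 14.0),
        window_h: float = 0.5,
        k_empty: float = 6.0,
    ) -> "MealSchedule":
        """Repeat daily meal offsets out to `t_end` hours."""
        times: list[float] = []
        day = 0.0
        while day <= t_end:
            times.extend(day + o for o in offsets if day + o <= t_end)
            day += 24.0
        return cls(times=tuple(times), window_h=window_h, k_empty=k_empty)

    def boundaries(self, t_end: float) -> list[float]:
        """Window edges inside (0, t_end), for solver breakpoints."""
        edges: list[float] = []
        for t in self.times:
            for e in (t, t + self.window_h):
                if 0.0 < e < t_end:
                    edges.append(e)
        return edges


def meal_signal(t: float, meals: MealSchedule) -> float:
    """1.0 inside a gallbladder-emptying window, else 0.0."""
    for start in meals.times:
        if start <= t < start + meals.window_h:
            return 1.0
        if start > t:
            break
    return 0.0


#: Order of the formation-flux vector in :class:`HepaticFluxes`.
FORMED_SPECIES = ("M3", "M4", "M5", "M1", "M4G")


@dataclass
class HepaticFluxes:
    """Derivatives plus named output fluxes of the liver block (mg/h)."""

    dliver: np.ndarray  #: (6[, batch]) d/dt of liver amounts
    biliary: np.ndarray  #: (3[, batch]) secretion into the gallbladder
    to_central: np.ndarray  #: (6[, batch]) net liver -> central flux
    elim_m5: np.ndarray | float  #: hepatic elimination of M5
    formation: np.ndarray  #: (5[, batch]) formation rates, `FORMED_SPECIES` order


def hepatic_rhs(
    liver: np.ndarray,
    portal: Mapping[str, np.ndarray | float],
    central_plasma: np.ndarray,
    params: ParameterSet,
    physiology: Physiology,
) -> HepaticFluxes:
    """Liver mass balance for all six species.

    Parameters
    ----------
    liver
        Amounts in mg, shape ``(6[, batch])`` ordered as `LIVER_SPECIES`.
    portal
        Portal absorption inflow (mg/h) keyed by species (only ``NAL`` and
        ``M4`` are absorbed; missing keys default to 0).
    central_plasma
        Plasma concentrations (mg/L) of the systemic central compartments,
        shape ``(6[, batch])`` in `LIVER_SPECIES` order.
    """
    liver = np.asarray(liver, dtype=float)
    if liver.shape[0] != len(LIVER_SPECIES):
        raise ValueError("liver state must have 6 species")
    c = liver / physiology.v_liver  # liver (blood-basis) concentrations
    q = physiology.q_h
    clx = physiology.cl_liver_exchange
    mw = params.mw

    i = {s: k for k, s in enumerate(LIVER_SPECIES)}
    d = np.zeros_like(liver)
    to_central = np.zeros_like(liver)
    biliary = np.zeros_like(liver[:3])

    # Parent: flow-limited exchange with central, metabolism, biliary secretion.
    metab = params.cl_int_h * c[i["NAL"]]
    bil_nal = params.cl_gi_p * c[i["NAL"]]
    to_central[i["NAL"]] = q * c[i["NAL"]] - q * params.bp_nal * central_plasma[i["NAL"]]
    d[i["NAL"]] = (
        portal.get("NAL", 0.0) - to_central[i["NAL"]] - metab - bil_nal
    )
    biliary[GB_SPECIES.index("NAL")] = bil_nal

    # Formation of the primary metabolites, MW-scaled to keep units in mg.
    form = {
        "M3": params.f_m3 * metab * (mw["M3"] / mw["NAL"]),
        "M4": params.f_m4 * metab * (mw["M4"] / mw["NAL"]),
        "M5": params.f_m5 * metab * (mw["M5"] / mw["NAL"]),
    }

    # Sequential metabolism.
    m3_to_m1 = params.cl_int_m3_to_m1 * c[i["M3"]]
    m4_to_m4g = params.cl_int_m4_to_m4g * c[i["M4"]]

    # Reversible liver <-> central exchange for the metabolites.
    bps = {"M1": params.bp_m1, "M3": params.bp_m3, "M4": params.bp_m4,
           "M5": params.bp_m5, "M4G": params.bp_m4g}
    for s, bp in bps.items():
        to_central[i[s]] = clx * (c[i[s]] - bp * central_plasma[i[s]])

    elim_m5 = params.cl_elim_m5 * c[i["M5"]]
    bil_m5 = params.cl_gi_m * c[i["M5"]]
    bil_m4g = params.cl_gi_m * c[i["M4G"]]
    biliary[GB_SPECIES.index("M5")] = bil_m5
    biliary[GB_SPECIES.index("M4G")] = bil_m4g

    m1_formed = m3_to_m1 * (mw["M1"] / mw["M3"])
    m4g_formed = m4_to_m4g * (mw["M4G"] / mw["M4"])
    d[i["M3"]] = form["M3"] - m3_to_m1 - to_central[i["M3"]]
    d[i["M1"]] = m1_formed - to_central[i["M1"]]
    d[i["M4"]] = (
        form["M4"] + portal.get("M4", 0.0) - m4_to_m4g - to_central[i["M4"]]
    )
    d[i["M4G"]] = m4g_formed - to_central[i["M4G"]] - bil_m4g
    d[i["M5"]] = form["M5"] - to_central[i["M5"]] - elim_m5 - bil_m5

    formation = np.stack([form["M3"] + np.zeros_like(c[0]),
                          form["M4"] + np.zeros_like(c[0]),
                          form["M5"] + np.zeros_like(c[0]),
                          m1_formed + np.zeros_like(c[0]),
                          m4g_formed + np.zeros_like(c[0])])
    return HepaticFluxes(dliver=d, biliary=biliary, to_central=to_central,
                         elim_m5=elim_m5, formation=formation)


def gallbladder_rhs(
    gb: np.ndarray,
    secretion: np.ndarray,
    t: float,
    meals: MealSchedule,
    meal_on: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Gallbladder filling/emptying.

    Between meals the gallbladder accumulates biliary secretion; during a
    meal window the stored amounts are ejected first-order into the duodenal
    inlet.  `meal_on` overrides the time-based signal (the engine integrates
    piecewise with the signal held constant inside each segment).

    Returns ``(d(gb)/dt, ejection rate per species)``, both mg/h.
    """
    gb = np.asarray(gb, dtype=float)
    if gb.shape[0] != len(GB_SPECIES):
        raise ValueError("gallbladder state must have 3 species")
    if t < 0:
        raise ValueError("t must be >= 0")
    signal = meal_signal(t, meals) if meal_on is None else float(meal_on)
    ejection = signal * meals.k_empty * gb
    return np.asarray(secretion, dtype=float) - ejection, ejection
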