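"""Compartmental systemic disposition linked reversibly to the liver.

Parent: 3-compartment mammillary model (central + two peripherals) whose
volumes sum to the simulated steady-state volume of 267 L.  M3: central plus
one peripheral compartment totaling its optimized 214 L.  M1, M4, M5 and the
M4-glucuronide are single central compartments.  All kinetics are linear.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import ParameterSet

__all__ = [
    "SYSTEMIC_STATE",
    "DispositionParams",
    "bp_convert",
    "plasma_from_blood",
    "systemic_rhs",
]

#: Systemic state entries, in order.
SYSTEMIC_STATE = (
    "NAL_c", "NAL_p1", "NAL_p2", "M1", "M3_c", "M3_p", "M4", "M5", "M4G",
)

#: Liver-facing species order used for exchange flux vectors.
EXCHANGE_SPECIES = ("NAL", "M1", "M3", "M4", "M5", "M4G")


@dataclass(frozen=True)
class DispositionParams:
    """Compartment volumes (L), intercompartmental and elimination CL (L/h)."""

    v_c: float = 60.0
    v_p1: float = 80.0
    v_p2: float = 127.0
    q_p1: float = 60.0
    q_p2: float = 20.0
    cl_nh: float = 4.14
    v_m1: float = 53.0
    v_m3_c: float = 15.0
    v_m3_p: float = 199.0
    q_m3: float = 20.0
    v_m4: float = 214.0
    v_m5: float = 15.0
    v_m4g: float = 15.0
    cl_elim_m1: float = 20.0
    cl_elim_m3: float = 4.0
    cl_elim_m4: float = 40.0
    cl_elim_m4g: float = 0.0  # no printed value; biliary secretion is its exit

    def __post_init__(self) -> None:
        for name in ("v_c", "v_p1", "v_p2", "v_m1", "v_m3_c", "v_m3_p",
                     "v_m4", "v_m5", "v_m4g"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def v_ss_parent(self) -> float:
        """Parent steady-state volume (equal partitioning): V_c + V_p1 + V_p2."""
        return self.v_c + self.v_p1 + self.v_p2

    @classmethod
    def from_parameter_set(
        cls,
        params: ParameterSet,
        v_c: float = 60.0,
        v_p1: float = 80.0,
        q_p1: float = 60.0,
        q_p2: float = 20.0,
        v_m3_c: float = 15.0,
        q_m3: float = 20.0,
    ) -> "DispositionParams":
        """Derive volumes/clearances from a population parameter set.

        The parent peripheral split is chosen so the three volumes sum to
        the simulated V_ss; the M3 peripheral absorbs its total volume
        beyond the extracellular central compartment.
        """
        return cls(
            v_c=v_c,
            v_p1=v_p1,
            v_p2=params.v_nal - v_c - v_p1,
            q_p1=q_p1,
            q_p2=q_p2,
            cl_nh=params.cl_nh,
            v_m1=params.v_m1,
            v_m3_c=min(v_m3_c, params.v_m3 / 2.0),
            v_m3_p=params.v_m3 - min(v_m3_c, params.v_m3 / 2.0),
            q_m3=q_m3,
            v_m4=params.v_m4,
            v_m5=params.v_m5,
            v_m4g=params.v_m4g,
            cl_elim_m1=params.cl_elim_m1,
            cl_elim_m3=params.cl_elim_m3,
            cl_elim_m4=params.cl_elim_m4,
        )

    def central_volumes(self) -> np.ndarray:
        """Central volume per exchange species, `EXCHANGE_SPECIES` order."""
        return np.array([self.v_c, self.v_m1, self.v_m3_c, self.v_m4,
                         self.v_m5, self.v_m4g])


def bp_convert(plasma_conc, bp: float):
    """Plasma -> blood concentration via the blood:plasma ratio."""
    if bp <= 0:
        raise ValueError("bp must be > 0")
    return plasma_conc * bp


def plasma_from_blood(blood_conc, bp: float):
    """Inverse of :func:`bp_convert`."""
    if bp <= 0:
        raise ValueError("bp must be > 0")
    return blood_conc / bp


def central_plasma(state: np.ndarray, dp: DispositionParams) -> np.ndarray:
    """Central plasma concentrations (mg/L) per exchange species."""
    idx = [SYSTEMIC_STATE.index(k) for k in
           ("NAL_c", "M1", "M3_c", "M4", "M5", "M4G")]
    return state[idx] / dp.central_volumes().reshape((-1,) + (1,) * (state.ndim - 1))


def systemic_rhs(
    state: np.ndarray,
    liver_exchange: np.ndarray,
    dp: DispositionParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Linear mammillary kinetics of the systemic compartments.

    Parameters
    ----------
    state
        Amounts in mg, shape ``(9[, batch])`` in `SYSTEMIC_STATE` order.
    liver_exchange
        Net liver -> central flux (mg/h) per species, shape ``(6[, batch])``
        in `EXCHANGE_SPECIES` order.

    Returns
    -------
    dstate, elim
        State derivative and irreversible elimination flux per exchange
        species (M5 eliminates in the liver, so its entry is 0 here).
    """
    state = np.asarray(state, dtype=float)
    if state.shape[0] != len(SYSTEMIC_STATE):
        raise ValueError("systemic state must have 9 entries")
    liver_exchange = np.asarray(liver_exchange, dtype=float)
    if liver_exchange.shape[0] != len(EXCHANGE_SPECIES):
        raise ValueError("liver_exchange must have 6 entries")

    s = {k: i for i, k in enumerate(SYSTEMIC_STATE)}
    e = {k: i for i, k in enumerate(EXCHANGE_SPECIES)}
    d = np.zeros_like(state)
    elim = np.zeros_like(liver_exchange)

    # Parent 3-compartment block.
    c_c = state[s["NAL_c"]] / dp.v_c
    c_p1 = state[s["NAL_p1"]] / dp.v_p1
    c_p2 = state[s["NAL_p2"]] / dp.v_p2
    f1 = dp.q_p1 * (c_c - c_p1)
    f2 = dp.q_p2 * (c_c - c_p2)
    elim[e["NAL"]] = dp.cl_nh * c_c
    d[s["NAL_c"]] = liver_exchange[e["NAL"]] - f1 - f2 - elim[e["NAL"]]
    d[s["NAL_p1"]] = f1
    d[s["NAL_p2"]] = f2

    # M1: single compartment, central elimination.
    c_m1 = state[s["M1"]] / dp.v_m1
    elim[e["M1"]] = dp.cl_elim_m1 * c_m1
    d[s["M1"]] = liver_exchange[e["M1"]] - elim[e["M1"]]

    # M3: central + peripheral, central elimination.
    c_m3 = state[s["M3_c"]] / dp.v_m3_c
    c_m3p = state[s["M3_p"]] / dp.v_m3_p
    f3 = dp.q_m3 * (c_m3 - c_m3p)
    elim[e["M3"]] = dp.cl_elim_m3 * c_m3
    d[s["M3_c"]] = liver_exchange[e["M3"]] - f3 - elim[e["M3"]]
    d[s["M3_p"]] = f3

    # M4: single compartment, central elimination.
    c_m4 = state[s["M4"]] / dp.v_m4
    elim[e["M4"]] = dp.cl_elim_m4 * c_m4
    d[s["M4"]] = liver_exchange[e["M4"]] - elim[e["M4"]]

    # M5 eliminates in the liver; its systemic compartment only exchanges.
    d[s["M5"]] = liver_exchange[e["M5"]]

    # M4-glucuronide: optional renal clearance hook (default 0).
    c_m4g = state[s["M4G"]] / dp.v_m4g
    elim[e["M4G"]] = dp.cl_elim_m4g * c_m4g
    d[s["M4G"]] = liver_exchange[e["M4G"]] - elim[e["M4G"]]

    return d, elim
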