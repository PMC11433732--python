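"""Population parameter sets and hepatic clearance arithmetic.

All clearances and flows are stored in L/h, volumes in L, amounts in mg,
molecular weights in g/mol.  Hepatic blood flow defaults to 1.45 L/min and
is normalized to 87 L/h at construction.

The three population parameter sets (``healthy``, ``moderate``, ``severe``)
ship as packaged YAML fixtures and are loaded with
:func:`load_parameter_set`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping

import yaml

__all__ = [
    "GROUPS",
    "ANALYTES",
    "MOLECULAR_WEIGHTS",
    "Physiology",
    "ParameterSet",
    "ClfObservation",
    "load_parameter_set",
    "validate",
    "well_stirred_clh",
    "well_stirred_clint",
    "initial_factor_a",
    "partition_formation_clints",
]

GROUPS = ("healthy", "moderate", "severe")

#: Circulating analytes reported in concentration-time output.
ANALYTES = ("NAL", "M1", "M3", "M4", "M5")

#: All modeled species, including the non-circulating glucuronide of M4.
SPECIES = ("NAL", "M1", "M3", "M4", "M5", "M4G")

# Computed from the molecular formulas: parent C21H27NO4; the hydroxy
# metabolites add one oxygen; glucuronides add C6H8O6 (176.12); M1 is the
# tri-oxidized ring-opened product (parent + 3 O - 2 H).
MOLECULAR_WEIGHTS: Mapping[str, float] = {
    "NAL": 357.45,
    "M1": 403.43,
    "M3": 373.45,
    "M4": 373.45,
    "M5": 533.57,
    "M4G": 549.57,
}


@dataclass(frozen=True)
class Physiology:
    """System-level physiological constants shared across populations."""

    q_h: float = 1.45 * 60.0  #: hepatic blood flow, L/h
    v_liver: float = 1.8  #: liver volume, L
    v_extracellular: float = 15.0  #: extracellular water, L
    intestinal_transit_h: float = 3.3  #: mean small-intestinal transit, h
    dispersion: float = 0.0017  #: axial dispersion, tube-lengths^2 / h
    gallbladder_k_empty: float = 6.0  #: first-order emptying during a meal, 1/h
    meal_offsets_h: tuple[float, ...] = (3.0, 9.0, 14.0)  #: daily meal times, h
    meal_window_h: float = 0.5  #: duration of each emptying window, h
    cl_liver_exchange: float = 100.0  #: metabolite liver<->central exchange, L/h

    def __post_init__(self) -> None:
        for name in ("q_h", "v_liver", "v_extracellular", "intestinal_transit_h"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.dispersion < 0 or self.gallbladder_k_empty < 0:
            raise ValueError("dispersion and gallbladder_k_empty must be >= 0")


@dataclass(frozen=True)
class ParameterSet:
    """Group-specific model parameters (clearances L/h, volumes L)."""

    group: str
    dose_mg: float
    cl_int_h: float
    cl_nh: float
    cl_gi_multiplier: float
    f_m3: float
    f_m4: float
    f_m5: float
    cl_int_m3_to_m1: float
    cl_int_m4_to_m4g: float
    v_nal: float
    v_m1: float
    v_m3: float
    v_m4: float
    v_m5: float
    v_m4g: float
    cl_elim_m1: float
    cl_elim_m3: float
    cl_elim_m4: float
    cl_elim_m5: float
    bp_nal: float
    bp_m1: float
    bp_m3: float
    bp_m4: float
    bp_m5: float
    bp_m4g: float
    k_rel: float
    factor_a: float | None = None
    clf_observed: float | None = None
    mw: Mapping[str, float] = field(default_factory=lambda: dict(MOLECULAR_WEIGHTS))
    q_h: float = 87.0

    @property
    def cl_h(self) -> float:
        """Hepatic plasma clearance implied by the well-stirred model."""
        return well_stirred_clh(self.cl_int_h, self.q_h, self.bp_nal)

    @property
    def cl_gi_p(self) -> float:
        """Biliary secretory clearance of the parent, L/h."""
        return self.cl_gi_multiplier * self.cl_int_h

    @property
    def cl_gi_m(self) -> float:
        """Biliary secretory clearance of the glucuronides, L/h."""
        return self.cl_gi_multiplier * self.cl_int_h

    def formation_clints(self) -> dict[str, float]:
        return partition_formation_clints(self.cl_int_h, self.f_m3, self.f_m4, self.f_m5)

    def bp(self, species: str) -> float:
        return getattr(self, f"bp_{species.lower().replace('-', '')}")

    def with_overrides(self, **overrides: float) -> "ParameterSet":
        """Return a copy with named fields replaced.

        Metabolite fractions are kept on the simplex: if ``f_m5`` is given
        alone, ``f_m3``/``f_m4`` are rescaled proportionally; if ``f_m3``
        (and optionally ``f_m4``) are given, ``f_m5`` absorbs the remainder.
        """
        overrides = dict(overrides)
        frac_keys = {"f_m3", "f_m4", "f_m5"} & overrides.keys()
        if frac_keys:
            f_m3 = overrides.pop("f_m3", None)
            f_m4 = overrides.pop("f_m4", None)
            f_m5 = overrides.pop("f_m5", None)
            if frac_keys == {"f_m5"}:
                scale = (1.0 - f_m5) / (self.f_m3 + self.f_m4)
                f_m3, f_m4 = self.f_m3 * scale, self.f_m4 * scale
            elif len(frac_keys) == 3:
                pass
            elif f_m5 is None:
                f_m3 = self.f_m3 if f_m3 is None else f_m3
                f_m4 = self.f_m4 if f_m4 is None else f_m4
                f_m5 = 1.0 - f_m3 - f_m4
            else:
                # f_m5 plus one other given: the remaining fraction absorbs
                if f_m3 is None:
                    f_m3 = 1.0 - f_m4 - f_m5
                else:
                    f_m4 = 1.0 - f_m3 - f_m5
            if min(f_m3, f_m4, f_m5) < 0 or abs(f_m3 + f_m4 + f_m5 - 1) > 1e-9:
                raise ValueError("metabolite fractions left the simplex")
            overrides.update(f_m3=f_m3, f_m4=f_m4, f_m5=f_m5)
        return replace(self, **overrides)


@dataclass(frozen=True)
class ClfObservation:
    """Observed apparent oral clearance (dose/AUC) for one group."""

    group: str
    cl_over_f: float

    def __post_init__(self) -> None:
        if self.cl_over_f <= 0:
            raise ValueError("cl_over_f must be > 0")


def load_parameter_set(group: str) -> ParameterSet:
    """Load the packaged parameter set for one population group.

    Parameters
    ----------
    group : {'healthy', 'moderate', 'severe'}

    Raises
    ------
    ValueError
        If `group` is not one of the three modeled populations (the mild
        impairment group is excluded from modeling).
    """
    if group not in GROUPS:
        raise ValueError(
            f"unknown group {group!r}; expected one of {', '.join(GROUPS)}"
        )
    text = resources.files("ehrpk.data").joinpath(f"{group}.yaml").read_text()
    raw = yaml.safe_load(text)
    params = ParameterSet(**raw)
    report = validate(params)
    if report:
        raise ValueError(f"packaged parameter set {group!r} invalid: {report}")
    return params


def dump_parameter_set(params: ParameterSet, path) -> None:
    """Serialize a parameter set to the same key:value text format the
    packaged fixtures use (round-trips with :func:`read_parameter_set`)."""
    from dataclasses import asdict
    from pathlib import Path

    raw = asdict(params)
    raw.pop("mw")
    raw.pop("q_h")
    Path(path).write_text(yaml.safe_dump(raw, sort_keys=False))


def read_parameter_set(path) -> ParameterSet:
    """Load a parameter set from a key:value text configuration file."""
    from pathlib import Path

    raw = yaml.safe_load(Path(path).read_text())
    params = ParameterSet(**raw)
    report = validate(params)
    if report:
        raise ValueError(f"parameter set at {path} invalid: {report}")
    return params


def validate(params: ParameterSet) -> list[str]:
    """Check ParameterSet invariants; return one message per violation."""
    report: list[str] = []
    if abs(params.f_m3 + params.f_m4 + params.f_m5 - 1.0) > 1e-9:
        report.append("fractions sum != 1")
    for name in (
        "cl_int_h",
        "cl_nh",
        "cl_gi_multiplier",
        "cl_int_m3_to_m1",
        "cl_int_m4_to_m4g",
        "cl_elim_m1",
        "cl_elim_m3",
        "cl_elim_m4",
        "cl_elim_m5",
        "k_rel",
    ):
        if getattr(params, name) < 0:
            report.append(f"negative clearance: {name}")
    for name in ("v_nal", "v_m1", "v_m3", "v_m4", "v_m5", "v_m4g"):
        if getattr(params, name) <= 0:
            report.append(f"non-positive volume: {name}")
    for name in ("bp_nal", "bp_m1", "bp_m3", "bp_m4", "bp_m5", "bp_m4g"):
        if getattr(params, name) <= 0:
            report.append(f"non-positive blood:plasma ratio: {name}")
    for name in ("f_m3", "f_m4", "f_m5"):
        if not 0.0 <= getattr(params, name) <= 1.0:
            report.append(f"fraction out of [0,1]: {name}")
    if params.dose_mg <= 0:
        report.append("non-positive dose")
    if params.q_h <= 0:
        report.append("non-positive hepatic blood flow")
    return report


def well_stirred_clh(cl_int: float, q_h: float, bp: float, fu: float = 1.0) -> float:
    """Hepatic plasma clearance from intrinsic clearance (well-stirred model).

    Implemented in blood terms: ``CL_b = Q * fu*CL_int / (Q + fu*CL_int)``,
    converted to plasma with the blood:plasma ratio, ``CL_H = BP * CL_b``.
    The unbound fraction `fu` defaults to 1 (see package notes); the result
    is strictly below the flow limit ``bp * q_h``.
    """
    if q_h <= 0 or bp <= 0:
        raise ValueError("q_h and bp must be strictly positive")
    if cl_int < 0:
        raise ValueError("cl_int must be >= 0")
    return bp * q_h * fu * cl_int / (q_h + fu * cl_int)


def well_stirred_clint(cl_h: float, q_h: float, bp: float, fu: float = 1.0) -> float:
    """Invert :func:`well_stirred_clh`: intrinsic clearance from plasma CL_H."""
    if q_h <= 0 or bp <= 0:
        raise ValueError("q_h and bp must be strictly positive")
    if cl_h < 0:
        raise ValueError("cl_h must be >= 0")
    cl_b = cl_h / bp
    if cl_b >= q_h:
        raise ValueError("cl_h reaches the hepatic flow limit; cannot invert")
    return q_h * cl_b / (q_h - cl_b) / fu


def initial_factor_a(clf_healthy: float, clf_impaired: float) -> float:
    """Initial impairment scaling factor from observed CL/F values.

    Assuming reciprocal changes in clearance and bioavailability,
    ``a = sqrt((CL/F)_healthy / (CL/F)_impaired)``.
    """
    if clf_healthy <= 0 or clf_impaired <= 0:
        raise ValueError("CL/F values must be strictly positive")
    return math.sqrt(clf_healthy / clf_impaired)


def partition_formation_clints(
    cl_int_h: float, f_m3: float, f_m4: float, f_m5: float
) -> dict[str, float]:
    """Split parent intrinsic clearance into per-metabolite formation CL_int."""
    if abs(f_m3 + f_m4 + f_m5 - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    return {"M3": f_m3 * cl_int_h, "M4": f_m4 * cl_int_h, "M5": f_m5 * cl_int_h}
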