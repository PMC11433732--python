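"""Continuous intestinal absorption: a 1-D convection-dispersion tube.

Four luminal species (parent, its 3-glucuronide, the hydroxy-metabolite
glucuronide, and the hydroxy metabolite regenerated from it) travel along a
normalized tube [0, 1] and exchange across four radial layers per node:
lumen (C1), apical membrane (C2), enterocyte cytosol (C3), intracellular
lipid (C4).  Glucuronidase in the distal zone hydrolyzes luminal
glucuronides back to their aglycones; absorption is the C3 -> portal flux.

Discretization is finite-volume method-of-lines: first-order upwind
convection, central-difference dispersion, zero-diffusive-flux boundaries,
convective outflow at the distal end (pre-systemic fecal loss).  All state
arrays carry amounts (mg) per cell; an optional trailing batch axis is
supported so the engine can probe the (linear) right-hand side with a basis
matrix in one call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "LUMINAL_SPECIES",
    "N_LAYERS",
    "SpatialGrid",
    "LayerExchange",
    "TransportParams",
    "make_grid",
    "dissolution_release",
    "gus_profile",
    "intestinal_rhs",
]

#: Species with a luminal presence, in state order.
LUMINAL_SPECIES = ("NAL", "M5", "M4G", "M4")

#: GUS hydrolysis map: glucuronide -> aglycone.
GUS_REACTIONS = {"M5": "NAL", "M4G": "M4"}

N_LAYERS = 4  # C1 lumen, C2 apical membrane, C3 enterocyte, C4 lipid


@dataclass(frozen=True)
class SpatialGrid:
    """Uniform finite-volume grid over the normalized tube length [0, 1]."""

    n_nodes: int
    gus_zone_start: float

    @property
    def cell_width(self) -> float:
        return 1.0 / self.n_nodes

    @property
    def centers(self) -> np.ndarray:
        return (np.arange(self.n_nodes) + 0.5) * self.cell_width

    @property
    def gus_mask(self) -> np.ndarray:
        """True for cells owned by the distal glucuronidase zone.

        Cell ownership is half-open [z_i, z_{i+1}); a cell is GUS-active
        when its left edge is at or beyond the zone start.
        """
        edges = np.arange(self.n_nodes) * self.cell_width
        return edges >= self.gus_zone_start - 1e-12


def make_grid(n_nodes: int, gus_zone_start: float = 0.75) -> SpatialGrid:
    """Build a uniform grid with a distal glucuronidase zone."""
    if n_nodes < 8:
        raise ValueError("n_nodes must be >= 8 (discretization too coarse)")
    if not 0.0 < gus_zone_start < 1.0:
        raise ValueError("gus_zone_start must lie strictly inside (0, 1)")
    return SpatialGrid(n_nodes=int(n_nodes), gus_zone_start=float(gus_zone_start))


@dataclass(frozen=True)
class LayerExchange:
    """Per-species first-order layer-exchange clearances, L/h."""

    cl_12: float = 0.0  # lumen -> apical membrane
    cl_21: float = 0.0
    cl_23: float = 0.0  # apical membrane -> enterocyte
    cl_32: float = 0.0
    cl_34: float = 0.0  # enterocyte -> intracellular lipid
    cl_43: float = 0.0
    cl_portal: float = 0.0  # enterocyte -> portal/liver (absorption)

    def __post_init__(self) -> None:
        for name in ("cl_12", "cl_21", "cl_23", "cl_32", "cl_34", "cl_43", "cl_portal"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def _default_exchange() -> dict[str, LayerExchange]:
    # Parent and regenerated hydroxy metabolite are freely permeable
    # (BCS I, permeability-nonlimited); glucuronides are too polar for
    # passive uptake and are absorbed only after hydrolysis.
    absorbable = LayerExchange(
        cl_12=3.0, cl_21=0.3, cl_23=50.0, cl_32=50.0, cl_34=10.0, cl_43=10.0,
        cl_portal=50.0,
    )
    polar = LayerExchange()
    return {"NAL": absorbable, "M5": polar, "M4G": polar, "M4": absorbable}


@dataclass(frozen=True)
class TransportParams:
    """Axial transport, layer geometry/exchange and luminal reaction settings."""

    velocity: float = 1.0 / 3.3  #: convective velocity, tube lengths / h
    dispersion: float = 0.0017  #: axial dispersion, tube lengths^2 / h
    v_lumen: float = 1.0  #: total luminal fluid volume, L
    v_apical: float = 0.05
    v_cyto: float = 0.2
    v_lipid: float = 0.2
    exchange: Mapping[str, LayerExchange] = field(default_factory=_default_exchange)
    gus_rate: float = 0.25  #: luminal hydrolysis rate constant in the GUS zone, 1/h
    k_rel: float = 0.25  #: first-order tablet release, 1/h
    gastric_emptying: float = 4.0  #: emptying of dissolved drug, 1/h
    enterocyte_loss: float = 0.0  #: optional gut-metabolism hook, 1/h on C3

    def __post_init__(self) -> None:
        for name in ("velocity", "dispersion", "gus_rate", "k_rel",
                     "gastric_emptying", "enterocyte_loss"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("v_lumen", "v_apical", "v_cyto", "v_lipid"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    def layer_volumes(self) -> np.ndarray:
        return np.array([self.v_lumen, self.v_apical, self.v_cyto, self.v_lipid])


def dissolution_release(stomach_amount: float, k_rel: float) -> float:
    """First-order release rate (mg/h) from the undissolved tablet depot."""
    if stomach_amount < 0:
        raise ValueError("stomach_amount must be >= 0")
    if k_rel < 0:
        raise ValueError("k_rel must be >= 0")
    return k_rel * stomach_amount


def gus_profile(grid: SpatialGrid, gus_rate: float) -> np.ndarray:
    """Per-node hydrolysis rate constants (1/h): zero proximal to the zone."""
    if gus_rate < 0:
        raise ValueError("gus_rate must be >= 0")
    return np.where(grid.gus_mask, gus_rate, 0.0)


def intestinal_rhs(
    amounts: np.ndarray,
    transport: TransportParams,
    grid: SpatialGrid,
    inlet: np.ndarray,
    mw: Mapping[str, float],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Time derivative of the intestinal state.

    Parameters
    ----------
    amounts
        Array of shape ``(4 species, 4 layers, n_nodes[, batch])`` holding
        amounts in mg per finite-volume cell.
    inlet
        Mass inflow (mg/h) into the luminal inlet cell per species, shape
        ``(4[, batch])`` (gastric emptying plus gallbladder ejection).
    mw
        Molecular weights keyed by species, used to keep glucuronide
        hydrolysis molar-conservative.

    Returns
    -------
    damounts, portal, fecal
        Derivative array (same shape as `amounts`), portal absorption flux
        per species (mg/h) and distal fecal outflow per species (mg/h).
        The optional enterocyte loss term is included in `fecal` as
        pre-systemic loss.
    """
    n = grid.n_nodes
    if amounts.shape[:3] != (len(LUMINAL_SPECIES), N_LAYERS, n):
        raise ValueError(
            f"state shape {amounts.shape} inconsistent with grid ({n} nodes)"
        )
    inlet = np.asarray(inlet)
    if inlet.shape[0] != len(LUMINAL_SPECIES) or inlet.shape[1:] != amounts.shape[3:]:
        raise ValueError("inlet shape inconsistent with state")

    h = grid.cell_width
    k_conv = transport.velocity / h
    k_disp = transport.dispersion / h**2
    d = np.zeros_like(amounts)
    portal = np.zeros_like(inlet, dtype=float)
    fecal = np.zeros_like(inlet, dtype=float)
    vols = transport.layer_volumes()
    kgus = gus_profile(grid, transport.gus_rate)
    kgus = kgus.reshape(kgus.shape + (1,) * (amounts.ndim - 3))

    lumen = amounts[:, 0]  # (4, n[, batch])

    # Axial convection (first-order upwind) with distal convective outflow.
    out = k_conv * lumen
    d[:, 0, 1:] += out[:, :-1] - out[:, 1:]
    d[:, 0, 0] -= out[:, 0]
    fecal += out[:, -1]

    # Axial dispersion, zero-flux (reflecting) at both boundaries.
    if k_disp > 0:
        lap = np.empty_like(lumen)
        lap[:, 1:-1] = lumen[:, 2:] - 2.0 * lumen[:, 1:-1] + lumen[:, :-2]
        lap[:, 0] = lumen[:, 1] - lumen[:, 0]
        lap[:, -1] = lumen[:, -2] - lumen[:, -1]
        d[:, 0] += k_disp * lap

    # Inlet sources (stomach delivery + biliary ejection) enter cell 0.
    d[:, 0, 0] += inlet

    # Distal glucuronidase: hydrolysis of luminal glucuronides to aglycones,
    # molar-conservative (mass scaled by the MW ratio).
    for glu, agly in GUS_REACTIONS.items():
        gi = LUMINAL_SPECIES.index(glu)
        ai = LUMINAL_SPECIES.index(agly)
        rate = kgus * amounts[gi, 0]
        d[gi, 0] -= rate
        d[ai, 0] += rate * (mw[agly] / mw[glu])

    # Radial layer exchange and absorption, species by species.
    for si, species in enumerate(LUMINAL_SPECIES):
        ex = transport.exchange[species]
        a1, a2, a3, a4 = amounts[si, 0], amounts[si, 1], amounts[si, 2], amounts[si, 3]
        f12 = (ex.cl_12 / vols[0]) * a1 - (ex.cl_21 / vols[1]) * a2
        f23 = (ex.cl_23 / vols[1]) * a2 - (ex.cl_32 / vols[2]) * a3
        f34 = (ex.cl_34 / vols[2]) * a3 - (ex.cl_43 / vols[3]) * a4
        absb = (ex.cl_portal / vols[2]) * a3
        loss = transport.enterocyte_loss * a3
        d[si, 0] -= f12
        d[si, 1] += f12 - f23
        d[si, 2] += f23 - f34 - absb - loss
        d[si, 3] += f34
        portal[si] += absb.sum(axis=0)
        if transport.enterocyte_loss > 0:
            fecal[si] += loss.sum(axis=0)

    return d, portal, fecal
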