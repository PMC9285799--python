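"""Dissolved-iron speciation and the external Fe sources.

Speciation partitions dissolved Fe between free inorganic Fe (Fe') and
organically complexed Fe (FeL), assuming 1:1 equilibrium with a single
ligand class:

    K' = [FeL] / ([Fe'] [L']),   L_T = [L'] + [FeL],   dFe = [Fe'] + [FeL].

Half of FeL is treated as colloidal; that colloidal half is the substrate
for aggregation ("colloidal pumping") while Fe' is the substrate for
particle scavenging.

Four external sources supply dissolved Fe, each with its own delta
endmember rule:

* dust — fixed endmember (crustal +0.09 permil by default);
* sediments — endmember mixes a reductive (light) and a non-reductive
  (crustal) component, weighted by a sediment-oxygenation factor that is
  either depth-dependent, uniform, or driven by the organic-carbon export
  reaching the seafloor;
* hydrothermal vents — Fe scaled to the 3He flux (1e7 mol Fe per mol He)
  with 0.5-fold co-injection of ligands, fixed endmember;
* rivers — fixed at 0 permil;
* sea ice — exchanges Fe with the delta of the local dissolved pool
  (non-fractionating), disabled by default in column setups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .grid import VerticalGrid
from .isotopes import (
    DEFAULT_STANDARD,
    IsotopeFluxPair,
    IsotopePool,
    ReferenceStandard,
    split_process_flux,
    split_source_flux,
)

__all__ = [
    "LigandField",
    "Speciation",
    "solve_speciation",
    "f_sed_depth",
    "f_sed_cexp",
    "SedimentEndmemberScheme",
    "sediment_endmember",
    "sediment_flux",
    "hydrothermal_source",
    "SourceSpec",
    "SourceTendency",
    "assemble_sources",
    "HYDROTHERMAL_FE_PER_HE",
    "HYDROTHERMAL_LIGAND_RATIO",
]

logger = logging.getLogger(__name__)

#: mol Fe injected per mol 3He at hydrothermal vents.
HYDROTHERMAL_FE_PER_HE = 1.0e7
#: mol ligand co-injected per mol hydrothermal Fe.
HYDROTHERMAL_LIGAND_RATIO = 0.5

ArrayLike = Union[float, np.ndarray]


@dataclass
class LigandField:
    """Fe-binding ligand pool: total concentration and conditional stability.

    Units: ``total_ligand`` mol m-3; ``cond_stability`` m3 mol-1
    (1e11 M-1 == 1e8 m3 mol-1).
    """

    total_ligand: ArrayLike
    cond_stability: ArrayLike

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.total_ligand) < 0):
            raise ValueError("total ligand concentration must be non-negative")
        if np.any(np.asarray(self.cond_stability) < 0):
            raise ValueError("conditional stability constant must be non-negative")


@dataclass
class Speciation:
    """Equilibrium partition of dissolved Fe (all mol m-3)."""

    fe_prime: ArrayLike
    feL: ArrayLike
    colloidal_feL_fraction: float = 0.5

    @property
    def total(self) -> ArrayLike:
        return self.fe_prime + self.feL

    @property
    def colloidal(self) -> ArrayLike:
        """Colloidal FeL, the substrate of colloidal pumping."""
        return self.colloidal_feL_fraction * self.feL


def solve_speciation(
    dfe_total: ArrayLike,
    lig: LigandField,
    colloidal_feL_fraction: float = 0.5,
) -> Speciation:
    """Partition dissolved Fe between Fe' and FeL at 1:1 ligand equilibrium.

    The equilibrium gives a quadratic in [FeL]; the physical root is

        FeL = ( b - sqrt(b^2 - 4 FeT LT) ) / 2,   b = FeT + LT + 1/K',

    evaluated in the numerically stable form 2 FeT LT / (b + sqrt(...)) so
    that small concentrations do not suffer cancellation.  Total dFe is
    conserved exactly (Fe' is computed by difference).
    """
    if not 0.0 <= colloidal_feL_fraction <= 1.0:
        raise ValueError("colloidal FeL fraction must lie in [0, 1]")
    scalar = not (np.ndim(dfe_total) or np.ndim(lig.total_ligand))
    fet = np.asarray(dfe_total, dtype=float)
    if np.any(fet < 0):
        raise ValueError("dissolved Fe concentration must be non-negative")
    lt = np.broadcast_to(np.asarray(lig.total_ligand, dtype=float), fet.shape).astype(float)
    k = np.broadcast_to(np.asarray(lig.cond_stability, dtype=float), fet.shape).astype(float)

    feL = np.zeros_like(fet)
    ok = (k > 0) & (lt > 0) & (fet > 0)
    if np.any(ok):
        b = fet[ok] + lt[ok] + 1.0 / k[ok]
        disc = b * b - 4.0 * fet[ok] * lt[ok]
        # disc >= 0 always (b >= FeT + LT >= 2 sqrt(FeT LT)); clip roundoff
        root = np.sqrt(np.maximum(disc, 0.0))
        feL[ok] = 2.0 * fet[ok] * lt[ok] / (b + root)
    feL = np.minimum(feL, fet)  # guard roundoff
    fe_prime = fet - feL
    if scalar:
        return Speciation(float(fe_prime), float(feL), colloidal_feL_fraction)
    return Speciation(fe_prime, feL, colloidal_feL_fraction)


def f_sed_depth(
    depth: ArrayLike,
    shelf_depth: float = 400.0,
    deep_value: float = 0.003,
    e_folding: float = 250.0,
) -> ArrayLike:
    """Depth-dependent sediment oxygenation factor F_sed.

    Equals 1 on the shelf (depth <= 400 m) and relaxes exponentially to the
    deep asymptote ~0.003 (crustal, non-reductive conditions) with a 250 m
    e-folding scale, reaching <0.01 by ~2000 m.
    """
    scalar = not np.ndim(depth)
    z = np.asarray(depth, dtype=float)
    if np.any(z < 0):
        raise ValueError("depth must be non-negative")
    f = np.where(
        z <= shelf_depth,
        1.0,
        deep_value + (1.0 - deep_value) * np.exp(-(z - shelf_depth) / e_folding),
    )
    return float(f) if scalar else f


def f_sed_cexp(c_exp: ArrayLike, k_cexp: float = 60.0) -> ArrayLike:
    """Carbon-export based oxygenation factor: Cexp / (K + Cexp).

    ``c_exp`` and ``k_cexp`` share units (nmol C m-2 s-1 by convention;
    default half-saturation 60).  Bounded in [0, 1), saturating.
    """
    if not k_cexp > 0:
        raise ValueError("half-saturation constant must be positive")
    scalar = not np.ndim(c_exp)
    c = np.asarray(c_exp, dtype=float)
    if np.any(c < 0):
        raise ValueError("carbon export must be non-negative")
    f = c / (k_cexp + c)
    return float(f) if scalar else f


@dataclass
class SedimentEndmemberScheme:
    """Rule mapping local conditions to the sediment delta endmember.

    Modes: ``depth_dependent`` (reductive share = F_sed(z)), ``c_export``
    (reductive share = Cexp/(K+Cexp)), ``uniform`` (fixed value everywhere).
    Deltas in permil.
    """

    mode: str = "depth_dependent"
    delta_rd: float = -1.0
    delta_nrd: float = 0.09
    uniform_value: float = -0.8
    k_cexp: float = 60.0
    shelf_depth: float = 400.0
    deep_value: float = 0.003
    e_folding: float = 250.0

    def __post_init__(self) -> None:
        if self.mode not in ("depth_dependent", "uniform", "c_export"):
            raise ValueError(f"unknown sediment endmember mode {self.mode!r}")
        if not self.k_cexp > 0:
            raise ValueError("k_cexp must be positive")

    def reductive_fraction(self, depth: ArrayLike, c_exp: Optional[ArrayLike] = None) -> ArrayLike:
        if self.mode == "uniform":
            return np.ones_like(np.asarray(depth, dtype=float)) if np.ndim(depth) else 1.0
        if self.mode == "depth_dependent":
            return f_sed_depth(depth, self.shelf_depth, self.deep_value, self.e_folding)
        if c_exp is None:
            raise ValueError("c_export mode requires a seafloor carbon-export value")
        return f_sed_cexp(c_exp, self.k_cexp)

    def endmember(self, depth: ArrayLike, c_exp: Optional[ArrayLike] = None) -> ArrayLike:
        if self.mode == "uniform":
            return self.uniform_value
        return sediment_endmember(self.reductive_fraction(depth, c_exp), self)


def sediment_endmember(f: ArrayLike, scheme: SedimentEndmemberScheme) -> ArrayLike:
    """Mix reductive and non-reductive sediment endmembers.

    delta = f * delta_RD + (1 - f) * delta_NRD for reductive fraction
    f in [0, 1]; ``uniform`` schemes return the uniform value regardless.
    """
    if scheme.mode == "uniform":
        return scheme.uniform_value
    fa = np.asarray(f, dtype=float)
    if np.any(fa < 0) or np.any(fa > 1):
        raise ValueError("reductive fraction must lie in [0, 1]")
    out = fa * scheme.delta_rd + (1.0 - fa) * scheme.delta_nrd
    return float(out) if not np.ndim(f) else out


def sediment_flux(f_max: ArrayLike, f_sed: ArrayLike, pct_sed: ArrayLike = 1.0) -> ArrayLike:
    """Sedimentary Fe flux: maximum flux x oxygenation factor x seafloor
    area fraction of the cell."""
    fm = np.asarray(f_max, dtype=float)
    fs = np.asarray(f_sed, dtype=float)
    pc = np.asarray(pct_sed, dtype=float)
    if np.any(fm < 0) or np.any(fs < 0):
        raise ValueError("fluxes and factors must be non-negative")
    if np.any(pc < 0) or np.any(pc > 1):
        raise ValueError("seafloor area fraction must lie in [0, 1]")
    out = fm * fs * pc
    scalar = not (np.ndim(f_max) or np.ndim(f_sed) or np.ndim(pct_sed))
    return float(out) if scalar else out


def hydrothermal_source(he3_flux: ArrayLike) -> tuple:
    """Hydrothermal Fe and co-injected ligand fluxes from a 3He flux.

    Fe = 1e7 x He (mol Fe per mol He); ligand = 0.5 x Fe.
    """
    he = np.asarray(he3_flux, dtype=float)
    if np.any(he < 0):
        raise ValueError("3He flux must be non-negative")
    fe = HYDROTHERMAL_FE_PER_HE * he
    lig = HYDROTHERMAL_LIGAND_RATIO * fe
    if not np.ndim(he3_flux):
        return float(fe), float(lig)
    return fe, lig


@dataclass
class SourceSpec:
    """One external Fe source expressed as a per-cell volumetric tendency.

    ``flux`` is mol Fe m-3 s-1 per grid cell (boundary fluxes are divided
    by the receiving cell thickness before they get here).  The endmember
    rule is a fixed delta, a sediment scheme, or, for sea ice, the local
    dissolved pool.  ``ligand_ratio`` co-injects ligands (mol L per mol Fe).
    """

    kind: str
    flux: np.ndarray
    endmember: Optional[float] = None
    scheme: Optional[SedimentEndmemberScheme] = None
    ligand_ratio: float = 0.0
    c_exp: Optional[float] = None

    KINDS = ("dust", "sediment", "hydrothermal", "river", "ice")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown source kind {self.kind!r}")
        if np.any(np.asarray(self.flux) < 0):
            raise ValueError("source strengths must be non-negative")


@dataclass
class SourceTendency:
    """Summed per-cell source tendencies (mol m-3 s-1)."""

    fe: IsotopeFluxPair
    ligand: np.ndarray
    per_source: dict = field(default_factory=dict)


def assemble_sources(
    sources: Sequence[SourceSpec],
    grid: VerticalGrid,
    dfe_pool: IsotopePool,
    std: ReferenceStandard = DEFAULT_STANDARD,
) -> SourceTendency:
    """Split every source's bulk flux into isotope pairs and sum them.

    Fixed-endmember sources (dust, hydrothermal, river) use their
    prescribed delta; sediment sources evaluate their scheme at the local
    cell-bottom depth (or the configured seafloor carbon export); sea ice
    transfers Fe at the local dissolved pool's ratio (non-fractionating).
    The bulk Fe input strength is preserved exactly per source.
    """
    n = grid.n
    fe56 = np.zeros(n)
    fe54 = np.zeros(n)
    ligand = np.zeros(n)
    per_source: dict = {}
    for src in sources:
        flux = np.broadcast_to(np.asarray(src.flux, dtype=float), (n,))
        if src.kind == "sediment":
            if src.scheme is None:
                raise ValueError("sediment source requires an endmember scheme")
            delta = src.scheme.endmember(grid.bottom, src.c_exp)
            pair = split_source_flux(flux, np.broadcast_to(np.asarray(delta), (n,)), std)
        elif src.kind == "ice":
            pair = split_process_flux(flux, dfe_pool, 1.0)
        else:
            if src.endmember is None:
                raise ValueError(f"{src.kind} source requires a fixed endmember delta")
            pair = split_source_flux(flux, src.endmember, std)
        fe56 += pair.j56
        fe54 += pair.j54
        ligand += src.ligand_ratio * flux
        per_source[src.kind] = pair
    return SourceTendency(IsotopeFluxPair(fe56, fe54), ligand, per_source)
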