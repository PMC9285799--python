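"""Internal Fe-cycle transformations and their isotope behaviour.

Only two processes fractionate in the standard configuration:

* phytoplankton uptake of dissolved Fe, with alpha_uptake = 0.9995
  (preferential uptake of light Fe, same for both size classes);
* organic complexation, with alpha_complex = 1.0006, realised *indirectly*
  through the two abiotic removal pathways — colloidal pumping removes FeL
  (heavy-favouring, alpha) and particle scavenging removes Fe'
  (light-favouring, 1/alpha).

Everything else — remineralization of particulate Fe, zooplankton
recycling and losses, bacterial uptake — transfers Fe at the donor pool's
own ratio (alpha = 1), so any isotopic effect of those pathways is an
emergent consequence of which pools they connect, not of the transfer
itself.

All transfers here are expressed as isotope flux pairs drawn from a donor
pool; callers move the amounts, so conservation of each isotope between
donor and recipient is exact by construction.  When a discrete time step
would transfer more Fe than the donor holds, the transfer is clipped
proportionally (bulk and both isotopes by the same factor) and a warning
is logged — the continuous-time rate laws know nothing about step size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Union

import numpy as np

from .isotopes import FractionationFactor, IsotopeFluxPair, IsotopePool, split_process_flux
from .speciation import Speciation

__all__ = [
    "CyclingParams",
    "uptake_transfer",
    "scavenge_transfer",
    "colloidal_pump_transfer",
    "remineralize_transfer",
    "recycle_and_bacteria",
    "clip_to_donor",
]

logger = logging.getLogger(__name__)

ArrayLike = Union[float, np.ndarray]


@dataclass
class CyclingParams:
    """Fractionation factors and bulk rate constants of internal cycling.

    Rate constants are first-order (s-1) on their respective substrates;
    the Michaelis-Menten half-saturation applies to biological uptake.
    """

    alpha_uptake: float = 0.9995
    alpha_complex: float = 1.0006
    k_scavenge: float = 1.0e-5      # s-1, x particle load, on Fe'
    k_colloidal: float = 5.0e-9     # s-1, on colloidal FeL
    k_remin_small: float = 0.05 / 86400.0   # s-1, small particles
    k_remin_large: float = 0.02 / 86400.0   # s-1, large particles
    k_loss_phyto: float = 0.1 / 86400.0     # s-1, grazing + mortality
    recycle_fraction: float = 0.6   # share of phyto losses recycled to dFe
    small_particle_fraction: float = 0.75  # share of the particulate remainder
    k_bacteria: float = 1.0e-8      # s-1, dFe -> small pFe
    uptake_vmax: float = 3.0e-13    # mol m-3 s-1 at unit biomass forcing
    uptake_km: float = 2.0e-7       # mol m-3, Michaelis-Menten half-sat

    def __post_init__(self) -> None:
        FractionationFactor(self.alpha_uptake)
        FractionationFactor(self.alpha_complex)
        for name in (
            "k_scavenge", "k_colloidal", "k_remin_small", "k_remin_large",
            "k_loss_phyto", "k_bacteria", "uptake_vmax", "uptake_km",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.recycle_fraction <= 1.0:
            raise ValueError("recycle_fraction must lie in [0, 1]")
        if not 0.0 <= self.small_particle_fraction <= 1.0:
            raise ValueError("small_particle_fraction must lie in [0, 1]")


def clip_to_donor(
    pair: IsotopeFluxPair,
    donor: IsotopePool,
    dt: float,
    label: str = "transfer",
) -> IsotopeFluxPair:
    """Scale a flux pair so that neither isotope overdraws the donor in dt.

    The bulk flux and both isotope components are scaled by the same
    factor, preserving the pair's delta.  Clipping is logged.
    """
    amount56 = np.asarray(pair.j56) * dt
    amount54 = np.asarray(pair.j54) * dt
    avail56 = np.asarray(donor.fe56, dtype=float)
    avail54 = np.asarray(donor.fe54, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        f56 = np.where(amount56 > 0, avail56 / np.where(amount56 > 0, amount56, 1.0), np.inf)
        f54 = np.where(amount54 > 0, avail54 / np.where(amount54 > 0, amount54, 1.0), np.inf)
    factor = np.minimum(1.0, np.minimum(f56, f54))
    if np.any(factor < 1.0):
        logger.warning(
            "%s clipped in %d cell(s): step would overdraw donor pool", label,
            int(np.sum(factor < 1.0)),
        )
    scaled = pair.scaled(factor)
    if not np.ndim(pair.j56):
        return IsotopeFluxPair(float(np.asarray(scaled.j56)), float(np.asarray(scaled.j54)))
    return scaled


def uptake_transfer(
    dfe: IsotopePool,
    demand: ArrayLike,
    params: CyclingParams,
) -> IsotopeFluxPair:
    """Phytoplankton Fe uptake from the bulk dissolved pool.

    ``demand`` is the bulk uptake rate (mol m-3 s-1); the transfer samples
    the dissolved pool's ratio biased by alpha_uptake (< 1: the residual
    dissolved pool drifts heavy as uptake proceeds).
    """
    return split_process_flux(demand, dfe, params.alpha_uptake)


def scavenge_transfer(
    dfe: IsotopePool,
    spec: Speciation,
    particle_load: ArrayLike,
    params: CyclingParams,
) -> IsotopeFluxPair:
    """Abiotic scavenging of Fe' onto particles.

    Bulk rate k_scav x particle load x [Fe']; the isotope split uses the
    *inverse* complexation factor (1/alpha_complex), i.e. scavenging
    preferentially removes light Fe because the heavy fraction is held by
    ligands.
    """
    bulk = params.k_scavenge * np.asarray(particle_load, dtype=float) * np.asarray(
        spec.fe_prime, dtype=float
    )
    return split_process_flux(bulk, dfe, 1.0 / params.alpha_complex)


def colloidal_pump_transfer(
    dfe: IsotopePool,
    spec: Speciation,
    params: CyclingParams,
) -> IsotopeFluxPair:
    """Aggregation of colloidal FeL onto particles ("colloidal pumping").

    Bulk rate k_colloidal x colloidal FeL (half of FeL); the split uses
    alpha_complex directly, preferentially removing heavy Fe.
    """
    bulk = params.k_colloidal * np.asarray(spec.colloidal, dtype=float)
    return split_process_flux(bulk, dfe, params.alpha_complex)


def remineralize_transfer(pfe: IsotopePool, rate: ArrayLike) -> IsotopeFluxPair:
    """Release of dissolved Fe from a particulate pool, non-fractionating.

    The transferred flux carries the particle pool's own ratio (alpha = 1);
    any lightening of the dissolved pool by remineralization reflects the
    particles being lighter than ambient dFe, not the process itself.
    """
    return split_process_flux(rate, pfe, 1.0)


def recycle_and_bacteria(
    phyto: IsotopePool,
    dfe: IsotopePool,
    params: CyclingParams,
) -> dict:
    """Delta-preserving transfers around the biological loop.

    Phytoplankton losses (grazing + mortality, first-order k_loss_phyto)
    are split into a recycled share returned to dFe and a particulate
    remainder partitioned between small and large particles; bacterial
    uptake moves dFe to small particles.  All at alpha = 1, so every flux
    carries its donor's delta and total Fe is conserved by the caller's
    pool updates.

    Returns a dict of flux pairs (mol m-3 s-1):
    ``to_dfe``, ``to_small``, ``to_large`` (from phytoplankton) and
    ``bacteria_to_small`` (from dFe).
    """
    loss_bulk = params.k_loss_phyto * np.asarray(phyto.total, dtype=float)
    loss = split_process_flux(loss_bulk, phyto, 1.0)
    to_dfe = loss.scaled(params.recycle_fraction)
    particulate = loss.scaled(1.0 - params.recycle_fraction)
    to_small = particulate.scaled(params.small_particle_fraction)
    to_large = particulate.scaled(1.0 - params.small_particle_fraction)
    bact_bulk = params.k_bacteria * np.asarray(dfe.total, dtype=float)
    bacteria = split_process_flux(bact_bulk, dfe, 1.0)
    return {
        "to_dfe": to_dfe,
        "to_small": to_small,
        "to_large": to_large,
        "bacteria_to_small": bacteria,
    }
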