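"""Forward model for size- and temperature-dependent community metabolism.

Individual metabolic rate is modelled as a power law in carbon mass (exponent
``alpha``) multiplied by a Boltzmann–Arrhenius temperature response (activation
energy ``E`` in eV), normalised at a reference temperature ``Tc``::

    b_i(T) = b(Tc) * m_i**alpha * exp(E * (1/(k*Tc) - 1/(k*T)))

Community rate is the sum of individual rates over the whole assemblage, scaled
to per-litre abundance. All rate algebra is done on the natural-log scale
internally; exponentiation happens only at the I/O boundary.

.. note:: **Temperature-correction convention.** The corrected rate is the
   observed rate *divided* by the Arrhenius factor ``exp(E*(1/(k*Tc)-1/(k*T)))``.
   Multiplying instead (a plausible reading of the rearranged balance identity)
   would inflate warm-assay rates rather than remove the direct temperature
   effect; with the division convention a noise-free model rate corrects exactly
   onto mass-corrected biomass.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import DataError

#: Boltzmann's constant in eV/K, fixed to the three-digit value used throughout
#: (not the longer CODATA expansion).
BOLTZMANN_EV = 8.62e-5

#: Default reference temperature Tc = 18 degC in Kelvin.
T_REF = 291.15

__all__ = [
    "BOLTZMANN_EV",
    "T_REF",
    "MSTParams",
    "Community",
    "CommunitySummary",
    "boltzmann_factor",
    "q10_from_E",
    "individual_rate",
    "community_rate",
    "mass_corrected_biomass",
    "temperature_correct",
    "average_individual_rate",
]


@dataclass(frozen=True)
class MSTParams:
    """Parameters of the individual metabolic-rate model for one flux.

    Attributes
    ----------
    ln_b_tc:
        Natural log of the metabolic normalisation at ``t_ref``
        (log umol O2 L^-1 h^-1 per unit mass**alpha).
    alpha:
        Dimensionless size-scaling exponent.
    activation_energy:
        Activation energy E in eV.
    sigma:
        Lognormal observation-error SD (log units); 0 means noise-free.
    t_ref:
        Reference temperature Tc in Kelvin.
    """

    ln_b_tc: float
    alpha: float
    activation_energy: float
    sigma: float = 0.0
    t_ref: float = T_REF

    def __post_init__(self) -> None:
        if not np.isfinite(self.ln_b_tc):
            raise DataError("ln_b_tc must be finite")
        if not np.isfinite(self.alpha):
            raise DataError("alpha must be finite")
        if not np.isfinite(self.activation_energy):
            raise DataError("activation_energy must be finite")
        if self.sigma < 0:
            raise DataError(f"sigma must be >= 0, got {self.sigma}")
        if self.t_ref <= 0:
            raise DataError(f"t_ref must be > 0 K, got {self.t_ref}")


@dataclass
class Community:
    """One microcosm: labels, assay temperature, masses and measured fluxes.

    ``masses`` holds the individual carbon masses (ug C) of the sampled cells;
    ``scale_to_litre`` converts that sample to per-litre abundance, so
    ``n_tot = len(masses) * scale_to_litre``.
    """

    id: str
    mesocosm_treatment: str
    incubator_t: float
    masses: np.ndarray
    scale_to_litre: float = 1.0
    gpp_obs: Optional[float] = None
    cr_obs: Optional[float] = None
    mesocosm: Optional[str] = None
    incubator_treatment: Optional[str] = None

    def __post_init__(self) -> None:
        self.masses = np.asarray(self.masses, dtype=float)
        if self.incubator_t <= 0:
            raise DataError(f"{self.id}: incubator_t must be > 0 K")
        if self.masses.size and np.any(self.masses <= 0):
            raise DataError(f"{self.id}: all individual masses must be > 0")
        if self.scale_to_litre <= 0:
            raise DataError(f"{self.id}: scale_to_litre must be > 0")

    @property
    def n_tot(self) -> float:
        """Total abundance, cells per litre."""
        return self.masses.size * self.scale_to_litre

    @property
    def m_tot(self) -> float:
        """Total biomass, ug C per litre."""
        return float(self.masses.sum() * self.scale_to_litre)

    def observed_rate(self, flux: str) -> float:
        value = {"gpp": self.gpp_obs, "cr": self.cr_obs}.get(flux.lower())
        if value is None:
            raise DataError(f"{self.id}: no observed {flux} rate")
        return value


@dataclass(frozen=True)
class CommunitySummary:
    """Per-community aggregates of the individual size distribution."""

    n_tot: float
    m_tot: float
    mean_mass: float
    mass_corrected_biomass: Optional[float] = None
    avg_individual_rate: Optional[float] = None
    density_grid: Optional[np.ndarray] = field(default=None, compare=False)
    density: Optional[np.ndarray] = field(default=None, compare=False)


def boltzmann_factor(E: float, T: float, Tc: float = T_REF) -> float:
    """Arrhenius factor ``exp(E * (1/(k*Tc) - 1/(k*T)))``.

    Greater than 1 when ``T > Tc`` and ``E > 0``; exactly 1 at ``T == Tc``
    or ``E == 0``.
    """
    if T <= 0 or Tc <= 0:
        raise DataError(f"temperatures must be > 0 K (got T={T}, Tc={Tc})")
    k = BOLTZMANN_EV
    return float(np.exp(E * (1.0 / (k * Tc) - 1.0 / (k * T))))


def q10_from_E(E: float, t_low: float = 286.15, t_high: float = 296.15) -> float:
    """Q10 factor implied by activation energy ``E`` over a 10-K interval.

    The default interval (286.15–296.15 K) is the 10 degC window centred on
    the reference temperature 18 degC.
    """
    if abs((t_high - t_low) - 10.0) > 1e-9:
        raise DataError(
            f"Q10 requires t_high = t_low + 10 K (got {t_low}, {t_high})"
        )
    if t_low <= 0:
        raise DataError("temperatures must be > 0 K")
    k = BOLTZMANN_EV
    return float(np.exp((E / k) * (1.0 / t_low - 1.0 / t_high)))


def individual_rate(params: MSTParams, m, T: float):
    """Metabolic rate of an individual of mass ``m`` (ug C) at temperature ``T``."""
    m = np.asarray(m, dtype=float)
    if np.any(m <= 0):
        raise DataError("individual mass must be > 0")
    rate = np.exp(params.ln_b_tc) * m**params.alpha
    rate = rate * boltzmann_factor(params.activation_energy, T, params.t_ref)
    return float(rate) if rate.ndim == 0 else rate


def community_rate(params: MSTParams, community: Community) -> float:
    """Whole-community rate: per-litre sum of individual rates (additive)."""
    if community.masses.size == 0:
        raise DataError(f"{community.id}: empty mass vector")
    # log-sum-exp over log individual rates keeps extreme masses stable
    log_terms = (
        params.ln_b_tc
        + params.alpha * np.log(community.masses)
        + params.activation_energy
        * (1.0 / (BOLTZMANN_EV * params.t_ref) - 1.0 / (BOLTZMANN_EV * community.incubator_t))
    )
    m = log_terms.max()
    log_sum = m + np.log(np.exp(log_terms - m).sum())
    return float(np.exp(log_sum + np.log(community.scale_to_litre)))


def mass_corrected_biomass(
    masses, alpha: float, ln_b_tc: float, scale_to_litre: float = 1.0
) -> float:
    """Size-structure-aware metabolic capacity of the standing biomass.

    Equals ``b(Tc) * sum(m_i**alpha) * scale``, i.e. total biomass times the
    biomass-weighted mean of ``m**(alpha-1)`` under a common normalisation;
    identical to the community rate evaluated at the reference temperature.
    """
    masses = np.asarray(masses, dtype=float)
    if masses.size == 0:
        raise DataError("empty mass vector")
    if np.any(masses <= 0):
        raise DataError("all masses must be > 0")
    log_terms = ln_b_tc + alpha * np.log(masses)
    m = log_terms.max()
    return float(np.exp(m + np.log(np.exp(log_terms - m).sum()) + np.log(scale_to_litre)))


def temperature_correct(rate_obs: float, E: float, T: float, Tc: float = T_REF) -> float:
    """Remove the direct Arrhenius temperature effect from an observed rate.

    Divides by ``boltzmann_factor(E, T, Tc)`` — see the module note on the
    sign convention. At ``T == Tc`` the rate is returned unchanged.
    """
    if rate_obs <= 0:
        raise DataError(f"observed rate must be > 0, got {rate_obs}")
    return rate_obs / boltzmann_factor(E, T, Tc)


def average_individual_rate(community: Community, params: MSTParams) -> float:
    """Per-capita community rate: community rate divided by total abundance.

    Invariant to replicating every individual (ratio of extensive quantities).
    """
    n = community.n_tot
    if n <= 0:
        raise DataError(f"{community.id}: zero total abundance")
    return community_rate(params, community) / n
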