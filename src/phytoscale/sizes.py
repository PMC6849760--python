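"""Cytometry-to-carbon conversion and individual-size-distribution summaries.

Forward scatter is mapped to equivalent spherical diameter via a config-
injected power-law calibration (the coefficients are instrument-specific and
must be supplied); diameter to carbon via spherical biovolume and the fixed
carbon conversion 0.109e-6 ug C per um^3. Heterotroph records are summarised
(biomass fraction, warning above a threshold) and excluded from the scaling
analysis, which uses autotroph masses only.
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .core import Community, CommunitySummary, MSTParams, average_individual_rate, mass_corrected_biomass
from .errors import ConfigError, DataError

__all__ = [
    "CARBON_PER_UM3",
    "fsc_to_diameter",
    "diameter_to_carbon",
    "heterotroph_biomass_fraction",
    "summarise_isd",
    "read_cytometry",
    "cytometry_to_masses",
]

#: ug C per um^3 of biovolume.
CARBON_PER_UM3 = 0.109e-6

POPULATIONS = ("autotroph", "heterotroph")


def fsc_to_diameter(fsc, a: float, b: float):
    """Power-law calibration d = a * fsc**b (um); monotone increasing in fsc."""
    if a <= 0:
        raise ConfigError("calibration coefficient a must be > 0")
    if b == 0:
        warnings.warn("calibration exponent b = 0: all diameters collapse to a", stacklevel=2)
    fsc = np.asarray(fsc, dtype=float)
    if np.any(fsc <= 0):
        raise DataError("forward-scatter values must be > 0")
    d = a * fsc**b
    return float(d) if d.ndim == 0 else d


def diameter_to_carbon(d):
    """Carbon mass (ug C) of a spherical cell of diameter ``d`` um.

    Biovolume V = (4/3) * pi * (d/2)**3; mass = 0.109e-6 * V.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d <= 0):
        raise DataError("diameters must be > 0")
    volume = (4.0 / 3.0) * np.pi * (d / 2.0) ** 3
    m = CARBON_PER_UM3 * volume
    return float(m) if m.ndim == 0 else m


def heterotroph_biomass_fraction(
    records: pd.DataFrame, threshold: float = 0.05
) -> pd.Series:
    """Heterotroph share of total carbon per community; warns above threshold.

    Expects columns community_id, population, mass_ug_c. Communities with no
    heterotroph records get fraction 0.
    """
    required = {"community_id", "population", "mass_ug_c"}
    if not required.issubset(records.columns):
        raise DataError(f"cytometry mass table needs columns {sorted(required)}")
    bad = set(records["population"]) - set(POPULATIONS)
    if bad:
        raise DataError(f"unknown population labels: {sorted(bad)}")
    total = records.groupby("community_id")["mass_ug_c"].sum()
    het = (
        records[records["population"] == "heterotroph"]
        .groupby("community_id")["mass_ug_c"]
        .sum()
        .reindex(total.index, fill_value=0.0)
    )
    frac = het / total
    flagged = frac[frac >= threshold]
    for cid, f in flagged.items():
        warnings.warn(
            f"community {cid}: heterotrophs are {f:.1%} of carbon biomass "
            f"(threshold {threshold:.0%})",
            stacklevel=2,
        )
    return frac


def summarise_isd(
    community: Community,
    params: Optional[MSTParams] = None,
    n_grid: int = 256,
) -> CommunitySummary:
    """Aggregate one community's individual size distribution.

    Returns abundance, biomass and mean mass; with fitted ``params`` also the
    mass-corrected biomass and per-capita model rate. The kernel density is
    evaluated on a log-mass grid and normalised so it integrates to 1 over
    that grid (density of ln mass).
    """
    if community.masses.size == 0:
        raise DataError(f"{community.id}: no masses")
    n_tot = community.n_tot
    m_tot = community.m_tot
    mean_mass = m_tot / n_tot
    mcb = avg_rate = None
    if params is not None:
        mcb = mass_corrected_biomass(
            community.masses, params.alpha, params.ln_b_tc, community.scale_to_litre
        )
        avg_rate = average_individual_rate(community, params)
    grid = density = None
    log_m = np.log(community.masses)
    if np.unique(log_m).size > 1:
        kde = gaussian_kde(log_m)
        pad = 3.0 * kde.factor * log_m.std(ddof=1)
        grid = np.linspace(log_m.min() - pad, log_m.max() + pad, n_grid)
        density = kde(grid)
        density = density / np.trapezoid(density, grid)
    return CommunitySummary(
        n_tot=n_tot,
        m_tot=m_tot,
        mean_mass=mean_mass,
        mass_corrected_biomass=mcb,
        avg_individual_rate=avg_rate,
        density_grid=grid,
        density=density,
    )


def read_cytometry(path, calibration: Optional[dict] = None) -> pd.DataFrame:
    """Read an exported cytometry event table (CSV) into a tidy mass table.

    The file must carry exactly one of the columns ``fsc`` or ``diameter``
    plus community_id and population; FSC input additionally requires the
    power-law ``calibration`` dict with keys ``a`` and ``b``. Returns columns
    community_id, population, diameter_um, mass_ug_c.
    """
    df = pd.read_csv(path)
    return cytometry_to_masses(df, calibration=calibration)


def cytometry_to_masses(df: pd.DataFrame, calibration: Optional[dict] = None) -> pd.DataFrame:
    has_fsc = "fsc" in df.columns
    has_diam = "diameter" in df.columns
    if has_fsc == has_diam:
        raise DataError("cytometry table must have exactly one of 'fsc' or 'diameter'")
    if not {"community_id", "population"}.issubset(df.columns):
        raise DataError("cytometry table needs community_id and population columns")
    if has_fsc:
        if not calibration or not {"a", "b"} <= set(calibration):
            raise ConfigError(
                "forward-scatter input requires calibration={'a':..,'b':..}; "
                "supply it or provide a 'diameter' column instead"
            )
        diam = fsc_to_diameter(df["fsc"].to_numpy(), calibration["a"], calibration["b"])
    else:
        diam = df["diameter"].to_numpy(dtype=float)
    out = df[["community_id", "population"]].copy()
    out["diameter_um"] = diam
    out["mass_ug_c"] = diameter_to_carbon(diam)
    return out
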