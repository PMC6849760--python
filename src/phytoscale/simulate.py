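"""Synthetic communities with the statistical structure the analysis assumes.

The simulator reproduces a 2x2x10 reciprocal-transplant design: 10 mesocosms
per long-term treatment (ambient / warm), each inoculated into an ambient and
a warm incubator, giving 40 communities. Individual masses are lognormal with
treatment-specific arithmetic means (warm communities dominated by larger
cells); observed rates follow the forward model with multiplicative lognormal
noise; and, under the zero-sum energy budget, total abundance trades off
exactly against per-capita rate.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import picurve as _picurve
from .core import Community, MSTParams, average_individual_rate, community_rate
from .errors import ConfigError

__all__ = [
    "SimulationConfig",
    "simulate_size_distribution",
    "simulate_community",
    "simulate_experiment",
    "simulate_pi_curves",
    "simulate_asv_table",
    "write_simulated_dataset",
]

TREATMENTS = ("ambient", "warm")

# Table-style default truths for the two fluxes (per-litre rate convention).
DEFAULT_GPP_PARAMS = MSTParams(ln_b_tc=-3.46, alpha=0.88, activation_energy=0.61)
DEFAULT_CR_PARAMS = MSTParams(ln_b_tc=-5.50, alpha=0.80, activation_energy=1.27)


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs for the synthetic experiment; defaults give a realistic design."""

    n_mesocosms_per_treatment: int = 10
    incubator_temps: tuple[float, float] = (289.15, 293.15)
    mean_mass_ambient: float = 3.6e-5
    mean_mass_warm: float = 1.06e-4
    mass_logsd: float = 1.0
    #: lognormal SD of per-mesocosm mean mass around the treatment mean
    #: (within-treatment size-structure variance; unconstrained by design).
    mesocosm_mass_logsd: float = 0.25
    n_cells: int = 10_000
    true_params_gpp: MSTParams = DEFAULT_GPP_PARAMS
    true_params_cr: MSTParams = DEFAULT_CR_PARAMS
    #: zero-sum community energy budget for gross production (rate units);
    #: None disables the zero-sum rule and uses ``fixed_abundance`` instead.
    total_energy: Optional[float] = 5.0
    fixed_abundance: float = 1.0e6
    noise_sd: float = 0.3
    abundance_noise_sd: float = 0.0
    seed: int = 0
    # ASV-table knobs
    n_taxa: int = 30
    library_size: int = 10_000
    composition_effect: float = 0.8
    taxon_concentration: float = 50.0
    p_low_reads: float = 0.0

    def __post_init__(self) -> None:
        if self.n_mesocosms_per_treatment < 1:
            raise ConfigError("n_mesocosms_per_treatment must be >= 1")
        if self.n_cells < 1:
            raise ConfigError("n_cells must be >= 1")
        for name in ("mean_mass_ambient", "mean_mass_warm"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        if self.mass_logsd < 0 or self.mesocosm_mass_logsd < 0:
            raise ConfigError("log-SDs must be >= 0")
        if self.noise_sd < 0 or self.abundance_noise_sd < 0:
            raise ConfigError("noise SDs must be >= 0")
        if self.total_energy is not None and self.total_energy <= 0:
            raise ConfigError("total_energy must be > 0 when set")
        if self.fixed_abundance <= 0:
            raise ConfigError("fixed_abundance must be > 0")
        if not 0.0 <= self.p_low_reads <= 1.0:
            raise ConfigError("p_low_reads must be in [0, 1]")

    def mean_mass(self, treatment: str) -> float:
        if treatment not in TREATMENTS:
            raise ConfigError(f"unknown treatment {treatment!r}")
        return self.mean_mass_ambient if treatment == "ambient" else self.mean_mass_warm


def _lognormal_mean_preserving(rng, arithmetic_mean, logsd, size):
    """Lognormal draws whose arithmetic mean equals ``arithmetic_mean``."""
    mu = np.log(arithmetic_mean) - 0.5 * logsd**2
    return rng.lognormal(mean=mu, sigma=logsd, size=size)


def simulate_size_distribution(
    config: SimulationConfig, treatment: str, n_cells: Optional[int] = None, rng=None
) -> np.ndarray:
    """Draw individual carbon masses (ug C) for one treatment.

    The draws are lognormal with log-scale SD ``config.mass_logsd`` and
    arithmetic mean equal to the treatment's mean mass (degenerate at the
    mean when the SD is 0).
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = config.n_cells if n_cells is None else int(n_cells)
    if n < 1:
        raise ConfigError("n_cells must be >= 1")
    return _lognormal_mean_preserving(rng, config.mean_mass(treatment), config.mass_logsd, n)


def simulate_community(
    config: SimulationConfig,
    mesocosm_treatment: str,
    incubator_t: float,
    rng=None,
    community_id: str = "sim",
    mesocosm: Optional[str] = None,
    mesocosm_mean_mass: Optional[float] = None,
) -> Community:
    """Simulate one microcosm with observed GPP and CR rates.

    Under the zero-sum rule (``total_energy`` set) total abundance is
    ``total_energy / per-capita GPP rate`` — log abundance against log
    per-capita rate then has slope −1 by construction — optionally jittered
    by ``exp(N(0, abundance_noise_sd**2))``. With the rule off, abundance is
    ``fixed_abundance`` times the same jitter.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    mean_mass = (
        config.mean_mass(mesocosm_treatment)
        if mesocosm_mean_mass is None
        else mesocosm_mean_mass
    )
    masses = _lognormal_mean_preserving(rng, mean_mass, config.mass_logsd, config.n_cells)

    comm = Community(
        id=community_id,
        mesocosm_treatment=mesocosm_treatment,
        incubator_t=incubator_t,
        masses=masses,
        scale_to_litre=1.0,
        mesocosm=mesocosm,
    )
    per_capita_gpp = average_individual_rate(comm, config.true_params_gpp)
    if config.total_energy is not None:
        n_tot = config.total_energy / per_capita_gpp
    else:
        n_tot = config.fixed_abundance
    if config.abundance_noise_sd > 0:
        n_tot *= np.exp(rng.normal(0.0, config.abundance_noise_sd))
    comm.scale_to_litre = n_tot / config.n_cells

    gpp = community_rate(config.true_params_gpp, comm)
    cr = community_rate(config.true_params_cr, comm)
    if config.noise_sd > 0:
        gpp *= np.exp(rng.normal(0.0, config.noise_sd))
        cr *= np.exp(rng.normal(0.0, config.noise_sd))
    comm.gpp_obs = gpp
    comm.cr_obs = cr
    return comm


def simulate_experiment(config: SimulationConfig) -> tuple[list[Community], dict]:
    """Full factorial design: every mesocosm assayed in both incubators.

    Returns the list of communities (2 treatments x 2 incubators x
    ``n_mesocosms_per_treatment``) and a truth record of the generating
    parameters. Deterministic under a fixed ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    t_ambient, t_warm = config.incubator_temps
    communities: list[Community] = []
    for treatment in TREATMENTS:
        for idx in range(config.n_mesocosms_per_treatment):
            mesocosm = f"{treatment}_m{idx + 1:02d}"
            mean_mass = config.mean_mass(treatment)
            if config.mesocosm_mass_logsd > 0:
                mean_mass *= np.exp(rng.normal(0.0, config.mesocosm_mass_logsd))
            for inc_label, inc_t in (("ambient", t_ambient), ("warm", t_warm)):
                comm = simulate_community(
                    config,
                    treatment,
                    inc_t,
                    rng=rng,
                    community_id=f"{mesocosm}_{inc_label}",
                    mesocosm=mesocosm,
                    mesocosm_mean_mass=mean_mass,
                )
                comm.incubator_treatment = inc_label
                communities.append(comm)
    truth = {
        "gpp": dataclasses.asdict(config.true_params_gpp),
        "cr": dataclasses.asdict(config.true_params_cr),
        "total_energy": config.total_energy,
        "noise_sd": config.noise_sd,
        "abundance_noise_sd": config.abundance_noise_sd,
        "seed": config.seed,
    }
    return communities, truth


def simulate_pi_curves(
    communities: list[Community],
    irradiances=(0, 25, 50, 100, 200, 400, 800, 1200, 1600),
    i_opt: float = 300.0,
    flux_noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Net O2-flux light-response observations consistent with each community.

    Gross photosynthesis follows the photoinhibition curve with saturation
    rate equal to the community's observed GPP; the dark observation equals
    minus its observed CR. Gaussian noise (``flux_noise_sd``, absolute rate
    units) is optional.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for comm in communities:
        p_max, r_d = comm.observed_rate("gpp"), comm.observed_rate("cr")
        s = 3.0 * p_max / i_opt  # moderately steep light-limited slope
        for irr in irradiances:
            net = _picurve.eilers_gross(float(irr), p_max, i_opt, s) - r_d
            if flux_noise_sd > 0:
                net += rng.normal(0.0, flux_noise_sd)
            rows.append((comm.id, float(irr), net, False))
        dark = -r_d + (rng.normal(0.0, flux_noise_sd) if flux_noise_sd > 0 else 0.0)
        rows.append((comm.id, 0.0, dark, True))
    return pd.DataFrame(rows, columns=["community_id", "irradiance", "o2_flux", "is_dark"])


def simulate_asv_table(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Dirichlet-multinomial counts with a long-term-treatment signature.

    The two long-term treatments get distinct taxon profiles separated by
    ``composition_effect`` (0 = identical, 1 = fully distinct); the incubator
    has no effect on composition. With probability ``p_low_reads`` a sample
    gets a small library (< 1000 reads) to exercise the read-count filter.

    Returns ``(counts, sample_meta)``: counts indexed by sample id with one
    integer column per taxon, and per-sample treatment labels.
    """
    rng = np.random.default_rng(config.seed + 1)
    base = rng.dirichlet(np.ones(config.n_taxa) * 2.0)
    shifted = rng.dirichlet(np.ones(config.n_taxa) * 2.0)
    e = config.composition_effect
    profiles = {
        "ambient": base,
        "warm": (1.0 - e) * base + e * shifted,
    }
    counts_rows, meta_rows, index = [], [], []
    for treatment in TREATMENTS:
        for idx in range(config.n_mesocosms_per_treatment):
            for inc_label in ("ambient", "warm"):
                sample_id = f"{treatment}_m{idx + 1:02d}_{inc_label}"
                p = rng.dirichlet(profiles[treatment] * config.taxon_concentration)
                if rng.random() < config.p_low_reads:
                    lib = int(rng.integers(100, 1000))
                else:
                    lib = config.library_size
                counts_rows.append(rng.multinomial(lib, p))
                meta_rows.append((treatment, inc_label))
                index.append(sample_id)
    counts = pd.DataFrame(
        np.array(counts_rows, dtype=int),
        index=pd.Index(index, name="sample_id"),
        columns=[f"asv_{i + 1:03d}" for i in range(config.n_taxa)],
    )
    meta = pd.DataFrame(
        meta_rows,
        index=pd.Index(index, name="sample_id"),
        columns=["mesocosm_treatment", "incubator_treatment"],
    )
    return counts, meta


def communities_to_frames(communities: list[Community]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tidy tables: one row per community, and long-format masses."""
    comm_rows = []
    mass_frames = []
    for c in communities:
        comm_rows.append(
            {
                "community_id": c.id,
                "mesocosm": c.mesocosm,
                "mesocosm_treatment": c.mesocosm_treatment,
                "incubator_treatment": c.incubator_treatment,
                "incubator_t": c.incubator_t,
                "n_cells": c.masses.size,
                "scale_to_litre": c.scale_to_litre,
                "n_tot": c.n_tot,
                "gpp_obs": c.gpp_obs,
                "cr_obs": c.cr_obs,
            }
        )
        mass_frames.append(
            pd.DataFrame({"community_id": c.id, "mass_ug_c": c.masses})
        )
    return pd.DataFrame(comm_rows), pd.concat(mass_frames, ignore_index=True)


def frames_to_communities(communities_df: pd.DataFrame, masses_df: pd.DataFrame) -> list[Community]:
    """Inverse of :func:`communities_to_frames`."""
    grouped = masses_df.groupby("community_id")["mass_ug_c"]
    out = []
    for row in communities_df.itertuples(index=False):
        out.append(
            Community(
                id=row.community_id,
                mesocosm_treatment=row.mesocosm_treatment,
                incubator_t=float(row.incubator_t),
                masses=grouped.get_group(row.community_id).to_numpy(),
                scale_to_litre=float(row.scale_to_litre),
                gpp_obs=None if pd.isna(row.gpp_obs) else float(row.gpp_obs),
                cr_obs=None if pd.isna(row.cr_obs) else float(row.cr_obs),
                mesocosm=getattr(row, "mesocosm", None),
                incubator_treatment=getattr(row, "incubator_treatment", None),
            )
        )
    return out


FLOAT_FORMAT = "%.12g"


def write_simulated_dataset(config: SimulationConfig, outdir) -> dict:
    """Simulate the full experiment and write the tidy CSV/JSON bundle.

    Emits communities.csv, masses.csv, pi_curves.csv, asv_counts.csv,
    sample_meta.csv and truth.json under ``outdir``; returns the truth record.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    communities, truth = simulate_experiment(config)
    comm_df, masses_df = communities_to_frames(communities)
    comm_df.to_csv(outdir / "communities.csv", index=False, float_format=FLOAT_FORMAT)
    masses_df.to_csv(outdir / "masses.csv", index=False, float_format=FLOAT_FORMAT)
    pi_df = simulate_pi_curves(communities, seed=config.seed + 2)
    pi_df.to_csv(outdir / "pi_curves.csv", index=False, float_format=FLOAT_FORMAT)
    counts, meta = simulate_asv_table(config)
    counts.to_csv(outdir / "asv_counts.csv")
    meta.to_csv(outdir / "sample_meta.csv")
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
    return truth
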