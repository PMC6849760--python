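"""End-to-end orchestration: simulate/ingest -> sizes -> fluxes -> ML fit ->
scaling tests -> composition, with seeded determinism and a manifest.

Every stage writes tidy CSV/JSON into the output directory; the manifest
records the package version, per-stage seeds and SHA-256 hashes of all
inputs and outputs so a re-run of the same manifest is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .composition import bray_curtis, filter_and_rarefy, pcoa, permanova
from .core import T_REF, mass_corrected_biomass, temperature_correct, average_individual_rate
from .errors import ConfigError, DataError, PhytoscaleError
from .inference import compare_treatment_models, fit_mst
from .picurve import fit_pi_table
from .simulate import (
    FLOAT_FORMAT,
    SimulationConfig,
    frames_to_communities,
    write_simulated_dataset,
)
from .sma import compensation_test, proportionality_test

__all__ = ["PipelineConfig", "run_pipeline", "report", "load_config"]

STAGE_SEED_OFFSETS = {
    "simulate": 0,
    "pi": 1,
    "mst": 2,
    "bootstrap": 3,
    "rarefy": 4,
    "permanova": 5,
}


@dataclass
class PipelineConfig:
    outdir: str = "results"
    seed: int = 0
    t_ref: float = T_REF
    # inputs: either a simulation block or paths to existing tables
    simulation: Optional[dict] = field(default_factory=dict)
    communities_csv: Optional[str] = None
    masses_csv: Optional[str] = None
    pi_csv: Optional[str] = None
    asv_csv: Optional[str] = None
    sample_meta_csv: Optional[str] = None
    # where the fitted rates come from: "pi" (fit light curves) or "observed"
    rates_source: str = "pi"
    n_starts_pi: int = 200
    n_starts_mst: int = 50
    n_boot: int = 1000
    n_perm: int = 9999
    min_reads: int = 1000

    def __post_init__(self) -> None:
        if self.rates_source not in ("pi", "observed"):
            raise ConfigError(f"rates_source must be 'pi' or 'observed', got {self.rates_source!r}")
        if self.simulation is None and (self.communities_csv is None or self.masses_csv is None):
            raise ConfigError(
                "either a simulation block or communities_csv + masses_csv must be provided"
            )

    def stage_seed(self, stage: str) -> int:
        return int(self.seed) * 1000 + STAGE_SEED_OFFSETS[stage]


def load_config(path) -> PipelineConfig:
    """Read a YAML or JSON pipeline configuration."""
    text = Path(path).read_text()
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"could not parse config {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"config {path} must be a mapping")
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_json(path: Path, payload) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=_jsonify) + "\n")


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, frozenset):
        return sorted(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")


class _StageFailure(PhytoscaleError):
    pass


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every configured stage; returns the result bundle as a dict."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"outdir": str(outdir)}
    inputs: dict[str, str] = {}
    outputs: list[str] = []
    stage = "configure"
    try:
        # ---- simulate / ingest -------------------------------------------
        if config.simulation is not None:
            stage = "simulate"
            sim_conf = _simulation_config(config)
            data_dir = outdir / "data"
            write_simulated_dataset(sim_conf, data_dir)
            communities_csv = data_dir / "communities.csv"
            masses_csv = data_dir / "masses.csv"
            pi_csv = data_dir / "pi_curves.csv"
            asv_csv = data_dir / "asv_counts.csv"
            meta_csv = data_dir / "sample_meta.csv"
            outputs += [str(p) for p in (communities_csv, masses_csv, pi_csv, asv_csv, meta_csv)]
        else:
            communities_csv = Path(config.communities_csv)
            masses_csv = Path(config.masses_csv)
            pi_csv = Path(config.pi_csv) if config.pi_csv else None
            asv_csv = Path(config.asv_csv) if config.asv_csv else None
            meta_csv = Path(config.sample_meta_csv) if config.sample_meta_csv else None
        for p in (communities_csv, masses_csv, pi_csv, asv_csv, meta_csv):
            if p is not None and p.exists():
                inputs[str(p)] = _sha256(p)

        stage = "sizes"
        comm_df = pd.read_csv(communities_csv)
        masses_df = pd.read_csv(masses_csv)
        communities = frames_to_communities(comm_df, masses_df)

        # ---- flux extraction ---------------------------------------------
        stage = "flux_extraction"
        if config.rates_source == "pi":
            if pi_csv is None or not Path(pi_csv).exists():
                raise ConfigError(
                    "rates_source='pi' but no PI input table is configured; "
                    "set pi_csv or use rates_source='observed'"
                )
            pi_df = pd.read_csv(pi_csv)
            fits_df = fit_pi_table(
                pi_df, n_starts=config.n_starts_pi, seed=config.stage_seed("pi")
            )
            fits_path = outdir / "pi_fits.csv"
            fits_df.to_csv(fits_path, index=False, float_format=FLOAT_FORMAT)
            outputs.append(str(fits_path))
            by_id = fits_df.set_index("community_id")
            missing = [c.id for c in communities if c.id not in by_id.index]
            if missing:
                raise DataError(f"no PI curve for communities: {missing}")
            for c in communities:
                c.gpp_obs = float(by_id.loc[c.id, "gpp"])
                c.cr_obs = float(by_id.loc[c.id, "cr"])
        else:
            for c in communities:
                if c.gpp_obs is None or c.cr_obs is None:
                    raise DataError(f"{c.id}: rates_source='observed' but rates are missing")

        # ---- maximum-likelihood fit --------------------------------------
        stage = "mst_inference"
        mst_fits = {}
        comparisons = {}
        for flux in ("gpp", "cr"):
            mst_fits[flux] = fit_mst(
                communities,
                flux,
                n_starts=config.n_starts_mst,
                seed=config.stage_seed("mst"),
                t_ref=config.t_ref,
            )
            rows, _ = compare_treatment_models(
                communities, flux, n_starts=config.n_starts_mst,
                seed=config.stage_seed("mst"), t_ref=config.t_ref,
            )
            comparisons[flux] = rows
        mst_path = outdir / "mst_fit.json"
        _write_json(mst_path, {flux: fit.summary_dict() for flux, fit in mst_fits.items()})
        comp_df = pd.DataFrame(
            [
                {"flux": flux, **dataclasses.asdict(row)}
                for flux, rows in comparisons.items()
                for row in rows
            ]
        )
        comp_path = outdir / "model_comparison.csv"
        comp_df.to_csv(comp_path, index=False, float_format=FLOAT_FORMAT)
        outputs += [str(mst_path), str(comp_path)]

        # ---- scaling tests ------------------------------------------------
        stage = "scaling_tests"
        scaling = {}
        for flux in ("gpp", "cr"):
            scaling[f"proportionality_{flux}"] = proportionality_test(
                communities, mst_fits[flux], flux=flux,
                n_boot=config.n_boot, seed=config.stage_seed("bootstrap"),
            ).to_dict()
        scaling["compensation_gpp"] = compensation_test(
            communities, mst_fits["gpp"], flux="gpp",
            n_boot=config.n_boot, seed=config.stage_seed("bootstrap"),
        ).to_dict()
        scaling_path = outdir / "scaling_results.json"
        _write_json(scaling_path, scaling)
        plot_df = _per_community_table(communities, mst_fits)
        plot_path = outdir / "corrected_rates.csv"
        plot_df.to_csv(plot_path, index=False, float_format=FLOAT_FORMAT)
        outputs += [str(scaling_path), str(plot_path)]

        # ---- composition ---------------------------------------------------
        stage = "composition"
        composition_result = None
        if asv_csv is not None and Path(asv_csv).exists():
            counts = pd.read_csv(asv_csv, index_col=0)
            meta = pd.read_csv(meta_csv, index_col=0) if meta_csv else None
            rarefied = filter_and_rarefy(
                counts, min_reads=config.min_reads, seed=config.stage_seed("rarefy")
            )
            dm = bray_curtis(rarefied)
            dm_path = outdir / "distances.csv"
            dm.to_csv(dm_path, float_format=FLOAT_FORMAT)
            ord_res = pcoa(dm)
            pcoa_path = outdir / "pcoa.csv"
            ord_df = ord_res.coordinates.copy()
            ord_df.to_csv(pcoa_path, float_format=FLOAT_FORMAT)
            outputs += [str(dm_path), str(pcoa_path)]
            composition_result = {
                "n_samples": int(len(rarefied)),
                "proportion_explained": ord_res.proportion_explained[:2].tolist(),
            }
            if meta is not None:
                factors = meta.loc[dm.index, ["mesocosm_treatment", "incubator_treatment"]]
                perm = permanova(
                    dm, factors, n_perm=config.n_perm, seed=config.stage_seed("permanova")
                )
                perm_path = outdir / "permanova.json"
                _write_json(perm_path, perm.reset_index().to_dict(orient="records"))
                outputs.append(str(perm_path))
                composition_result["permanova"] = perm.reset_index().to_dict(orient="records")

        # ---- manifest + report ---------------------------------------------
        stage = "report"
        bundle.update(
            {
                "mst_fit": {flux: fit.summary_dict() for flux, fit in mst_fits.items()},
                "model_comparison": comp_df.to_dict(orient="records"),
                "scaling": scaling,
                "composition": composition_result,
            }
        )
        manifest = {
            "package_version": __version__,
            "seeds": {s: config.stage_seed(s) for s in STAGE_SEED_OFFSETS},
            "config": dataclasses.asdict(config),
            "inputs": inputs,
            "outputs": {p: _sha256(Path(p)) for p in outputs},
        }
        _write_json(outdir / "manifest.json", manifest)
        report_payload = report(bundle)
        (outdir / "report.txt").write_text(report_payload["text"])
        _write_json(outdir / "report.json", report_payload["tables"])
        bundle["manifest"] = manifest
        return bundle
    except PhytoscaleError as exc:
        raise type(exc)(f"stage '{stage}' failed: {exc}") from exc


def _simulation_config(config: PipelineConfig) -> SimulationConfig:
    raw = dict(config.simulation or {})
    raw.setdefault("seed", config.stage_seed("simulate"))
    known = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown simulation keys: {sorted(unknown)}")
    return SimulationConfig(**raw)


def _per_community_table(communities, mst_fits) -> pd.DataFrame:
    rows = []
    for c in communities:
        row = {
            "community_id": c.id,
            "mesocosm_treatment": c.mesocosm_treatment,
            "incubator_treatment": c.incubator_treatment,
            "incubator_t": c.incubator_t,
            "n_tot": c.n_tot,
            "m_tot": c.m_tot,
        }
        for flux in ("gpp", "cr"):
            p = mst_fits[flux].params_for(c.mesocosm_treatment)
            row[f"mass_corrected_biomass_{flux}"] = mass_corrected_biomass(
                c.masses, p.alpha, p.ln_b_tc, c.scale_to_litre
            )
            row[f"temperature_corrected_{flux}"] = temperature_correct(
                c.observed_rate(flux), p.activation_energy, c.incubator_t, p.t_ref
            )
        row["avg_individual_gpp"] = average_individual_rate(
            c, mst_fits["gpp"].params_for(c.mesocosm_treatment)
        )
        rows.append(row)
    return pd.DataFrame(rows)


def report(bundle: dict) -> dict:
    """Human-readable summary (text) plus the same numbers as JSON tables.

    Regenerating the report from a saved bundle is idempotent: the output is
    a pure function of the bundle contents.
    """
    lines = ["phytoscale pipeline report", "=" * 26, ""]
    tables: dict = {}

    mst = bundle.get("mst_fit", {})
    param_rows = []
    lines.append("Maximum-likelihood parameter estimates")
    for flux in ("gpp", "cr"):
        fit = mst.get(flux)
        if not fit:
            continue
        for name in ("E", "alpha", "ln_b_tc"):
            for key, est in sorted(fit["estimates"].items()):
                if key == name or key.startswith(f"{name}["):
                    ci = fit["ci"].get(key, {})
                    lo, hi = ci.get("lower"), ci.get("upper")
                    ci_txt = f" (95% CI {lo:.3g} to {hi:.3g})" if lo is not None else ""
                    lines.append(f"  {flux.upper():>3} {key:<18} {est: .4g}{ci_txt}")
                    param_rows.append(
                        {"flux": flux, "parameter": key, "estimate": est,
                         "ci_lower": lo, "ci_upper": hi}
                    )
    tables["parameters"] = param_rows

    lines.append("")
    lines.append("Scaling tests (SMA on log-log axes)")
    sma_rows = []
    for key, res in (bundle.get("scaling") or {}).items():
        test = res.get("slope_test") or {}
        ci = res.get("boot_ci_slope")
        ci_txt = f", bootstrap 95% CI {ci[0]:.3g} to {ci[1]:.3g}" if ci else ""
        lines.append(
            f"  {key}: slope {res['slope']:.3g} (b0={test.get('b0')}, "
            f"r={test.get('r', float('nan')):.3g}, df={test.get('df')}, "
            f"p={test.get('p', float('nan')):.3g}){ci_txt}; "
            f"intercept {res['intercept']:.3g}; R2 {res['r2']:.3g}; n={res['n']}"
        )
        sma_rows.append({"test": key, **{k: v for k, v in res.items()}})
    tables["scaling"] = sma_rows

    comp = bundle.get("composition")
    if comp and comp.get("permanova"):
        lines.append("")
        lines.append("PERMANOVA (sequential SS)")
        for row in comp["permanova"]:
            if row["term"] == "residual":
                continue
            lines.append(
                f"  {row['term']}: F={row['pseudo_F']:.3g}, "
                f"partial R2={row['partial_R2']:.3g}, p={row['p']:.4g}"
            )
        tables["permanova"] = comp["permanova"]

    lines.append("")
    return {"text": "\n".join(lines), "tables": tables}
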