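"""End-to-end orchestration of the computational workflow.

One :func:`run_pipeline` call reproduces the study's processing chain on
synthetic data: simulate instationary labeling per strain, apply the
measurement layer, correct isotopologue spectra, compute enrichment
time courses, fit logistic kinetics and half-times, build and validate
IDMS calibrations, quantify pools, and compare strains (Welch tests and
constant-turnover flux ratios). Every stage writes a CSV with provenance
headers; a rerun with the same configuration and seed is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .compare import GroupSummary, compare_labeling_dynamics, flux_ratio, welch_test
from .correction import DEFAULT_TRACER_PURITY, NATURAL_13C_ABUNDANCE, correct_table
from .idms import quantify_replicates, sample_ratio, validate_curve
from .kinetics import fit_table
from .pathway import PathwaySpec, default_pathway
from .simulate import (
    ILE_TIMEPOINTS,
    STRAIN_SCALES,
    apply_measurement_layer,
    default_quant_pools,
    make_calibration_series,
    make_quant_dataset,
    strain_config,
    simulate_labeling,
)
from .io import write_table

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]

logger = logging.getLogger("prenylflux")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one end-to-end synthetic-data run."""

    outdir: Path = Path("prenylflux_run")
    strains: tuple[str, ...] = ("WT", "S037", "S023")
    reference_strain: str = "WT"
    natural_13c_abundance: float = NATURAL_13C_ABUNDANCE
    tracer_purity: float = DEFAULT_TRACER_PURITY
    timepoints: tuple[float, ...] = ILE_TIMEPOINTS
    ile_noise_cv: float = 0.05
    ile_replicates: int = 2
    quant_noise_cv: float = 0.1
    quant_replicates: int = 3
    rng_seed: int = 1
    include_ile: bool = True
    include_quant: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "outdir", Path(self.outdir))
        unknown = set(self.strains) - set(STRAIN_SCALES)
        if unknown:
            raise ValueError(f"no pool scaling defined for strains {sorted(unknown)}")
        if self.reference_strain not in self.strains:
            raise ValueError("reference strain must be among the configured strains")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        if "strains" in doc:
            doc["strains"] = tuple(doc["strains"])
        if "timepoints" in doc:
            doc["timepoints"] = tuple(doc["timepoints"])
        return cls(**doc)

    def config_hash(self) -> str:
        payload = asdict(self)
        payload.pop("outdir")  # a location, not part of the scientific config
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class PipelineResult:
    """In-memory bundle of every stage output (also written as CSV)."""

    outdir: Path
    provenance: dict
    raw: pd.DataFrame | None = None
    corrected: pd.DataFrame | None = None
    enrichment: pd.DataFrame | None = None
    fits: pd.DataFrame | None = None
    t50_comparisons: pd.DataFrame | None = None
    calibration: pd.DataFrame | None = None
    concentrations: pd.DataFrame | None = None
    comparisons: pd.DataFrame | None = None


_QUANT_COMPOUNDS = ("MEV", "M5P", "M5PP", "IPP", "DMAPP", "GPP", "FPP", "GGPP")


def _child_seed(root: np.random.SeedSequence, *tags: str) -> int:
    """Deterministic sub-seed (< 2^31) derived from the run seed and tags."""
    digest = hashlib.sha256(("/".join(tags)).encode()).digest()
    tag_int = int.from_bytes(digest[:4], "big")
    child = np.random.SeedSequence(entropy=root.entropy, spawn_key=(tag_int,))
    return int(child.generate_state(1)[0] % (2**31))


def run_pipeline(config: RunConfig, pathway: PathwaySpec | None = None) -> PipelineResult:
    """Execute all configured stages; see the module docstring."""
    if pathway is None:
        pathway = default_pathway()
    root = np.random.SeedSequence(config.rng_seed)
    provenance = {
        "prenylflux_version": __version__,
        "rng_seed": config.rng_seed,
        "config_sha256": config.config_hash(),
    }
    result = PipelineResult(outdir=config.outdir, provenance=provenance)
    config.outdir.mkdir(parents=True, exist_ok=True)
    stages_run: list[str] = []

    if config.include_ile:
        logger.info("simulating labeling time courses for %s", config.strains)
        raw_parts = []
        for strain in config.strains:
            sim_cfg = strain_config(
                strain,
                pathway=pathway,
                tracer_purity=config.tracer_purity,
                natural_13c_abundance=config.natural_13c_abundance,
                timepoints=config.timepoints,
                noise_cv=config.ile_noise_cv,
                replicates=config.ile_replicates,
                rng_seed=_child_seed(root, "ile", strain),
            )
            states = simulate_labeling(sim_cfg)
            raw_parts.append(apply_measurement_layer(states, sim_cfg, strain=strain))
        result.raw = pd.concat(raw_parts, ignore_index=True)
        write_table(result.raw, config.outdir / "raw_measurements.csv", provenance)

        logger.info("correcting isotopologue spectra")
        result.corrected, result.enrichment = correct_table(
            result.raw, config.natural_13c_abundance, config.tracer_purity
        )
        write_table(result.corrected, config.outdir / "corrected.csv", provenance)
        write_table(result.enrichment, config.outdir / "enrichment.csv", provenance)

        logger.info("fitting logistic labeling kinetics")
        result.fits = fit_table(result.enrichment)
        write_table(result.fits, config.outdir / "fits.csv", provenance)

        usable = result.fits[~result.fits["degenerate"] & result.fits["t50_min"].notna()]
        t50_by_strain = {
            strain: {
                metabolite: group["t50_min"].tolist()
                for metabolite, group in sub.groupby("metabolite")
            }
            for strain, sub in usable.groupby("strain")
        }
        comp_parts = []
        ref = config.reference_strain
        for strain in config.strains:
            if strain == ref or strain not in t50_by_strain:
                continue
            comp = compare_labeling_dynamics(t50_by_strain[strain], t50_by_strain.get(ref, {}))
            comp.insert(0, "strain", strain)
            comp.insert(1, "reference", ref)
            comp_parts.append(comp)
        if comp_parts:
            result.t50_comparisons = pd.concat(comp_parts, ignore_index=True)
            write_table(result.t50_comparisons, config.outdir / "t50_comparisons.csv", provenance)
        stages_run += ["simulate", "correct", "kinetics"]
    else:
        logger.info("no labeling data configured: kinetics stage skipped")

    if config.include_quant:
        logger.info("building and validating IDMS calibrations")
        curves = {}
        cal_rows = []
        for compound in _QUANT_COMPOUNDS:
            table = make_calibration_series(
                compound,
                noise_cv=config.quant_noise_cv,
                rng_seed=_child_seed(root, "cal", compound),
            )
            curve = validate_curve(table, compound=compound)
            curves[compound] = curve
            low, high = curve.linear_range_pmol or (np.nan, np.nan)
            cal_rows.append(
                {
                    "compound": compound,
                    "slope": curve.slope,
                    "intercept": curve.intercept,
                    "r_squared": curve.r_squared,
                    "lod_pmol": curve.lod_pmol,
                    "loq_pmol": curve.loq_pmol,
                    "linear_low_pmol": low,
                    "linear_high_pmol": high,
                }
            )
        result.calibration = pd.DataFrame(cal_rows)
        write_table(result.calibration, config.outdir / "calibration.csv", provenance)

        logger.info("quantifying pools by IDMS for %s", config.strains)
        conc_rows = []
        summaries: dict[tuple[str, str], GroupSummary] = {}
        for strain in config.strains:
            sim_cfg = strain_config(
                strain,
                pathway=pathway,
                noise_cv=config.quant_noise_cv,
                replicates=config.quant_replicates,
                rng_seed=_child_seed(root, "quant", strain),
            )
            table = make_quant_dataset(sim_cfg, default_quant_pools(strain), strain=strain)
            for compound, group in table.groupby("metabolite"):
                ratios = [
                    sample_ratio(rep_rows)
                    for _, rep_rows in group.groupby("replicate")
                ]
                quant = quantify_replicates(
                    ratios,
                    curves[compound],
                    biomass_gdcw=sim_cfg.biomass_gdcw,
                    strain=strain,
                    metabolite=compound,
                    resuspension_ul=sim_cfg.resuspension_ul,
                    injection_ul=sim_cfg.injection_ul,
                )
                summaries[(strain, compound)] = GroupSummary(
                    mean=quant.concentration_nmol_gdcw,
                    sd=quant.sd_nmol_gdcw,
                    n=quant.n_replicates,
                )
                conc_rows.append(
                    {
                        "strain": strain,
                        "metabolite": compound,
                        "concentration_nmol_gdcw": quant.concentration_nmol_gdcw,
                        "sd_nmol_gdcw": quant.sd_nmol_gdcw,
                        "n_replicates": quant.n_replicates,
                        "true_nmol_gdcw": default_quant_pools(strain)[compound],
                    }
                )
        result.concentrations = pd.DataFrame(conc_rows)
        write_table(result.concentrations, config.outdir / "concentrations.csv", provenance)

        logger.info("comparing strains (Welch tests, flux ratios)")
        comp_rows = []
        ref = config.reference_strain
        for strain in config.strains:
            if strain == ref:
                continue
            for compound in _QUANT_COMPOUNDS:
                a = summaries[(strain, compound)]
                b = summaries[(ref, compound)]
                welch = welch_test(a, b)
                ratio = flux_ratio(a, b)
                comp_rows.append(
                    {
                        "strain": strain,
                        "reference": ref,
                        "metabolite": compound,
                        "mean": a.mean,
                        "sd": a.sd,
                        "ref_mean": b.mean,
                        "ref_sd": b.sd,
                        "welch_t": welch.t,
                        "welch_df": welch.df,
                        "p_value": welch.p_value,
                        "flux_ratio": ratio.ratio,
                        "flux_ratio_sd": ratio.sd,
                    }
                )
        result.comparisons = pd.DataFrame(comp_rows)
        write_table(result.comparisons, config.outdir / "comparisons.csv", provenance)
        stages_run += ["calibration", "quantify", "compare"]

    with open(config.outdir / "run.json", "w", encoding="utf-8") as fh:
        json.dump({**provenance, "stages": stages_run}, fh, indent=2, sort_keys=True)
    logger.info("pipeline complete: %s", ", ".join(stages_run) or "no stages configured")
    return result
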