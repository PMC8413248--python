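"""Readers, writers, run configuration and pipeline orchestration.

Formats: cohort tables as comma-separated text ('.' decimal separator,
header row, leading '#' metadata lines carrying the generating seed),
instrument tables in the de-facto GWAS summary-statistics layout
(tab-separated: snp, effect_allele, other_allele, eaf, beta, se, n), truth
records as JSON, optional minimal VCF 4.2 genotype export, and a JSON
results bundle with a provenance manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .simulate import (
    GAD7_MAX,
    PHQ9_MAX,
    SimulationConfig,
    TruthRecord,
    generate_cohort,
)
from . import mr as mr_mod
from . import observational as obs_mod
from . import specificity as spec_mod

logger = logging.getLogger(__name__)

REQUIRED_COHORT_COLUMNS = [
    "participant_id",
    "age",
    "sex",
    "bmi",
    "smoking",
    "alcohol",
    "activity",
    "ethnicity",
    "tdi",
    "diabetes",
    "cvd",
    "crp",
    "dep_score",
    "anx_score",
]


# ---------------------------------------------------------------------------
# cohort I/O


def write_cohort(cohort: pd.DataFrame, path, seed: int | None = None) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# inflamr cohort v{__version__}\n")
        if seed is not None:
            fh.write(f"# seed={int(seed)}\n")
        cohort.to_csv(fh, index=False, lineterminator="\n")


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a cohort CSV; invalid rows are rejected with reasons.

    Rejection reasons (machine-readable codes in ``df.attrs['rejected']``):
    nonpositive_crp, dep_score_range, anx_score_range, dosage_range.
    """
    df = pd.read_csv(path, comment="#")
    missing = [c for c in REQUIRED_COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file missing required column(s): {missing}")
    snp_cols = [c for c in df.columns if c.startswith("g_")]
    reasons = {}

    def _reject(mask, code):
        for i in df.index[mask]:
            reasons.setdefault(int(i), code)

    _reject(~(df["crp"] > 0), "nonpositive_crp")
    _reject(
        (df["dep_score"] < 0) | (df["dep_score"] > PHQ9_MAX), "dep_score_range"
    )
    _reject(
        (df["anx_score"] < 0) | (df["anx_score"] > GAD7_MAX), "anx_score_range"
    )
    for c in snp_cols:
        _reject((df[c] < 0) | (df[c] > 2), "dosage_range")
    if reasons:
        for i, code in reasons.items():
            logger.warning("rejecting cohort row %d: %s", i, code)
        df = df.drop(index=list(reasons))
    df = df.reset_index(drop=True)
    df.attrs["rejected"] = reasons
    logger.info("read cohort: %d rows, %d genotype columns", len(df), len(snp_cols))
    return df


# ---------------------------------------------------------------------------
# instrument I/O


def write_instruments(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_instruments(path) -> pd.DataFrame:
    tab = pd.read_csv(path, sep="\t", comment="#")
    return mr_mod.validate_instruments(tab)


# ---------------------------------------------------------------------------
# truth record I/O


def write_truth(truth: TruthRecord, path) -> None:
    Path(path).write_text(truth.to_json(), encoding="utf-8")


def read_truth(path) -> TruthRecord:
    return TruthRecord.from_json(Path(path).read_text(encoding="utf-8"))


# ---------------------------------------------------------------------------
# minimal VCF export


def write_vcf(cohort: pd.DataFrame, truth: TruthRecord, path) -> None:
    """Minimal VCF 4.2 export of the genotype columns (GT from dosage).

    Variants are placed on a synthetic contig at consecutive positions; the
    effect allele is written as ALT so dosages count ALT copies.
    """
    snp_cols = [c for c in cohort.columns if c.startswith("g_")]
    samples = [f"S{pid}" for pid in cohort["participant_id"]]
    lines = [
        "##fileformat=VCFv4.2",
        f"##source=inflamr_v{__version__}",
        "##contig=<ID=1>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(samples),
    ]
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    for j, snp in enumerate(snp_cols):
        i = truth.snp_ids.index(snp)
        ref, alt = truth.other_alleles[i], truth.effect_alleles[i]
        dos = np.rint(cohort[snp].to_numpy(float)).astype(int)
        gts = "\t".join(gt_map[int(d)] for d in dos)
        lines.append(f"1\t{1000 + j}\t{snp}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gts}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# run configuration and pipeline


@dataclass
class RunConfig:
    """Structured configuration of a full pipeline run."""

    seed: int = 0
    out_dir: str = "results"
    cohort_path: str | None = None  # when None, simulate
    instruments_path: str | None = None
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    stages: tuple = ("simulate", "observational", "specificity", "mr")
    observational_outcomes: tuple = ("dep_score", "anx_score", "dep_dx", "gad_dx")
    observational_k: int = 5
    observational_models: tuple = (1, 2, 3, 4)
    observational_ipw: bool = False
    specificity_outcomes: tuple = ("categorical",)
    specificity_model: int = 4
    mr_designs: tuple = ("one_sample",)
    mr_exposures: tuple = ("crp", "il6")
    mr_outcomes: tuple = ("dep_score", "dep_dx", "anx_score", "gad_dx")
    mr_ipw: bool = False
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "simulation" in d and isinstance(d["simulation"], dict):
            d["simulation"] = SimulationConfig.from_dict(d["simulation"])
        for k, v in list(d.items()):
            if isinstance(v, list):
                d[k] = tuple(v)
        return cls(**d)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        text = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(text.encode()).hexdigest()[:16]


def load_run_config(path) -> RunConfig:
    import yaml

    with open(path, encoding="utf-8") as fh:
        return RunConfig.from_dict(yaml.safe_load(fh) or {})


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def _quantile_result_dict(r: obs_mod.QuantileAssociationResult) -> dict:
    return _jsonable(
        {
            "outcome": r.outcome,
            "K": r.K,
            "model": r.model,
            "sex_stratum": r.sex_stratum,
            "n": r.n,
            "ipw": r.ipw,
            "cut_points": r.quantiles.cut_points,
            "group_medians": r.quantiles.group_medians,
            "group_sizes": r.quantiles.group_sizes,
            "odds_ratios": r.odds_ratios,
            "ci_low": r.ci_low,
            "ci_high": r.ci_high,
            "floated_lambdas": r.lambdas,
            "trend_or": r.trend_or,
            "trend_ci": r.trend_ci,
            "trend_p": r.trend_p,
            "continuous_or": r.continuous_or,
            "continuous_ci": r.continuous_ci,
            "continuous_p": r.continuous_p,
        }
    )


def _specificity_dict(res: dict) -> dict:
    lrt = res["lrt"]
    free = res["free"]
    return _jsonable(
        {
            "lr": lrt.lr,
            "df": lrt.df,
            "p": lrt.p,
            "rho": lrt.rho,
            "analysis": lrt.analysis,
            "or_dep": lrt.or_dep,
            "or_anx": lrt.or_anx,
            "converged": free.converged,
            "mutual_adjustment": res["mutual_adjustment"],
        }
    )


@dataclass
class ResultsBundle:
    manifest: dict
    observational: list
    specificity: list
    mr: list
    truth: TruthRecord | None = None


def run_pipeline(config: RunConfig) -> ResultsBundle:
    """Execute simulate -> observational -> specificity -> mr per config.

    Deterministic given the config seed; writes all result families plus a
    provenance manifest to ``config.out_dir``.  A stage failure aborts with
    the stage name while earlier outputs remain on disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    manifest = {
        "version": __version__,
        "seed": int(config.seed),
        "config_hash": config.config_hash(),
        "stages_run": [],
        "stages_skipped": [],
    }
    truth = None
    stage = "input"
    try:
        if "simulate" in config.stages and config.cohort_path is None:
            stage = "simulate"
            sim_cfg = dataclasses.replace(config.simulation, seed=config.seed)
            cohort, truth = generate_cohort(sim_cfg)
            write_cohort(cohort, out / "cohort.csv", seed=config.seed)
            write_truth(truth, out / "truth.json")
            manifest["stages_run"].append("simulate")
        else:
            if config.cohort_path is None:
                raise ValueError("no cohort path given and simulate stage disabled")
            cohort = read_cohort(config.cohort_path)
            manifest["stages_skipped"].append("simulate")

        observational = []
        if "observational" in config.stages:
            stage = "observational"
            ipw = None
            if config.observational_ipw and "selected" in cohort.columns:
                ipw = obs_mod.fit_selection_model(cohort).weights
            for outcome in config.observational_outcomes:
                for model in config.observational_models:
                    r = obs_mod.fit_doseresponse(
                        cohort,
                        outcome=outcome,
                        K=config.observational_k,
                        model=model,
                        ipw_weights=ipw,
                    )
                    observational.append(_quantile_result_dict(r))
            manifest["stages_run"].append("observational")
        else:
            manifest["stages_skipped"].append("observational")

        specificity = []
        if "specificity" in config.stages:
            stage = "specificity"
            for kind in config.specificity_outcomes:
                res = spec_mod.specificity_analysis(
                    cohort, outcomes=kind, model=config.specificity_model
                )
                specificity.append(_specificity_dict(res))
            manifest["stages_run"].append("specificity")
        else:
            manifest["stages_skipped"].append("specificity")

        mr_results = []
        if "mr" in config.stages:
            stage = "mr"
            instruments = None
            if config.instruments_path is not None:
                instruments = read_instruments(config.instruments_path)
            elif truth is not None:
                instruments = pd.concat(
                    [truth.instrument_table("crp"), truth.instrument_table("il6r")],
                    ignore_index=True,
                )
            ipw = None
            if config.mr_ipw and "selected" in cohort.columns:
                ipw = obs_mod.fit_selection_model(cohort).weights
            for design in config.mr_designs:
                for exposure in config.mr_exposures:
                    for outcome in config.mr_outcomes:
                        res = mr_mod.run_mr(
                            design,
                            exposure,
                            outcome,
                            cohort=cohort,
                            instruments=instruments,
                            ipw_weights=ipw,
                        )
                        mr_results.append(res.to_dict())
            manifest["stages_run"].append("mr")
        else:
            manifest["stages_skipped"].append("mr")
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    (out / "observational.json").write_text(
        json.dumps(observational, indent=2, sort_keys=True), encoding="utf-8"
    )
    (out / "specificity.json").write_text(
        json.dumps(specificity, indent=2, sort_keys=True), encoding="utf-8"
    )
    (out / "mr.json").write_text(
        json.dumps(mr_results, indent=2, sort_keys=True), encoding="utf-8"
    )
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8"
    )
    return ResultsBundle(
        manifest=manifest,
        observational=observational,
        specificity=specificity,
        mr=mr_results,
        truth=truth,
    )
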