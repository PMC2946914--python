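"""End-to-end orchestration: simulate -> extract -> filter -> aggregate
-> qc -> associate, with a reconciled funnel report.

A run directory is self-describing: it contains the config copy, the
seed, per-stage outputs and a ``report.json`` whose value counts
reconcile exactly at every stage boundary (any discrepancy is a hard
failure).  Identical config + seed reproduce the directory byte for
byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .aggregate import aggregate_median, cohort_summary
from .assoc import GENOME_WIDE_P, gc_adjust, genomic_lambda, manhattan_data, qq_data, run_gwas
from .emr import apply_inpatient_exclusion, flag_inpatient
from .filters import (
    drop_empty_patients,
    load_lexicon,
    load_policies,
    load_registry,
    run_filter,
)
from .qc import QCThresholds, apply_qc
from .simulate import CausalEffect, SimConfig, simulate_dataset, write_dataset
from .traits import TRAITS


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the
    reconciliation state at failure."""


@dataclass
class RunConfig:
    """Everything a pipeline run needs.

    For synthetic runs ``sim`` holds the generator settings; otherwise
    the ``*_path`` fields point at on-disk tables.  One master seed
    drives every stage.
    """

    seed: int = 0
    sim: SimConfig | None = None
    labs_path: str | None = None
    events_path: str | None = None
    episodes_path: str | None = None
    notes_path: str | None = None
    covariates_path: str | None = None
    ped_prefix: str | None = None  # prefix of .ped/.map for real-data runs
    registry_path: str | None = None
    lexicon_path: str | None = None
    policies_path: str | None = None
    thresholds: QCThresholds = field(default_factory=QCThresholds)
    traits: tuple = TRAITS
    covariates: tuple = ("age", "male", "pad")
    rescue_scope: str = "patient-trait"
    significance: float = GENOME_WIDE_P

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = None
        if "sim" in raw:
            sim_raw = dict(raw.pop("sim") or {})
            causal = [CausalEffect(**c) for c in sim_raw.pop("causal_spec", [])]
            if "maf_range" in sim_raw:
                sim_raw["maf_range"] = tuple(sim_raw["maf_range"])
            sim = SimConfig(causal_spec=causal, **sim_raw)
        thresholds = QCThresholds(**raw.pop("thresholds", {}))
        cfg = cls(sim=sim, thresholds=thresholds, **raw)
        if cfg.sim is not None:
            cfg.sim.seed = cfg.seed
        return cfg


def validate_config(config: RunConfig) -> list[str]:
    """Return a list of problems (empty = valid); never mutates state."""
    problems = []
    if config.sim is None:
        for name in ("labs_path", "events_path", "episodes_path", "notes_path",
                     "covariates_path"):
            p = getattr(config, name)
            if p is None:
                problems.append(f"{name} is required when no simulation is configured")
            elif not Path(p).exists():
                problems.append(f"{name}: file not found: {p}")
        if config.ped_prefix is None:
            problems.append("ped_prefix is required when no simulation is configured")
        elif not Path(f"{config.ped_prefix}.ped").exists():
            problems.append(f"ped_prefix: file not found: {config.ped_prefix}.ped")
    else:
        problems.extend(f"sim: {p}" for p in config.sim.validate())
    for name in ("registry_path", "lexicon_path", "policies_path"):
        p = getattr(config, name)
        if p is not None and not Path(p).exists():
            problems.append(f"{name}: file not found: {p}")
    try:
        config.thresholds.validate()
    except ValueError as e:
        problems.append(f"thresholds: {e}")
    for t in config.traits:
        if t not in TRAITS:
            problems.append(f"unknown trait {t!r}")
    for c in config.covariates:
        if c not in ("age", "male", "pad"):
            problems.append(f"unknown covariate {c!r}")
    if config.rescue_scope not in ("patient-trait", "patient"):
        problems.append(f"unknown rescue_scope {config.rescue_scope!r}")
    if not 0 < config.significance < 1:
        problems.append("significance must be in (0, 1)")
    return problems


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute every stage, write all outputs under ``out_dir`` and
    return the report dict (also written as report.json)."""
    problems = validate_config(config)
    if problems:
        raise PipelineError("config: " + "; ".join(problems))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    policies = load_policies(config.policies_path)
    registry = load_registry(config.registry_path, policies=policies)
    lexicon = load_lexicon(config.lexicon_path)

    # ---- stage: inputs -------------------------------------------------
    if config.sim is not None:
        config.sim.seed = config.seed
        ds = simulate_dataset(config.sim, registry=registry, lexicon=lexicon)
        write_dataset(ds, out / "synthetic")
        labs = ds.labs
        events, episodes, notes = ds.events, ds.episodes, ds.notes
        covariates = ds.patients[["patient_id", "age", "male", "pad"]]
        genotypes = ds.genotypes
    else:
        labs = pd.read_csv(config.labs_path, sep="\t", dtype={"patient_id": str})
        events = pd.read_csv(config.events_path, sep="\t", dtype=str)
        episodes = pd.read_csv(config.episodes_path, sep="\t", dtype=str)
        notes = pd.read_csv(config.notes_path, sep="\t", dtype=str)
        covariates = pd.read_csv(config.covariates_path, sep="\t")
        covariates["patient_id"] = covariates["patient_id"].astype(str)
        from .plink import read_ped_map

        genotypes = read_ped_map(config.ped_prefix)

    report = {
        "version": __version__,
        "seed": config.seed,
        "funnel": {},
        "lambda_gc": {},
    }
    funnel = report["funnel"]
    funnel["values_in"] = int(len(labs))
    funnel["patients_in"] = int(labs["patient_id"].nunique())

    # ---- stage: inpatient exclusion ------------------------------------
    flagged = flag_inpatient(labs, episodes)
    kept, inpatient_excluded = apply_inpatient_exclusion(
        flagged, rescue_scope=config.rescue_scope
    )
    funnel["inpatient_excluded"] = int(len(inpatient_excluded))
    funnel["inpatient_rescued"] = int(kept["rescued"].sum())
    if len(kept) + len(inpatient_excluded) != len(labs):
        raise PipelineError("extract: inpatient partition does not reconcile")
    inpatient_excluded.to_csv(out / "inpatient_excluded.tsv", sep="\t", index=False)

    # ---- stage: phenotype filter ---------------------------------------
    fresult, freport = run_filter(kept, events, notes, registry, lexicon)
    fresult.to_csv(out / "filter_audit.tsv", sep="\t", index=False)
    funnel["window_excluded"] = int((fresult["decision"] == "exclude").sum())
    funnel["values_kept"] = int((fresult["decision"] == "keep").sum())
    if funnel["window_excluded"] + funnel["values_kept"] != len(kept):
        raise PipelineError("filter: decision partition does not reconcile")
    report["filter"] = freport

    cohort, dropped, per_trait = drop_empty_patients(fresult)
    funnel["patients_dropped"] = int(len(dropped))
    funnel["patients_cohort"] = int(len(cohort))
    per_trait.to_csv(out / "filter_per_trait.tsv", sep="\t", index=False)

    kept_labs = kept.merge(
        fresult.loc[fresult["decision"] == "keep", ["lab_id"]], on="lab_id"
    )

    # ---- stage: aggregation --------------------------------------------
    phenotypes = aggregate_median(kept_labs, covariates=covariates)
    phenotypes.to_csv(out / "phenotypes.tsv", sep="\t", index=False)
    funnel["phenotype_rows"] = int(len(phenotypes))
    if funnel["phenotype_rows"] != funnel["patients_cohort"]:
        raise PipelineError("aggregate: phenotype rows != cohort patients")
    summary = cohort_summary(phenotypes)
    summary.to_csv(out / "cohort_summary.tsv", sep="\t", index=False)

    # ---- stage: genotype QC --------------------------------------------
    funnel["markers_in"] = int(genotypes.n_markers)
    g_qc, qc_report = apply_qc(genotypes, config.thresholds)
    funnel["markers_after_qc"] = int(g_qc.n_markers)
    funnel["samples_after_qc"] = int(g_qc.n_samples)
    (out / "qc_report.json").write_text(
        json.dumps(qc_report.as_dict(), indent=2, sort_keys=True)
    )

    # ---- stage: association --------------------------------------------
    gwas = run_gwas(g_qc, phenotypes, traits=config.traits, covariates=config.covariates)
    funnel["assoc_rows"] = int(len(gwas))
    expected = int(g_qc.n_markers) * len(config.traits)
    if funnel["assoc_rows"] != expected:
        raise PipelineError(
            f"assoc: {funnel['assoc_rows']} rows, expected {expected}"
        )
    sig_rows = []
    for trait in config.traits:
        sub = gwas[gwas["trait"] == trait]
        lam = genomic_lambda(sub)
        report["lambda_gc"][trait] = round(lam, 4)
        adj = gc_adjust(sub, lam)
        adj.to_csv(out / f"assoc_{trait}.tsv", sep="\t", index=False)
        qq_data(sub).to_csv(out / f"qq_{trait}.tsv", sep="\t", index=False)
        manhattan_data(sub, config.significance).to_csv(
            out / f"manhattan_{trait}.tsv", sep="\t", index=False
        )
        hits = adj[adj["p"] < config.significance]
        sig_rows.append(hits)
    significant = pd.concat(sig_rows, ignore_index=True)
    significant.to_csv(out / "significant.tsv", sep="\t", index=False)
    report["n_significant"] = int(len(significant))
    report["significance_threshold"] = config.significance

    cfg = {
        "seed": config.seed,
        "traits": list(config.traits),
        "covariates": list(config.covariates),
        "rescue_scope": config.rescue_scope,
        "significance": config.significance,
        "thresholds": dataclasses.asdict(config.thresholds),
    }
    if config.sim is not None:
        sim = dataclasses.asdict(config.sim)
        sim["causal_spec"] = [dataclasses.asdict(e) for e in config.sim.causal_spec]
        sim["maf_range"] = list(config.sim.maf_range)
        cfg["sim"] = sim
    (out / "config.json").write_text(json.dumps(cfg, indent=2, sort_keys=True))
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
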