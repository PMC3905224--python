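"""End-to-end orchestration: simulate -> phenotype -> associate -> meta ->
gene test -> enrichment -> validation -> evidence.

Two execution modes mirror how multi-cohort studies are organised:

``meta``
    all cohorts are combined by inverse-variance meta-analysis before the
    gene-based and enrichment stages (the discovery-consortium layout);
``replication``
    cohort 0 is the discovery sample (weighted enrichment, Bonferroni
    correction), the remaining cohorts are analysed separately with the
    unit-weighted statistic, and the per-cohort enrichment P-values are
    combined with Stouffer's weighted Z.

Every stage writes its output before the next starts, records a derived
seed in the run manifest, and can be resumed from disk.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from gwaspath import io as gio
from gwaspath.assoc import ivw_meta, qc_filter, snp_association
from gwaspath.enrichment import empirical_validation, gsea
from gwaspath.evidence import bonferroni, stouffer_weighted
from gwaspath.genes import DEFAULT_SCHEDULE, DEFAULT_WINDOW_KB, gene_based_scan, rank_genes
from gwaspath.phenotypes import battery_scores
from gwaspath.synthetic import (
    CAUSAL_SET,
    GENOME_SET,
    make_gene_annotation,
    make_gene_sets,
    simulate_genotypes,
    simulate_phenotypes,
)
from gwaspath.types import EnrichmentConfig, QcThresholds, SimulationConfig

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Full pipeline configuration with the analysis defaults.

    ``bonferroni_m`` is the number of set-by-phenotype hypotheses the
    discovery P is corrected for; 0 means "count the candidate sets tested
    here" (the genome-wide set is never counted).
    """

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    qc: QcThresholds = field(default_factory=QcThresholds)
    enrichment: EnrichmentConfig = field(default_factory=EnrichmentConfig)
    window_kb: float = DEFAULT_WINDOW_KB
    mc_schedule: tuple[int, ...] = DEFAULT_SCHEDULE
    mode: str = "meta"
    residualize_order: str = "after"
    bonferroni_m: int = 0
    run_validation: bool = False
    out_dir: str = "gwaspath_run"

    def __post_init__(self) -> None:
        if self.mode not in ("meta", "replication"):
            raise ValueError("mode must be 'meta' or 'replication'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(
            simulation=SimulationConfig(**raw.get("simulation", {})),
            qc=QcThresholds(**raw.get("qc", {})),
            enrichment=EnrichmentConfig(**raw.get("enrichment", {})),
            **{
                k: tuple(v) if k == "mc_schedule" else v
                for k, v in raw.items()
                if k not in ("simulation", "qc", "enrichment")
            },
        )

    def to_dict(self) -> dict:
        return asdict(self)


def _score_phenotype(battery, age, sex, order: str = "after") -> pd.Series:
    """General-factor score with age/sex control (order configurable)."""
    return battery_scores(battery, age, sex, residualize=order)


def _analyse_cohort(genotypes, battery, age, sex, qc: QcThresholds):
    """QC + association for one cohort; returns (clean genotypes, sumstats)."""
    clean, report = qc_filter(genotypes, qc)
    score = _score_phenotype(battery, age, sex)
    stats = snp_association(clean, score)
    return clean, stats, report


def simulate_and_test(
    sim: SimulationConfig,
    enr: EnrichmentConfig | None = None,
    qc: QcThresholds | None = None,
    window_kb: float = DEFAULT_WINDOW_KB,
    schedule: tuple[int, ...] = DEFAULT_SCHEDULE,
    candidate_sets: tuple[str, ...] = None,
) -> dict:
    """One-shot in-memory run of the whole chain on a fresh synthetic cohort.

    Simulates every cohort, meta-analyses them, runs the gene-based scan
    (LD from cohort 0) and the enrichment test for the causal and decoy
    sets. Returns a dict with per-set EnrichmentResults, the ranked list,
    and the gene-result frame. This is the entry point calibration and
    power studies use.
    """
    enr = enr or EnrichmentConfig(seed=sim.seed)
    qc = qc or QcThresholds()
    annotation = make_gene_annotation(sim)
    gene_sets = make_gene_sets(annotation, sim)

    per_cohort = []
    ld_reference = None
    for c in range(sim.n_cohorts):
        genotypes = simulate_genotypes(annotation, sim, cohort_index=c)
        battery, age, sex, _ = simulate_phenotypes(
            genotypes, annotation, gene_sets[CAUSAL_SET], sim, cohort_index=c
        )
        clean, stats, _ = _analyse_cohort(genotypes, battery, age, sex, qc)
        per_cohort.append(stats)
        if c == 0:
            ld_reference = clean
    meta = ivw_meta(per_cohort)
    genes, _ = annotation
    gene_results = gene_based_scan(
        meta, ld_reference, genes, window_kb=window_kb,
        schedule=schedule, seed=sim.seed,
    )
    ranked = rank_genes(gene_results)
    names = candidate_sets or tuple(n for n in gene_sets if n != GENOME_SET)
    results = gsea(ranked, {n: gene_sets[n] for n in names}, enr)
    return {
        "annotation": annotation,
        "gene_sets": gene_sets,
        "meta": meta,
        "gene_results": gene_results,
        "ranked": ranked,
        "results": {r.set_name: r for r in results},
    }


def replicate_study(
    n_replicates: int,
    base_seed: int = 0,
    h2_set: float = 0.2,
    h2_background: float = 0.05,
    n_perm: int = 2000,
    schedule: tuple[int, ...] = (1000, 10_000),
    **sim_kwargs,
) -> pd.DataFrame:
    """Causal- and decoy-set enrichment P-values over replicate simulations.

    Each replicate re-runs the whole chain (simulate -> phenotype -> QC ->
    association -> meta -> gene test -> enrichment) with seed
    ``base_seed + i``, under reduced Monte-Carlo budgets suited to repeated
    execution. With ``h2_set=0`` this measures the pipeline's calibration
    (the causal-set P should be uniform); with the default architecture it
    measures power.
    """
    rows = []
    for i in range(n_replicates):
        seed = (base_seed + i) % (2**31 - 1)
        sim = SimulationConfig(
            h2_set=h2_set, h2_background=h2_background, seed=seed, **sim_kwargs
        )
        enr = EnrichmentConfig(n_perm=n_perm, seed=seed)
        out = simulate_and_test(sim, enr, schedule=schedule)
        rows.append(
            {
                "seed": seed,
                "causal_p": out["results"][CAUSAL_SET].p_perm,
                "decoy_p": out["results"]["decoy_set"].p_perm,
                "causal_es": out["results"][CAUSAL_SET].es,
            }
        )
    return pd.DataFrame(rows)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, resume: bool = False) -> dict:
    """Execute (or resume) the full pipeline, writing one file per stage.

    Returns the run manifest: config snapshot, per-stage seeds, output
    paths with checksums, and timestamps. Re-running with the same config
    and seed reproduces every output bit-for-bit.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = config.simulation
    manifest: dict = {
        "config": config.to_dict(),
        "master_seed": sim.seed,
        "stages": {},
        "files": {},
    }

    def record(stage: str, *paths: Path) -> None:
        manifest["stages"][stage] = {"time": time.strftime("%Y-%m-%dT%H:%M:%S")}
        for p in paths:
            manifest["files"][p.name] = _sha256(p)

    # ---- stage: simulate --------------------------------------------------
    annotation = make_gene_annotation(sim)
    genes, snps = annotation
    gene_sets = make_gene_sets(annotation, sim)
    bed = out / "annotation.bed"
    gmt = out / "gene_sets.gmt"
    cohort_files = [out / f"cohort{c}.dosage.tsv" for c in range(sim.n_cohorts)]
    pheno_files = [out / f"cohort{c}.pheno.tsv" for c in range(sim.n_cohorts)]
    if not (resume and bed.exists() and gmt.exists()
            and all(f.exists() for f in cohort_files + pheno_files)):
        gio.write_gene_bed(genes, bed)
        gio.write_gmt(gene_sets, gmt)
        for c in range(sim.n_cohorts):
            genotypes = simulate_genotypes(annotation, sim, cohort_index=c)
            battery, age, sex, _ = simulate_phenotypes(
                genotypes, annotation, gene_sets[CAUSAL_SET], sim, cohort_index=c
            )
            gio.write_dosage_tsv(genotypes, cohort_files[c])
            gio.write_phenotype_tsv(battery.to_frame(), age, sex, pheno_files[c])
    record("simulate", bed, gmt, *cohort_files, *pheno_files)

    # ---- stages: phenotype, assoc (per cohort) ----------------------------
    from gwaspath.synthetic import TestBattery

    sumstat_files = [out / f"cohort{c}.sumstats.tsv" for c in range(sim.n_cohorts)]
    score_files = [out / f"cohort{c}.score.tsv" for c in range(sim.n_cohorts)]
    clean_cohorts: list = [None] * sim.n_cohorts
    per_cohort_stats: list = []
    for c in range(sim.n_cohorts):
        genotypes = gio.read_dosage_tsv(cohort_files[c])
        pheno = gio.read_phenotype_tsv(pheno_files[c])
        tests = [col for col in pheno.columns if col.startswith("test_")]
        battery = TestBattery(
            sample_ids=[str(s) for s in pheno.index],
            test_names=tests,
            scores=pheno[tests].to_numpy(dtype=float),
        )
        score = _score_phenotype(
            battery, pheno["age"].to_numpy(float), pheno["sex"].to_numpy(float),
            order=config.residualize_order,
        )
        score.rename("score").to_frame().to_csv(score_files[c], sep="\t")
        clean, report = qc_filter(genotypes, config.qc)
        clean_cohorts[c] = clean
        if resume and sumstat_files[c].exists():
            stats = gio.read_summary_stats(sumstat_files[c])
        else:
            stats = snp_association(clean, score)
            gio.write_summary_stats(stats, sumstat_files[c])
        per_cohort_stats.append(stats)
        logger.info(
            "cohort %d: %d/%d SNPs passed QC", c, report.n_passed, report.n_input
        )
    record("phenotype", *score_files)
    record("assoc", *sumstat_files)

    # ---- stage: meta ------------------------------------------------------
    meta_file = out / "meta.sumstats.tsv"
    if config.mode == "meta":
        if resume and meta_file.exists():
            meta = gio.read_summary_stats(meta_file)
        else:
            meta = ivw_meta(per_cohort_stats)
            gio.write_summary_stats(meta, meta_file)
        record("meta", meta_file)
        analysis_units = [("meta", meta, clean_cohorts[0])]
    else:
        analysis_units = [
            (f"cohort{c}", per_cohort_stats[c], clean_cohorts[c])
            for c in range(sim.n_cohorts)
        ]

    # ---- stages: gene test + enrichment (+ validation) --------------------
    candidate_names = [n for n in gene_sets if n != GENOME_SET]
    enrichment_tables = {}
    per_unit_results = {}
    for u, (unit, stats, ld_ref) in enumerate(analysis_units):
        gene_file = out / f"{unit}.genes.tsv"
        if resume and gene_file.exists():
            gene_results = gio.read_gene_results(gene_file)
        else:
            gene_results = gene_based_scan(
                stats, ld_ref, genes, window_kb=config.window_kb,
                schedule=config.mc_schedule, seed=sim.seed,
            )
            gio.write_gene_results(gene_results, gene_file)
        record(f"gene_test:{unit}", gene_file)

        ranked = rank_genes(gene_results)
        enr = config.enrichment
        if config.mode == "replication" and u > 0:
            # replication units use the unit-weighted statistic
            enr = EnrichmentConfig(**{**asdict(enr), "weight_exponent": 0.0})
        results = gsea(ranked, {n: gene_sets[n] for n in candidate_names}, enr)
        per_unit_results[unit] = {r.set_name: r for r in results}

        if config.run_validation:
            for r in results:
                meets = (
                    r.p_perm <= enr.discovery_p_max
                    or r.fdr_q < enr.discovery_fdr_max
                )
                if meets:
                    v = empirical_validation(ranked, gene_sets[r.set_name], r, enr)
                    r.frac_random_p = v.fraction_exceeding_p
                    r.frac_random_fdr = v.fraction_exceeding_fdr
                    r.validated = v.validated
        table = pd.DataFrame([r.to_row() for r in results])
        enr_file = out / f"{unit}.enrichment.tsv"
        gio.write_enrichment_table(table, enr_file)
        enrichment_tables[unit] = table
        record(f"gsea:{unit}", enr_file)

    # ---- stage: evidence --------------------------------------------------
    m = config.bonferroni_m or len(candidate_names)
    evidence: dict = {"bonferroni_m": m, "sets": {}}
    from gwaspath.types import CohortEvidence

    for set_name in candidate_names:
        units = list(per_unit_results)
        p_discovery = per_unit_results[units[0]][set_name].p_perm
        corrected = bonferroni(p_discovery, m)
        entry = {
            "p_discovery": p_discovery,
            "p_discovery_bonferroni": corrected,
        }
        cohort_evidence = []
        for u, unit in enumerate(units):
            p_u = corrected if u == 0 else per_unit_results[unit][set_name].p_perm
            n_u = sim.n_samples
            if 0.0 < p_u < 1.0:
                cohort_evidence.append(CohortEvidence(unit, p_u, n_u))
        if cohort_evidence:
            p_comb, table = stouffer_weighted(cohort_evidence)
            entry["p_combined"] = p_comb
            entry["cohorts"] = table.to_dict(orient="records")
        evidence["sets"][set_name] = entry
    evidence_file = out / "evidence.json"
    gio.write_manifest(evidence, evidence_file)
    record("evidence", evidence_file)

    manifest_file = out / "manifest.json"
    gio.write_manifest(manifest, manifest_file)
    manifest["manifest_path"] = str(manifest_file)
    manifest["enrichment"] = {
        unit: table.to_dict(orient="records")
        for unit, table in enrichment_tables.items()
    }
    manifest["evidence"] = evidence
    return manifest
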