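"""Shared domain types for the pathway-analysis pipeline."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

MISSING = np.nan


@dataclass(frozen=True)
class SnpInfo:
    """A biallelic SNP with target minor-allele frequency for simulation.

    Positions are 1-based. ``target_maf`` is the alt-allele frequency the
    generator aims for; for real data it is simply the observed frequency.
    """

    snp_id: str
    chromosome: int
    position: int
    ref_allele: str = "A"
    alt_allele: str = "G"
    target_maf: float = 0.25

    def __post_init__(self) -> None:
        if not (0.0 < self.target_maf <= 0.5):
            raise ValueError(
                f"{self.snp_id}: target_maf must lie in (0, 0.5], got {self.target_maf}"
            )
        if self.position < 1:
            raise ValueError(f"{self.snp_id}: position must be >= 1")


@dataclass(frozen=True)
class GeneModel:
    """A gene body as a 1-based inclusive interval on one chromosome."""

    gene_id: str
    chromosome: int
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start {self.start} > end {self.end}")


class GenotypeMatrix:
    """Samples x SNPs dosage matrix with its SNP map.

    Dosages are expected alt-allele counts in [0, 2]; NaN marks missing.
    """

    def __init__(
        self,
        sample_ids: list[str],
        snps: list[SnpInfo],
        dosages: np.ndarray,
    ) -> None:
        dosages = np.asarray(dosages, dtype=float)
        if dosages.shape != (len(sample_ids), len(snps)):
            raise ValueError(
                f"dosage shape {dosages.shape} inconsistent with "
                f"{len(sample_ids)} samples x {len(snps)} SNPs"
            )
        if dosages.size:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN column
                lo, hi = np.nanmin(dosages), np.nanmax(dosages)
            if lo < 0 or hi > 2:
                raise ValueError("non-missing dosages must lie in [0, 2]")
        ids = [s.snp_id for s in snps]
        if len(set(ids)) != len(ids):
            raise ValueError("snp_ids must be unique")
        self.sample_ids = list(sample_ids)
        self.snps = list(snps)
        self.dosages = dosages
        self._index = {sid: j for j, sid in enumerate(ids)}

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    def column(self, snp_id: str) -> np.ndarray:
        return self.dosages[:, self._index[snp_id]]

    def subset_snps(self, snp_ids: list[str]) -> "GenotypeMatrix":
        cols = [self._index[s] for s in snp_ids]
        return GenotypeMatrix(
            self.sample_ids,
            [self.snps[c] for c in cols],
            self.dosages[:, cols],
        )

    def alt_freq(self) -> np.ndarray:
        """Observed alt-allele frequency per SNP, ignoring missing entries."""
        return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        f = self.alt_freq()
        return np.minimum(f, 1.0 - f)


class GeneSetCollection:
    """Named gene sets with per-set descriptions (GMT semantics)."""

    def __init__(
        self,
        sets: dict[str, list[str]],
        descriptions: Optional[dict[str, str]] = None,
    ) -> None:
        for name, genes in sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise ValueError(f"gene set {name!r} contains duplicate genes")
        self.sets = {name: list(genes) for name, genes in sets.items()}
        self.descriptions = dict(descriptions or {})

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def items(self):
        return self.sets.items()


@dataclass
class SimulationConfig:
    """Parameters of the synthetic multi-cohort study.

    Defaults describe the study conditions the test-suite and calibration
    runs assume: unrelated samples, common LD-blocked SNPs, a cognitive test
    battery driven by one latent factor with age/sex nuisance effects, and a
    polygenic architecture whose causal variants are concentrated in one
    designated 50-gene set over a diffuse background.
    """

    n_cohorts: int = 1
    n_samples: int = 2000
    n_genes: int = 500
    snps_per_gene: tuple[int, int] = (3, 8)
    intergene_gap_bp: int = 150_000
    snp_spacing_bp: int = 2_000
    ld_rho: float = 0.7
    maf_range: tuple[float, float] = (0.05, 0.5)
    causal_set_size: int = 50
    h2_set: float = 0.2
    h2_background: float = 0.05
    n_tests: int = 4
    factor_loadings: tuple[float, ...] = (0.7, 0.7, 0.7, 0.7)
    beta_age: float = -0.03
    beta_sex: float = 0.1
    age_range: tuple[int, int] = (55, 75)
    missing_rate: float = 0.0
    overlap_mode: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.h2_set < 0 or self.h2_background < 0:
            raise ValueError("heritability fractions must be non-negative")
        if self.h2_set + self.h2_background >= 1:
            raise ValueError("h2_set + h2_background must be < 1")
        if not (0 <= self.ld_rho < 1):
            raise ValueError("ld_rho must lie in [0, 1)")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if self.snps_per_gene[0] < 1 or self.snps_per_gene[0] > self.snps_per_gene[1]:
            raise ValueError("snps_per_gene must be a (min, max) with 1 <= min <= max")
        if self.causal_set_size > self.n_genes:
            raise ValueError("causal_set_size cannot exceed n_genes")
        if len(self.factor_loadings) != self.n_tests:
            raise ValueError("need one factor loading per battery test")
        if any(not (0 < l <= 1) for l in self.factor_loadings):
            raise ValueError("factor loadings must lie in (0, 1]")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must lie in [0, 1)")
        # each gene body must fit between consecutive gene starts
        body = (self.snps_per_gene[1] - 1) * self.snp_spacing_bp
        if not self.overlap_mode and body >= self.intergene_gap_bp:
            raise ValueError(
                "intergene_gap_bp too small for requested snps_per_gene/spacing"
            )

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class QcThresholds:
    """Per-SNP quality-control thresholds.

    Defaults follow common GWAS practice for chip data: call rate > 0.98,
    MAF > 0.01, Hardy-Weinberg exact P > 0.001; for imputed dosages a
    quality score > 0.3 and MAF > 0.005.
    """

    call_rate_min: float = 0.98
    maf_min: float = 0.01
    hwe_p_min: float = 0.001
    imputation_quality_min: float = 0.3
    imputed_maf_min: float = 0.005

    def __post_init__(self) -> None:
        for name, v in asdict(self).items():
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass
class EnrichmentConfig:
    """Knobs of the competitive enrichment stage.

    ``weight_exponent`` 1 weights the running sum by each gene's -log10 P
    (discovery convention); 0 gives the unit-weighted statistic used for
    replication. ``n_perm`` permutations form the null; ``n_random_sets``
    size-matched random sets drive the empirical validation, each evaluated
    with ``n_perm_validation`` permutations.
    """

    weight_exponent: float = 1.0
    n_perm: int = 15_000
    n_random_sets: int = 1000
    n_perm_validation: int = 2000
    empirical_criterion: float = 0.95
    discovery_p_max: float = 0.05
    discovery_fdr_max: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_perm < 1 or self.n_perm_validation < 1:
            raise ValueError("permutation counts must be >= 1")
        if not (0.0 < self.empirical_criterion < 1.0):
            raise ValueError("empirical_criterion must lie in (0, 1)")


@dataclass(frozen=True)
class CohortEvidence:
    """One cohort's enrichment P-value with its sample size (Stouffer weight)."""

    cohort: str
    p: float
    n: int

    def __post_init__(self) -> None:
        if not (0.0 < self.p < 1.0):
            raise ValueError(
                f"{self.cohort}: p must lie strictly in (0, 1) for the Z transform"
            )
        if self.n < 1:
            raise ValueError(f"{self.cohort}: sample size must be a positive integer")


def rng_for(master_seed: int, *context) -> np.random.Generator:
    """Derived, reproducible random generator for one stochastic stage.

    Context items (stage names, cohort indices, gene ids) are folded into a
    SeedSequence so each stage gets an independent stream and adding a new
    stage never perturbs an existing one.
    """
    key = [_to_uint(c) for c in context]
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=key))


def _to_uint(item) -> int:
    if isinstance(item, (int, np.integer)):
        return int(item) & 0x7FFFFFFF
    # stable string hash (FNV-1a, 32-bit) -- hash() is salted per process
    h = 0x811C9DC5
    for byte in str(item).encode():
        h = ((h ^ byte) * 0x01000193) & 0xFFFFFFFF
    return h & 0x7FFFFFFF
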