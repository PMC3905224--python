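"""Synthetic multi-cohort fixtures with the statistical structure the
pipeline assumes.

Genotypes are generated per gene by Gaussian-copula thresholding: each
haplotype is a latent AR(1) Gaussian vector (adjacent-SNP correlation
``ld_rho``) dichotomised at the MAF-matching quantile, so LD decays
geometrically with marker distance and realised allele frequencies track
their targets. Individuals are sums of two independent haplotypes; cohorts
are independent draws from the same process.

Phenotypes follow a latent-factor battery: a genetic value built from
causal-set SNPs (variance ``h2_set``) plus a diffuse background
(``h2_background``) plus residual forms latent g; each battery test loads
on g and carries additive age and sex nuisance effects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from gwaspath.types import (
    GeneModel,
    GeneSetCollection,
    GenotypeMatrix,
    SimulationConfig,
    SnpInfo,
    rng_for,
)

CAUSAL_SET = "causal_set"
DECOY_SET = "decoy_set"
GENOME_SET = "all_genes"


@dataclass
class TestBattery:
    """Raw scores of a cognitive test battery (samples x tests)."""

    __test__ = False  # bare data holder, despite the Test* name

    sample_ids: list[str]
    test_names: list[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.sample_ids), len(self.test_names)):
            raise ValueError("battery score shape inconsistent with ids/names")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.scores, index=pd.Index(self.sample_ids, name="sample_id"),
            columns=self.test_names,
        )


def make_gene_annotation(
    config: SimulationConfig,
) -> tuple[list[GeneModel], list[SnpInfo]]:
    """Lay out genes along one chromosome and place SNPs inside gene bodies.

    Genes are separated by ``intergene_gap_bp`` (default 150 kb) so that
    +/-50 kb windows are disjoint; with ``overlap_mode`` the first two genes
    are placed within 50 kb of each other so one SNP can map to both.
    """
    rng = rng_for(config.seed, "annotation")
    lo, hi = config.snps_per_gene
    n_snps_per_gene = rng.integers(lo, hi + 1, size=config.n_genes)
    mafs = rng.uniform(*config.maf_range, size=int(n_snps_per_gene.sum()))

    genes: list[GeneModel] = []
    snps: list[SnpInfo] = []
    cursor = 1_000_000  # leave headroom at the chromosome start
    k = 0
    width = len(str(config.n_genes))
    for g in range(config.n_genes):
        m = int(n_snps_per_gene[g])
        start = cursor
        end = start + (m - 1) * config.snp_spacing_bp if m > 1 else start
        gene_id = f"GENE{g + 1:0{width}d}"
        genes.append(GeneModel(gene_id, 1, start, end))
        for j in range(m):
            snps.append(
                SnpInfo(
                    snp_id=f"rs{g + 1:0{width}d}_{j + 1}",
                    chromosome=1,
                    position=start + j * config.snp_spacing_bp,
                    target_maf=float(mafs[k]),
                )
            )
            k += 1
        if config.overlap_mode and g == 0:
            # next gene starts 40 kb after this one ends: inside the 50 kb window
            cursor = end + 40_000
        else:
            cursor = end + config.intergene_gap_bp
    return genes, snps


def _gene_blocks(genes: list[GeneModel], snps: list[SnpInfo]) -> list[np.ndarray]:
    """Column indices of each gene's own SNPs, in annotation order."""
    pos = np.array([s.position for s in snps])
    chrom = np.array([s.chromosome for s in snps])
    blocks = []
    for g in genes:
        mask = (chrom == g.chromosome) & (pos >= g.start) & (pos <= g.end)
        blocks.append(np.flatnonzero(mask))
    return blocks


def simulate_genotypes(
    annotation: tuple[list[GeneModel], list[SnpInfo]],
    config: SimulationConfig,
    cohort_index: int = 0,
) -> GenotypeMatrix:
    """Draw one cohort's dosage matrix.

    Per gene, 2n haplotypes are latent AR(1) Gaussians with correlation
    ``ld_rho ** |i-j|`` between SNPs i and j, thresholded at the alt-allele
    frequency quantile. The dosage is the sum of the two haplotypes, so LD
    measured on dosages matches the haplotype copula up to discretisation.
    """
    genes, snps = annotation
    rng = rng_for(config.seed, "genotypes", cohort_index)
    n = config.n_samples
    rho = config.ld_rho
    n_snps = len(snps)
    thresholds = norm.isf([s.target_maf for s in snps])

    dosages = np.empty((n, n_snps))
    for block in _gene_blocks(genes, snps):
        m = block.size
        if m == 0:
            continue
        z = rng.standard_normal((2 * n, m))
        latent = np.empty_like(z)
        latent[:, 0] = z[:, 0]
        scale = np.sqrt(1.0 - rho * rho)
        for j in range(1, m):
            latent[:, j] = rho * latent[:, j - 1] + scale * z[:, j]
        carriers = latent > thresholds[block]
        dosages[:, block] = (
            carriers[:n].astype(float) + carriers[n:].astype(float)
        )
    if config.missing_rate > 0:
        miss = rng.random(dosages.shape) < config.missing_rate
        dosages[miss] = np.nan
    sample_ids = [f"C{cohort_index}_S{i + 1:05d}" for i in range(n)]
    return GenotypeMatrix(sample_ids, snps, dosages)


def make_gene_sets(
    annotation: tuple[list[GeneModel], list[SnpInfo]],
    config: SimulationConfig,
) -> GeneSetCollection:
    """Designate the causal set, a size-matched random decoy, and the genome set.

    The causal set is a seeded uniform draw of ``causal_set_size`` genes; the
    decoy is an independent uniform draw of the same size from all genes, so
    its overlap with the causal set follows the hypergeometric law.
    """
    genes, _ = annotation
    ids = [g.gene_id for g in genes]
    k = config.causal_set_size
    rng = rng_for(config.seed, "gene_sets")
    causal = sorted(rng.choice(ids, size=k, replace=False).tolist())
    decoy = sorted(rng.choice(ids, size=k, replace=False).tolist())
    return GeneSetCollection(
        {CAUSAL_SET: causal, DECOY_SET: decoy, GENOME_SET: ids},
        descriptions={
            CAUSAL_SET: "genes carrying the concentrated causal architecture",
            DECOY_SET: "size-matched random control set",
            GENOME_SET: "every annotated gene",
        },
    )


def simulate_phenotypes(
    genotypes: GenotypeMatrix,
    annotation: tuple[list[GeneModel], list[SnpInfo]],
    causal_set: list[str],
    config: SimulationConfig,
    cohort_index: int = 0,
) -> tuple[TestBattery, np.ndarray, np.ndarray, np.ndarray]:
    """Simulate the test battery plus age, sex, and the latent factor.

    Latent g = sqrt(h2_set) * standardized causal-set polygenic score
    + sqrt(h2_background) * standardized background score + residual scaled
    so Var(g) = 1. Test t = loading_t * g + sqrt(1 - loading_t^2) * noise
    + beta_age * age + beta_sex * sex.

    Returns (battery, age, sex, latent_g); latent_g is kept for recovery
    checks and never written to the phenotype table.
    """
    if not causal_set:
        raise ValueError("causal_set must contain at least one gene")
    genes, snps = annotation
    known = {g.gene_id for g in genes}
    missing = [g for g in causal_set if g not in known]
    if missing:
        raise ValueError(f"causal genes absent from annotation: {missing[:5]}")

    rng = rng_for(config.seed, "phenotypes", cohort_index)
    n = genotypes.n_samples
    causal = set(causal_set)
    blocks = _gene_blocks(genes, snps)
    causal_cols = np.concatenate(
        [b for g, b in zip(genes, blocks) if g.gene_id in causal and b.size]
    )
    background_cols = np.concatenate(
        [b for g, b in zip(genes, blocks) if g.gene_id not in causal and b.size]
        or [np.empty(0, dtype=int)]
    )

    X = genotypes.dosages
    if np.isnan(X).any():
        col_mean = np.nanmean(X, axis=0)
        X = np.where(np.isnan(X), col_mean[None, :], X)

    def scaled_score(cols: np.ndarray, h2: float) -> np.ndarray:
        if h2 <= 0 or cols.size == 0:
            return np.zeros(n)
        effects = rng.standard_normal(cols.size)
        score = X[:, cols] @ effects
        sd = score.std()
        if sd == 0:
            return np.zeros(n)
        return np.sqrt(h2) * (score - score.mean()) / sd

    g_set = scaled_score(causal_cols, config.h2_set)
    g_bg = scaled_score(background_cols, config.h2_background)
    resid_var = 1.0 - config.h2_set - config.h2_background
    latent_g = g_set + g_bg + np.sqrt(resid_var) * rng.standard_normal(n)

    age = rng.integers(config.age_range[0], config.age_range[1] + 1, size=n).astype(float)
    sex = rng.integers(0, 2, size=n).astype(float)

    loadings = np.asarray(config.factor_loadings)
    noise = rng.standard_normal((n, config.n_tests))
    scores = (
        latent_g[:, None] * loadings[None, :]
        + noise * np.sqrt(1.0 - loadings**2)[None, :]
        + config.beta_age * age[:, None]
        + config.beta_sex * sex[:, None]
    )
    battery = TestBattery(
        sample_ids=list(genotypes.sample_ids),
        test_names=[f"test_{t + 1}" for t in range(config.n_tests)],
        scores=scores,
    )
    return battery, age, sex, latent_g
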