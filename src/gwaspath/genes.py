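"""LD-aware gene-based association: window assignment, LD estimation,
sum-of-squared-Z empirical P-values, and genome-wide gene ranking.

The gene statistic is S = sum of squared SNP Z-scores within the gene's
window. Its null distribution accounts for both the number of SNPs and
their linkage disequilibrium by Monte-Carlo simulation from a multivariate
normal with the SNPs' dosage-correlation matrix as covariance, so a gene's
empirical P is comparable across genes regardless of SNP content.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from gwaspath.types import GeneModel, GenotypeMatrix, SnpInfo, rng_for

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_KB = 50.0
#: adaptive Monte-Carlo ladder; escalate while the tail count is unstable
DEFAULT_SCHEDULE = (1_000, 10_000, 100_000)


@dataclass
class GeneResult:
    """Empirical gene-based result."""

    gene_id: str
    n_snps: int
    stat: float
    p: float
    n_sims: int

    def __post_init__(self) -> None:
        if self.stat < 0:
            raise ValueError("gene statistic must be non-negative")
        if not (0.0 < self.p <= 1.0):
            raise ValueError("empirical p must lie in (0, 1]")


def assign_snps(
    snps: list[SnpInfo],
    genes: list[GeneModel],
    window_kb: float = DEFAULT_WINDOW_KB,
) -> dict[str, list[str]]:
    """Map each gene to the SNPs inside its +/-window, position order.

    The window is inclusive at both ends; a SNP inside several windows is
    assigned to every such gene. Genes without SNPs are omitted.
    """
    window = int(round(window_kb * 1000))
    # group SNP positions per chromosome for binary search
    by_chrom: dict[int, tuple[np.ndarray, list[str]]] = {}
    for chrom in {s.chromosome for s in snps}:
        sub = sorted(
            (s for s in snps if s.chromosome == chrom), key=lambda s: s.position
        )
        by_chrom[chrom] = (
            np.array([s.position for s in sub]),
            [s.snp_id for s in sub],
        )
    assignment: dict[str, list[str]] = {}
    for gene in genes:
        if gene.chromosome not in by_chrom:
            continue
        pos, ids = by_chrom[gene.chromosome]
        lo = np.searchsorted(pos, gene.start - window, side="left")
        hi = np.searchsorted(pos, gene.end + window, side="right")
        if hi > lo:
            assignment[gene.gene_id] = ids[lo:hi]
    if not assignment:
        warnings.warn("no SNP fell inside any gene window", stacklevel=2)
    return assignment


def ld_matrix(genotypes: GenotypeMatrix, snp_ids: list[str]) -> np.ndarray:
    """Pairwise Pearson dosage correlation, repaired to positive
    semi-definite by eigenvalue clipping and unit-diagonal rescaling."""
    if not snp_ids:
        raise ValueError("need at least one SNP")
    cols = np.column_stack([genotypes.column(s) for s in snp_ids])
    if np.isnan(cols).any():
        mean = np.nanmean(cols, axis=0)
        cols = np.where(np.isnan(cols), mean[None, :], cols)
    if cols.shape[0] < 2:
        raise ValueError("need at least two samples to estimate LD")
    sds = cols.std(axis=0, ddof=0)
    dead = np.flatnonzero(sds < 1e-12)
    if dead.size:
        raise ValueError(
            f"zero-variance SNP(s) in LD block: {[snp_ids[j] for j in dead]}"
        )
    R = np.corrcoef(cols, rowvar=False)
    if R.ndim == 0:  # single SNP
        return np.ones((1, 1))
    return _repair_psd(R)


def _repair_psd(R: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    """Clip eigenvalues at ``floor`` and rescale to unit diagonal."""
    R = (R + R.T) / 2.0
    eigvals, eigvecs = np.linalg.eigh(R)
    if eigvals.min() >= floor:
        return R
    eigvals = np.clip(eigvals, floor, None)
    fixed = (eigvecs * eigvals) @ eigvecs.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return fixed


def _mvn_factor(ld: np.ndarray) -> np.ndarray:
    """A factor L with L L^T = ld; eigen route tolerates rank deficiency."""
    try:
        return np.linalg.cholesky(ld)
    except np.linalg.LinAlgError:
        eigvals, eigvecs = np.linalg.eigh((ld + ld.T) / 2.0)
        if eigvals.min() < -1e-8:
            raise ValueError("LD matrix not positive semi-definite after repair")
        return eigvecs * np.sqrt(np.clip(eigvals, 0.0, None))


def gene_empirical_p(
    z_scores: np.ndarray,
    ld: np.ndarray,
    schedule: tuple[int, ...] = DEFAULT_SCHEDULE,
    seed: int = 0,
    gene_id: str = "",
    min_tail: int = 100,
) -> GeneResult:
    """Monte-Carlo empirical P for S = sum z_i^2 under a MVN(0, LD) null.

    At each rung B of the schedule, B vectors u ~ MVN(0, ld) yield null
    statistics S* = sum u^2 and p = (1 + #{S* >= S}) / (B + 1); simulation
    escalates to the next rung while the exceedance count is below
    ``min_tail`` (i.e. while p * B < min_tail), so small P-values rest on
    enough tail mass. The add-one correction keeps p strictly positive.
    """
    z = np.asarray(z_scores, dtype=float)
    ld = np.asarray(ld, dtype=float)
    if z.ndim != 1 or ld.shape != (z.size, z.size):
        raise ValueError("z_scores length must match the LD matrix dimension")
    S = float(np.sum(z**2))
    L = _mvn_factor(ld)
    rng = rng_for(seed, "gene_mc", gene_id)
    exceed = 0
    used = 0
    for B in schedule:
        draw = B - used
        if draw > 0:
            # draw in blocks to bound memory on the largest rung
            for start in range(0, draw, 200_000):
                b = min(200_000, draw - start)
                u = rng.standard_normal((b, L.shape[1])) @ L.T
                exceed += int(np.count_nonzero((u**2).sum(axis=1) >= S))
            used = B
        if exceed >= min_tail:
            break
    p = (1 + exceed) / (used + 1)
    return GeneResult(gene_id=gene_id, n_snps=z.size, stat=S, p=p, n_sims=used)


def gene_based_scan(
    meta: pd.DataFrame,
    genotypes: GenotypeMatrix,
    genes: list[GeneModel],
    window_kb: float = DEFAULT_WINDOW_KB,
    schedule: tuple[int, ...] = DEFAULT_SCHEDULE,
    seed: int = 0,
) -> pd.DataFrame:
    """Run the gene-based test for every gene with post-QC SNPs.

    ``meta`` is a summary-stat frame (needs snp_id and z); ``genotypes``
    provides the LD reference — the analysis cohort's own dosages. Returns a
    frame ``gene_id chr start end n_snps stat p n_sims``. Per-gene seeds are
    derived from (seed, gene_id) so parallel or partial runs reproduce.
    """
    zmap = dict(zip(meta["snp_id"], meta["z"].astype(float)))
    available = set(zmap) & set(genotypes.snp_ids)
    assignment = assign_snps(genotypes.snps, genes, window_kb)
    gene_ix = {g.gene_id: g for g in genes}
    rows = []
    for gene_id, snp_ids in assignment.items():
        usable = [s for s in snp_ids if s in available]
        if not usable:
            continue
        z = np.array([zmap[s] for s in usable])
        if len(usable) == 1:
            # 1-df case is closed form: the SNP's own two-sided P
            p1 = float(np.clip(2.0 * stats.norm.sf(abs(z[0])),
                               np.finfo(float).tiny, 1.0))
            res = GeneResult(gene_id=gene_id, n_snps=1, stat=float(z[0] ** 2),
                             p=p1, n_sims=0)
        else:
            ld = ld_matrix(genotypes, usable)
            res = gene_empirical_p(z, ld, schedule=schedule, seed=seed,
                                   gene_id=gene_id)
        g = gene_ix[gene_id]
        rows.append(
            (gene_id, g.chromosome, g.start, g.end, res.n_snps, res.stat,
             res.p, res.n_sims)
        )
    frame = pd.DataFrame(
        rows,
        columns=["gene_id", "chr", "start", "end", "n_snps", "stat", "p", "n_sims"],
    )
    logger.info("gene scan: %d genes tested", len(frame))
    return frame.sort_values("gene_id").reset_index(drop=True)


def rank_genes(results: pd.DataFrame | list[GeneResult]) -> pd.DataFrame:
    """Order genes by descending -log10 P (ties broken by gene id).

    Returns a frame ``gene_id p weight`` whose ``weight`` column is the
    running-sum weight used by the enrichment stage.
    """
    if isinstance(results, list):
        frame = pd.DataFrame(
            {"gene_id": [r.gene_id for r in results], "p": [r.p for r in results]}
        )
    else:
        frame = results[["gene_id", "p"]].copy()
    if frame["gene_id"].duplicated().any():
        dupes = frame.loc[frame["gene_id"].duplicated(), "gene_id"].tolist()
        raise ValueError(f"duplicate gene ids in results: {dupes[:5]}")
    frame["weight"] = -np.log10(frame["p"].astype(float))
    frame = frame.sort_values(
        ["weight", "gene_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return frame
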