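"""Per-cohort QC, additive-model single-SNP association, and fixed-effect
inverse-variance meta-analysis.

Summary statistics travel as a :class:`pandas.DataFrame` with the fixed
column schema ``snp_id chr pos effect_allele other_allele eaf beta se z p n``
(meta-analysed frames add ``k_studies``); readers tolerate extra columns.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy import stats

from gwaspath.types import GenotypeMatrix, QcThresholds

logger = logging.getLogger(__name__)

SUMMARY_COLUMNS = [
    "snp_id", "chr", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "z", "p", "n",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact two-sided Hardy-Weinberg equilibrium P-value.

    Conditional on the observed allele counts, the heterozygote count under
    HWE follows a known exact distribution over all counts of the same
    parity. The P-value sums the probabilities of every heterozygote count
    no more probable than the observed one.
    """
    for c in (n_AA, n_Aa, n_aa):
        if c < 0 or int(c) != c:
            raise ValueError("genotype counts must be non-negative integers")
    n = int(n_AA + n_Aa + n_aa)
    if n < 1:
        raise ValueError("need at least one genotyped sample")
    n_a = int(n_Aa + 2 * n_aa)  # minor-allele count (relabel if needed)
    n_A = int(n_Aa + 2 * n_AA)
    rare = min(n_a, n_A)
    # attainable heterozygote counts share the parity of the rare-allele count
    hets = np.arange(rare % 2, rare + 1, 2)
    homr = (rare - hets) // 2
    homc = n - hets - homr
    logp = (
        hets * np.log(2.0)
        + gammaln(n + 1)
        - gammaln(hets + 1)
        - gammaln(homr + 1)
        - gammaln(homc + 1)
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    observed = probs[np.searchsorted(hets, n_Aa)]
    return float(min(1.0, probs[probs <= observed * (1 + 1e-12)].sum()))


@dataclass
class QcReport:
    """Per-SNP QC outcome: removal reasons keyed by snp_id."""

    n_input: int
    n_passed: int
    removed: dict[str, str] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"snp_id": list(self.removed), "reason": list(self.removed.values())}
        )


def qc_filter(
    genotypes: GenotypeMatrix,
    thresholds: QcThresholds | None = None,
    imputation_quality: np.ndarray | None = None,
    genotyped_mask: np.ndarray | None = None,
) -> tuple[GenotypeMatrix, QcReport]:
    """Remove SNPs failing call-rate, MAF or HWE thresholds.

    HWE uses hard calls (rounded dosages) and is evaluated on the subset
    flagged as directly genotyped (``genotyped_mask``; all SNPs by default).
    The imputation-quality and imputed-MAF filters apply only when a quality
    vector is supplied, and then only to SNPs not flagged as genotyped.
    The first failing check, in the order call_rate, maf, imputation_quality,
    hwe, is recorded as the removal reason.
    """
    thresholds = thresholds or QcThresholds()
    D = genotypes.dosages
    n, p = D.shape
    if genotyped_mask is None:
        genotyped_mask = np.ones(p, dtype=bool)
    genotyped_mask = np.asarray(genotyped_mask, dtype=bool)

    call_rate = 1.0 - np.isnan(D).mean(axis=0)
    maf = genotypes.maf()

    removed: dict[str, str] = {}
    keep = np.ones(p, dtype=bool)
    for j, snp in enumerate(genotypes.snps):
        if call_rate[j] < thresholds.call_rate_min:
            removed[snp.snp_id] = "call_rate"
        elif genotyped_mask[j] and maf[j] <= thresholds.maf_min:
            removed[snp.snp_id] = "maf"
        elif not genotyped_mask[j] and imputation_quality is not None:
            if imputation_quality[j] <= thresholds.imputation_quality_min:
                removed[snp.snp_id] = "imputation_quality"
            elif maf[j] <= thresholds.imputed_maf_min:
                removed[snp.snp_id] = "maf"
        if snp.snp_id in removed:
            keep[j] = False
            continue
        if genotyped_mask[j]:
            hard = np.rint(D[~np.isnan(D[:, j]), j]).astype(int)
            counts = np.bincount(hard, minlength=3)
            if hwe_exact_test(counts[0], counts[1], counts[2]) <= thresholds.hwe_p_min:
                removed[snp.snp_id] = "hwe"
                keep[j] = False

    kept_ids = [s.snp_id for s, k in zip(genotypes.snps, keep) if k]
    if not kept_ids:
        raise ValueError(
            "QC removed every SNP; relax the thresholds or inspect the input"
        )
    out = genotypes.subset_snps(kept_ids)
    report = QcReport(n_input=p, n_passed=len(kept_ids), removed=removed)
    logger.info("QC: %d/%d SNPs passed", report.n_passed, report.n_input)
    return out, report


def snp_association(
    genotypes: GenotypeMatrix,
    phenotype: pd.Series,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Additive-model OLS association of a phenotype with every SNP dosage.

    Per SNP the model is phenotype ~ intercept + covariates + dosage; the
    reported beta is the dosage coefficient and p is two-sided from its t
    statistic. Missing dosages are mean-imputed per SNP. Monomorphic SNPs
    are emitted with beta 0 and p 1 and flagged in the ``monomorphic``
    column. Computation residualises phenotype and dosages on the covariate
    block once (Frisch-Waugh), which is exact OLS and vectorises over SNPs.
    """
    ids = list(genotypes.sample_ids)
    y = phenotype.reindex(ids)
    if y.isna().any():
        raise ValueError("phenotype missing for some genotyped samples")
    y = np.asarray(y, dtype=float)
    n = len(ids)

    if covariates is not None:
        C = covariates.reindex(ids)
        if C.isna().any().any():
            raise ValueError("covariates missing for some genotyped samples")
        C = np.column_stack([np.ones(n), np.asarray(C, dtype=float)])
    else:
        C = np.ones((n, 1))
    q, _ = np.linalg.qr(C)
    if np.linalg.matrix_rank(C) < C.shape[1]:
        raise ValueError("covariate matrix (with intercept) is rank deficient")

    D = genotypes.dosages.copy()
    if np.isnan(D).any():
        col_mean = np.nanmean(D, axis=0)
        D = np.where(np.isnan(D), col_mean[None, :], D)

    y_res = y - q @ (q.T @ y)
    D_res = D - q @ (q.T @ D)

    sxx = (D_res**2).sum(axis=0)
    mono = sxx < 1e-12
    sxx_safe = np.where(mono, 1.0, sxx)
    beta = (D_res * y_res[:, None]).sum(axis=0) / sxx_safe
    dof = n - C.shape[1] - 1
    if dof < 1:
        raise ValueError("not enough samples for the covariate-adjusted model")
    rss = (y_res**2).sum() - beta**2 * sxx_safe
    sigma2 = np.maximum(rss, 0.0) / dof
    se = np.sqrt(sigma2 / sxx_safe)
    se_safe = np.where(se < 1e-300, 1e-300, se)
    tstat = beta / se_safe
    with np.errstate(over="ignore"):
        p = 2.0 * stats.t.sf(np.abs(tstat), dof)
    tiny = np.finfo(float).tiny
    p = np.clip(p, tiny, 1.0)

    beta = np.where(mono, 0.0, beta)
    p = np.where(mono, 1.0, p)
    tstat = np.where(mono, 0.0, tstat)
    se = np.where(mono, np.inf, se)

    eaf = D.mean(axis=0) / 2.0
    frame = pd.DataFrame(
        {
            "snp_id": genotypes.snp_ids,
            "chr": [s.chromosome for s in genotypes.snps],
            "pos": [s.position for s in genotypes.snps],
            "effect_allele": [s.alt_allele for s in genotypes.snps],
            "other_allele": [s.ref_allele for s in genotypes.snps],
            "eaf": eaf,
            "beta": beta,
            "se": se,
            "z": tstat,
            "p": p,
            "n": n,
            "monomorphic": mono,
        }
    )
    return frame


def _is_strand_ambiguous(a1: str, a2: str) -> bool:
    return _COMPLEMENT.get(a1.upper()) == a2.upper()


def ivw_meta(per_cohort: list[pd.DataFrame]) -> pd.DataFrame:
    """Fixed-effect inverse-variance meta-analysis of per-cohort summaries.

    SNPs are matched by id and effect alleles harmonised to the first
    cohort's orientation (flipping beta and frequency where cohorts report
    the opposite allele pair); SNPs with irreconcilable allele pairs are
    dropped with a warning. Weights are 1/se^2; pooled
    beta = sum(w_i b_i)/sum(w_i), se = 1/sqrt(sum(w_i)), p two-sided normal.
    """
    if not per_cohort:
        raise ValueError("need at least one cohort")
    frames = []
    ref = per_cohort[0].set_index("snp_id")
    for i, frame in enumerate(per_cohort):
        f = frame.set_index("snp_id").copy()
        if "monomorphic" in f.columns:
            f = f[~f["monomorphic"].astype(bool)]
        if (f["se"] <= 0).any() or ~np.isfinite(f["se"]).all():
            bad = f.index[(f["se"] <= 0) | ~np.isfinite(f["se"])]
            f = f.drop(index=bad)
        if i > 0:
            f = _harmonize(ref, f)
        frames.append(f)

    all_ids = sorted(set().union(*[set(f.index) for f in frames]))
    k = len(frames)
    betas = np.full((k, len(all_ids)), np.nan)
    ses = np.full((k, len(all_ids)), np.nan)
    ns = np.zeros((k, len(all_ids)))
    eafs = np.full((k, len(all_ids)), np.nan)
    for i, f in enumerate(frames):
        loc = f.reindex(all_ids)
        betas[i] = loc["beta"]
        ses[i] = loc["se"]
        ns[i] = loc["n"].fillna(0)
        eafs[i] = loc["eaf"]

    w = np.where(np.isnan(ses), 0.0, 1.0 / np.square(ses))
    betas0 = np.where(np.isnan(betas), 0.0, betas)
    wsum = w.sum(axis=0)
    beta = (w * betas0).sum(axis=0) / wsum
    se = 1.0 / np.sqrt(wsum)
    z = beta / se
    p = np.clip(2.0 * stats.norm.sf(np.abs(z)), np.finfo(float).tiny, 1.0)
    k_studies = (w > 0).sum(axis=0)
    n_total = ns.sum(axis=0).astype(int)
    # frequency: sample-size weighted mean across contributing cohorts
    n_w = np.where(np.isnan(eafs), 0.0, ns)
    eaf = (n_w * np.where(np.isnan(eafs), 0.0, eafs)).sum(axis=0) / np.maximum(
        n_w.sum(axis=0), 1.0
    )

    meta_ref = ref.reindex(all_ids)
    out = pd.DataFrame(
        {
            "snp_id": all_ids,
            "chr": meta_ref["chr"].to_numpy(),
            "pos": meta_ref["pos"].to_numpy(),
            "effect_allele": meta_ref["effect_allele"].to_numpy(),
            "other_allele": meta_ref["other_allele"].to_numpy(),
            "eaf": eaf,
            "beta": beta,
            "se": se,
            "z": z,
            "p": p,
            "n": n_total,
            "k_studies": k_studies,
        }
    )
    return out[out["k_studies"] >= 1].reset_index(drop=True)


def _harmonize(ref: pd.DataFrame, other: pd.DataFrame) -> pd.DataFrame:
    """Align a cohort's effect alleles to the reference orientation."""
    shared = other.index.intersection(ref.index)
    out = other.copy()
    dropped = []
    for snp in shared:
        ea_r = str(ref.at[snp, "effect_allele"]).upper()
        oa_r = str(ref.at[snp, "other_allele"]).upper()
        ea = str(other.at[snp, "effect_allele"]).upper()
        oa = str(other.at[snp, "other_allele"]).upper()
        if (ea, oa) == (ea_r, oa_r):
            continue
        if (ea, oa) == (oa_r, ea_r):
            out.at[snp, "beta"] = -other.at[snp, "beta"]
            out.at[snp, "z"] = -other.at[snp, "z"]
            out.at[snp, "eaf"] = 1.0 - other.at[snp, "eaf"]
            out.at[snp, "effect_allele"] = ea_r
            out.at[snp, "other_allele"] = oa_r
        else:
            dropped.append(snp)
    if dropped:
        ambiguous = [s for s in dropped if _is_strand_ambiguous(
            str(other.at[s, "effect_allele"]), str(other.at[s, "other_allele"]))]
        warnings.warn(
            f"dropped {len(dropped)} SNP(s) with irreconcilable allele pairs "
            f"({len(ambiguous)} strand-ambiguous)",
            stacklevel=3,
        )
        out = out.drop(index=dropped)
    return out
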