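"""Multiple-testing correction and cross-cohort evidence combination.

Enrichment P-values are one-sided by construction, so cohorts are combined
with Stouffer's weighted Z-transform using square-root-sample-size weights:
Z_i = Phi^{-1}(1 - p_i), Z = sum(w_i Z_i) / sqrt(sum w_i^2), combined
p = 1 - Phi(Z). The discovery cohort's P is Bonferroni-corrected for the
number of set-by-phenotype tests before combination.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import norm

from gwaspath.types import CohortEvidence

_P_FLOOR = 1e-300
_P_CEIL = 1.0 - 1e-16


def bonferroni(p: float, m: int) -> float:
    """Bonferroni-corrected P-value: min(1, m * p)."""
    if not (0.0 < p <= 1.0):
        raise ValueError("p must lie in (0, 1]")
    if m < 1 or int(m) != m:
        raise ValueError("m must be a positive integer")
    return min(1.0, m * p)


def stouffer_weighted(evidence: list[CohortEvidence]) -> tuple[float, pd.DataFrame]:
    """Stouffer's weighted Z-transform combination of one-sided P-values.

    Weights are sqrt(n_i); the result is invariant to rescaling all weights.
    Returns the combined P and a per-cohort table of Z-scores and weights.
    """
    if not evidence:
        raise ValueError("need at least one cohort")
    p = np.array([e.p for e in evidence], dtype=float)
    if ((p <= 0) | (p >= 1)).any():
        raise ValueError("p-values must lie strictly in (0, 1)")
    clipped = np.clip(p, _P_FLOOR, _P_CEIL)
    if (clipped != p).any():
        warnings.warn("p-value(s) clipped to avoid infinite Z", stacklevel=2)
    z = norm.isf(clipped)
    w = np.sqrt([e.n for e in evidence])
    z_comb = float((w * z).sum() / np.sqrt((w**2).sum()))
    p_comb = float(norm.sf(z_comb))
    table = pd.DataFrame(
        {
            "cohort": [e.cohort for e in evidence],
            "p": p,
            "n": [e.n for e in evidence],
            "weight": w,
            "z": z,
        }
    )
    return p_comb, table
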