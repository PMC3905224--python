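"""Cognitive phenotype construction from a test battery.

Three operations mirror how ageing-cohort studies score their batteries:
a general-factor score as the first unrotated principal component of the
test correlation matrix (regression-scored), ordinary-least-squares
residualisation on age and sex with standardised residuals, and a composite
formed as the re-standardised mean of two standardised scores.

Scores are carried as :class:`pandas.Series` indexed by sample id; every
operation returns a standardized series (mean 0, sd 1).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm

from gwaspath.synthetic import TestBattery

_STD_TOL = 1e-12


def _standardize(values: np.ndarray, what: str = "scores") -> np.ndarray:
    sd = values.std(ddof=0)
    if sd < _STD_TOL:
        raise ValueError(f"{what} have (near-)zero variance; cannot standardize")
    return (values - values.mean()) / sd


def gf_scores(battery: TestBattery) -> pd.Series:
    """First-unrotated-component factor scores of a test battery.

    Tests are standardized, the first eigenvector of their correlation
    matrix is extracted, and regression scores (loading-weighted test
    values scaled by the inverse eigenvalue) are computed and standardized.
    The component is oriented so the mean test loading is positive, which
    makes the sign stable across resamples of the same battery.
    """
    X = np.asarray(battery.scores, dtype=float)
    n, k = X.shape
    if n < 2:
        raise ValueError("need at least 2 samples for factor extraction")
    sds = X.std(axis=0, ddof=0)
    dead = np.flatnonzero(sds < _STD_TOL)
    if dead.size:
        names = [battery.test_names[j] for j in dead]
        raise ValueError(f"zero-variance test(s): {names}")
    Z = (X - X.mean(axis=0)) / sds
    R = np.corrcoef(Z, rowvar=False)
    if k == 1:
        scores = Z[:, 0]
    else:
        eigvals, eigvecs = np.linalg.eigh(R)
        v1 = eigvecs[:, -1]
        if v1.mean() < 0:
            v1 = -v1
        # regression scoring for PCA: Z v1 / lambda1; the scale cancels on
        # standardization but is kept for fidelity to the scoring rule
        scores = Z @ v1 / eigvals[-1]
    return pd.Series(
        _standardize(scores, "factor scores"),
        index=pd.Index(battery.sample_ids, name="sample_id"),
        name="gf",
    )


def residualize_age_sex(
    scores: pd.Series, age: np.ndarray, sex: np.ndarray
) -> pd.Series:
    """Standardised residuals of an OLS fit of scores on age and sex."""
    y = np.asarray(scores, dtype=float)
    age = np.asarray(age, dtype=float)
    sex = np.asarray(sex, dtype=float)
    if not (len(y) == len(age) == len(sex)):
        raise ValueError("scores, age and sex must have equal length")
    X = sm.add_constant(np.column_stack([age, sex]), has_constant="add")
    resid = sm.OLS(y, X).fit().resid
    if resid.std(ddof=0) < _STD_TOL:
        raise ValueError(
            "scores are an exact linear function of age and sex; residuals degenerate"
        )
    return pd.Series(_standardize(resid, "residuals"), index=scores.index,
                     name=scores.name)


def battery_scores(
    battery: TestBattery,
    age: np.ndarray,
    sex: np.ndarray,
    residualize: str = "after",
) -> pd.Series:
    """Factor score with age/sex control, in either order.

    ``residualize="after"`` (default) extracts the factor from the raw
    battery and residualises the score; ``"before"`` residualises each test
    column first and extracts the factor from the residualised battery —
    the two conventions seen across ageing-cohort studies.
    """
    if residualize == "after":
        return residualize_age_sex(gf_scores(battery), age, sex)
    if residualize == "before":
        columns = [
            residualize_age_sex(
                pd.Series(battery.scores[:, j], index=battery.sample_ids), age, sex
            ).to_numpy()
            for j in range(battery.scores.shape[1])
        ]
        residualised = TestBattery(
            sample_ids=battery.sample_ids,
            test_names=battery.test_names,
            scores=np.column_stack(columns),
        )
        return gf_scores(residualised)
    raise ValueError("residualize must be 'after' or 'before'")


def composite_mean(scores_a: pd.Series, scores_b: pd.Series) -> pd.Series:
    """Re-standardised per-sample mean of two standardized scores.

    The two inputs must cover the same samples; they are aligned by id.
    """
    if set(scores_a.index) != set(scores_b.index):
        raise ValueError("composite inputs cover different samples")
    b = scores_b.reindex(scores_a.index)
    raw = (np.asarray(scores_a, dtype=float) + np.asarray(b, dtype=float)) / 2.0
    return pd.Series(
        _standardize(raw, "composite scores"), index=scores_a.index, name="g"
    )
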