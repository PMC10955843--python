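"""Semantic measures of mental health and covariate-controlled age correlations.

A semantic measure of a construct (depression, anxiety, harmony,
satisfaction) is the cross-validated out-of-fold prediction of the
construct's rating scale from the All-texts semantic representation.
The measure is correlated with age directly and again with the
corresponding rating scale partialled out (first-order partial
correlation); a surviving partial correlation indicates that the words
carry age-related mental-health information beyond the scale itself.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import ALL_TEXTS, CohortTable
from .prediction import CVResult, bonferroni, cross_validate
from .semantic_space import encode_response

CONSTRUCT_SCALE = {
    "depression": "phq9",
    "anxiety": "gad7",
    "harmony": "hils",
    "satisfaction": "swls",
}


@dataclass
class SemanticMeasure:
    construct: str
    scale: str
    values: pd.Series  # participant id -> out-of-fold prediction
    cv: CVResult = field(repr=False, default=None)


def build_semantic_measure(
    cohort: CohortTable,
    space,
    construct: str,
    seed: int = 0,
    outer_folds: int = 10,
    grid: Sequence[int] | None = None,
) -> SemanticMeasure:
    """Out-of-fold predictions of a construct's rating scale from All texts."""
    scale = CONSTRUCT_SCALE[construct]
    responses = cohort.responses_for(ALL_TEXTS)
    by_id = {r.id: r for r in cohort.records}
    ids, X, y = [], [], []
    for pid, words in responses.items():
        vec = encode_response(space, words)
        if vec.is_missing:
            continue
        ids.append(pid)
        X.append(vec.values)
        y.append(by_id[pid].scale_scores[scale])
    res = cross_validate(
        np.array(X), np.array(y, dtype=float), outer_folds=outer_folds,
        grid=grid, seed=seed, p_method="none", target_name=scale,
    )
    return SemanticMeasure(
        construct=construct, scale=scale,
        values=pd.Series(res.predictions, index=ids), cv=res,
    )


def partial_correlation(
    x: np.ndarray, y: np.ndarray, z: np.ndarray
) -> tuple[float, float]:
    """First-order partial correlation of x and y given z, with its p-value.

    Correlates the residuals of x-on-z with the residuals of y-on-z
    (intercepts included); p comes from the t transform with n - 3
    degrees of freedom.  A constant z reduces to the simple correlation
    (with a warning).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError("need n >= 4")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y)) and np.all(np.isfinite(z))):
        raise ValueError("inputs must be finite")
    if np.std(z) == 0:
        warnings.warn("covariate is constant; partial correlation reduces to simple correlation")
        r, p = stats.pearsonr(x, y)
        return float(r), float(p)

    design = np.column_stack([np.ones(n), z])
    rx = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
    ry = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
    if np.std(rx) <= 1e-10 * max(np.std(x), 1e-300) or np.std(ry) <= 1e-10 * max(np.std(y), 1e-300):
        # one variable is an (exact) linear function of z
        return 0.0, 1.0
    r = float(np.corrcoef(rx, ry)[0, 1])
    if abs(r) >= 1.0:
        return float(np.sign(r)), 0.0
    df = n - 3
    t = r * np.sqrt(df / (1.0 - r * r))
    return r, float(2.0 * stats.t.sf(abs(t), df=df))


def regression_residual_correlation(
    x: np.ndarray, y: np.ndarray, Z: np.ndarray
) -> tuple[float, float]:
    """Multi-covariate variant: residualise x and y on a covariate matrix Z.

    p-value df = n - 2 - k for k covariates.  Available as an alternative
    to the single-covariate partial correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if Z.shape[0] != len(x):
        Z = Z.T
    n, k = Z.shape
    design = np.column_stack([np.ones(n), Z])
    rx = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
    ry = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
    if np.std(rx) == 0 or np.std(ry) == 0:
        return 0.0, 1.0
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 2 - k
    if abs(r) >= 1.0:
        return float(np.sign(r)), 0.0
    t = r * np.sqrt(df / (1.0 - r * r))
    return r, float(2.0 * stats.t.sf(abs(t), df=df))


def age_correlation_table(
    cohort: CohortTable,
    measures: Sequence[SemanticMeasure],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per construct: rating-scale/age r, semantic-measure/age r, and the
    semantic-measure/age correlation partialling out the rating scale.

    Bonferroni correction uses m = number of constructs (4 by default).
    """
    ages = pd.Series({r.id: r.age for r in cohort.records}, dtype=float)
    rows = []
    for m in measures:
        ids = m.values.index.intersection(ages.index)
        scale_vals = pd.Series(
            {r.id: r.scale_scores[m.scale] for r in cohort.records}, dtype=float
        ).loc[ids]
        x = m.values.loc[ids].to_numpy()
        a = ages.loc[ids].to_numpy()
        z = scale_vals.to_numpy()
        r_scale, p_scale = stats.pearsonr(z, a)
        r_meas, p_meas = stats.pearsonr(x, a)
        r_part, p_part = partial_correlation(x, a, z)
        rows.append(
            {
                "measure": m.construct,
                "n": len(ids),
                "r_scale_age": float(r_scale),
                "p_scale_age": float(p_scale),
                "r_semantic_age": float(r_meas),
                "p_semantic_age": float(p_meas),
                "r_partial": r_part,
                "p_partial": p_part,
            }
        )
    table = pd.DataFrame(rows)
    mtests = len(table)
    for col, flag_col in (
        ("p_scale_age", "sig_scale"),
        ("p_semantic_age", "sig_semantic"),
        ("p_partial", "sig_partial"),
    ):
        table[flag_col] = bonferroni(table[col].tolist(), m=mtests, alpha=alpha).flags
    return table
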