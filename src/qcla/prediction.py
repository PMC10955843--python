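"""Cross-validated multiple linear regression from semantic representations.

The model is ordinary least squares ``y = c @ x`` on the leading embedding
dimensions (SVD dimensions are variance-ordered) plus an intercept.
Performance is estimated with 10% leave-out cross-validation; the number of
dimensions entering the regression is chosen by a nested (inner) CV on each
training fold.  Reported metrics mirror the standard battery table:
Pearson r between predicted and empirical values, r^2, RMSE in target
units, a two-sided p-value for r, and the extremes of the predictions.

A note on the correlation estimate: the pooled out-of-fold Pearson r is
computed on the centered slope component of the predictions (each fold's
training-mean prediction removed).  The training-fold mean is a linear function of the
held-out fold's mean with a negative sign, so keeping the per-fold
intercepts in the pooled correlation injects a spurious negative component
under the null.  Removing them is leak-free (the slope component uses no
held-out information) and makes the analytic p-value exact for Gaussian
targets under independence.  RMSE, Min and Max are computed from the full
honest predictions, intercepts included.  Set ``debias_fold_means=False``
for the raw pooled correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05


def default_grid(d: int, n_train: int) -> list[int]:
    """Dimension grid: powers of two up to 512, capped at min(d, n_train/2)."""
    cap = min(d, max(1, n_train // 2), 512)
    grid = [g for g in (2, 4, 8, 16, 32, 64, 128, 256, 512) if g <= cap]
    return grid or [min(d, cap)]


@dataclass
class PredictionModel:
    coefficients: np.ndarray  # intercept first, then n_dims_used slopes
    n_dims_used: int
    target_name: str = "age"
    training_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.n_dims_used < 1:
            raise ValueError("n_dims_used must be >= 1")
        if not np.all(np.isfinite(self.coefficients)):
            raise ValueError("coefficients must be finite")

    @property
    def intercept(self) -> float:
        return float(self.coefficients[0])

    @property
    def slopes(self) -> np.ndarray:
        return self.coefficients[1:]

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return self.intercept + X[:, : self.n_dims_used] @ self.slopes


def fit_linear_model(
    X: np.ndarray, y: np.ndarray, n_dims: int, target_name: str = "age"
) -> PredictionModel:
    """OLS on the first ``n_dims`` dimensions plus an intercept.

    Rank-deficient designs fall back to a minimal L2 penalty
    (1e-8, scaled to the design) so degenerate inputs cannot crash a
    battery run; the fallback is logged.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    n, d = X.shape
    if n_dims > d:
        raise ValueError(f"n_dims={n_dims} exceeds representation dimensionality {d}")
    if y.shape != (n,):
        raise ValueError("y length must match X rows")
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("missing values in X or y")
    if n <= n_dims + 1:
        raise ValueError(f"need n > n_dims + 1 (n={n}, n_dims={n_dims})")

    design = np.column_stack([np.ones(n), X[:, :n_dims]])
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    ridge_used = False
    if rank < design.shape[1]:
        gram = design.T @ design
        lam = 1e-8 * np.trace(gram) / design.shape[1]
        coef = np.linalg.solve(gram + lam * np.eye(design.shape[1]), design.T @ y)
        ridge_used = True
        logger.warning("rank-deficient design (rank %d < %d); ridge fallback used", rank, design.shape[1])
    return PredictionModel(
        coefficients=coef,
        n_dims_used=n_dims,
        target_name=target_name,
        training_meta={"n_train": n, "ridge_fallback": ridge_used},
    )


def _fold_assignments(n: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """Random unstratified assignment of n items to k folds of near-equal size."""
    order = rng.permutation(n)
    folds = np.empty(n, dtype=int)
    for j, chunk in enumerate(np.array_split(order, k)):
        folds[chunk] = j
    return folds


def _slope_r(pred_slope: np.ndarray, y: np.ndarray) -> float:
    if np.std(pred_slope) == 0 or np.std(y) == 0:
        return 0.0
    return float(np.corrcoef(pred_slope, y)[0, 1])


def select_dimensions(
    X: np.ndarray,
    y: np.ndarray,
    grid: Sequence[int],
    inner_folds: int = 5,
    rng: np.random.Generator | None = None,
) -> int:
    """Pick the grid value maximising inner-CV Pearson r; ties -> smallest.

    Intended to be run on a training fold only (the caller guarantees the
    held-out data never enters).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, d = X.shape
    grid = sorted({g for g in grid if 1 <= g <= d})
    if not grid:
        raise ValueError("empty dimension grid after bounds filtering")
    if len(grid) == 1:
        return grid[0]
    rng = rng or np.random.default_rng(0)
    folds = _fold_assignments(n, min(inner_folds, n), rng)

    best_g, best_r = None, -np.inf
    for g in grid:
        preds = np.full(n, np.nan)
        ok = True
        for j in np.unique(folds):
            test = folds == j
            train = ~test
            if train.sum() <= g + 1:
                ok = False
                break
            model = fit_linear_model(X[train], y[train], g)
            # centered slope component only; see module docstring
            preds[test] = model.predict(X[test]) - y[train].mean()
        if not ok:
            continue
        r = _slope_r(preds, y)
        if r > best_r + 1e-12:
            best_g, best_r = g, r
    if best_g is None:
        raise ValueError("all inner fits failed (training folds too small for the grid)")
    return best_g


@dataclass
class CVResult:
    """Cross-validated prediction outcome (one battery-table row)."""

    predictions: np.ndarray
    r: float
    r2: float
    rmse: float
    p: float
    min_pred: float
    max_pred: float
    n: int
    fold_assignments: np.ndarray = field(default=None, repr=False)
    dims_per_fold: list[int] = field(default_factory=list, repr=False)
    target_name: str = "age"


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    outer_folds: int = 10,
    grid: Sequence[int] | None = None,
    seed: int | np.random.Generator = 0,
    inner_folds: int = 5,
    debias_fold_means: bool = True,
    p_method: str = "permutation",
    n_permutations: int = 199,
    target_name: str = "age",
) -> CVResult:
    """10% leave-out cross-validation with nested dimension selection.

    Every participant is predicted exactly once by a model trained without
    them; dimension selection is re-run inside each training fold.
    Metrics are assembled over the pooled out-of-fold predictions.

    ``p_method`` selects how the p-value for the pooled correlation is
    obtained.  The default ``"permutation"`` refits the fold models under
    permutations of the target (fold assignments and selected dimensions
    held fixed), which respects the dependence that cross-validation
    induces between folds; the pooled null correlation is overdispersed
    relative to an ordinary sample correlation (fold models share
    training data), so the ``"analytic"`` t transform understates p and
    is provided for comparison only.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, d = X.shape
    if n < outer_folds:
        raise ValueError(f"n={n} smaller than outer_folds={outer_folds}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    folds = _fold_assignments(n, outer_folds, rng)
    if grid is None:
        # keep the default grid within the numerical rank of the
        # representation (sparse single-question encodings are often
        # far from full column rank)
        d = min(d, int(np.linalg.matrix_rank(X)))

    preds = np.full(n, np.nan)
    preds_slope = np.full(n, np.nan)
    dims_used: list[int] = []
    for j in range(outer_folds):
        test = folds == j
        train = ~test
        y_train = y[train]
        if len(np.unique(y_train)) < 2:
            raise ValueError(f"training fold {j} has < 2 distinct target values")
        fold_grid = grid if grid is not None else default_grid(d, int(train.sum()))
        g = select_dimensions(X[train], y_train, fold_grid, inner_folds=inner_folds, rng=rng)
        model = fit_linear_model(X[train], y_train, g, target_name=target_name)
        full = model.predict(X[test])
        preds[test] = full
        # OLS passes through the training means, so subtracting the training
        # mean of y leaves exactly the centered slope component
        preds_slope[test] = full - y_train.mean()
        dims_used.append(g)

    assert not np.isnan(preds).any()
    r = _slope_r(preds_slope if debias_fold_means else preds, y)
    rmse = float(np.sqrt(np.mean((preds - y) ** 2)))
    if p_method == "permutation":
        p = _cv_permutation_p(X, y, folds, dims_used, r, n_permutations, rng)
    elif p_method == "analytic":
        p = pvalue_for_r(r, n)
    elif p_method == "none":
        p = np.nan
    else:
        raise ValueError(f"unknown p_method {p_method!r}")
    return CVResult(
        predictions=preds,
        r=r,
        r2=r * r,
        rmse=rmse,
        p=p,
        min_pred=float(preds.min()),
        max_pred=float(preds.max()),
        n=n,
        fold_assignments=folds,
        dims_per_fold=dims_used,
        target_name=target_name,
    )


def _cv_permutation_p(
    X: np.ndarray,
    y: np.ndarray,
    folds: np.ndarray,
    dims_per_fold: Sequence[int],
    r_obs: float,
    n_permutations: int,
    rng: np.random.Generator,
) -> float:
    """Permutation p for the pooled out-of-fold correlation.

    For each permutation of y the per-fold OLS models are refit (via
    cached training pseudoinverses) and the pooled debiased correlation
    recomputed, reproducing the between-fold dependence of the observed
    statistic.  Fold assignments and per-fold dimensionalities are held
    fixed.  Two-sided; add-one smoothed.
    """
    caches = []
    for j, g in zip(np.unique(folds), dims_per_fold):
        test = folds == j
        train = ~test
        d_train = np.column_stack([np.ones(train.sum()), X[train, :g]])
        d_test = np.column_stack([np.ones(test.sum()), X[test, :g]])
        caches.append((train, test, np.linalg.pinv(d_train), d_test))
    n = len(y)
    hits = 0
    for _ in range(n_permutations):
        yp = y[rng.permutation(n)]
        preds = np.empty(n)
        for train, test, pinv, d_test in caches:
            yt = yp[train]
            preds[test] = d_test @ (pinv @ yt) - yt.mean()
        if abs(_slope_r(preds, yp)) >= abs(r_obs) - 1e-12:
            hits += 1
    return (hits + 1) / (n_permutations + 1)


def pvalue_for_r(r: float, n: int) -> float:
    """Two-sided p for a Pearson correlation under the true-r-of-zero null.

    Uses the t transform ``t = r * sqrt((n - 2) / (1 - r^2))`` with n - 2
    degrees of freedom; |r| = 1 returns the p -> 0 limit.
    """
    if n < 3:
        raise ValueError("need n >= 3")
    if not np.isfinite(r):
        return np.nan
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def permutation_pvalue(
    pred: np.ndarray, y: np.ndarray, n_permutations: int = 10_000, seed: int = 0
) -> float:
    """Permutation alternative to the analytic transform (two-sided)."""
    rng = np.random.default_rng(seed)
    pred = np.asarray(pred, dtype=float)
    y = np.asarray(y, dtype=float)
    obs = abs(_slope_r(pred, y))
    hits = 0
    for _ in range(n_permutations):
        hits += abs(_slope_r(pred, rng.permutation(y))) >= obs
    return (hits + 1) / (n_permutations + 1)


@dataclass
class MultipleTestReport:
    raw_p: list[float]
    m: int
    alpha: float
    flags: list[str]  # "significant_corrected" | "significant_uncorrected" | "ns"

    def n_corrected(self) -> int:
        return sum(f == "significant_corrected" for f in self.flags)

    def n_uncorrected(self) -> int:
        return sum(f != "ns" for f in self.flags)


def bonferroni(raw_p: Sequence[float], m: int | None = None, alpha: float = DEFAULT_ALPHA) -> MultipleTestReport:
    """Tier p-values: corrected-significant (p <= alpha/m), uncorrected (p <= alpha), ns."""
    raw_p = [float(p) for p in raw_p]
    if any((p < 0 or p > 1) and np.isfinite(p) for p in raw_p):
        raise ValueError("p-values must lie in [0, 1]")
    m = m if m is not None else len(raw_p)
    if m < 1:
        raise ValueError("m must be >= 1")
    flags = []
    for p in raw_p:
        if not np.isfinite(p):
            flags.append("ns")
        elif p <= alpha / m:
            flags.append("significant_corrected")
        elif p <= alpha:
            flags.append("significant_uncorrected")
        else:
            flags.append("ns")
    return MultipleTestReport(raw_p=raw_p, m=m, alpha=alpha, flags=flags)


def run_question_battery(
    cohort,
    space,
    target: str = "age",
    inventory=None,
    outer_folds: int = 10,
    grid: Sequence[int] | None = None,
    seed: int = 0,
    min_participants: int = 50,
    alpha: float = DEFAULT_ALPHA,
    n_permutations: int = 1999,
):
    """One cross-validated model per question variable plus All texts.

    Returns ``(table, report, results)`` where ``table`` is a DataFrame
    with the battery columns (label, n, r, p, r2, rmse, min_pred,
    max_pred, significance), ``report`` the Bonferroni tiering with m =
    number of variables actually tested, and ``results`` the per-label
    :class:`CVResult` objects.
    """
    import pandas as pd

    from .cohort import ALL_TEXTS
    from .semantic_space import encode_response

    inventory = inventory or cohort.inventory
    rng = np.random.default_rng(seed)
    rows = []
    results: dict[str, CVResult] = {}
    for label in (ALL_TEXTS,) + tuple(inventory.labels):
        responses = cohort.responses_for(label)
        encoded = {}
        for pid, words in responses.items():
            vec = encode_response(space, words)
            if not vec.is_missing:
                encoded[pid] = vec.values
        if len(encoded) < min_participants:
            logger.warning("question %r skipped: only %d usable participants", label, len(encoded))
            continue
        ids = [r.id for r in cohort.records if r.id in encoded]
        X = np.array([encoded[i] for i in ids])
        by_id = {r.id: r for r in cohort.records}
        if target == "age":
            yv = np.array([by_id[i].age for i in ids], dtype=float)
        else:
            yv = np.array([by_id[i].scale_scores[target] for i in ids], dtype=float)
        res = cross_validate(
            X, yv, outer_folds=outer_folds, grid=grid, seed=rng,
            n_permutations=n_permutations, target_name=target,
        )
        results[label] = res
        rows.append(
            {
                "label": label,
                "n": res.n,
                "r": res.r,
                "p": res.p,
                "r2": res.r2,
                "rmse": res.rmse,
                "min_pred": res.min_pred,
                "max_pred": res.max_pred,
            }
        )
    if not rows:
        raise ValueError("no question variable had enough participants")
    table = pd.DataFrame(rows)
    report = bonferroni(table["p"].tolist(), m=len(table), alpha=alpha)
    table["significance"] = report.flags
    return table, report, results
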