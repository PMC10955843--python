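"""Young/old model-transfer experiment and its repeated-measures analysis.

For each of the 17 question variables (16 questions plus All texts) and
each of the four rating scales (PHQ-9, GAD-7, HILS, SWLS) a prediction
model is trained within the young half, within the old half, and across
halves, giving a 2 (train group) x 2 (test group) grid of 68 per-model
performances (Pearson r and MSE).  Same-group cells use 10-fold
cross-validation inside the group (resubstitution would overstate them);
opposite-group cells train on the full other group and test on the full
target group.  The 68 performances are then analysed as subjects in a
2x2 within-subject ANOVA with factors age (test group: young vs old) and
testing-training (same vs opposite data).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import ALL_TEXTS, AgeSplit, CohortTable
from .prediction import cross_validate, default_grid, fit_linear_model, select_dimensions
from .semantic_space import encode_response

logger = logging.getLogger(__name__)

GROUPS = ("young", "old")
CONDITIONS = ("same", "opposite")


@dataclass
class TransferResult:
    """Long-format table: train_group, test_group, question, scale, r, mse."""

    table: pd.DataFrame
    dropped_keys: list[tuple[str, str]] = field(default_factory=list)

    def model_keys(self) -> list[tuple[str, str]]:
        return sorted(set(zip(self.table["question"], self.table["scale"])))

    def cell(self, train_group: str, test_group: str) -> pd.DataFrame:
        t = self.table
        return t[(t["train_group"] == train_group) & (t["test_group"] == test_group)]

    def wide(self, response: str = "r") -> pd.DataFrame:
        """model_key x (age, condition) matrix for the within-subject ANOVA."""
        t = self.table.copy()
        t["age"] = t["test_group"]
        t["condition"] = np.where(t["train_group"] == t["test_group"], "same", "opposite")
        return t.pivot_table(
            index=["question", "scale"], columns=["age", "condition"], values=response
        )

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _encode_group(cohort: CohortTable, space, label: str, ids: Sequence[str]):
    """Encode one question variable for one group; returns (X, kept ids)."""
    responses = cohort.responses_for(label)
    X, kept = [], []
    for pid in ids:
        words = responses.get(pid)
        if not words:
            continue
        vec = encode_response(space, words)
        if vec.is_missing:
            continue
        X.append(vec.values)
        kept.append(pid)
    if not X:
        return np.empty((0, space.dimensionality)), []
    return np.array(X), kept


def _plain_r(pred: np.ndarray, y: np.ndarray) -> float:
    if np.std(pred) == 0 or np.std(y) == 0:
        return 0.0
    return float(np.corrcoef(pred, y)[0, 1])


def run_transfer(
    cohort: CohortTable,
    space,
    split: AgeSplit,
    scales: Sequence[str] = ("phq9", "gad7", "hils", "swls"),
    inventory=None,
    seed: int = 0,
    outer_folds: int = 10,
    grid: Sequence[int] | None = None,
    min_group: int = 30,
) -> TransferResult:
    """Fill the 2x2 transfer grid of per-(question, scale) model performances.

    A model key that cannot be estimated in some cell (too few usable
    participants in a group) is dropped from ALL four cells so the
    repeated-measures design stays balanced; drops are logged.
    """
    inventory = inventory or cohort.inventory
    rng = np.random.default_rng(seed)
    ids_by_group = {"young": split.young_ids, "old": split.old_ids}
    labels = (ALL_TEXTS,) + tuple(inventory.labels)

    by_id = {r.id: r for r in cohort.records}
    rows = []
    dropped: list[tuple[str, str]] = []
    for label in labels:
        encoded = {g: _encode_group(cohort, space, label, ids_by_group[g]) for g in GROUPS}
        data = {
            g: {
                s: (encoded[g][0], np.array([by_id[p].scale_scores[s] for p in encoded[g][1]]))
                for s in scales
            }
            for g in GROUPS
        }
        for scale in scales:
            if any(len(data[g][scale][1]) < min_group for g in GROUPS):
                dropped.append((label, scale))
                logger.warning("model key (%s, %s) dropped: group below %d", label, scale, min_group)
                continue
            key_rows = []
            try:
                for g in GROUPS:
                    Xg, yg = data[g][scale]
                    # same-group: cross-validated inside the group
                    res = cross_validate(
                        Xg, yg, outer_folds=min(outer_folds, len(yg)), grid=grid,
                        seed=rng, p_method="none", target_name=scale,
                    )
                    key_rows.append(
                        dict(train_group=g, test_group=g, question=label, scale=scale,
                             r=res.r, mse=res.rmse**2)
                    )
                    # opposite-group: full train on g, full test on the other
                    other = GROUPS[1 - GROUPS.index(g)]
                    Xo, yo = data[other][scale]
                    fold_grid = grid if grid is not None else default_grid(
                        min(Xg.shape[1], int(np.linalg.matrix_rank(Xg))), len(yg)
                    )
                    gdim = select_dimensions(Xg, yg, fold_grid, rng=rng)
                    model = fit_linear_model(Xg, yg, gdim, target_name=scale)
                    pred = model.predict(Xo)
                    key_rows.append(
                        dict(train_group=g, test_group=other, question=label, scale=scale,
                             r=_plain_r(pred, yo), mse=float(np.mean((pred - yo) ** 2)))
                    )
            except ValueError as exc:
                dropped.append((label, scale))
                logger.warning("model key (%s, %s) dropped: %s", label, scale, exc)
                continue
            rows.extend(key_rows)
    if not rows:
        raise ValueError("no model key could be estimated in all four cells")
    return TransferResult(table=pd.DataFrame(rows), dropped_keys=dropped)


@dataclass
class AnovaResult:
    """Two-way within-subject ANOVA over the transfer grid.

    Effects: ``age`` (test group), ``condition`` (same vs opposite
    training data) and their interaction, each tested against its own
    effect-by-subject error term with df (1, n_subjects - 1).
    """

    response: str
    n_subjects: int
    effects: pd.DataFrame  # index: age, condition, age:condition; cols: SS, df, SS_error, df_error, F, p
    ss_subjects: float
    ss_total: float

    def F(self, effect: str) -> float:
        return float(self.effects.loc[effect, "F"])

    def p(self, effect: str) -> float:
        return float(self.effects.loc[effect, "p"])


def repeated_anova_2x2(
    result: TransferResult | pd.DataFrame,
    response: str = "r",
    fisher_z: bool = False,
) -> AnovaResult:
    """2x2 within-subject ANOVA on the per-model performances.

    ``result`` may be a :class:`TransferResult` or an already-pivoted
    wide table (subjects x 4 cells with a 2-level MultiIndex).  The design
    must be balanced: every subject observed in all four cells.
    ``fisher_z`` applies the arctanh transform to correlations first.
    """
    wide = result.wide(response) if isinstance(result, TransferResult) else result
    if wide.isna().any().any() or wide.shape[1] != 4:
        raise ValueError("unbalanced design: every model key needs all four cells")
    y = wide.to_numpy(dtype=float)
    if fisher_z:
        y = np.arctanh(np.clip(y, -0.999999, 0.999999))
    n = y.shape[0]
    if n < 2:
        raise ValueError("need at least two subjects")

    cols = list(wide.columns)  # MultiIndex (age, condition)
    a_levels = sorted({c[0] for c in cols})
    b_levels = sorted({c[1] for c in cols})
    # reshape to (subject, a, b)
    cube = np.empty((n, 2, 2))
    for i, a in enumerate(a_levels):
        for j, b in enumerate(b_levels):
            cube[:, i, j] = y[:, cols.index((a, b))]

    grand = cube.mean()
    subj = cube.mean(axis=(1, 2))
    a_mean = cube.mean(axis=(0, 2))
    b_mean = cube.mean(axis=(0, 1))
    ab_mean = cube.mean(axis=0)

    ss_subj = 4 * np.sum((subj - grand) ** 2)
    ss_a = 2 * n * np.sum((a_mean - grand) ** 2)
    ss_b = 2 * n * np.sum((b_mean - grand) ** 2)
    ss_ab = n * np.sum((ab_mean - a_mean[:, None] - b_mean[None, :] + grand) ** 2)

    sa_mean = cube.mean(axis=2)  # subject x a
    sb_mean = cube.mean(axis=1)  # subject x b
    ss_a_err = 2 * np.sum((sa_mean - subj[:, None] - a_mean[None, :] + grand) ** 2)
    ss_b_err = 2 * np.sum((sb_mean - subj[:, None] - b_mean[None, :] + grand) ** 2)
    ss_total = np.sum((cube - grand) ** 2)
    resid = (
        cube
        - sa_mean[:, :, None]
        - sb_mean[:, None, :]
        - ab_mean[None, :, :]
        + subj[:, None, None]
        + a_mean[None, :, None]
        + b_mean[None, None, :]
        - grand
    )
    ss_ab_err = np.sum(resid**2)

    df_err = n - 1
    # sums of squares at round-off scale are noise, not effects
    tiny = 1e-12 * max(ss_total, 1.0)
    rows = {}
    for name, ss_eff, ss_err in (
        ("age", ss_a, ss_a_err),
        ("condition", ss_b, ss_b_err),
        ("age:condition", ss_ab, ss_ab_err),
    ):
        ms_eff = 0.0 if ss_eff < tiny else ss_eff / 1
        ms_err = (0.0 if ss_err < tiny else ss_err) / df_err
        if ms_err == 0:
            F = np.inf if ms_eff > 0 else 0.0
        else:
            F = ms_eff / ms_err
        p = 1.0 if F == 0 else float(stats.f.sf(F, 1, df_err))
        rows[name] = dict(SS=ss_eff, df=1, SS_error=ss_err, df_error=df_err, F=F, p=p)
    effects = pd.DataFrame.from_dict(rows, orient="index")
    return AnovaResult(
        response=response, n_subjects=n, effects=effects,
        ss_subjects=float(ss_subj), ss_total=float(ss_total),
    )


def summarize_fig3(result: TransferResult) -> pd.DataFrame:
    """Per-cell means of r and MSE with subject-level dispersion.

    Rows are the four (test group, condition) cells; columns give the
    mean, SD and SEM over the per-model performances.
    """
    t = result.table.copy()
    t["age"] = t["test_group"]
    t["condition"] = np.where(t["train_group"] == t["test_group"], "same", "opposite")
    out = t.groupby(["age", "condition"]).agg(
        mean_r=("r", "mean"), sd_r=("r", "std"),
        mean_mse=("mse", "mean"), sd_mse=("mse", "std"),
        n_models=("r", "size"),
    )
    out["sem_r"] = out["sd_r"] / np.sqrt(out["n_models"])
    out["sem_mse"] = out["sd_mse"] / np.sqrt(out["n_models"])
    return out.reset_index()
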