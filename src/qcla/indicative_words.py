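"""Words statistically indicative of participant groups.

Each candidate word splits the cohort into users and non-users; a Welch
two-sample t-test compares a numeric target (age, or a rating-scale
total, or a group-membership indicator) between the two. Significant
words, sized by their corpus frequency and coloured by their p-value,
form word-cloud data for either side of the contrast.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import ALL_TEXTS, AgeSplit, CohortTable
from .prediction import bonferroni

logger = logging.getLogger(__name__)

MIN_USERS_DEFAULT = 5
TOP_N_DEFAULT = 100


@dataclass
class WordStat:
    word: str
    n_users: int
    t: float
    p: float
    direction: str  # label of the group the word leans toward
    frequency: int  # token count in the dataset


@dataclass
class WordCloudData:
    """Up to ``top_n`` entries per direction; size = frequency, colour = p."""

    direction: str
    entries: pd.DataFrame  # columns: word, size_weight, color_weight, p, t, n_users
    correction: bool
    m: int

    def words(self) -> list[str]:
        return self.entries["word"].tolist()

    def to_csv(self, path) -> None:
        self.entries.assign(direction=self.direction).to_csv(path, index=False)


def _word_usage(cohort: CohortTable, label: str = ALL_TEXTS):
    """Per-participant word sets and dataset token counts."""
    responses = cohort.responses_for(label)
    usage = {pid: set(words) for pid, words in responses.items()}
    freq = Counter(w for words in responses.values() for w in words)
    return usage, freq


def word_group_ttest(
    values_users: np.ndarray,
    values_nonusers: np.ndarray,
    word: str,
    frequency: int,
    labels: tuple[str, str] = ("high", "low"),
    min_users: int = MIN_USERS_DEFAULT,
) -> WordStat | None:
    """Welch t comparing the target between users and non-users of a word.

    Returns ``None`` (and the caller records the skip) when either side is
    smaller than ``min_users``.  ``labels`` names the (positive, negative)
    directions of the mean difference.
    """
    values_users = np.asarray(values_users, dtype=float)
    values_nonusers = np.asarray(values_nonusers, dtype=float)
    if len(values_users) < min_users or len(values_nonusers) < min_users:
        return None
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat, p = stats.ttest_ind(values_users, values_nonusers, equal_var=False)
    if not np.isfinite(t_stat):
        # degenerate (e.g. both sides constant at the same value)
        t_stat, p = 0.0, 1.0
    direction = labels[0] if t_stat > 0 else labels[1]
    return WordStat(
        word=word,
        n_users=len(values_users),
        t=float(t_stat),
        p=float(p),
        direction=direction,
        frequency=frequency,
    )


def compute_word_stats(
    cohort: CohortTable,
    target: Mapping[str, float],
    labels: tuple[str, str],
    min_users: int = MIN_USERS_DEFAULT,
    label: str = ALL_TEXTS,
) -> tuple[list[WordStat], list[str]]:
    """t statistics for every dataset word meeting the user threshold.

    ``target`` maps participant id -> numeric value.  Returns the stats
    and the list of words skipped for falling below ``min_users``.
    """
    usage, freq = _word_usage(cohort, label)
    ids = [pid for pid in usage if pid in target]
    vals = {pid: float(target[pid]) for pid in ids}
    stats_out: list[WordStat] = []
    skipped: list[str] = []
    for word in sorted(freq):
        users = np.array([vals[p] for p in ids if word in usage[p]])
        nonusers = np.array([vals[p] for p in ids if word not in usage[p]])
        st = word_group_ttest(users, nonusers, word, freq[word], labels, min_users)
        if st is None:
            skipped.append(word)
        else:
            stats_out.append(st)
    if skipped:
        logger.info("%d words below the %d-user threshold", len(skipped), min_users)
    return stats_out, skipped


def _build_clouds(
    word_stats: Sequence[WordStat],
    labels: tuple[str, str],
    correction: bool,
    top_n: int,
    alpha: float = 0.05,
) -> dict[str, WordCloudData]:
    m = len(word_stats)
    report = bonferroni([s.p for s in word_stats], m=max(m, 1), alpha=alpha)
    clouds = {}
    for lab in labels:
        side = [
            s
            for s, flag in zip(word_stats, report.flags)
            if s.direction == lab
            and (flag == "significant_corrected" if correction else s.p <= alpha)
        ]
        side.sort(key=lambda s: (s.p, -abs(s.t), s.word))
        side = side[:top_n]
        if not side:
            warnings.warn(f"no significant words for direction {lab!r}; empty cloud")
        entries = pd.DataFrame(
            {
                "word": [s.word for s in side],
                "size_weight": [s.frequency for s in side],
                "color_weight": [s.p for s in side],
                "p": [s.p for s in side],
                "t": [s.t for s in side],
                "n_users": [s.n_users for s in side],
            }
        )
        clouds[lab] = WordCloudData(direction=lab, entries=entries, correction=correction, m=m)
    return clouds


def indicative_cloud(
    cohort: CohortTable,
    target: Mapping[str, float] | None = None,
    split: AgeSplit | None = None,
    labels: tuple[str, str] = ("old", "young"),
    correction: bool = True,
    top_n: int = TOP_N_DEFAULT,
    min_users: int = MIN_USERS_DEFAULT,
    alpha: float = 0.05,
) -> dict[str, WordCloudData]:
    """Word clouds for the two sides of a numeric contrast (default: age).

    ``target`` defaults to participant age.  ``labels`` names the
    (positive-t, negative-t) directions.  With ``correction`` only
    Bonferroni-corrected-significant words enter a cloud; each direction
    keeps its ``top_n`` most indicative words.
    """
    if target is None:
        target = {r.id: r.age for r in cohort.records}
    word_stats, _ = compute_word_stats(cohort, target, labels, min_users)
    return _build_clouds(word_stats, labels, correction, top_n, alpha)


def crossed_cloud(
    cohort: CohortTable,
    axis1: AgeSplit,
    axis2_high_ids: Sequence[str],
    axis1_labels: tuple[str, str] = ("young", "old"),
    axis2_labels: tuple[str, str] = ("high", "low"),
    correction: bool = True,
    top_n: int = TOP_N_DEFAULT,
    min_users: int = MIN_USERS_DEFAULT,
    min_cell: int = 10,
    alpha: float = 0.05,
) -> dict[tuple[str, str], WordCloudData]:
    """2x2 grid of clouds: age split crossed with a scale median split.

    Each cell's cloud contrasts membership in that cell against the rest
    of the cohort (user-vs-non-user t-test on the membership indicator,
    keeping words leaning toward the cell).  Cells below ``min_cell``
    participants are suppressed with a warning.
    """
    high = set(axis2_high_ids)
    cells = {
        (axis1_labels[0], axis2_labels[0]): set(axis1.young_ids) & high,
        (axis1_labels[0], axis2_labels[1]): set(axis1.young_ids) - high,
        (axis1_labels[1], axis2_labels[0]): set(axis1.old_ids) & high,
        (axis1_labels[1], axis2_labels[1]): set(axis1.old_ids) - high,
    }
    out: dict[tuple[str, str], WordCloudData] = {}
    for key, members in cells.items():
        if len(members) < min_cell:
            warnings.warn(f"cell {key} has only {len(members)} participants; cloud suppressed")
            continue
        indicator = {r.id: float(r.id in members) for r in cohort.records}
        word_stats, _ = compute_word_stats(cohort, indicator, ("in_cell", "rest"), min_users)
        clouds = _build_clouds(word_stats, ("in_cell", "rest"), correction, top_n, alpha)
        cloud = clouds["in_cell"]
        cloud.direction = f"{key[0]}/{key[1]}"
        out[key] = cloud
    return out


def reference_contrast_cloud(
    cohort: CohortTable,
    reference_freq: Mapping[str, float],
    top_n: int = TOP_N_DEFAULT,
    alpha: float = 0.05,
    correction: bool = True,
) -> WordCloudData:
    """Words over-represented in the dataset relative to a reference corpus.

    Scores each word by a smoothed log-odds ratio (add-one smoothing, so
    words absent from the reference stay finite) and screens with a
    two-proportion z-test against the reference share.  The reference
    pseudo-total is set to the dataset token total.
    """
    _, freq = _word_usage(cohort)
    n_tokens = sum(freq.values())
    if n_tokens == 0:
        raise ValueError("cohort contains no words")
    ref_total = n_tokens
    v = len(freq)
    rows = []
    for word, c in freq.items():
        ref_c = reference_freq.get(word, 0.0) * ref_total
        share = (c + 1) / (n_tokens + v)
        ref_share = (ref_c + 1) / (ref_total + v)
        log_odds = np.log(share / (1 - share)) - np.log(ref_share / (1 - ref_share))
        # two-proportion z on raw shares
        p_pool = (c + ref_c) / (n_tokens + ref_total)
        se = np.sqrt(p_pool * (1 - p_pool) * (1 / n_tokens + 1 / ref_total))
        z = 0.0 if se == 0 else (c / n_tokens - ref_c / ref_total) / se
        p = float(2 * stats.norm.sf(abs(z)))
        rows.append((word, c, log_odds, z, p))
    df = pd.DataFrame(rows, columns=["word", "frequency", "log_odds", "z", "p"])
    m = len(df)
    thr = alpha / m if correction else alpha
    df = df[(df["log_odds"] > 0) & (df["p"] <= thr)]
    df = df.sort_values(["log_odds", "word"], ascending=[False, True]).head(top_n)
    entries = pd.DataFrame(
        {
            "word": df["word"].values,
            "size_weight": df["frequency"].values,
            "color_weight": df["p"].values,
            "p": df["p"].values,
            "t": df["z"].values,
            "n_users": df["frequency"].values,
        }
    )
    if entries.empty:
        warnings.warn("no words over-represented relative to the reference; empty cloud")
    return WordCloudData(direction="dataset", entries=entries, correction=correction, m=m)


def model_scored_words(
    space, model, words: Sequence[str], top_n: int = TOP_N_DEFAULT
) -> pd.DataFrame:
    """Alternative indicativeness mode: score single words through a trained model.

    Each word's embedding is pushed through the regression model fitted on
    the All-texts representation, giving a predicted target value per word;
    words are ranked by that prediction.  Provided as a secondary reading
    of per-word indicativeness; the user-vs-non-user t-test is the default.
    """
    from .semantic_space import encode_response

    rows = []
    for w in words:
        vec = encode_response(space, [w])
        if vec.is_missing:
            continue
        rows.append((w, float(model.predict(vec.values[None, :])[0])))
    df = pd.DataFrame(rows, columns=["word", "predicted"])
    return df.sort_values("predicted", ascending=False).head(top_n).reset_index(drop=True)
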