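"""Participant cohort handling.

A cohort is one row per participant: age, gender, rating-scale totals
(PHQ-9 depression, GAD-7 anxiety, HILS harmony in life, SWLS satisfaction
with life), a control-item pass flag, and word responses to up to 16
open-ended questions.  This module loads and validates the table, applies
the control-question exclusion, concatenates responses into the derived
"All texts" variable, median-splits by age and computes descriptive
corpus statistics.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: instrument score ranges
SCALE_RANGES: dict[str, tuple[int, int]] = {
    "phq9": (0, 27),
    "gad7": (0, 21),
    "hils": (5, 35),
    "swls": (5, 35),
}

SCALES = tuple(SCALE_RANGES)

ALL_TEXTS = "all_texts"


@dataclass(frozen=True)
class QuestionInventory:
    """The 16 open-ended question variables plus the derived All-texts one.

    Word budgets: five words for the three mental-health questions, three
    for the three reason questions, three for the two positive-psychology
    questions and two for each of the eight symptom questions (46 word
    boxes in total).
    """

    labels: tuple[str, ...]
    words_requested: Mapping[str, int]

    def __post_init__(self) -> None:
        if set(self.labels) != set(self.words_requested):
            raise ValueError("labels and words_requested must cover the same questions")

    @property
    def max_words(self) -> int:
        return sum(self.words_requested.values())

    @property
    def all_labels(self) -> tuple[str, ...]:
        """Base labels plus the derived All-texts variable."""
        return self.labels + (ALL_TEXTS,)


def default_inventory() -> QuestionInventory:
    words = {
        # mental-health questions: five words each
        "general": 5,
        "depression": 5,
        "worry": 5,
        # reason questions: three words each
        "general_reason": 3,
        "depression_reason": 3,
        "worry_reason": 3,
        # positive psychology: three words each
        "satisfaction": 3,
        "harmony": 3,
        # symptom questions: two words each
        "sleep": 2,
        "concentration": 2,
        "appetite": 2,
        "energy": 2,
        "self": 2,
        "movement": 2,
        "affect_behaviour": 2,
        "interest": 2,
    }
    return QuestionInventory(labels=tuple(words), words_requested=words)


@dataclass
class ParticipantRecord:
    id: str
    age: float
    gender: str
    scale_scores: dict[str, float]
    controls_passed: bool
    responses: dict[str, list[str]]

    def n_words(self) -> int:
        return sum(len(v) for v in self.responses.values())


@dataclass
class CohortTable:
    records: list[ParticipantRecord]
    inventory: QuestionInventory = field(default_factory=default_inventory)
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate participant ids")

    def __len__(self) -> int:
        return len(self.records)

    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def ages(self) -> np.ndarray:
        return np.array([r.age for r in self.records], dtype=float)

    def scale(self, name: str) -> np.ndarray:
        return np.array([r.scale_scores[name] for r in self.records], dtype=float)

    def subset(self, ids: Sequence[str]) -> "CohortTable":
        wanted = set(ids)
        return CohortTable(
            [r for r in self.records if r.id in wanted],
            inventory=self.inventory,
            provenance=self.provenance + [f"subset to {len(wanted)} ids"],
        )

    def responses_for(self, label: str) -> dict[str, list[str]]:
        """id -> word list for one question variable (or All texts)."""
        if label == ALL_TEXTS:
            out = {}
            for r in self.records:
                words = concat_all_texts(r, self.inventory)
                if words is not None:
                    out[r.id] = words
            return out
        return {r.id: r.responses[label] for r in self.records if r.responses.get(label)}


@dataclass
class RejectionReport:
    rejected: list[tuple[str, str]] = field(default_factory=list)  # (id, reason)

    def add(self, pid: str, reason: str) -> None:
        self.rejected.append((pid, reason))

    def __len__(self) -> int:
        return len(self.rejected)


def _response_columns(inventory: QuestionInventory) -> list[tuple[str, str]]:
    cols = []
    for label in inventory.labels:
        for k in range(1, inventory.words_requested[label] + 1):
            cols.append((label, f"q_{label}_w{k}"))
    return cols


def load_cohort(
    path: str | Path,
    inventory: QuestionInventory | None = None,
    age_range: tuple[float, float] = (18, 70),
) -> tuple[CohortTable, RejectionReport]:
    """Read and validate a cohort CSV/TSV.

    Required columns: ``id, age, gender, phq9, gad7, hils, swls,
    controls_passed`` plus one ``q_<label>_w<k>`` column per word box.
    Rows violating range invariants are collected into the rejection
    report rather than silently dropped; duplicated ids are an error.
    """
    inventory = inventory or default_inventory()
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, dtype={"id": str}, keep_default_na=False, na_values=[""])

    required = ["id", "age", "gender", "phq9", "gad7", "hils", "swls", "controls_passed"]
    resp_cols = _response_columns(inventory)
    missing = [c for c in required if c not in df.columns]
    missing += [c for _, c in resp_cols if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    if df["id"].duplicated().any():
        dupes = df.loc[df["id"].duplicated(), "id"].tolist()
        raise ValueError(f"duplicated participant ids: {dupes}")

    records: list[ParticipantRecord] = []
    report = RejectionReport()
    for _, row in df.iterrows():
        pid = str(row["id"])
        problems = []
        age = float(row["age"])
        if not (age_range[0] <= age <= age_range[1]):
            problems.append(f"age {age} outside {age_range}")
        scores = {}
        for name, (lo, hi) in SCALE_RANGES.items():
            val = float(row[name])
            if not (lo <= val <= hi):
                problems.append(f"{name} {val} outside [{lo}, {hi}]")
            scores[name] = val
        if problems:
            report.add(pid, "; ".join(problems))
            continue
        responses: dict[str, list[str]] = {label: [] for label in inventory.labels}
        for label, col in resp_cols:
            val = row[col]
            if isinstance(val, str) and val.strip():
                responses[label].append(val.strip().lower())
        records.append(
            ParticipantRecord(
                id=pid,
                age=age,
                gender=str(row["gender"]),
                scale_scores=scores,
                controls_passed=_parse_bool(row["controls_passed"]),
                responses=responses,
            )
        )
    cohort = CohortTable(records, inventory=inventory, provenance=[f"loaded {path.name}"])
    if len(report):
        logger.warning("rejected %d rows on validation: %s", len(report), report.rejected[:5])
    return cohort, report


def _parse_bool(val: object) -> bool:
    if isinstance(val, (bool, np.bool_)):
        return bool(val)
    s = str(val).strip().lower()
    if s in ("1", "true", "yes"):
        return True
    if s in ("0", "false", "no"):
        return False
    raise ValueError(f"cannot parse boolean {val!r}")


def write_cohort(cohort: CohortTable, path: str | Path) -> None:
    """Write the CSV dialect read by :func:`load_cohort`."""
    inventory = cohort.inventory
    resp_cols = _response_columns(inventory)
    rows = []
    for r in cohort.records:
        row: dict[str, object] = {
            "id": r.id,
            "age": r.age,
            "gender": r.gender,
            "controls_passed": r.controls_passed,
        }
        row.update({k: r.scale_scores[k] for k in SCALE_RANGES})
        for label, col in resp_cols:
            words = r.responses.get(label, [])
            k = int(col.rsplit("w", 1)[1])
            row[col] = words[k - 1] if k <= len(words) else ""
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def apply_control_filter(cohort: CohortTable) -> CohortTable:
    """Drop participants who failed the control questions; log the count."""
    kept = [r for r in cohort.records if r.controls_passed]
    n_excluded = len(cohort) - len(kept)
    logger.info("control filter excluded %d of %d participants", n_excluded, len(cohort))
    return CohortTable(
        kept,
        inventory=cohort.inventory,
        provenance=cohort.provenance + [f"control filter excluded {n_excluded}"],
    )


def concat_all_texts(
    record: ParticipantRecord, inventory: QuestionInventory | None = None
) -> list[str] | None:
    """Concatenate all question responses in inventory order.

    Returns ``None`` when every response is empty (the participant is then
    excluded from All-texts analyses).
    """
    inventory = inventory or default_inventory()
    words: list[str] = []
    for label in inventory.labels:
        words.extend(record.responses.get(label, []))
    return words or None


@dataclass
class AgeSplit:
    threshold: float
    young_ids: list[str]
    old_ids: list[str]


def median_split(cohort: CohortTable, threshold: float | str = "median") -> AgeSplit:
    """Partition into young (< threshold) and old (>= threshold).

    A participant whose age equals the threshold goes to the old group.
    ``threshold="median"`` uses the sample median.
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    ages = cohort.ages()
    thr = float(np.median(ages)) if threshold == "median" else float(threshold)
    young = [r.id for r in cohort.records if r.age < thr]
    old = [r.id for r in cohort.records if r.age >= thr]
    if not young or not old:
        warnings.warn(f"degenerate age split at {thr}: {len(young)} young, {len(old)} old")
    return AgeSplit(threshold=thr, young_ids=young, old_ids=old)


def corpus_stats(
    cohort: CohortTable,
    reference_freq: Mapping[str, float] | Callable[[str], float] | None = None,
) -> dict[str, float]:
    """Descriptive word statistics over the cohort's responses.

    Reports total and unique word counts, mean/SD words per participant,
    the mean reference corpus frequency of the words used, and Pearson
    correlations of per-participant mean (log) word frequency with age.
    Correlations against a constant are undefined and reported as NaN
    with a warning, never as zero.
    """
    from scipy import stats

    lookup: Callable[[str], float]
    if reference_freq is None:
        lookup = lambda w: np.nan
    elif callable(reference_freq):
        lookup = reference_freq
    else:
        table = reference_freq
        lookup = lambda w: table.get(w, 0.0)

    per_counts = []
    per_freq = []
    per_logfreq = []
    ages = []
    all_words: list[str] = []
    for r in cohort.records:
        words = concat_all_texts(r, cohort.inventory) or []
        all_words.extend(words)
        per_counts.append(len(words))
        ages.append(r.age)
        freqs = np.array([lookup(w) for w in words], dtype=float)
        freqs = freqs[np.isfinite(freqs)]
        if freqs.size:
            per_freq.append(float(freqs.mean()))
            with np.errstate(divide="ignore"):
                lf = np.log(freqs[freqs > 0])
            per_logfreq.append(float(lf.mean()) if lf.size else np.nan)
        else:
            per_freq.append(np.nan)
            per_logfreq.append(np.nan)

    counts = np.array(per_counts, dtype=float)
    ages_arr = np.array(ages, dtype=float)

    def _corr(x: np.ndarray) -> tuple[float, float]:
        mask = np.isfinite(x) & np.isfinite(ages_arr)
        if mask.sum() < 3:
            return np.nan, np.nan
        xv, yv = x[mask], ages_arr[mask]
        if np.std(xv) == 0 or np.std(yv) == 0:
            warnings.warn("correlation undefined for a constant variable; reporting NaN")
            return np.nan, np.nan
        r, p = stats.pearsonr(xv, yv)
        return float(r), float(p)

    r_freq, p_freq = _corr(np.array(per_freq))
    r_logfreq, p_logfreq = _corr(np.array(per_logfreq))
    finite_freq = np.array(per_freq, dtype=float)
    finite_freq = finite_freq[np.isfinite(finite_freq)]
    return {
        "total_words": float(len(all_words)),
        "unique_words": float(len(set(all_words))),
        "mean_words_per_participant": float(counts.mean()) if counts.size else np.nan,
        "sd_words_per_participant": float(counts.std(ddof=1)) if counts.size > 1 else np.nan,
        "mean_reference_frequency": float(finite_freq.mean()) if finite_freq.size else np.nan,
        "r_freq_age": r_freq,
        "p_freq_age": p_freq,
        "r_logfreq_age": r_logfreq,
        "p_logfreq_age": p_logfreq,
    }
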