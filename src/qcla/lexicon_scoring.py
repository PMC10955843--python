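"""Lexicon-category scoring of texts and category-age correlations.

A category score is the percentage of a text's tokens that match the
category's word list, with trailing-asterisk entries matching by prefix
(the LIWC wildcard convention).  Category scores over the All-texts
variable are then correlated with age, Bonferroni-corrected over the
number of categories.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import ALL_TEXTS, CohortTable
from .prediction import bonferroni


@dataclass(frozen=True)
class LexiconCategory:
    name: str
    words: frozenset[str]

    def __post_init__(self) -> None:
        if not self.words:
            raise ValueError(f"category {self.name!r} is empty")
        if any(w != w.lower() for w in self.words):
            raise ValueError(f"category {self.name!r} has non-lowercase entries")

    def matches(self, token: str) -> bool:
        token = token.lower()
        if token in self.words:
            return True
        # trailing-asterisk prefix entries
        for w in self.words:
            if w.endswith("*") and token.startswith(w[:-1]):
                return True
        return False


def default_lexicon() -> list[LexiconCategory]:
    """The bundled open substitute set of 63 categories."""
    from ._lexicon_data import SUBSTITUTE_LEXICON

    return [LexiconCategory(name, frozenset(words)) for name, words in SUBSTITUTE_LEXICON.items()]


def load_category_file(path: str | Path) -> LexiconCategory:
    """One category per file: first line ``category: <name>``, then one word per line."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    if not lines or not lines[0].startswith("category:"):
        raise ValueError("first line must be 'category: <name>'")
    name = lines[0].split(":", 1)[1].strip()
    words = frozenset(w.strip().lower() for w in lines[1:] if w.strip())
    return LexiconCategory(name, words)


def load_lexicon_json(path: str | Path) -> list[LexiconCategory]:
    """Combined JSON form ``{name: [words]}``."""
    data = json.loads(Path(path).read_text(encoding="utf-8"))
    return [LexiconCategory(name, frozenset(w.lower() for w in words)) for name, words in data.items()]


def score_text(words: Sequence[str], category: LexiconCategory) -> float:
    """Percentage of tokens matching the category (tokens counted with multiplicity).

    Raises on an empty text: the score is undefined and the participant
    should be excluded for that category.
    """
    if not words:
        raise ValueError("score undefined for an empty text")
    n_match = sum(category.matches(w) for w in words)
    return 100.0 * n_match / len(words)


def score_cohort(
    cohort: CohortTable,
    categories: Sequence[LexiconCategory] | None = None,
    label: str = ALL_TEXTS,
) -> pd.DataFrame:
    """Participants x categories table of percentage scores (NaN when empty text)."""
    categories = categories if categories is not None else default_lexicon()
    responses = cohort.responses_for(label)
    rows = {}
    for r in cohort.records:
        words = responses.get(r.id)
        if words:
            rows[r.id] = [score_text(words, cat) for cat in categories]
        else:
            rows[r.id] = [np.nan] * len(categories)
    return pd.DataFrame.from_dict(rows, orient="index", columns=[c.name for c in categories])


def correlate_categories(
    scores: pd.DataFrame,
    age: Mapping[str, float] | pd.Series,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pearson correlation of each category score with age.

    Returns a table with columns ``category, n, r, p, direction,
    significance`` where direction is "old" for r > 0 and "young" for
    r < 0, and significance tiers come from a Bonferroni correction with
    m = number of categories.  Constant score columns are reported as
    not-available (NaN) with a warning.
    """
    age_s = pd.Series(age, dtype=float)
    rows = []
    for cat in scores.columns:
        joined = pd.concat([scores[cat], age_s], axis=1, join="inner").dropna()
        n = len(joined)
        if n < 3 or joined.iloc[:, 0].std() == 0 or joined.iloc[:, 1].std() == 0:
            if n >= 3:
                warnings.warn(f"category {cat!r} score is constant; correlation not available")
            rows.append({"category": cat, "n": n, "r": np.nan, "p": np.nan, "direction": "na"})
            continue
        r, p = stats.pearsonr(joined.iloc[:, 0], joined.iloc[:, 1])
        rows.append(
            {
                "category": cat,
                "n": n,
                "r": float(r),
                "p": float(p),
                "direction": "old" if r > 0 else "young",
            }
        )
    table = pd.DataFrame(rows)
    report = bonferroni(table["p"].fillna(1.0).tolist(), m=len(table), alpha=alpha)
    table["significance"] = report.flags
    table.loc[table["r"].isna(), "significance"] = "na"
    return table
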