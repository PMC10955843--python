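"""Synthetic reference corpus and cohort generator with known ground truth.

The study's participant data is not public, so every pipeline stage is
exercised on synthetic cohorts whose generative parameters are known.
The generator emulates the study conditions: ~876 retained participants
(883 drawn, a 7/883 control-failure rate), ages uniform on 18-70, four
rating scales produced as noisy discretised transforms of latent traits,
and 16 open-ended questions answered with short word lists (46 word
boxes, blanks calibrated to a mean of ~42 words per participant).

Age and trait structure of the language follows the directions the study
reports: depression/anxiety traits decline with age; younger
participants lean on work/school/stress vocabulary and older ones on
loneliness/worry/finance vocabulary (group "marker" words); older
participants express their traits in their word choices more reliably
than younger ones, and partly through old-specific vocabulary, which is
what makes same-group models transfer imperfectly across groups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .cohort import CohortTable, ParticipantRecord, QuestionInventory, default_inventory

# ---------------------------------------------------------------------------
# vocabulary
# ---------------------------------------------------------------------------

#: group marker words (inspired by the young/old indicative-word themes:
#: school/work/stress for the young, loneliness/worry/finances and calm
#: confidence for the old); disjoint from the shared category lexicons.
YOUNG_MARKERS_NEG = (
    "stressed", "scared", "tense", "bored", "empty", "unmotivated", "irritated",
    "anger", "uncertain", "emotional", "confused", "restless", "upset",
    "fidgety", "crying", "poor",
)
YOUNG_MARKERS_POS = ("school", "work", "kids", "relationship")
OLD_MARKERS_NEG = (
    "alone", "worried", "anxious", "fearful", "concerned", "irritable",
    "scattered", "blue", "helpless", "negative", "loss", "finances", "bills",
)
OLD_MARKERS_POS = ("calm", "confident", "loving", "productive", "alert", "fulfilled", "relaxed")

YOUNG_MARKERS = YOUNG_MARKERS_NEG + YOUNG_MARKERS_POS
OLD_MARKERS = OLD_MARKERS_NEG + OLD_MARKERS_POS

#: shared category lexicons (used by both groups; trait- and
#: question-dependent weights)
CATEGORY_LEXICONS: dict[str, tuple[str, ...]] = {
    "depression": (
        "depressed", "sad", "hopeless", "miserable", "gloomy", "tired", "low",
        "down", "unhappy", "weary", "numb", "drained",
    ),
    "anxiety": (
        "nervous", "panic", "uneasy", "afraid", "dread", "jittery",
        "apprehensive", "overwhelmed", "fear", "frightened",
    ),
    "stress": (
        "stress", "pressure", "busy", "rushed", "deadline", "overworked",
        "hectic", "strained", "frantic", "tension",
    ),
    "positive": (
        "happy", "good", "fine", "okay", "content", "hopeful", "joyful",
        "excited", "proud", "great", "cheerful", "peaceful", "grateful",
        "positive", "satisfied", "energetic",
    ),
    "work_school": (
        "job", "career", "boss", "office", "college", "class", "homework",
        "coworkers", "unemployed", "studying",
    ),
    "money": (
        "debt", "rent", "expenses", "income", "savings", "budget", "salary",
        "broke", "poverty", "payments",
    ),
    "relationships": (
        "family", "friends", "partner", "marriage", "husband", "wife",
        "children", "parents", "lonely", "divorce", "social", "love",
    ),
    "body_energy": (
        "sleep", "insomnia", "pain", "health", "appetite", "hungry",
        "lethargic", "sluggish", "exhausted", "headache", "energy", "awake",
        "sick", "aching",
    ),
    "neutral": (
        "normal", "average", "moderate", "typical", "regular", "usual",
        "routine", "general", "steady", "stable", "plain", "ordinary",
        "medium", "balanced", "common", "life", "days", "things",
        "sometimes", "often", "mostly", "somewhat", "fairly", "quite",
        "really", "maybe", "perhaps", "very",
    ),
}

#: base category-weight profile per question variable
QUESTION_TOPICS: dict[str, dict[str, float]] = {
    "general": {"depression": 2, "anxiety": 1.5, "positive": 2, "neutral": 1.5, "body_energy": 1},
    "depression": {"depression": 3, "positive": 1.5, "neutral": 1, "body_energy": 0.5},
    "worry": {"anxiety": 3, "positive": 1.5, "neutral": 1},
    "general_reason": {"work_school": 2, "money": 1.5, "relationships": 2, "stress": 1.5, "neutral": 1},
    "depression_reason": {"work_school": 1.5, "money": 1.5, "relationships": 2, "stress": 1.5, "neutral": 1},
    "worry_reason": {"work_school": 1.5, "money": 2, "relationships": 1.5, "stress": 1.5, "neutral": 1},
    "satisfaction": {"positive": 3, "relationships": 1, "neutral": 1.5, "depression": 0.5},
    "harmony": {"positive": 3, "neutral": 1.5, "depression": 0.5},
    "sleep": {"body_energy": 3, "neutral": 1.5, "depression": 0.5},
    "concentration": {"neutral": 2, "body_energy": 1, "depression": 1, "stress": 1},
    "appetite": {"body_energy": 3, "neutral": 1.5},
    "energy": {"body_energy": 2.5, "positive": 1, "depression": 1, "neutral": 1},
    "self": {"positive": 1.5, "depression": 1.5, "neutral": 1.5, "anxiety": 0.5},
    "movement": {"body_energy": 2, "neutral": 2, "positive": 0.5},
    "affect_behaviour": {"depression": 1.5, "anxiety": 1.5, "positive": 1.5, "neutral": 1},
    "interest": {"positive": 1.5, "neutral": 2, "depression": 1, "work_school": 0.5},
}


def full_vocabulary() -> list[str]:
    vocab: list[str] = []
    for words in CATEGORY_LEXICONS.values():
        vocab.extend(words)
    vocab.extend(YOUNG_MARKERS)
    vocab.extend(OLD_MARKERS)
    return sorted(set(vocab))


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition parameters of the synthetic cohort.

    ``n_participants`` is the target retained count; the generator draws
    ``round(n / (1 - control_failure_rate))`` raw participants and marks
    ``round(raw * rate)`` of them as control failures (883 drawn -> 876
    retained at the defaults).
    """

    n_participants: int = 876
    age_range: tuple[int, int] = (18, 70)
    control_failure_rate: float = 7 / 883
    blank_rate: float = 4 / 46  # per word box; yields ~42 words on average

    # effect sizes
    age_trait_slope: float = 0.25       # trait decline with age (r scale)
    trait_comorbidity: float = 0.6      # shared distress factor loading
    scale_reliability: float = 0.8      # scale ~ trait attenuation
    marker_rate: float = 0.25           # group-marker share of word slots
    shared_trait_loading: float = 0.4   # trait modulation of shared categories
    # trait-expression multiplier at the youngest / oldest age; scales both
    # the shared-category modulation and the marker-valence coupling, so
    # older participants describe their state more reliably (and partly
    # through old-specific vocabulary)
    expressiveness_young: float = 0.5
    expressiveness_old: float = 1.5

    # corpus
    corpus_ngrams: int = 12_000
    ngram_order: int = 5
    topic_purity: float = 0.75
    doc_length: int = 10  # n-grams per single-topic document

    inventory: QuestionInventory = field(default_factory=default_inventory)

    def __post_init__(self) -> None:
        if not (0 <= self.control_failure_rate < 1):
            raise ValueError("control_failure_rate must be in [0, 1)")
        if not (0 <= self.blank_rate < 1):
            raise ValueError("blank_rate must be in [0, 1)")
        if self.n_participants < 1:
            raise ValueError("n_participants must be positive")
        for label in self.inventory.labels:
            if label not in QUESTION_TOPICS:
                raise ValueError(f"no topic profile for question {label!r}")


def null_config(**overrides) -> GeneratorConfig:
    """A cohort with no planted language signal: words independent of age
    and traits (marker usage off, no trait modulation)."""
    base = GeneratorConfig(
        age_trait_slope=0.0,
        marker_rate=0.0,
        shared_trait_loading=0.0,
        expressiveness_young=0.0,
        expressiveness_old=0.0,
    )
    return replace(base, **overrides)


@dataclass
class SyntheticTruth:
    """Hidden parameters sufficient to compute oracle quantities."""

    config: GeneratorConfig
    participants: pd.DataFrame  # id, age, dep, anx, harm, satis, distress
    marker_words: dict[str, tuple[str, ...]]
    category_lexicons: dict[str, tuple[str, ...]]


# ---------------------------------------------------------------------------
# reference corpus
# ---------------------------------------------------------------------------


def generate_reference_corpus(config: GeneratorConfig, seed: int = 0) -> list[str]:
    """Topic-structured token stream standing in for a large n-gram corpus.

    Documents of ``doc_length`` n-grams are sampled one topic at a time;
    within a document each token comes from the topic lexicon with
    probability ``topic_purity`` and from the neutral lexicon otherwise,
    so same-category words co-occur far more than cross-category ones.
    Deterministic under the seed.
    """
    rng = np.random.default_rng(seed)
    topics: dict[str, tuple[str, ...]] = dict(CATEGORY_LEXICONS)
    topics["young_markers"] = YOUNG_MARKERS
    topics["old_markers"] = OLD_MARKERS
    names = sorted(topics)
    neutral = CATEGORY_LEXICONS["neutral"]

    tokens: list[str] = []
    n_docs = math.ceil(config.corpus_ngrams / config.doc_length)
    grams_left = config.corpus_ngrams
    for _ in range(n_docs):
        topic = topics[names[rng.integers(len(names))]]
        n_grams = min(config.doc_length, grams_left)
        grams_left -= n_grams
        for _ in range(n_grams * config.ngram_order):
            if rng.random() < config.topic_purity:
                tokens.append(topic[rng.integers(len(topic))])
            else:
                tokens.append(neutral[rng.integers(len(neutral))])
    return tokens


def reference_frequencies(tokens: list[str]) -> dict[str, float]:
    """Relative token frequencies of a corpus (reference frequency table)."""
    from collections import Counter

    counts = Counter(tokens)
    total = sum(counts.values())
    return {w: c / total for w, c in counts.items()}


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def _clip_round(x: np.ndarray, lo: int, hi: int) -> np.ndarray:
    return np.clip(np.round(x), lo, hi)


def generate_cohort(
    config: GeneratorConfig | None = None, seed: int = 0
) -> tuple[CohortTable, SyntheticTruth]:
    """Draw a cohort with age- and trait-dependent word usage.

    Latent traits (depression, anxiety and two wellbeing variants) share
    a common distress factor and decline (wellbeing: rise) with age at
    ``age_trait_slope``.  Scale totals are discretised noisy transforms
    of the traits clipped to the instrument ranges.  Words are drawn per
    question from a mixture of category lexicons whose weights depend on
    the question topic, the participant's traits, and - through the
    marker mechanism - their age.
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(seed)
    inv = config.inventory

    rate = config.control_failure_rate
    n_raw = round(config.n_participants / (1 - rate)) if rate > 0 else config.n_participants
    n_fail = round(n_raw * rate)
    lo, hi = config.age_range

    ages = rng.integers(lo, hi + 1, size=n_raw).astype(float)
    z_age = (ages - (lo + hi) / 2) / ((hi - lo) / math.sqrt(12))

    b = config.age_trait_slope
    lam = config.trait_comorbidity
    unique = math.sqrt(max(0.0, 1 - b * b - lam * lam))
    g = rng.standard_normal(n_raw)  # shared distress factor
    dep = -b * z_age + lam * g + unique * rng.standard_normal(n_raw)
    anx = -b * z_age + lam * g + unique * rng.standard_normal(n_raw)
    wb_unique = math.sqrt(max(0.0, 1 - (0.6 * b) ** 2 - 0.65**2))
    harm = 0.6 * b * z_age - 0.65 * g + wb_unique * rng.standard_normal(n_raw)
    satis = 0.6 * b * z_age - 0.65 * g + wb_unique * rng.standard_normal(n_raw)

    rel = math.sqrt(config.scale_reliability)
    noise = math.sqrt(1 - config.scale_reliability)

    def observed(trait: np.ndarray) -> np.ndarray:
        return rel * trait + noise * rng.standard_normal(n_raw)

    phq9 = _clip_round(11 + 6 * observed(dep), 0, 27)
    gad7 = _clip_round(9 + 5 * observed(anx), 0, 21)
    hils = _clip_round(20 + 6 * observed(harm), 5, 35)
    swls = _clip_round(20 + 6 * observed(satis), 5, 35)

    genders = rng.choice(["female", "male", "other"], size=n_raw, p=[538 / 876, 327 / 876, 11 / 876])
    fail_idx = set(rng.choice(n_raw, size=n_fail, replace=False).tolist())

    # standardise mean distress for the valence coupling
    mh = (dep + anx) / 2.0
    mh_sd = math.sqrt((1 + lam * lam + b * b) / 2) or 1.0
    mh_z = mh / mh_sd

    w_y = (hi - ages) / (hi - lo)  # young affinity in [0, 1]
    expr = config.expressiveness_young + (config.expressiveness_old - config.expressiveness_young) * (1 - w_y)

    records: list[ParticipantRecord] = []
    for i in range(n_raw):
        responses: dict[str, list[str]] = {}
        p_ym = config.marker_rate * w_y[i]
        p_om = config.marker_rate * (1 - w_y[i])
        loading = config.shared_trait_loading * expr[i]
        for label in inv.labels:
            base = QUESTION_TOPICS[label]
            weights = {}
            for cat, w in base.items():
                mod = 1.0
                if cat == "depression":
                    mod = 1 + loading * dep[i]
                elif cat == "anxiety":
                    mod = 1 + loading * anx[i]
                elif cat == "positive":
                    mod = 1 - loading * mh_z[i]
                elif cat == "stress":
                    mod = 1 + 0.5 * loading * mh_z[i]
                weights[cat] = max(0.05 * w, w * mod)
            cats = list(weights)
            probs = np.array([weights[c] for c in cats])
            probs = probs / probs.sum()

            words: list[str] = []
            for _ in range(inv.words_requested[label]):
                if rng.random() < config.blank_rate:
                    continue
                u = rng.random()
                if u < p_ym:
                    p_neg = _sigmoid(expr[i] * mh_z[i])
                    pool = YOUNG_MARKERS_NEG if rng.random() < p_neg else YOUNG_MARKERS_POS
                elif u < p_ym + p_om:
                    p_neg = _sigmoid(expr[i] * mh_z[i])
                    pool = OLD_MARKERS_NEG if rng.random() < p_neg else OLD_MARKERS_POS
                else:
                    cat = cats[rng.choice(len(cats), p=probs)]
                    pool = CATEGORY_LEXICONS[cat]
                words.append(pool[rng.integers(len(pool))])
            responses[label] = words
        records.append(
            ParticipantRecord(
                id=f"p{i:04d}",
                age=float(ages[i]),
                gender=str(genders[i]),
                scale_scores={
                    "phq9": float(phq9[i]),
                    "gad7": float(gad7[i]),
                    "hils": float(hils[i]),
                    "swls": float(swls[i]),
                },
                controls_passed=i not in fail_idx,
                responses=responses,
            )
        )

    cohort = CohortTable(records, inventory=inv, provenance=[f"synthetic seed={seed}"])
    truth = SyntheticTruth(
        config=config,
        participants=pd.DataFrame(
            {
                "id": [r.id for r in records],
                "age": ages,
                "dep": dep,
                "anx": anx,
                "harm": harm,
                "satis": satis,
                "distress": mh_z,
            }
        ).set_index("id"),
        marker_words={"young": YOUNG_MARKERS, "old": OLD_MARKERS},
        category_lexicons=dict(CATEGORY_LEXICONS),
    )
    return cohort, truth


# ---------------------------------------------------------------------------
# oracle ceiling
# ---------------------------------------------------------------------------


def true_feature_matrix(cohort: CohortTable, truth: SyntheticTruth) -> tuple[np.ndarray, list[str]]:
    """Per-participant counts of the generator's own word pools.

    Columns: one count per shared category plus the four marker pools.
    These are the generative features, so a regression on them bounds what
    any pipeline can recover from the words.
    """
    pools: dict[str, set[str]] = {c: set(w) for c, w in truth.category_lexicons.items()}
    pools["young_neg"] = set(YOUNG_MARKERS_NEG)
    pools["young_pos"] = set(YOUNG_MARKERS_POS)
    pools["old_neg"] = set(OLD_MARKERS_NEG)
    pools["old_pos"] = set(OLD_MARKERS_POS)
    names = sorted(pools)
    from .cohort import concat_all_texts

    X = np.zeros((len(cohort), len(names)))
    for row, rec in enumerate(cohort.records):
        words = concat_all_texts(rec, cohort.inventory) or []
        for w in words:
            for j, name in enumerate(names):
                if w in pools[name]:
                    X[row, j] += 1
    return X, names


def oracle_ceiling(
    truth: SyntheticTruth,
    cohort: CohortTable,
    target: str = "age",
    seed: int = 0,
    outer_folds: int = 10,
) -> float:
    """Achievable cross-validated r: regress the target on the true
    generative word-pool counts."""
    from .prediction import cross_validate

    X, _ = true_feature_matrix(cohort, truth)
    if target == "age":
        y = cohort.ages()
    else:
        y = cohort.scale(target)
    res = cross_validate(X, y, outer_folds=outer_folds, grid=[X.shape[1]], seed=seed)
    return res.r
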