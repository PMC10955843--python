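"""Latent semantic analysis word embeddings and response encoding.

The semantic space is built in three steps: a word-by-word co-occurrence
matrix counted over sliding n-gram windows of a token corpus, a
``log(count + 1)`` transform, and a truncated singular value decomposition
whose word factor rows are renormalised to unit length.  A free-text
response (a short list of words) is encoded as the renormalised sum of its
in-vocabulary word vectors, and responses are compared with the cosine of
the angle between their vectors.
"""

from __future__ import annotations

import json
import logging
import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

_PUNCT = string.punctuation + "‘’“”–—"

#: default embedding dimensionality
DEFAULT_DIMENSIONALITY = 512

#: unit-norm tolerance for stored vectors
NORM_TOL = 1e-9


def tokenize(text: str) -> list[str]:
    """Lowercase and strip leading/trailing punctuation; no stemming.

    Responses are single descriptive words, so normalisation is kept
    minimal.  Tokens that are empty after stripping are dropped.
    """
    out = []
    for raw in text.split():
        tok = raw.lower().strip(_PUNCT)
        if tok:
            out.append(tok)
    return out


@dataclass
class CorpusCounts:
    """Word x context co-occurrence counts from an n-gram corpus.

    ``counts[i, j]`` is the number of (ordered) co-occurrences of
    ``vocabulary[i]`` with ``context_labels[j]`` inside an n-token window.
    Contexts are the vocabulary itself (symmetric construction).
    """

    vocabulary: list[str]
    context_labels: list[str]
    counts: np.ndarray
    ngram_order: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.ngram_order < 1:
            raise ValueError("ngram_order must be >= 1")
        if len(set(self.vocabulary)) != len(self.vocabulary):
            raise ValueError("duplicate words in vocabulary")
        if len(set(self.context_labels)) != len(self.context_labels):
            raise ValueError("duplicate context labels")
        if self.counts.shape != (len(self.vocabulary), len(self.context_labels)):
            raise ValueError("counts shape does not match labels")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def word_frequencies(self) -> dict[str, float]:
        """Relative corpus frequency per word (row share of total counts)."""
        totals = self.counts.sum(axis=1).astype(float)
        denom = totals.sum()
        if denom == 0:
            return {w: 0.0 for w in self.vocabulary}
        return {w: t / denom for w, t in zip(self.vocabulary, totals)}


def build_cooccurrence(
    tokens: Iterable[str] | Iterable[tuple[str, int]],
    ngram_order: int = 5,
    min_count: int = 1,
) -> CorpusCounts:
    """Count word-word co-occurrences within sliding n-gram windows.

    Accepts either a plain token stream, or n-gram count records
    ``(ngram_string, count)`` where each record contributes ``count``
    occurrences of its window.  Every ordered pair of distinct positions
    within a window increments one cell, so the matrix is symmetric.
    Words whose total corpus count falls below ``min_count`` are dropped
    (rows and columns).
    """
    if ngram_order < 1:
        raise ValueError("ngram_order must be >= 1")
    if ngram_order < 2:
        raise ValueError("windowed co-occurrence requires ngram_order >= 2")

    windows: list[tuple[list[str], int]] = []
    materialized = list(tokens)
    if not materialized:
        raise ValueError("empty corpus")
    if isinstance(materialized[0], tuple):
        for gram, cnt in materialized:  # type: ignore[misc]
            toks = gram.split()
            if toks:
                windows.append((toks, int(cnt)))
    else:
        stream = [str(t) for t in materialized]
        if len(stream) < ngram_order:
            windows.append((stream, 1))
        else:
            for i in range(len(stream) - ngram_order + 1):
                windows.append((stream[i : i + ngram_order], 1))
    if not windows:
        raise ValueError("empty corpus")

    totals: dict[str, int] = {}
    for toks, cnt in windows:
        for t in toks:
            totals[t] = totals.get(t, 0) + cnt
    vocab = sorted(w for w, c in totals.items() if c >= min_count)
    if not vocab:
        raise ValueError("min_count filtered out the whole vocabulary")
    index = {w: i for i, w in enumerate(vocab)}

    counts = np.zeros((len(vocab), len(vocab)), dtype=np.int64)
    for toks, cnt in windows:
        ids = [index.get(t, -1) for t in toks]
        for a in range(len(ids)):
            ia = ids[a]
            if ia < 0:
                continue
            for b in range(len(ids)):
                if a == b:
                    continue
                ib = ids[b]
                if ib >= 0:
                    counts[ia, ib] += cnt
    return CorpusCounts(vocab, list(vocab), counts, ngram_order)


def log_normalize(counts: CorpusCounts | np.ndarray) -> np.ndarray:
    """Apply the ``ln(count + 1)`` transform cell-wise."""
    mat = counts.counts if isinstance(counts, CorpusCounts) else np.asarray(counts)
    if np.any(mat < 0):
        raise ValueError("counts must be non-negative")
    return np.log1p(mat.astype(float))


@dataclass
class SemanticSpace:
    """Vocabulary-indexed matrix of unit-length word embedding vectors."""

    vocabulary: list[str]
    vectors: np.ndarray
    dimensionality: int
    ngram_order: int = 5
    scaling: str = "us"  # "us" = singular-value weighted, "u" = raw left factor
    norm_tolerance: float = NORM_TOL
    _index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.shape != (len(self.vocabulary), self.dimensionality):
            raise ValueError("vectors shape does not match vocabulary/dimensionality")
        norms = np.linalg.norm(self.vectors, axis=1)
        if self.vocabulary and not np.allclose(norms, 1.0, atol=max(self.norm_tolerance, 1e-9)):
            raise ValueError("word vectors must be unit length")
        self._index = {w: i for i, w in enumerate(self.vocabulary)}

    def __contains__(self, word: str) -> bool:
        return word in self._index

    def __len__(self) -> int:
        return len(self.vocabulary)

    def vector(self, word: str) -> np.ndarray:
        return self.vectors[self._index[word]]

    # -- persistence: TSV of vectors + JSON metadata sidecar ----------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        with open(path, "w", encoding="utf-8") as fh:
            for w, v in zip(self.vocabulary, self.vectors):
                fh.write(w + "\t" + "\t".join(format(float(x), ".17g") for x in v) + "\n")
        meta = {
            "dimensionality": self.dimensionality,
            "ngram_order": self.ngram_order,
            "scaling": self.scaling,
            "tokenizer": "lowercase-strip-punct-v1",
        }
        with open(path.with_suffix(path.suffix + ".json"), "w", encoding="utf-8") as fh:
            json.dump(meta, fh, indent=1)

    @classmethod
    def load(cls, path: str | Path) -> "SemanticSpace":
        path = Path(path)
        vocab: list[str] = []
        rows: list[list[float]] = []
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                vocab.append(parts[0])
                rows.append([float(x) for x in parts[1:]])
        with open(path.with_suffix(path.suffix + ".json"), encoding="utf-8") as fh:
            meta = json.load(fh)
        return cls(
            vocabulary=vocab,
            vectors=np.array(rows),
            dimensionality=meta["dimensionality"],
            ngram_order=meta["ngram_order"],
            scaling=meta["scaling"],
        )


def cap_dimensionality(d: int, shape: tuple[int, int]) -> int:
    """Cap a requested dimensionality at ``min(rows, cols) - 1`` with a log line.

    Small synthetic corpora cannot support the default 512 dimensions; the
    cap is applied explicitly and logged rather than failing.
    """
    bound = max(1, min(shape) - 1)
    if d > bound:
        logger.info("dimensionality capped from %d to %d for a %sx%s matrix", d, bound, *shape)
        return bound
    return d


def embed(
    normalized: np.ndarray,
    d: int = DEFAULT_DIMENSIONALITY,
    vocabulary: Sequence[str] | None = None,
    ngram_order: int = 5,
    scaling: str = "us",
) -> SemanticSpace:
    """Truncated SVD of the log-transformed count matrix -> unit word vectors.

    The rank-``d`` word factor is taken as ``U[:, :d] * s[:d]``
    (singular-value weighted; ``scaling="u"`` uses the raw left factor)
    and each row is renormalised to unit length.  Sign convention: each
    singular vector is flipped so its largest-magnitude entry is positive,
    making outputs reproducible.  All-zero rows cannot be normalised and
    are dropped from the vocabulary with a log message.
    """
    mat = np.asarray(normalized, dtype=float)
    if not np.all(np.isfinite(mat)):
        raise ValueError("matrix must be finite")
    n_rows, n_cols = mat.shape
    if d < 1 or d > min(n_rows, n_cols):
        raise ValueError(f"d={d} must be in [1, min(rows, cols)={min(n_rows, n_cols)}]")
    if scaling not in ("us", "u"):
        raise ValueError("scaling must be 'us' or 'u'")
    if vocabulary is None:
        vocabulary = [f"w{i}" for i in range(n_rows)]
    vocabulary = list(vocabulary)

    u, s, _ = np.linalg.svd(mat, full_matrices=False)
    u = u[:, :d]
    s = s[:d]
    # deterministic sign: largest-|entry| of each left singular vector positive
    flip = np.sign(u[np.argmax(np.abs(u), axis=0), np.arange(d)])
    flip[flip == 0] = 1.0
    u = u * flip
    vectors = u * s if scaling == "us" else u

    norms = np.linalg.norm(vectors, axis=1)
    # numerically-zero rows (e.g. words with all-zero counts) cannot be
    # unit-normalised
    keep = norms > 1e-12 * max(norms.max(), 1.0)
    if not np.all(keep):
        dropped = [vocabulary[i] for i in np.flatnonzero(~keep)]
        logger.warning("dropping %d all-zero word rows: %s", len(dropped), dropped[:10])
    vectors = vectors[keep] / norms[keep, None]
    vocab_kept = [w for w, k in zip(vocabulary, keep) if k]
    return SemanticSpace(
        vocabulary=vocab_kept,
        vectors=vectors,
        dimensionality=d,
        ngram_order=ngram_order,
        scaling=scaling,
    )


def build_space(
    tokens: Iterable[str],
    d: int = DEFAULT_DIMENSIONALITY,
    ngram_order: int = 5,
    min_count: int = 1,
    scaling: str = "us",
) -> SemanticSpace:
    """Convenience pipeline: counts -> log transform -> truncated SVD."""
    counts = build_cooccurrence(tokens, ngram_order=ngram_order, min_count=min_count)
    mat = log_normalize(counts)
    d = cap_dimensionality(d, mat.shape)
    return embed(mat, d=d, vocabulary=counts.vocabulary, ngram_order=ngram_order, scaling=scaling)


@dataclass
class ResponseVector:
    """Unit vector for a word response; ``n_known_words == 0`` marks a
    missing response (no in-vocabulary words), distinguishable from any
    valid vector."""

    values: np.ndarray
    n_known_words: int

    @property
    def is_missing(self) -> bool:
        return self.n_known_words == 0


def encode_response(space: SemanticSpace, words: Sequence[str]) -> ResponseVector:
    """Sum the embedding vectors of in-vocabulary words and renormalise.

    Tokens are normalised (lowercase, punctuation stripped) before lookup.
    Out-of-vocabulary words are ignored; if none remain the response is
    returned as missing rather than as a zero vector.
    """
    total = np.zeros(space.dimensionality)
    n_known = 0
    for raw in words:
        toks = tokenize(raw)
        for tok in toks:
            if tok in space:
                total += space.vector(tok)
                n_known += 1
    if n_known == 0:
        return ResponseVector(np.full(space.dimensionality, np.nan), 0)
    norm = np.linalg.norm(total)
    if norm == 0:
        # opposite vectors can cancel exactly; treat as missing
        return ResponseVector(np.full(space.dimensionality, np.nan), 0)
    return ResponseVector(total / norm, n_known)


def cosine(a: ResponseVector | np.ndarray, b: ResponseVector | np.ndarray) -> float:
    """Cosine similarity: inner product over the product of magnitudes."""
    va = a.values if isinstance(a, ResponseVector) else np.asarray(a, dtype=float)
    vb = b.values if isinstance(b, ResponseVector) else np.asarray(b, dtype=float)
    na = np.linalg.norm(va)
    nb = np.linalg.norm(vb)
    if not np.isfinite(na) or not np.isfinite(nb) or na == 0 or nb == 0:
        raise ValueError("cosine undefined for zero or missing vectors")
    return float(np.clip(va @ vb / (na * nb), -1.0, 1.0))


def read_token_file(path: str | Path) -> list[str]:
    """Plain-text whitespace-separated token corpus."""
    with open(path, encoding="utf-8") as fh:
        return tokenize(fh.read())


def read_ngram_counts(path: str | Path) -> list[tuple[str, int]]:
    """TSV n-gram count file: ``ngram<TAB>count`` per line."""
    records = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            gram, cnt = line.rsplit("\t", 1)
            records.append((gram, int(cnt)))
    return records
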