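"""Embedding construction: co-occurrence counts, log transform, SVD, encoding."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import qcla
from qcla.semantic_space import (
    build_cooccurrence,
    build_space,
    cap_dimensionality,
    cosine,
    embed,
    encode_response,
    log_normalize,
    tokenize,
)


def brute_force_cooccurrence(tokens, order):
    """Independent oracle: enumerate every window and every ordered pair."""
    counts = {}
    for i in range(len(tokens) - order + 1):
        window = tokens[i : i + order]
        for a in range(order):
            for b in range(order):
                if a != b:
                    counts[(window[a], window[b])] = counts.get((window[a], window[b]), 0) + 1
    return counts


class TestCooccurrence:
    @pytest.mark.parametrize(
        "tokens,order",
        [
            ("a b a b".split(), 2),
            ("a b c a c b a".split(), 3),
            ("the cat sat on the mat the cat".split(), 5),
        ],
    )
    def test_matches_window_enumeration_oracle(self, tokens, order):
        cc = build_cooccurrence(tokens, ngram_order=order)
        oracle = brute_force_cooccurrence(tokens, order)
        idx = {w: i for i, w in enumerate(cc.vocabulary)}
        for (a, b), n in oracle.items():
            assert cc.counts[idx[a], idx[b]] == n
        assert cc.counts.sum() == sum(oracle.values())

    def test_adjacent_pair_counts(self):
        cc = build_cooccurrence("a b a b".split(), ngram_order=2)
        idx = {w: i for i, w in enumerate(cc.vocabulary)}
        # windows (a,b), (b,a), (a,b): each increments both ordered cells
        assert cc.counts[idx["a"], idx["b"]] == 3
        assert cc.counts[idx["b"], idx["a"]] == 3

    def test_single_repeated_token(self):
        cc = build_cooccurrence("x x x".split(), ngram_order=2)
        assert cc.vocabulary == ["x"]
        assert cc.counts[0, 0] > 0

    def test_disjoint_windows_never_cooccur(self):
        cc = build_cooccurrence([("a b", 2), ("c d", 3)], ngram_order=2)
        idx = {w: i for i, w in enumerate(cc.vocabulary)}
        for x in "ab":
            for z in "cd":
                assert cc.counts[idx[x], idx[z]] == 0

    def test_min_count_drops_rare_words(self):
        cc = build_cooccurrence("a b a b a rare".split(), ngram_order=2, min_count=2)
        assert "rare" not in cc.vocabulary
        assert set(cc.vocabulary) == {"a", "b"}

    def test_errors(self):
        with pytest.raises(ValueError):
            build_cooccurrence([], ngram_order=2)
        with pytest.raises(ValueError):
            build_cooccurrence("a b".split(), ngram_order=0)
        with pytest.raises(ValueError):
            build_cooccurrence("a b".split(), ngram_order=1)


class TestLogNormalize:
    def test_analytic_values(self):
        mat = log_normalize(np.array([[0, 1], [2, 7]]))
        assert mat[0, 0] == 0.0
        assert mat[0, 1] == pytest.approx(np.log(2), abs=1e-12)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            log_normalize(np.array([[-1, 0]]))

    @given(st.lists(st.integers(0, 10_000), min_size=2, max_size=20, unique=True))
    @settings(deadline=None, max_examples=50)
    def test_preserves_zero_pattern_and_strict_order(self, counts):
        arr = np.array(counts)
        out = log_normalize(arr.reshape(1, -1)).ravel()
        assert ((arr == 0) == (out == 0)).all()
        assert (np.argsort(out, kind="stable") == np.argsort(arr, kind="stable")).all()


class TestEmbed:
    @pytest.mark.parametrize("shape", [(4, 5), (8, 8), (12, 12), (12, 7)])
    def test_full_rank_embedding_preserves_row_cosines(self, shape, rng):
        mat = rng.random(shape) + 0.1
        d = min(shape)
        space = embed(mat, d=d)
        raw = mat / np.linalg.norm(mat, axis=1, keepdims=True)
        for i in range(shape[0]):
            for j in range(shape[0]):
                assert cosine(space.vectors[i], space.vectors[j]) == pytest.approx(
                    float(raw[i] @ raw[j]), abs=1e-6
                )

    def test_rank_one_matrix_collapses_to_sign(self, rng):
        mat = np.outer(rng.random(6) + 0.5, rng.random(8) + 0.5)
        space = embed(mat, d=1)
        for i in range(6):
            assert abs(cosine(space.vectors[0], space.vectors[i])) == pytest.approx(1.0, abs=1e-9)

    def test_unit_norms(self, rng):
        space = embed(rng.random((10, 10)), d=6)
        norms = np.linalg.norm(space.vectors, axis=1)
        assert np.allclose(norms, 1.0, atol=1e-9)

    def test_deterministic_across_runs(self, rng):
        mat = rng.random((9, 9))
        a = embed(mat, d=5)
        b = embed(mat, d=5)
        assert np.array_equal(a.vectors, b.vectors)

    def test_dimension_bound_enforced(self, rng):
        with pytest.raises(ValueError):
            embed(rng.random((4, 6)), d=5)

    def test_zero_row_dropped(self, rng):
        mat = rng.random((5, 6))
        mat[2] = 0.0
        space = embed(mat, d=4, vocabulary=list("abcde"))
        assert "c" not in space.vocabulary
        assert len(space) == 4

    def test_cap_dimensionality(self):
        assert cap_dimensionality(512, (100, 100)) == 99
        assert cap_dimensionality(50, (100, 100)) == 50


class TestEncodeAndCosine:
    def test_single_word_is_its_embedding(self, tiny_space):
        vec = encode_response(tiny_space, ["alpha"])
        assert np.allclose(vec.values, tiny_space.vector("alpha"))
        assert vec.n_known_words == 1

    def test_repetition_invariant(self, tiny_space):
        once = encode_response(tiny_space, ["beta"])
        thrice = encode_response(tiny_space, ["beta"] * 3)
        assert np.allclose(once.values, thrice.values)

    def test_two_orthogonal_words(self, tiny_space):
        vec = encode_response(tiny_space, ["alpha", "beta"])
        assert cosine(vec, tiny_space.vector("alpha")) == pytest.approx(1 / np.sqrt(2), abs=1e-12)
        assert cosine(vec, tiny_space.vector("beta")) == pytest.approx(1 / np.sqrt(2), abs=1e-12)

    def test_oov_only_marks_missing(self, tiny_space):
        vec = encode_response(tiny_space, ["nope", "missing"])
        assert vec.is_missing
        with pytest.raises(ValueError):
            cosine(vec, tiny_space.vector("alpha"))

    def test_tokens_normalised_before_lookup(self, tiny_space):
        vec = encode_response(tiny_space, ["Alpha,", "BETA!"])
        assert vec.n_known_words == 2

    @given(st.permutations(["alpha", "beta", "gamma", "beta"]))
    @settings(deadline=None, max_examples=24)
    def test_permutation_invariant(self, words):
        space = qcla.SemanticSpace(
            vocabulary=["alpha", "beta", "gamma", "delta"],
            vectors=np.eye(4),
            dimensionality=4,
        )
        base = encode_response(space, ["alpha", "beta", "gamma", "beta"])
        assert np.allclose(encode_response(space, list(words)).values, base.values)

    def test_cosine_identities(self, rng):
        v = rng.random(5)
        assert cosine(v, v) == pytest.approx(1.0)
        assert cosine(v, -v) == pytest.approx(-1.0)
        assert cosine(np.array([1.0, 0.0]), np.array([0.0, 1.0])) == pytest.approx(0.0)
        with pytest.raises(ValueError):
            cosine(v, np.zeros(5))


def test_tokenize_strips_punctuation_and_lowercases():
    assert tokenize("Hello, WORLD!  (worried)") == ["hello", "world", "worried"]


def test_space_round_trip(tmp_path, rng):
    space = embed(rng.random((6, 6)), d=4, vocabulary=list("abcdef"))
    path = tmp_path / "space.tsv"
    space.save(path)
    loaded = qcla.SemanticSpace.load(path)
    assert loaded.vocabulary == space.vocabulary
    assert np.allclose(loaded.vectors, space.vectors)
    assert loaded.dimensionality == 4


def test_build_space_caps_default_dimensionality():
    space = build_space("a b c a b c a c b".split(), d=512, ngram_order=2)
    assert space.dimensionality <= 3
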