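"""Sentence vectors, vector unpacking, component selection, density measures."""

import numpy as np
import pytest

import semdens as sd
from semdens.density import _two_group_f
from semdens.preprocess import ContentSentence, TaggedSentence, Token


def _content(keys):
    return ContentSentence(tuple(keys), "p")


class TestComposeSentenceVector:
    def test_normalized_sum_of_word_embeddings(self, ortho_space):
        sv = sd.compose_sentence_vector(
            _content(["NN_w00", "NN_w01", "NN_w02"]), ortho_space)
        expected = np.zeros(16)
        expected[:3] = 1 / np.sqrt(3)
        assert np.allclose(sv.vector, expected)
        assert sv.n_content == 3

    def test_single_word_is_unit_embedding(self, ortho_space):
        sv = sd.compose_sentence_vector(_content(["NN_w05"]), ortho_space)
        assert np.allclose(sv.vector, ortho_space.vector("NN_w05"))

    def test_two_orthonormal_words_coefficients(self, ortho_space):
        sv = sd.compose_sentence_vector(_content(["NN_w00", "NN_w01"]), ortho_space)
        assert sv.vector[0] == pytest.approx(1 / np.sqrt(2))
        assert sv.vector[1] == pytest.approx(1 / np.sqrt(2))
        assert np.linalg.norm(sv.vector) == pytest.approx(1.0, abs=1e-9)

    def test_oov_keys_skipped_but_counted_out(self, ortho_space):
        sv = sd.compose_sentence_vector(
            _content(["NN_w00", "NN_unknown"]), ortho_space)
        assert sv.n_content == 1

    def test_no_vocabulary_overlap_skips_sentence(self, ortho_space):
        with pytest.raises(sd.SkipSentence):
            sd.compose_sentence_vector(_content(["NN_nope"]), ortho_space)


class TestUnpack:
    def test_exact_single_component(self, ortho_space):
        sv = sd.compose_sentence_vector(_content(["NN_w03"]), ortho_space)
        res = sd.unpack(sv, ortho_space)
        assert res.final_cost < 1e-4
        assert res.weights["NN_w03"] == pytest.approx(1.0, abs=1e-3)
        assert all(k == "NN_w03" for k in res.weights)

    def test_matches_least_squares_projection(self, ortho_space):
        # normalized sum of 4 orthonormal basis words -> coefficients 0.5
        sv = sd.compose_sentence_vector(
            _content(["NN_w00", "NN_w01", "NN_w02", "NN_w03"]), ortho_space)
        res = sd.unpack(sv, ortho_space)
        proj = ortho_space.matrix @ sv.vector  # exact projection coefficients
        for i, k in enumerate(ortho_space.keys):
            assert res.weights.get(k, 0.0) == pytest.approx(proj[i], abs=1e-3)

    def test_unequal_mixture_recovers_closed_form(self, ortho_space):
        y = sd.unit_normalize(2 * np.eye(16)[0] + np.eye(16)[1])
        sv = sd.SentenceVector(vector=y, word_keys=("NN_w00", "NN_w01"), n_content=2)
        res = sd.unpack(sv, ortho_space)
        assert res.weights["NN_w00"] == pytest.approx(2 / np.sqrt(5), abs=1e-3)
        assert res.weights["NN_w01"] == pytest.approx(1 / np.sqrt(5), abs=1e-3)

    def test_pruned_weights_are_exactly_zero(self, concept_space):
        sent = _content(concept_space.keys[:4])
        sv = sd.compose_sentence_vector(sent, concept_space)
        res = sd.unpack(sv, concept_space, sd.UnpackingConfig.desk_scale())
        assert all(w != 0.0 for w in res.weights.values())
        assert res.nonzero_count < len(concept_space)

    def test_cost_trace_non_increasing_below_stability_bound(self, ortho_space):
        sv = sd.compose_sentence_vector(
            _content(["NN_w00", "NN_w04", "NN_w08"]), ortho_space)
        res = sd.unpack(sv, ortho_space,
                        sd.UnpackingConfig(learning_rate=0.5, max_iterations=1000))
        assert all(b <= a + 1e-12 for a, b in zip(res.cost_trace, res.cost_trace[1:]))

    def test_divergent_learning_rate_flagged(self, ortho_space):
        sv = sd.compose_sentence_vector(_content(["NN_w00"]), ortho_space)
        with pytest.raises(sd.NumericInstabilityError):
            sd.unpack(sv, ortho_space,
                      sd.UnpackingConfig(learning_rate=6.0, max_iterations=500,
                                         prune="magnitude",
                                         convergence_tol=0.0))

    def test_density_invariant_to_word_order(self, concept_space, fast_unpack):
        keys = list(concept_space.keys[:5])
        a = sd.unpack_sentence(_content(keys), concept_space, fast_unpack)
        b = sd.unpack_sentence(_content(keys[::-1]), concept_space, fast_unpack)
        assert a.density == b.density
        assert a.selected_components == b.selected_components


def _bruteforce_select(weights, n_content, cutoff=0.25, equal_tol=1e-3):
    """Independent enumeration oracle for F-ratio component selection."""
    vals = sorted((abs(v) for v in weights if v != 0), reverse=True)
    K = len(vals)
    if K <= 2 or (max(vals) - min(vals)) / max(vals) < equal_tol:
        return K, False
    fs = []
    for s in range(1, K):
        g1, g2 = vals[:s], vals[s:]
        gm = sum(vals) / K
        m1, m2 = sum(g1) / len(g1), sum(g2) / len(g2)
        msb = len(g1) * (m1 - gm) ** 2 + len(g2) * (m2 - gm) ** 2
        ssw = sum((x - m1) ** 2 for x in g1) + sum((x - m2) ** 2 for x in g2)
        f = float("inf") if ssw == 0 else msb / (ssw / (K - 2))
        fs.append((f, s))
    fs.sort(key=lambda t: (-t[0], t[1]))
    m = fs[0][1]
    if m / n_content <= cutoff and len(fs) > 1:
        return fs[1][1], True
    return m, False


class TestSelectComponents:
    def test_clear_two_group_split(self):
        weights = {"a": 0.9, "b": 0.85, "c": 0.1, "d": 0.08}
        selected, m, density, repart = sd.select_components(weights, n_content=4)
        assert selected == {"a", "b"}
        assert (m, density, repart) == (2, 0.5, False)

    def test_two_nonzero_weights_degenerate_rule(self):
        selected, m, _, _ = sd.select_components({"a": 0.9, "b": 0.1}, n_content=2)
        assert selected == {"a", "b"} and m == 2

    def test_identical_weights_select_all(self):
        selected, m, _, _ = sd.select_components(
            {k: 0.5 for k in "abcde"}, n_content=5)
        assert m == 5

    def test_low_density_triggers_second_best_split(self):
        # dominant single weight -> best split m=1 -> density 1/8 <= 0.25
        weights = {"a": 0.95, "b": 0.30, "c": 0.28, "d": 0.05, "e": 0.04}
        selected, m, density, repart = sd.select_components(weights, n_content=8)
        expect_m, expect_repart = _bruteforce_select(weights.values(), 8)
        assert repart and expect_repart
        assert m == expect_m > 1

    def test_no_nonzero_weights_skips(self):
        with pytest.raises(sd.SkipSentence):
            sd.select_components({"a": 0.0}, n_content=3)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bruteforce_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(50):
            k = int(rng.integers(1, 12))
            weights = {f"w{i}": float(rng.random()) for i in range(k)}
            n = int(rng.integers(max(1, k // 2), 2 * k + 1))
            _, m, density, repart = sd.select_components(weights, n_content=n)
            em, erep = _bruteforce_select(weights.values(), n)
            assert (m, repart) == (em, erep)
            assert density == pytest.approx(m / n)

    def test_f_ratio_perfect_split_is_infinite(self):
        assert _two_group_f(np.array([0.8, 0.8, 0.2, 0.2]), 2) == np.inf


class TestDensityMeasures:
    def test_density_ratio_examples(self):
        assert sd.semantic_density(2, 4) == 0.5
        assert sd.semantic_density(5, 5) == 1.0
        with pytest.raises(sd.SkipSentence):
            sd.semantic_density(1, 0)

    def test_repeated_word_halves_density(self, ortho_space):
        # one word spoken twice: one meaning component over two tokens
        res = sd.unpack_sentence(_content(["NN_w02", "NN_w02"]), ortho_space)
        assert res.m == 1
        assert res.density == 0.5

    def test_oracle_equivalence_on_orthonormal_lexicon(self, ortho_space):
        # repeat-free sentences: selected components = the word set, density 1
        rng = np.random.default_rng(4)
        for _ in range(5):
            distinct = rng.choice(16, size=rng.integers(2, 6), replace=False)
            keys = [f"NN_w{i:02d}" for i in distinct]
            res = sd.unpack_sentence(_content(keys), ortho_space)
            assert res.selected_components == set(keys)
            assert res.density == pytest.approx(1.0)

    def test_repeat_dominance_reduces_density(self, ortho_space):
        # one word twice among two distinct: components {both}, density 2/3
        res = sd.unpack_sentence(
            _content(["NN_w00", "NN_w01", "NN_w00"]), ortho_space)
        assert res.m == 2
        assert res.density == pytest.approx(2 / 3)

    def test_mean_density(self):
        assert sd.mean_density([1.0, 0.5]) == 0.75
        assert sd.mean_density([0.7]) == 0.7
        rng = np.random.default_rng(0)
        xs = rng.random(100)
        assert sd.mean_density(xs) == pytest.approx(sum(xs) / len(xs))
        with pytest.raises(sd.SkipSentence):
            sd.mean_density([])

    def test_participant_density_aggregates(self, ortho_space):
        sents = [_content(["NN_w00", "NN_w01"]), _content(["NN_w02", "NN_w02"])]
        pd_ = sd.participant_density("p1", sents, ortho_space)
        assert pd_.sentence_count == 2
        assert pd_.mean_density == pytest.approx((1.0 + 0.5) / 2)


def _tagged(tag_seq):
    tokens = tuple(Token(f"t{i}", tag, f"t{i}") for i, tag in enumerate(tag_seq))
    return TaggedSentence(tokens=tokens, participant_id="p", speaker="participant")


class TestComparators:
    def test_idea_density_counting_rule(self):
        sent = _tagged(["VB", "VB", "JJ", "IN"] + ["NN"] * 6)
        assert sd.idea_density(sent) == pytest.approx(0.4)
        assert sd.idea_density(_tagged(["NN", "NN", "NN"])) == 0.0
        with pytest.raises(sd.SkipSentence):
            sd.idea_density(_tagged([]))

    def test_information_value_single_word(self):
        space = sd.EmbeddingSpace(["NN_a"], np.array([[1.0, 1.0]]), {"NN_a": 1})
        mean_len, res_len = sd.information_value(_content(["NN_a"]), space)
        assert mean_len == pytest.approx(np.sqrt(2))
        assert res_len == pytest.approx(np.sqrt(2))

    def test_information_value_cancellation(self):
        space = sd.EmbeddingSpace(["NN_a", "NN_b"],
                                  np.array([[0.6, 0.8], [-0.6, -0.8]]),
                                  {"NN_a": 1, "NN_b": 1})
        mean_len, res_len = sd.information_value(_content(["NN_a", "NN_b"]), space)
        assert mean_len == pytest.approx(1.0)
        assert res_len == pytest.approx(0.0, abs=1e-12)

    def test_information_value_matches_bruteforce(self, concept_space):
        keys = list(concept_space.keys[:5])
        mean_len, res_len = sd.information_value(_content(keys), concept_space)
        vecs = concept_space.vectors(keys)
        assert mean_len == pytest.approx(
            np.mean([np.linalg.norm(v) for v in vecs]))
        assert res_len == pytest.approx(np.linalg.norm(vecs.sum(axis=0)))
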