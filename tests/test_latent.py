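"""Probe profiling, baseline contrast, clustering, concept predictors."""

import numpy as np
import pytest

import semdens as sd
from semdens.density import SentenceVector
from semdens.latent import ProbeProfile


def _sv(vec):
    vec = np.asarray(vec, dtype=float)
    return SentenceVector(vector=vec / np.linalg.norm(vec),
                          word_keys=(), n_content=1)


class TestCosine:
    def test_identity_orthogonal_and_closed_form(self):
        v = np.array([0.2, -0.5, 1.0])
        assert sd.cosine(v, v) == pytest.approx(1.0)
        assert sd.cosine([1, 0], [0, 1]) == pytest.approx(0.0)
        assert sd.cosine([1, 0], [1, 1]) == pytest.approx(1 / np.sqrt(2))

    def test_zero_vector_rejected(self):
        with pytest.raises(sd.DegenerateInputError):
            sd.cosine([0, 0], [1, 0])


class TestProbeProfile:
    def test_sentence_equal_to_probe_scores_one(self, ortho_space):
        sents = [_sv(ortho_space.vector("NN_w03"))]
        prof = sd.probe_profile(["NN_w03"], sents, ortho_space, "p")
        assert prof.scores["NN_w03"] == pytest.approx(1.0)

    def test_max_over_sentences_matches_bruteforce(self, concept_space):
        rng = np.random.default_rng(1)
        sents = [_sv(rng.standard_normal(concept_space.dimension))
                 for _ in range(4)]
        probes = list(concept_space.keys[:20])
        prof = sd.probe_profile(probes, sents, concept_space, "p")
        for p in probes:
            expected = max(sd.cosine(concept_space.vector(p), s.vector)
                           for s in sents)
            assert prof.scores[p] == pytest.approx(expected)

    def test_missing_probes_dropped(self, ortho_space):
        prof = sd.probe_profile(["NN_w00", "NN_missing"],
                                [_sv(np.eye(16)[0])], ortho_space, "p")
        assert set(prof.scores) == {"NN_w00"}

    def test_scores_monotone_under_added_sentences(self, concept_space):
        rng = np.random.default_rng(2)
        probes = list(concept_space.keys[:10])
        sents = [_sv(rng.standard_normal(concept_space.dimension))
                 for _ in range(5)]
        small = sd.probe_profile(probes, sents[:2], concept_space, "p")
        big = sd.probe_profile(probes, sents, concept_space, "p")
        for p in probes:
            assert big.scores[p] >= small.scores[p] - 1e-12

    def test_no_sentences_rejected(self, ortho_space):
        with pytest.raises(sd.InvalidInputError):
            sd.probe_profile(["NN_w00"], [], ortho_space, "p")


class TestGroupProfile:
    def test_single_profile_is_identity(self):
        p = ProbeProfile("a", {"x": 0.4, "y": -0.1}, "max-over-sentences")
        g = sd.group_profile([p])
        assert g.scores == pytest.approx(p.scores)

    def test_mean_of_two(self):
        a = ProbeProfile("a", {"x": 0.2}, "max-over-sentences")
        b = ProbeProfile("b", {"x": 0.4}, "max-over-sentences")
        assert sd.group_profile([a, b]).scores["x"] == pytest.approx(0.3)

    def test_matches_bruteforce_mean(self):
        rng = np.random.default_rng(3)
        probes = [f"p{i}" for i in range(6)]
        profiles = [ProbeProfile(f"e{j}", {p: float(rng.uniform(-1, 1))
                                           for p in probes},
                                 "max-over-sentences") for j in range(9)]
        g = sd.group_profile(profiles)
        for p in probes:
            assert g.scores[p] == pytest.approx(
                np.mean([prof.scores[p] for prof in profiles]))

    def test_probe_mismatch_rejected(self):
        a = ProbeProfile("a", {"x": 0.2}, "max-over-sentences")
        b = ProbeProfile("b", {"y": 0.4}, "max-over-sentences")
        with pytest.raises(sd.InvalidInputError):
            sd.group_profile([a, b])


class TestContrastWeight:
    def _profiles(self, g, b):
        probes = [f"p{i}" for i in range(len(g))]
        return (ProbeProfile("g", dict(zip(probes, g)), "mean-over-entities"),
                ProbeProfile("b", dict(zip(probes, b)), "mean-over-entities"))

    def test_baseline_at_mean_gets_zero_weight(self):
        g, b = self._profiles([0.5, 0.5, 0.5], [0.2, 0.2, 0.2])
        cm = sd.contrast_weight(g, b)
        for w in cm.weighted_scores.values():
            assert w == pytest.approx(0.0)

    def test_monotone_in_baseline_rarity(self):
        g, b = self._profiles([0.6, 0.6], [0.1, 0.4])
        cm = sd.contrast_weight(g, b)
        assert cm.weighted_scores["p0"] > cm.weighted_scores["p1"]

    def test_log_ratio_matches_hand_computation(self):
        gvals = [0.8, 0.3, 0.6, 0.2, 0.9]
        bvals = [0.1, 0.5, 0.25, 0.4, 0.05]
        g, b = self._profiles(gvals, bvals)
        cm = sd.contrast_weight(g, b)
        mean_b = np.mean(bvals)
        for i in range(5):
            assert cm.weighted_scores[f"p{i}"] == pytest.approx(
                gvals[i] * np.log(mean_b / bvals[i]))

    def test_difference_of_identical_profiles_is_zero(self):
        g, _ = self._profiles([0.3, 0.7, 0.1], [0, 0, 0])
        cm = sd.contrast_weight(g, g, method="difference")
        assert all(w == 0 for w in cm.weighted_scores.values())

    def test_difference_method(self):
        g, b = self._profiles([0.6, 0.2], [0.1, 0.4])
        cm = sd.contrast_weight(g, b, method="difference")
        assert cm.weighted_scores["p0"] == pytest.approx(0.5)
        assert cm.weighted_scores["p1"] == pytest.approx(-0.2)


class TestTopProbes:
    def _matrix(self, weights):
        probes = sorted(weights)
        g = ProbeProfile("g", {p: 0.5 for p in probes}, "mean-over-entities")
        from semdens.latent import ContrastMatrix
        return ContrastMatrix(tuple(probes), np.zeros(len(probes)),
                              np.zeros(len(probes)), dict(weights), "difference")

    def test_descending_positive_selection(self):
        cm = self._matrix({"a": 0.1, "b": 0.5, "c": -0.2, "d": 0.3})
        assert sd.top_probes(cm, 2) == ["b", "d"]
        assert sd.top_probes(cm, 10) == ["b", "d", "a"]

    def test_all_negative_gives_empty(self):
        cm = self._matrix({"a": -0.1, "b": -0.5})
        assert sd.top_probes(cm, 3) == []

    def test_ties_break_lexicographically(self):
        cm = self._matrix({"z": 0.5, "a": 0.5, "m": 0.5})
        assert sd.top_probes(cm, 2) == ["a", "m"]

    def test_matches_full_sort(self):
        rng = np.random.default_rng(5)
        weights = {f"p{i}": float(rng.uniform(-1, 1)) for i in range(30)}
        cm = self._matrix(weights)
        expected = [p for p, w in sorted(weights.items(),
                                         key=lambda kv: (-kv[1], kv[0]))
                    if w > 0][:3]
        assert sd.top_probes(cm, 3) == expected


class TestClusterProbes:
    def _blob_space(self, centers, per_blob, noise, seed):
        rng = np.random.default_rng(seed)
        keys, rows = [], []
        for c, center in enumerate(centers):
            for i in range(per_blob):
                keys.append(f"NN_c{c}w{i}")
                rows.append(np.asarray(center) + noise * rng.standard_normal(len(center)))
        return sd.EmbeddingSpace(keys, np.array(rows), {k: 1 for k in keys})

    @pytest.mark.parametrize("seed", range(5))
    def test_recovers_three_planted_blobs(self, seed):
        centers = 10 * np.eye(3)
        space = self._blob_space(centers, per_blob=8, noise=0.3, seed=seed)
        sol = sd.cluster_probes(space.keys, space, range(2, 7), seed=seed)
        assert sol.k == 3
        assert sol.silhouette > 0.5
        # members of one blob share a label
        for c in range(3):
            labels = {sol.labels[k] for k in space.keys if k.startswith(f"NN_c{c}")}
            assert len(labels) == 1

    def test_duplicated_points_two_groups(self):
        space = self._blob_space([(0, 0, 5), (5, 0, 0)], per_blob=4,
                                 noise=0.0, seed=0)
        sol = sd.cluster_probes(space.keys, space, range(2, 4), seed=0)
        assert sol.k == 2
        assert sol.silhouette == pytest.approx(1.0)

    def test_deterministic_for_fixed_seed(self, concept_space):
        probes = list(concept_space.keys[:30])
        a = sd.cluster_probes(probes, concept_space, range(2, 6), seed=9)
        b = sd.cluster_probes(probes, concept_space, range(2, 6), seed=9)
        assert a.labels == b.labels and a.k == b.k

    def test_too_few_probes_rejected(self, ortho_space):
        with pytest.raises(sd.InvalidInputError):
            sd.cluster_probes(["NN_w00", "NN_w01"], ortho_space, range(2, 4), 0)


class TestConceptVector:
    def test_single_key_is_unit_embedding(self, ortho_space):
        cv = sd.concept_vector(["NN_w07"], ortho_space)
        assert np.allclose(cv.vector, ortho_space.vector("NN_w07"))

    def test_two_orthonormal_keys(self, ortho_space):
        cv = sd.concept_vector(["NN_w00", "NN_w01"], ortho_space)
        assert cv.vector[0] == pytest.approx(1 / np.sqrt(2))
        assert np.linalg.norm(cv.vector) == pytest.approx(1.0, abs=1e-9)

    def test_out_of_vocabulary_members_dropped(self, ortho_space):
        cv = sd.concept_vector(["NN_w00", "NN_nope"], ortho_space)
        assert cv.member_keys == {"NN_w00"}
        with pytest.raises(sd.InvalidInputError):
            sd.concept_vector(["NN_nope"], ortho_space)


class TestConceptPredictor:
    def test_matching_sentence_scores_one(self, ortho_space):
        cv = sd.concept_vector(["NN_w00", "NN_w01"], ortho_space)
        assert sd.concept_predictor(cv, [_sv(cv.vector)]) == pytest.approx(1.0)

    def test_orthogonal_sentences_score_zero(self, ortho_space):
        cv = sd.concept_vector(["NN_w00"], ortho_space)
        sents = [_sv(np.eye(16)[5]), _sv(np.eye(16)[9])]
        assert sd.concept_predictor(cv, sents) == pytest.approx(0.0)

    def test_matches_exhaustive_max(self, concept_space):
        rng = np.random.default_rng(8)
        cv = sd.concept_vector(list(concept_space.keys[:4]), concept_space)
        sents = [_sv(rng.standard_normal(concept_space.dimension))
                 for _ in range(7)]
        expected = max(sd.cosine(cv.vector, s.vector) for s in sents)
        assert sd.concept_predictor(cv, sents) == pytest.approx(expected)

    def test_invariant_to_sentence_duplication(self, concept_space):
        rng = np.random.default_rng(9)
        cv = sd.concept_vector(list(concept_space.keys[:3]), concept_space)
        sents = [_sv(rng.standard_normal(concept_space.dimension))
                 for _ in range(4)]
        assert sd.concept_predictor(cv, sents) == pytest.approx(
            sd.concept_predictor(cv, sents + sents))

    def test_no_sentences_rejected(self, ortho_space):
        cv = sd.concept_vector(["NN_w00"], ortho_space)
        with pytest.raises(sd.InvalidInputError):
            sd.concept_predictor(cv, [])
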