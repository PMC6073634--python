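"""Similarity, composome/compotype detection, repertoire statistics,
information content, eigen-analysis and enantioselection metrics."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import gardsim as g


class TestSimilarity:
    def test_self_similarity_is_one(self, rng):
        for _ in range(5):
            x = rng.integers(0, 9, 12)
            x[0] += 1
            assert g.similarity_H(x, x) == pytest.approx(1.0)

    def test_disjoint_supports_are_orthogonal(self):
        assert g.similarity_H([1, 2, 0, 0], [0, 0, 3, 1]) == 0.0

    def test_hand_value(self):
        assert g.similarity_H([1, 1, 0], [1, 0, 1]) == pytest.approx(0.5)

    def test_scale_invariance_and_symmetry(self, rng):
        x = rng.integers(0, 10, 8) + 1
        y = rng.integers(0, 10, 8) + 1
        assert g.similarity_H(x, y) == pytest.approx(g.similarity_H(y, x))
        assert g.similarity_H(7 * x, y) == pytest.approx(g.similarity_H(x, y))

    def test_zero_vector_rejected(self):
        with pytest.raises(g.GardError):
            g.similarity_H([0, 0], [1, 1])


class TestCarpet:
    def test_symmetric_unit_diagonal_bounded(self, short_trace):
        sim = g.carpet(short_trace)
        assert np.allclose(sim, sim.T)
        assert np.allclose(np.diag(sim), 1.0)
        assert sim.min() >= 0.0 and sim.max() <= 1.0

    def test_alternating_orthogonal_checkerboard(self):
        a = np.array([4, 0, 0, 0])
        b = np.array([0, 0, 3, 1])
        comps = np.array([a, b] * 4)
        sim = g.carpet(comps)
        expected = np.fromfunction(lambda i, j: ((i + j) % 2 == 0) * 1.0, (8, 8))
        assert np.allclose(sim, expected)

    def test_single_generation_rejected(self):
        with pytest.raises(g.GardError):
            g.carpet(np.array([[1, 2]]))


class TestDetectComposomes:
    def test_constant_trace_is_one_episode(self):
        comps = np.tile([5, 3, 0, 2], (20, 1))
        eps = g.detect_composomes(comps, threshold=0.9, min_length=5)
        assert len(eps) == 1 and (eps[0].start, eps[0].end) == (0, 19)
        assert eps[0].min_similarity == pytest.approx(1.0)

    def test_iid_random_compositions_have_no_episodes(self, rng):
        # sparse random multisets over a large repertoire are nearly orthogonal
        comps = np.array([np.bincount(rng.integers(0, 400, 30), minlength=400)
                          for _ in range(60)])
        assert g.detect_composomes(comps, threshold=0.9, min_length=5) == []

    def test_planted_block_recovered_exactly(self):
        comps, (start, end) = g.planted_composome_trace(seed=4)
        eps = g.detect_composomes(comps, threshold=0.9, min_length=5)
        assert [(e.start, e.end) for e in eps] == [(start, end)]

    def test_centroid_mode_agrees_on_planted_fixture(self):
        comps, (start, end) = g.planted_composome_trace(seed=4)
        eps = g.detect_composomes(comps, threshold=0.9, min_length=5, mode="centroid")
        assert [(e.start, e.end) for e in eps] == [(start, end)]

    def test_threshold_validation(self, short_trace):
        with pytest.raises(g.GardError):
            g.detect_composomes(short_trace, threshold=1.5)


class TestClusterCompotypes:
    def _episode(self, comp, start=0, length=5):
        return g.Episode(start, start + length - 1, np.asarray(comp, float), 1.0)

    def test_identical_episodes_collapse_to_one(self):
        eps = [self._episode([4, 4, 0, 0], start=10 * k) for k in range(3)]
        cts = g.cluster_compotypes(eps, threshold=0.9, n_generations=30)
        assert len(cts) == 1
        assert cts[0].frequency == pytest.approx(15 / 30)

    def test_orthogonal_groups_make_two_compotypes(self):
        eps = [self._episode([4, 4, 0, 0], 0), self._episode([0, 0, 5, 1], 10),
               self._episode([8, 8, 0, 0], 20), self._episode([0, 0, 10, 2], 30)]
        cts = g.cluster_compotypes(eps, threshold=0.9, n_generations=40)
        assert len(cts) == 2
        assert all(len(ct.episodes) == 2 for ct in cts)

    def test_appending_a_centroid_copy_is_invariant(self):
        eps = [self._episode([4, 4, 0, 0], 0), self._episode([0, 0, 5, 1], 10)]
        cts = g.cluster_compotypes(eps, threshold=0.9, n_generations=20)
        clone = self._episode(cts[0].centroid * 100, start=40)
        cts2 = g.cluster_compotypes(eps + [clone], threshold=0.9, n_generations=20)
        assert len(cts2) == len(cts)
        assert np.allclose(cts2[0].centroid, cts[0].centroid)

    def test_empty_list_rejected(self):
        with pytest.raises(g.GardError):
            g.cluster_compotypes([])


class TestRepertoire:
    @pytest.mark.parametrize("x, expected", [
        (np.ones(30), 30), ([0, 7, 0], 1), ([3, 0, 1, 0], 2),
    ])
    def test_repertoire_size(self, x, expected):
        assert g.repertoire_size(x) == expected

    def test_random_assembly_moments_analytic(self):
        mean, std = g.expected_repertoire(100, 100)
        assert round(mean, 1) == 63.4 and round(std, 1) == 3.1

    def test_trivial_cases(self):
        mean1, std1 = g.expected_repertoire(1, 50)
        assert mean1 == pytest.approx(1.0) and std1 == pytest.approx(0.0, abs=1e-6)
        mean, std = g.expected_repertoire(2, 2)
        # four equally likely draws: D = 1,2,2,1 -> mean 1.5, std 0.5
        assert mean == pytest.approx(1.5) and std == pytest.approx(0.5)

    @pytest.mark.parametrize("n, ng", [(10, 10), (50, 200)])
    def test_moments_match_monte_carlo(self, n, ng, rng):
        draws = rng.integers(0, ng, size=(20_000, n))
        distinct = np.array([len(np.unique(row)) for row in draws])
        mean, std = g.expected_repertoire(n, ng)
        se = distinct.std() / np.sqrt(len(distinct))
        assert abs(distinct.mean() - mean) < 3 * se
        assert abs(distinct.std() - std) < 0.1 * std


class TestEntropy:
    def test_uniform_is_log_m(self):
        assert g.entropy([2, 2, 2, 0]) == pytest.approx(math.log(3))

    def test_single_type_is_zero(self):
        assert g.entropy([0, 9, 0]) == 0.0

    def test_hand_value_and_bits(self):
        assert g.entropy([3, 1]) == pytest.approx(0.5623, abs=1e-4)
        assert g.entropy([1, 1], base=2) == pytest.approx(1.0)

    def test_composomes_are_lower_entropy_than_random(self, default_params, rng):
        trace = g.run_trace(default_params, 300, seed=42)
        eps = g.detect_composomes(trace)
        assert eps, "no composome episodes in the default trace"
        episode_entropy = np.mean([
            g.entropy(trace.compositions[e.start:e.end + 1].mean(axis=0)) for e in eps
        ])
        random_entropy = np.mean([
            g.entropy(np.bincount(rng.integers(0, 100, 100), minlength=100))
            for _ in range(10_000)
        ])
        assert episode_entropy < random_entropy


class TestInformation:
    def test_known_counts(self):
        assert g.n_compositions(1, 77) == 77
        assert g.n_compositions(0, 5) == 1
        assert f"{g.n_compositions(100, 100):.1e}" == "4.5e+58"
        assert f"{g.n_compositions(36, 100):.1e}" == "7.7e+32"

    @given(st.integers(0, 6), st.integers(1, 6))
    def test_matches_brute_force_enumeration(self, n, ng):
        brute = sum(1 for _ in itertools.combinations_with_replacement(range(ng), n))
        assert g.n_compositions(n, ng) == brute

    def test_sequential_bits(self):
        assert g.information_bits(100, 2, "sequential") == 100.0

    @given(st.integers(1, 40), st.integers(1, 64))
    def test_compositional_never_exceeds_sequential(self, n, ng):
        assert (g.information_bits(n, ng, "compositional")
                <= g.information_bits(n, ng, "sequential") + 1e-9)

    def test_ratio_rises_with_repertoire(self):
        ratios = [g.information_bits(50, ng, "compositional")
                  / g.information_bits(50, ng, "sequential")
                  for ng in (4, 64, 1024, 4096)]
        assert all(a < b for a, b in zip(ratios, ratios[1:]))
        assert ratios[-1] > 0.6


class TestCanonicalComposome:
    def test_rank_one_closed_form(self):
        u, v = np.array([1.0, 2.0]), np.array([1.0, 1.0])
        vec = g.canonical_composome(np.outer(u, v))
        assert np.allclose(vec, [1 / 3, 2 / 3])

    def test_strictly_positive_output(self, small_beta):
        vec = g.canonical_composome(small_beta)
        assert np.all(vec > 0) and vec.sum() == pytest.approx(1.0)

    def test_permutation_equivariance(self, small_beta, rng):
        perm = rng.permutation(20)
        base = g.canonical_composome(small_beta)
        conj = g.canonical_composome(small_beta.values[np.ix_(perm, perm)])
        assert np.allclose(conj, base[perm])

    def test_degenerate_leading_pair_rejected(self):
        with pytest.raises(g.GardError):
            g.canonical_composome(np.array([[2.0, 0.0], [0.0, 2.0]]))

    def test_zero_row_warns(self):
        values = np.array([[0.0, 0.0], [1.0, 2.0]])
        with pytest.warns(RuntimeWarning):
            g.canonical_composome(values)


class TestEnantioMetrics:
    @pytest.fixture()
    def chiral3(self):
        return g.ChiralParameters(3)

    def test_racemic_is_self_antipodal(self, chiral3):
        x = np.array([2, 3, 1, 2, 3, 1])
        assert g.antipode_similarity_M(x, chiral3) == pytest.approx(1.0)
        assert g.enantiomeric_excess(x, chiral3) == 0.0

    def test_homochiral_extremes(self, chiral3):
        x = np.array([4, 1, 2, 0, 0, 0])
        assert g.antipode_similarity_M(x, chiral3) == 0.0
        assert g.enantiomeric_excess(x, chiral3) == 1.0

    def test_hand_values(self):
        chiral1 = g.ChiralParameters(1)
        assert g.antipode_similarity_M([3, 1], chiral1) == pytest.approx(0.6)
        assert g.enantiomeric_excess([3, 1], chiral1) == pytest.approx(0.5)

    def test_empty_assembly_rejected(self, chiral3):
        with pytest.raises(g.GardError):
            g.enantiomeric_excess(np.zeros(6), chiral3)
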