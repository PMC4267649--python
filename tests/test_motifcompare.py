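"""Motif similarity, Z-score calibration, distances and clustering."""

import math
from fractions import Fraction

import numpy as np
import pytest

from motifthread.errors import ComparisonError
from motifthread.fixtures import make_random_pwms
from motifthread.motifcompare import (ComparisonParams, ComparisonResult,
                                      DecoySet, _fisher_greater,
                                      benchmark_success, build_decoy_set,
                                      cut_clusters, fisher_slide_compare,
                                      reverse_complement_pwm,
                                      similarity_zscore, upgma_tree,
                                      z_to_distance)
from motifthread.motifgen import PWM


def point_mass(word: str) -> PWM:
    mat = np.zeros((len(word), 4))
    for i, c in enumerate(word):
        mat[i, "ACGT".index(c)] = 1.0
    return PWM(mat, name=word)


def hypergeom_tail_oracle(L: int, m: int) -> Fraction:
    """Exact one-sided tail of the 2x2 Fisher table by direct enumeration."""
    r = round(L / 4)
    K = m + r          # first-column total
    N = 2 * L          # grand total
    total = math.comb(N, L)
    acc = Fraction(0)
    for x in range(m, min(K, L) + 1):
        acc += Fraction(math.comb(K, x) * math.comb(N - K, L - x), total)
    return acc


class TestReverseComplement:
    def test_point_mass_probe(self):
        rc = reverse_complement_pwm(point_mass("TTAATGTGT"))
        assert rc.consensus() == "ACACATTAA"

    def test_involution(self):
        pwm = make_random_pwms(1, 6, seed=2)[0]
        back = reverse_complement_pwm(reverse_complement_pwm(pwm))
        assert np.array_equal(back.matrix, pwm.matrix)

    def test_uniform_unchanged(self):
        uni = PWM(np.full((4, 4), 0.25))
        assert np.array_equal(reverse_complement_pwm(uni).matrix, uni.matrix)


class TestFisherSlide:
    def test_identical_motifs_align_at_zero(self):
        pwm = point_mass("ACGGTCAT")
        r = fisher_slide_compare(pwm, pwm)
        assert (r.offset, r.strand, r.overlap) == (0, "+", 8)
        assert r.p_value == pytest.approx(float(hypergeom_tail_oracle(8, 8)))

    def test_six_of_eight_matches(self):
        a = point_mass("ACGGTCAT")
        b = point_mass("TCGGTCAG")  # differs at both ends
        r = fisher_slide_compare(a, b, exact_overlap=8)
        assert r.p_value == pytest.approx(849 / 12870)

    def test_reverse_complement_found_on_minus_strand(self):
        pwm = point_mass("ACGGTCAT")
        rc = reverse_complement_pwm(pwm)
        r_self = fisher_slide_compare(pwm, pwm)
        r_rc = fisher_slide_compare(pwm, rc)
        assert r_rc.p_value == r_self.p_value
        assert r_rc.strand == "-"

    def test_symmetric_in_best_p_for_equal_lengths(self):
        a, b = make_random_pwms(2, 7, seed=21)
        assert (fisher_slide_compare(a, b).p_value
                == pytest.approx(fisher_slide_compare(b, a).p_value))

    def test_too_short_rejected(self):
        with pytest.raises(ComparisonError):
            fisher_slide_compare(point_mass("AC"), point_mass("ACGT"))

    def test_exhaustive_hypergeometric_oracle(self):
        """Fisher tail equals direct hypergeometric enumeration, L <= 12."""
        for L in range(3, 13):
            for m in range(0, L + 1):
                assert _fisher_greater(L, m) == pytest.approx(
                    float(hypergeom_tail_oracle(L, m)), rel=1e-9)


class TestDecoySet:
    def test_duplicates_collapse(self):
        pwm = point_mass("ACGGTCAT")
        with pytest.warns(UserWarning):
            decoys = build_decoy_set([pwm, pwm])
        assert len(decoys) == 1

    def test_dissimilar_random_motifs_all_kept(self):
        params = ComparisonParams()
        motifs = make_random_pwms(12, 8, seed=31)
        decoys = build_decoy_set(motifs, params)
        # audit: every retained pair is non-redundant at the cutoff
        kept = decoys.motifs
        for i in range(len(kept)):
            for j in range(i + 1, len(kept)):
                p = fisher_slide_compare(kept[i], kept[j], params).p_value
                assert p >= params.decoy_redundancy_p

    def test_empty_input_rejected(self):
        with pytest.raises(ComparisonError):
            build_decoy_set([])


class TestZScore:
    @pytest.fixture()
    def decoys(self):
        return build_decoy_set(make_random_pwms(30, 8, seed=41))

    def test_null_mean_maps_to_zero(self, decoys):
        params = ComparisonParams()
        query = make_random_pwms(1, 8, seed=55)[0]
        xs = [-math.log10(r.p_value) for r in decoys.pair_results(params)
              if r.overlap == 8]
        assert len(xs) >= 8  # the null is taken at exactly this length
        result = ComparisonResult(offset=0, strand="+", overlap=8,
                                  p_value=10 ** (-np.mean(xs)))
        assert similarity_zscore(result, query, decoys,
                                 params) == pytest.approx(0.0, abs=1e-9)

    def test_extreme_z_capped_at_ten(self, decoys):
        query = make_random_pwms(1, 8, seed=66)[0]
        r = ComparisonResult(offset=0, strand="+", overlap=8, p_value=1e-30)
        z = similarity_zscore(r, query, decoys)  # raw z far above the cap
        assert z == 10.0

    def test_self_similarity_exceeds_success_threshold(self, decoys):
        params = ComparisonParams()
        query = make_random_pwms(1, 8, seed=77)[0]
        r = fisher_slide_compare(query, query, params)
        assert similarity_zscore(r, query, decoys, params) > params.z_success

    def test_degenerate_calibration_rejected(self):
        pwm = point_mass("ACGGTCAT")
        # three identical decoys: every null comparison has the same p,
        # so the decoy variance is exactly zero
        twin = point_mass("TACCGGAT")
        decoys = DecoySet([twin, twin, twin])
        r = fisher_slide_compare(pwm, pwm)
        with pytest.raises(ComparisonError, match="degenerate"):
            similarity_zscore(r, pwm, decoys)

    def test_monotone_in_p_value(self, decoys):
        query = make_random_pwms(1, 8, seed=88)[0]
        zs = []
        for p in (1e-6, 1e-4, 1e-2, 0.5):
            r = ComparisonResult(offset=0, strand="+", overlap=8, p_value=p)
            zs.append(similarity_zscore(r, query, decoys))
        assert zs == sorted(zs, reverse=True)


class TestDistanceTransform:
    @pytest.mark.parametrize("z,expected", [
        (10.0, 0.0), (2.0, 8 / 11.1), (-1.1, 1.0),
    ])
    def test_values(self, z, expected):
        assert z_to_distance(z) == pytest.approx(expected)

    def test_monotone_decreasing_in_z(self):
        zs = np.linspace(-1.1, 10.0, 20)
        ds = [z_to_distance(z) for z in zs]
        assert ds == sorted(ds, reverse=True)
        assert all(0 <= d <= 1 for d in ds)


class TestUpgma:
    def test_three_leaf_hand_case(self):
        d = np.array([[0.0, 0.2, 0.6], [0.2, 0.0, 0.6], [0.6, 0.6, 0.0]])
        tree = upgma_tree(d, ["A", "B", "C"])
        assert tree.height == pytest.approx(0.3)
        inner = next(c for c in tree.children if not c.is_leaf)
        assert inner.height == pytest.approx(0.1)
        assert set(inner.leaves()) == {"A", "B"}

    def test_two_leaves_join_at_half_distance(self):
        tree = upgma_tree(np.array([[0.0, 0.5], [0.5, 0.0]]), ["X", "Y"])
        assert tree.height == pytest.approx(0.25)

    def test_invalid_matrices_rejected(self):
        with pytest.raises(ValueError):
            upgma_tree(np.array([[0.0, 1.0], [2.0, 0.0]]), ["A", "B"])
        bad = np.array([[0.0, np.nan], [np.nan, 0.0]])
        with pytest.raises(ValueError):
            upgma_tree(bad, ["A", "B"])

    def test_newick_output_parses(self):
        import io

        from Bio import Phylo

        d = np.array([[0.0, 0.2, 0.6], [0.2, 0.0, 0.6], [0.6, 0.6, 0.0]])
        tree = upgma_tree(d, ["A", "B", "C"])
        parsed = Phylo.read(io.StringIO(tree.to_newick()), "newick")
        assert sorted(t.name for t in parsed.get_terminals()) == ["A", "B",
                                                                  "C"]

    def test_agrees_with_scipy_average_linkage(self):
        """Cophenetic heights match an independent UPGMA implementation."""
        from scipy.cluster.hierarchy import cophenet, linkage
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(17)
        for _ in range(20):
            cond = rng.uniform(0.1, 1.0, size=28)  # 8 leaves, distinct dists
            d = squareform(cond)
            labels = [f"L{i}" for i in range(8)]
            tree = upgma_tree(d, labels)

            def coph(tree, a, b, h=None):
                # height of the smallest subtree containing both leaves
                if a in tree.leaves() and b in tree.leaves():
                    for c in tree.children:
                        got = coph(c, a, b) if not c.is_leaf else None
                        if got is not None:
                            return got
                    return tree.height
                return None

            ref = squareform(cophenet(linkage(cond, method="average")))
            for i in range(8):
                for j in range(i + 1, 8):
                    mine = coph(tree, f"L{i}", f"L{j}")
                    assert 2 * mine == pytest.approx(ref[i, j], rel=1e-9)


class TestClusterCut:
    def _tree_from_z(self, z_matrix, labels):
        params = ComparisonParams()
        n = len(labels)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                if i != j:
                    d[i, j] = z_to_distance(z_matrix[i][j], params)
        return upgma_tree(d, labels)

    def test_all_similar_single_cluster(self):
        z = [[10, 5, 6], [5, 10, 7], [6, 7, 10]]
        tree = self._tree_from_z(z, ["a", "b", "c"])
        assert cut_clusters(tree) == [{"a", "b", "c"}]

    def test_all_dissimilar_singletons(self):
        z = [[10, -1, -0.5], [-1, 10, -0.9], [-0.5, -0.9, 10]]
        tree = self._tree_from_z(z, ["a", "b", "c"])
        clusters = {frozenset(c) for c in cut_clusters(tree)}
        assert clusters == {frozenset({"a"}), frozenset({"b"}),
                            frozenset({"c"})}

    def test_two_planted_families_recovered(self):
        labels = ["a1", "a2", "a3", "b1", "b2"]
        z = [[0.0] * 5 for _ in range(5)]
        for i in range(5):
            z[i][i] = 10.0
        for i, j in ((0, 1), (0, 2), (1, 2), (3, 4)):
            z[i][j] = z[j][i] = 8.0   # within-family: very similar
        for i in (0, 1, 2):
            for j in (3, 4):
                z[i][j] = z[j][i] = -1.0  # across families: dissimilar
        tree = self._tree_from_z(z, labels)
        clusters = sorted(cut_clusters(tree), key=len)
        assert clusters == [{"b1", "b2"}, {"a1", "a2", "a3"}]


class TestBenchmark:
    def test_perfect_predictions(self):
        decoys = build_decoy_set(make_random_pwms(30, 8, seed=41))
        pairs = [(m, m) for m in make_random_pwms(5, 8, seed=51)]
        assert benchmark_success(pairs, decoys) == 1.0

    def test_empty_pairs_rejected(self):
        decoys = build_decoy_set(make_random_pwms(10, 8, seed=41))
        with pytest.raises(ComparisonError):
            benchmark_success([], decoys)
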