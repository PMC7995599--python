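import math

import networkx as nx
import numpy as np
import pytest

from cemda.io import DAGCollection, DiseaseDAG, SimilarityMatrix
from cemda.similarity import (combined_semantic_similarity, d1_contributions,
                              d2_contributions, gaussian_profile_kernel,
                              integrate_similarity, semantic_similarity)
from cemda.synthetic import generate_dag_collection


def dag(target, edges):
    g = nx.DiGraph()
    g.add_node(target)
    g.add_edges_from(edges)
    return DiseaseDAG(target, g)


def brute_force_d1(d, target, children, delta):
    """Memoization-free exhaustive recursion of the attenuated contribution."""
    if d == target:
        return 1.0
    return max(delta * brute_force_d1(c, target, children, delta)
               for c in children[d])


class TestAttenuatedContributions:
    def test_target_alone(self):
        t = d1_contributions(dag("D", []))
        assert t.contributions == {"D": 1.0}
        assert t.semantic_value == 1.0

    def test_chain(self):
        t = d1_contributions(dag("D", [("A", "B"), ("B", "D")]), delta=0.5)
        assert t.contributions == {"D": 1.0, "B": 0.5, "A": 0.25}
        assert t.semantic_value == pytest.approx(1.75, abs=1e-15)

    def test_diamond_takes_max_over_children(self):
        edges = [("A", "B"), ("A", "C"), ("B", "D"), ("C", "D")]
        t = d1_contributions(dag("D", edges), delta=0.5)
        assert t.contributions["A"] == pytest.approx(0.25)
        assert t.semantic_value == pytest.approx(2.25)

    def test_delta_out_of_range(self):
        with pytest.raises(ValueError):
            d1_contributions(dag("D", []), delta=1.0)

    def test_matches_exhaustive_recursion_on_random_dags(self):
        checked = 0
        for seed in range(40):
            coll = generate_dag_collection(5, max_depth=4, branching=3,
                                           seed=seed)
            for disease in coll.diseases:
                g = coll[disease]
                children = {n: g.children(n) for n in g.nodes}
                table = d1_contributions(g, 0.5)
                for node in g.nodes:
                    ref = brute_force_d1(node, disease, children, 0.5)
                    assert abs(table.contributions[node] - ref) < 1e-12
                checked += 1
        assert checked == 200


class TestInformationContent:
    def test_node_in_all_dags_contributes_zero(self):
        coll = DAGCollection({f"D{i}": dag(f"D{i}", [("A", f"D{i}")])
                              for i in range(4)})
        assert d2_contributions(coll)["A"] == pytest.approx(0.0)

    def test_rare_node_natural_log(self):
        dags = {f"D{i}": dag(f"D{i}", []) for i in range(10)}
        coll = DAGCollection(dags)
        contrib = d2_contributions(coll)
        assert contrib["D0"] == pytest.approx(-math.log(0.1), abs=1e-12)

    def test_two_private_dags(self):
        coll = DAGCollection({"D1": dag("D1", []), "D2": dag("D2", [])})
        contrib = d2_contributions(coll)
        assert contrib["D1"] == contrib["D2"] == pytest.approx(math.log(2))


class TestSemanticSimilarity:
    def test_self_similarity_is_one(self):
        t = d1_contributions(dag("D", [("A", "D")]))
        assert semantic_similarity(t, t) == pytest.approx(1.0)

    def test_disjoint_is_zero(self):
        t1 = d1_contributions(dag("D1", []))
        t2 = d1_contributions(dag("D2", []))
        assert semantic_similarity(t1, t2) == 0.0

    def test_shared_root_cross_chain_is_one_third(self):
        t1 = d1_contributions(dag("D1", [("A", "D1")]), 0.5)
        t2 = d1_contributions(dag("D2", [("A", "D2")]), 0.5)
        assert semantic_similarity(t1, t2) == pytest.approx(1 / 3, abs=1e-15)

    def test_shared_ancestor_never_decreases_similarity(self):
        # adding a common ancestor on top of both DAGs cannot lower the score
        for seed in range(20):
            rngc = generate_dag_collection(2, max_depth=3, branching=2,
                                           seed=seed)
            d1, d2 = rngc.diseases
            t1 = d1_contributions(rngc[d1], 0.5)
            t2 = d1_contributions(rngc[d2], 0.5)
            before = semantic_similarity(t1, t2)
            g1 = rngc[d1].graph.copy()
            g2 = rngc[d2].graph.copy()
            for g, tgt in [(g1, d1), (g2, d2)]:
                roots = [n for n in g if g.in_degree(n) == 0]
                for r in roots:
                    g.add_edge("SHARED", r)
                if not roots:
                    g.add_edge("SHARED", tgt)
            a1 = d1_contributions(DiseaseDAG(d1, g1), 0.5)
            a2 = d1_contributions(DiseaseDAG(d2, g2), 0.5)
            assert semantic_similarity(a1, a2) >= before - 1e-12


class TestCombinedSemanticSimilarity:
    def test_average_of_variants_against_oracle(self):
        coll = generate_dag_collection(5, max_depth=4, branching=2, seed=7)
        ss = combined_semantic_similarity(coll, 0.5)
        diseases = coll.diseases
        shared = d2_contributions(coll)
        for i, di in enumerate(diseases):
            for j, dj in enumerate(diseases):
                if i == j:
                    assert ss.values[i, j] == 1.0
                    continue
                t1 = d1_contributions(coll[di], 0.5)
                t2 = d1_contributions(coll[dj], 0.5)
                s1 = semantic_similarity(t1, t2)
                ti = {d: shared[d] for d in coll[di].nodes}
                tj = {d: shared[d] for d in coll[dj].nodes}
                common = ti.keys() & tj.keys()
                num = sum(ti[d] + tj[d] for d in common)
                den = sum(ti.values()) + sum(tj.values())
                s2 = num / den if den else 0.0
                assert abs(ss.values[i, j] - (s1 + s2) / 2) < 1e-12

    def test_log_base_invariance_of_variant_two(self):
        """Changing the log base rescales contributions and semantic values
        identically, leaving the variant-2 similarity unchanged."""
        coll = generate_dag_collection(6, max_depth=3, branching=2, seed=3)
        shared = d2_contributions(coll)
        d1_, d2_ = coll.diseases[:2]
        for base_scale in (1.0, math.log2(math.e)):  # nat vs log2
            ti = {d: shared[d] * base_scale for d in coll[d1_].nodes}
            tj = {d: shared[d] * base_scale for d in coll[d2_].nodes}
            common = ti.keys() & tj.keys()
            num = sum(ti[d] + tj[d] for d in common)
            den = sum(ti.values()) + sum(tj.values())
            if base_scale == 1.0:
                ref = num / den
            else:
                assert num / den == pytest.approx(ref, abs=1e-12)


class TestGaussianKernel:
    def test_identical_profiles_similarity_one(self):
        prof = np.array([[1, 0, 1], [1, 0, 1]])
        k = gaussian_profile_kernel(prof, ["a", "b"])
        assert k.values[0, 1] == pytest.approx(1.0)

    def test_orthogonal_unit_profiles(self):
        prof = np.array([[1, 0], [0, 1]])
        k = gaussian_profile_kernel(prof, ["a", "b"], alpha0=1.0)
        assert k.values[0, 1] == pytest.approx(math.exp(-2), abs=1e-12)

    def test_symmetric_unit_diagonal_on_random_profiles(self, rng):
        prof = (rng.random((8, 6)) < 0.4).astype(float)
        prof[0] = 1  # guarantee a nonzero profile
        k = gaussian_profile_kernel(prof, [f"e{i}" for i in range(8)])
        np.testing.assert_allclose(k.values, k.values.T)
        np.testing.assert_allclose(np.diag(k.values), 1.0)
        assert k.values.min() >= 0 and k.values.max() <= 1

    def test_all_zero_profiles_error(self):
        with pytest.raises(ValueError, match="bandwidth"):
            gaussian_profile_kernel(np.zeros((3, 4)), list("abc"))


class TestIntegration:
    def _mats(self, rng):
        a = rng.random((3, 3))
        a = np.clip((a + a.T) / 2, 0, 1)
        np.fill_diagonal(a, 1)
        b = rng.random((3, 3))
        b = np.clip((b + b.T) / 2, 0, 1)
        np.fill_diagonal(b, 1)
        names = list("xyz")
        return SimilarityMatrix(names, a), SimilarityMatrix(names, b)

    def test_all_true_mask_gives_primary(self, rng):
        p, f = self._mats(rng)
        out = integrate_similarity(p, f, np.ones((3, 3), bool))
        np.testing.assert_array_equal(out.values, p.values)

    def test_all_false_mask_gives_fallback(self, rng):
        p, f = self._mats(rng)
        out = integrate_similarity(p, f, np.zeros((3, 3), bool))
        np.testing.assert_array_equal(out.values, f.values)

    def test_mixed_mask_elementwise(self, rng):
        p, f = self._mats(rng)
        mask = np.array([[1, 0, 1], [0, 1, 0], [1, 0, 1]], bool)
        out = integrate_similarity(p, f, mask)
        ref = np.where(mask, p.values, f.values)
        np.testing.assert_array_equal(out.values, ref)

    def test_shape_mismatch_errors(self, rng):
        p, f = self._mats(rng)
        with pytest.raises(ValueError):
            integrate_similarity(p, f, np.ones((2, 2), bool))
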