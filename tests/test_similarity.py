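import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pbmda.containers import AssociationMatrix, DiseaseDAG
from pbmda.similarity import (
    disease_semantic_similarity,
    gaussian_kernel_bandwidth,
    gaussian_kernel_matrix,
    integrate_similarity,
    semantic_contributions,
    semantic_similarity_matrix,
)
from conftest import toy_similarity


def dag(disease, edges, extra_terms=()):
    terms = {disease, *extra_terms, *(t for e in edges for t in e)}
    return DiseaseDAG(disease, frozenset(terms), frozenset(edges))


def brute_force_contribution(d: DiseaseDAG, term: str, delta: float) -> float:
    """Oracle: max over all child-ward term sequences of delta**steps."""
    if term == d.disease:
        return 1.0
    best = 0.0
    stack = [(term, 0)]
    while stack:
        node, depth = stack.pop()
        if node == d.disease:
            best = max(best, delta**depth)
            continue
        for c in d.children_of(node):
            stack.append((c, depth + 1))
    return best


def brute_force_ss(di, dj, delta):
    pi = {t: brute_force_contribution(di, t, delta) for t in di.terms}
    pj = {t: brute_force_contribution(dj, t, delta) for t in dj.terms}
    shared = set(pi) & set(pj)
    num = sum(pi[t] + pj[t] for t in shared)
    return num / (sum(pi.values()) + sum(pj.values()))


class TestSemanticContributions:
    def test_lone_disease(self):
        p = semantic_contributions(dag("A", []), 0.5)
        assert p.contributions == {"A": 1.0}
        assert p.semantic_value == 1.0

    def test_single_parent(self):
        p = semantic_contributions(dag("A", [("R", "A")]), 0.5)
        assert p.contributions == {"A": 1.0, "R": 0.5}
        assert p.semantic_value == 1.5

    def test_diamond_takes_max_path(self):
        # R is both a direct parent of A and a grandparent via B
        p = semantic_contributions(dag("A", [("R", "A"), ("R", "B"), ("B", "A")]), 0.5)
        assert p.contributions["R"] == 0.5  # max(0.5*1, 0.5*0.5)
        assert p.semantic_value == pytest.approx(2.0)

    @pytest.mark.parametrize("delta", [0.0, 1.0, -0.2, 1.5])
    def test_delta_out_of_range(self, delta):
        with pytest.raises(ValueError):
            semantic_contributions(dag("A", []), delta)

    def test_random_dags_match_path_enumeration_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            n_anc = int(rng.integers(1, 6))
            terms = ["D"] + [f"T{k}" for k in range(n_anc)]
            edges = set()
            # each ancestor parents at least one strictly later (closer to D) term
            for k in range(n_anc):
                lower = ["D"] + [f"T{j}" for j in range(k)]
                for child in rng.choice(lower, size=rng.integers(1, len(lower) + 1), replace=False):
                    edges.add((f"T{k}", str(child)))
            d = dag("D", sorted(edges))
            delta = float(rng.uniform(0.1, 0.9))
            p = semantic_contributions(d, delta)
            for t in terms:
                assert p.contributions[t] == pytest.approx(brute_force_contribution(d, t, delta))
            assert all(0 < c <= 1 for c in p.contributions.values())
            assert p.semantic_value >= 1.0


class TestDiseaseSemanticSimilarity:
    def test_identical_dags_give_one(self):
        p = semantic_contributions(dag("A", [("R", "A")]), 0.5)
        assert disease_semantic_similarity(p, p) == pytest.approx(1.0)

    def test_disjoint_dags_give_zero(self):
        pa = semantic_contributions(dag("A", [("R1", "A")]), 0.5)
        pb = semantic_contributions(dag("B", [("R2", "B")]), 0.5)
        assert disease_semantic_similarity(pa, pb) == 0.0

    def test_shared_root_third(self):
        pa = semantic_contributions(dag("A", [("R", "A")]), 0.5)
        pb = semantic_contributions(dag("B", [("R", "B")]), 0.5)
        assert disease_semantic_similarity(pa, pb) == pytest.approx(1 / 3)

    def test_mismatched_decay_rejected(self):
        pa = semantic_contributions(dag("A", []), 0.5)
        pb = semantic_contributions(dag("B", []), 0.4)
        with pytest.raises(ValueError):
            disease_semantic_similarity(pa, pb)

    def test_added_shared_ancestor_never_decreases_similarity(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            depth_a = int(rng.integers(1, 4))
            depth_b = int(rng.integers(1, 4))
            chain_a = [("R", "A")] + [(f"Xa{k+1}", f"Xa{k}" if k else "R") for k in range(depth_a - 1)]
            chain_b = [("R", "B")] + [(f"Xb{k+1}", f"Xb{k}" if k else "R") for k in range(depth_b - 1)]
            da, db = dag("A", chain_a), dag("B", chain_b)
            before = brute_force_ss(da, db, 0.5)
            # graft a fresh shared ancestor above the common root R of both
            da2 = dag("A", list(chain_a) + [("NEW", "R")])
            db2 = dag("B", list(chain_b) + [("NEW", "R")])
            after = disease_semantic_similarity(
                semantic_contributions(da2, 0.5), semantic_contributions(db2, 0.5)
            )
            assert after >= before - 1e-12
            assert after == pytest.approx(brute_force_ss(da2, db2, 0.5))


class TestSemanticSimilarityMatrix:
    def test_single_disease(self):
        m = semantic_similarity_matrix({"A": dag("A", [])})
        assert m.values.tolist() == [[1.0]]

    def test_pairwise_value(self):
        dags = {"A": dag("A", [("R", "A")]), "B": dag("B", [("R", "B")])}
        m = semantic_similarity_matrix(dags)
        assert m.values[0, 1] == pytest.approx(1 / 3)
        np.testing.assert_allclose(m.values, m.values.T)

    def test_disease_without_dag_uncovered(self):
        dags = {"A": dag("A", [])}
        m = semantic_similarity_matrix(dags, labels=["A", "B"])
        assert m.coverage[0, 0]
        assert not m.coverage[0, 1] and not m.coverage[1, 1]


class TestGaussianKernel:
    def _identity_Y(self):
        return AssociationMatrix(np.eye(2), ["m1", "m2"], ["d1", "d2"])

    def test_bandwidth_identity(self):
        assert gaussian_kernel_bandwidth(self._identity_Y(), "diseases") == pytest.approx(1.0)

    def test_bandwidth_all_ones(self):
        Y = AssociationMatrix(np.ones((3, 2)), ["m1", "m2", "m3"], ["d1", "d2"])
        assert gaussian_kernel_bandwidth(Y, "diseases") == pytest.approx(1 / 3)

    def test_bandwidth_linear_in_gamma_prime(self):
        assert gaussian_kernel_bandwidth(self._identity_Y(), "diseases", 2.0) == pytest.approx(2.0)

    def test_all_zero_Y_rejected(self):
        Y = AssociationMatrix(np.zeros((2, 2)), ["m1", "m2"], ["d1", "d2"])
        with pytest.raises(ValueError):
            gaussian_kernel_bandwidth(Y, "diseases")

    def test_kernel_identity_profiles(self):
        Y = AssociationMatrix(np.array([[1.0, 0.0], [1.0, 0.0]]), ["m1", "m2"], ["d1", "d2"])
        K = gaussian_kernel_matrix(Y, "miRNAs")
        assert K.values[0, 1] == pytest.approx(1.0)

    def test_kernel_identity_Y_value(self):
        K = gaussian_kernel_matrix(self._identity_Y(), "diseases")
        # gamma = 1, squared profile distance 2
        assert K.values[0, 1] == pytest.approx(np.exp(-2.0))
        assert np.diag(K.values).tolist() == [1.0, 1.0]

    def test_doubling_gamma_prime_squares_entries(self):
        K1 = gaussian_kernel_matrix(self._identity_Y(), "diseases", 1.0)
        K2 = gaussian_kernel_matrix(self._identity_Y(), "diseases", 2.0)
        np.testing.assert_allclose(K2.values[0, 1], K1.values[0, 1] ** 2)

    def test_kernel_decreasing_in_distance(self):
        Y = AssociationMatrix(
            np.array([[1, 1, 1, 0], [1, 1, 0, 0], [1, 0, 0, 0], [0, 0, 0, 0]], dtype=float),
            ["m1", "m2", "m3", "m4"],
            ["d1", "d2", "d3", "d4"],
        )
        K = gaussian_kernel_matrix(Y, "miRNAs").values
        # m1's profile distance grows from m2 to m3 to m4, so similarity falls
        assert K[0, 1] > K[0, 2] > K[0, 3]

    def test_zero_profile_row_still_defined(self):
        Y = AssociationMatrix(np.array([[1.0, 0.0], [0.0, 0.0]]), ["m1", "m2"], ["d1", "d2"])
        K = gaussian_kernel_matrix(Y, "miRNAs")
        assert np.isfinite(K.values).all()


class TestIntegrateSimilarity:
    def test_full_coverage_keeps_primary(self):
        prim = toy_similarity([[1.0, 0.2], [0.2, 1.0]], ["a", "b"], "FS")
        kern = toy_similarity([[1.0, 0.9], [0.9, 1.0]], ["a", "b"], "KM")
        out = integrate_similarity(prim, kern)
        np.testing.assert_allclose(out.values, prim.values)
        assert out.role == "Sm"

    def test_no_coverage_uses_kernel(self):
        prim = toy_similarity(np.eye(2), ["a", "b"], "FS", coverage=np.zeros((2, 2), bool))
        kern = toy_similarity([[1.0, 0.9], [0.9, 1.0]], ["a", "b"], "KD")
        out = integrate_similarity(prim, kern)
        np.testing.assert_allclose(out.values, kern.values)
        assert out.role == "Sd"

    def test_mixed_coverage_cellwise(self):
        cov = np.array([[True, True], [True, False]])
        prim = toy_similarity([[1.0, 0.3], [0.3, 0.0]], ["a", "b"], "FS", coverage=cov)
        kern = toy_similarity([[1.0, 0.9], [0.9, 1.0]], ["a", "b"], "KM")
        out = integrate_similarity(prim, kern)
        assert out.values[0, 1] == 0.3  # covered explicit value, even though low
        assert out.values[1, 1] == 1.0  # uncovered diagonal falls back to kernel

    def test_explicit_zero_kept_unless_nonzero_flag(self):
        prim = toy_similarity([[1.0, 0.0], [0.0, 1.0]], ["a", "b"], "FS")
        kern = toy_similarity([[1.0, 0.9], [0.9, 1.0]], ["a", "b"], "KM")
        assert integrate_similarity(prim, kern).values[0, 1] == 0.0
        assert integrate_similarity(prim, kern, coverage_from_nonzero=True).values[0, 1] == 0.9

    def test_idempotent(self):
        cov = np.array([[True, False], [False, True]])
        prim = toy_similarity(np.eye(2), ["a", "b"], "FS", coverage=cov)
        kern = toy_similarity([[1.0, 0.4], [0.4, 1.0]], ["a", "b"], "KM")
        once = integrate_similarity(prim, kern)
        twice = integrate_similarity(once, kern)
        np.testing.assert_array_equal(once.values, twice.values)

    def test_label_mismatch_rejected(self):
        prim = toy_similarity(np.eye(2), ["a", "b"], "FS")
        kern = toy_similarity(np.eye(2), ["a", "c"], "KM")
        with pytest.raises(ValueError):
            integrate_similarity(prim, kern)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    n=st.integers(2, 6),
    seed=st.integers(0, 10_000),
)
def test_kernel_matrix_invariants(n, seed):
    """Symmetry, unit diagonal, (0, 1] range for any non-empty binary Y."""
    rng = np.random.default_rng(seed)
    Y = (rng.random((n, n + 1)) < 0.4).astype(float)
    if Y.sum() == 0:
        Y[0, 0] = 1.0
    A = AssociationMatrix(Y, [f"m{i}" for i in range(n)], [f"d{j}" for j in range(n + 1)])
    for axis in ("miRNAs", "diseases"):
        K = gaussian_kernel_matrix(A, axis).values
        np.testing.assert_allclose(K, K.T, atol=1e-12)
        np.testing.assert_array_equal(np.diag(K), 1.0)
        assert (K > 0).all() and (K <= 1).all()
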