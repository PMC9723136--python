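import numpy as np
import pytest

from hyperbroad.exceptions import ValidationError
from hyperbroad.hypergraph import (
    Hypergraph,
    build_knn_hypergraph,
    degrees,
    ho_features,
    hypergraph_laplacian,
)


def edge_sets(hg):
    return [set(np.flatnonzero(hg.incidence[:, j]).tolist()) for j in range(hg.n_hyperedges)]


def full_hyperedge(n):
    """Single hyperedge containing all n vertices, encoded as n identical columns
    is not needed — use one column with k=n-1 semantics via a manual instance."""
    return Hypergraph(incidence=np.ones((n, 1)), weights=np.ones(1), k=n - 1)


def bruteforce_laplacian(hg):
    """Triple-loop accumulation of D_v - H W D_e^{-1} H^T."""
    h, w = hg.incidence, hg.weights
    m, me = h.shape
    d_v = np.array([sum(w[e] * h[i, e] for e in range(me)) for i in range(m)])
    d_e = np.array([sum(h[i, e] for i in range(m)) for e in range(me)])
    lap = np.diag(d_v).astype(float)
    for i in range(m):
        for j in range(m):
            for e in range(me):
                lap[i, j] -= h[i, e] * w[e] * h[j, e] / d_e[e]
    return lap


def test_1d_knn_example():
    hg = build_knn_hypergraph(np.array([[0.0], [1.0], [10.0], [11.0]]), k=1)
    assert edge_sets(hg) == [{0, 1}, {1, 0}, {2, 3}, {3, 2}]
    np.testing.assert_array_equal(hg.incidence.sum(axis=0), [2, 2, 2, 2])


def test_saturated_k_gives_all_ones_incidence():
    rng = np.random.default_rng(0)
    hg = build_knn_hypergraph(rng.standard_normal((6, 3)), k=5)
    np.testing.assert_array_equal(hg.incidence, np.ones((6, 6)))


def test_tie_break_lowest_index():
    # vertices 1 and 2 coincide; both are equidistant from 0 as well
    feats = np.array([[0.0], [1.0], [1.0], [5.0]])
    hg = build_knn_hypergraph(feats, k=1)
    sets = edge_sets(hg)
    assert sets[0] == {0, 1}  # 1 and 2 tie at distance 1; lowest index wins
    assert sets[1] == {1, 2}  # coincident points pick each other
    assert sets[2] == {2, 1}
    assert sets[3] == {3, 1}  # 1 and 2 tie at distance 4; lowest index wins


def test_k_out_of_range_and_nonfinite_rejected():
    feats = np.zeros((4, 2))
    with pytest.raises(ValidationError, match="k must be"):
        build_knn_hypergraph(feats, k=4)
    with pytest.raises(ValidationError, match="k must be"):
        build_knn_hypergraph(feats, k=0)
    feats[0, 0] = np.nan
    with pytest.raises(ValidationError, match="non-finite"):
        build_knn_hypergraph(feats, k=1)


def test_degrees_saturated_and_pair_cases():
    rng = np.random.default_rng(1)
    hg = build_knn_hypergraph(rng.standard_normal((5, 2)), k=4)
    d_v, d_e = degrees(hg)
    np.testing.assert_array_equal(d_v, np.full(5, 5.0))
    np.testing.assert_array_equal(d_e, np.full(5, 5.0))

    pair = build_knn_hypergraph(np.array([[0.0], [1.0], [10.0], [11.0]]), k=1)
    d_v, d_e = degrees(pair)
    np.testing.assert_array_equal(d_v, [2, 2, 2, 2])
    np.testing.assert_array_equal(d_e, [2, 2, 2, 2])


def test_doubling_weights_scales_vertex_degrees_only():
    hg = build_knn_hypergraph(np.random.default_rng(2).standard_normal((7, 3)), k=2)
    d_v, d_e = degrees(hg)
    hg2 = Hypergraph(incidence=hg.incidence, weights=2 * hg.weights, k=hg.k)
    d_v2, d_e2 = degrees(hg2)
    np.testing.assert_array_equal(d_v2, 2 * d_v)
    np.testing.assert_array_equal(d_e2, d_e)


def test_laplacian_annihilates_constants():
    rng = np.random.default_rng(3)
    hg = build_knn_hypergraph(rng.standard_normal((12, 4)), k=3)
    ho = hypergraph_laplacian(hg)
    np.testing.assert_allclose(ho.laplacian @ np.ones(12), 0.0, atol=1e-10)


def test_single_full_hyperedge_closed_form():
    n = 5
    ho = hypergraph_laplacian(full_hyperedge(n))
    expected = np.eye(n) - np.full((n, n), 1.0 / n)
    np.testing.assert_allclose(ho.laplacian, expected, atol=1e-12)
    eig = np.sort(np.linalg.eigvalsh(ho.laplacian))
    np.testing.assert_allclose(eig, [0.0] + [1.0] * (n - 1), atol=1e-12)


def test_two_pair_block_normalized_laplacian():
    hg = build_knn_hypergraph(np.array([[0.0], [1.0], [10.0], [11.0]]), k=1)
    ho = hypergraph_laplacian(hg)
    block = np.array([[0.5, -0.5], [-0.5, 0.5]])
    np.testing.assert_allclose(ho.laplacian_norm[:2, :2], block, atol=1e-12)
    np.testing.assert_allclose(ho.laplacian_norm[2:, 2:], block, atol=1e-12)
    np.testing.assert_allclose(ho.laplacian_norm[:2, 2:], 0.0, atol=1e-12)


def test_matrix_formula_equals_bruteforce_triple_loop():
    rng = np.random.default_rng(4)
    for m in (4, 6, 10):
        hg = build_knn_hypergraph(rng.standard_normal((m, 3)), k=min(3, m - 1))
        hg = Hypergraph(
            incidence=hg.incidence, weights=rng.uniform(0.5, 2.0, m), k=hg.k
        )
        ho = hypergraph_laplacian(hg)
        np.testing.assert_allclose(ho.laplacian, bruteforce_laplacian(hg), atol=1e-12)


def test_random_walk_operator_is_row_stochastic():
    rng = np.random.default_rng(5)
    hg = build_knn_hypergraph(rng.standard_normal((15, 4)), k=4)
    d_v, d_e = degrees(hg)
    h = hg.incidence
    p = (h * hg.weights / d_e) @ h.T / d_v[:, None]
    np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-10)


def test_degree_conservation_unit_weights():
    rng = np.random.default_rng(6)
    hg = build_knn_hypergraph(rng.standard_normal((20, 5)), k=4)
    d_v, d_e = degrees(hg)
    assert d_v.sum() == d_e.sum() == hg.incidence.sum()


def test_ho_features_full_hyperedge_quarter():
    ho = hypergraph_laplacian(full_hyperedge(4))
    fv = ho_features(ho)
    np.testing.assert_allclose(fv.values, np.full(6, 0.25), atol=1e-12)


def test_permuting_rois_permutes_features_consistently():
    rng = np.random.default_rng(7)
    feats = rng.standard_normal((8, 4))
    perm = rng.permutation(8)
    ho = hypergraph_laplacian(build_knn_hypergraph(feats, 2))
    ho_p = hypergraph_laplacian(build_knn_hypergraph(feats[perm], 2))
    np.testing.assert_allclose(ho_p.assoc, ho.assoc[np.ix_(perm, perm)], atol=1e-12)


def test_saturated_assoc_is_feature_independent():
    rng = np.random.default_rng(8)
    a = hypergraph_laplacian(build_knn_hypergraph(rng.standard_normal((6, 3)), 5)).assoc
    b = hypergraph_laplacian(build_knn_hypergraph(rng.uniform(size=(6, 9)), 5)).assoc
    np.testing.assert_allclose(a, b, atol=1e-12)


def test_incidence_invariants_enforced():
    with pytest.raises(ValidationError, match="k\\+1"):
        Hypergraph(incidence=np.eye(3), weights=np.ones(3), k=1)
    with pytest.raises(ValidationError, match="positive"):
        Hypergraph(incidence=np.ones((3, 1)), weights=np.zeros(1), k=2)
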