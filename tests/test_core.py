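"""DIME core: scoring, percentile membership, cluster ranking, networks."""

import numpy as np
import pytest

from dime.errors import DimeError
from dime import nmf
from dime.core import (
    DimeConfig,
    build_dime_network,
    extract_disease_matrix,
    prune_for_display,
    rank_clusters,
    run_dime,
    scale_scores,
    top_percentile_select,
)
from dime.io import DiseaseGeneNetwork, ImmunomeMatrix


def _net(genes, did="D1"):
    net = DiseaseGeneNetwork()
    for g in genes:
        net.add(did, did, g)
    return net


# ----------------------------------------------------------------- primitives


@pytest.mark.parametrize(
    "v,expected",
    [
        ([2, 4, 8], [0.25, 0.5, 1.0]),
        ([1, 1, 1], [1, 1, 1]),
        ([0, 0, 5], [0, 0, 1]),
    ],
)
def test_scale_scores(v, expected):
    assert np.allclose(scale_scores(np.array(v, dtype=float)), expected)


def test_scale_scores_zero_vector_errors():
    with pytest.raises(DimeError):
        scale_scores(np.zeros(3))


def test_top_percentile_interpolated_threshold():
    scores = {"a": 0.1, "b": 0.4, "c": 0.7, "d": 1.0}
    # q-quantile at h = 0.75*3 = 2.25 -> 0.7 + 0.25*(1.0-0.7) = 0.775
    assert top_percentile_select(scores, 0.75) == {"d"}


def test_top_percentile_all_equal_and_singleton():
    assert top_percentile_select({"a": 0.5, "b": 0.5}) == {"a", "b"}
    assert top_percentile_select({"only": 0.3}) == {"only"}


def test_top_percentile_never_empty():
    rng = np.random.default_rng(0)
    for _ in range(20):
        scores = {f"i{j}": float(v) for j, v in enumerate(rng.uniform(0, 1, 9))}
        assert top_percentile_select(scores)


def _fact(W, H):
    W = np.asarray(W, dtype=float)
    H = np.asarray(H, dtype=float)
    return nmf.Factorization(
        W=W, H=H, k=W.shape[1], seed=0,
        divergence_trace=[0.0], n_iter=0, converged=True,
    )


def test_rank_clusters_closed_form():
    f = _fact(np.array([[3.0], [4.0]]), np.array([[1.0, 2.0]]))
    [(idx, weight)] = rank_clusters(f)
    assert idx == 0
    assert weight == pytest.approx(5 * np.sqrt(5), abs=1e-12)


def test_rank_clusters_order_and_ties():
    W = np.array([[1.0, 2.0, 1.0], [0.0, 0.0, 0.0]])
    H = np.array([[1.0, 0.0], [1.0, 0.0], [1.0, 0.0]])
    ranked = rank_clusters(_fact(W, H))
    assert [i for i, _ in ranked] == [1, 0, 2]  # tie between 0 and 2 keeps 0 first


def test_rank_clusters_matches_bruteforce_oracle():
    rng = np.random.default_rng(4)
    for _ in range(50):
        m, n, k = rng.integers(2, 12, size=3)
        f = _fact(rng.uniform(0, 3, (m, k)), rng.uniform(0, 3, (k, n)))
        got = dict(rank_clusters(f))
        for i in range(k):
            brute = np.linalg.norm(np.outer(f.W[:, i], f.H[i, :]))
            assert got[i] == pytest.approx(brute, abs=1e-10)


def test_decomposition_identity():
    rng = np.random.default_rng(9)
    f = _fact(rng.uniform(0, 2, (6, 3)), rng.uniform(0, 2, (3, 5)))
    total = sum(np.outer(f.W[:, i], f.H[i, :]) for i in range(3))
    assert np.allclose(total, f.W @ f.H, atol=1e-10)


# ------------------------------------------------------------- disease matrices


def test_extract_disease_matrix(small_immunome):
    dm = extract_disease_matrix(small_immunome, _net({"g1", "g3", "gX"}), "D1", min_genes=2)
    assert dm.gene_ids == ["g1", "g3"]  # immunome order preserved
    assert dm.n_dropped_genes == 1
    assert np.allclose(dm.values, small_immunome.values[[1, 3], :])


def test_extract_too_few_genes(small_immunome):
    with pytest.raises(DimeError, match="too few"):
        extract_disease_matrix(small_immunome, _net({"g1", "g2"}), "D1", min_genes=15)


def test_extract_unknown_disease(small_immunome):
    with pytest.raises(DimeError):
        extract_disease_matrix(small_immunome, _net({"g1"}), "D9")


# ------------------------------------------------------------------- run_dime


def test_run_dime_deterministic(bench):
    imm, gt, net = bench
    cfg = DimeConfig(n_restarts=3, n_runs_consensus=4, k_max=3)
    a = run_dime(imm, net, "D1", seed=7, config=cfg)
    b = run_dime(imm, net, "D1", seed=7, config=cfg)
    assert a.to_json() == b.to_json()


def test_run_dime_k1_single_cluster(bench):
    imm, gt, net = bench
    res = run_dime(imm, net, "D1", k=1, seed=0, config=DimeConfig(n_restarts=2))
    assert res.k == 1
    (c,) = res.clusters
    assert c.rank == 1
    assert max(c.dac_scores.values()) == 1.0
    assert max(c.dag_scores.values()) == 1.0
    assert c.top_dacs and c.top_dags


def test_run_dime_invariant_under_cluster_relabeling(bench_result):
    """Rank order and top sets are a function of the factorization only up
    to cluster relabeling."""
    res = bench_result
    f = res.factorization
    perm = list(reversed(range(f.k)))
    shuffled = nmf.Factorization(
        W=f.W[:, perm], H=f.H[perm, :], k=f.k, seed=f.seed,
        divergence_trace=f.divergence_trace, n_iter=f.n_iter, converged=f.converged,
    )
    ranked_orig = [w for _, w in rank_clusters(f)]
    ranked_perm = [w for _, w in rank_clusters(shuffled)]
    assert np.allclose(ranked_orig, ranked_perm)


def test_run_dime_recovers_planted_modules(bench, bench_result):
    imm, gt, net = bench
    res = bench_result
    assert res.k == 2
    # the top (rank-1) cluster is the stronger planted module
    assert res.top_cluster.top_dacs == gt.module_cells("M1")
    assert res.top_cluster.top_dags == gt.module_genes("M1")
    assert res.clusters[1].top_dacs == gt.module_cells("M2")


# ------------------------------------------------------------------- networks


def test_build_network_complete_bipartite(bench, bench_result):
    imm, gt, net = bench
    nw = build_dime_network(bench_result, imm)
    for c in bench_result.clusters:
        edges = [e for e in nw.edges if e.cluster_rank == c.rank]
        assert len(edges) == len(c.top_dacs) * len(c.top_dags)
        assert {e.cell for e in edges} == c.top_dacs
        assert {e.gene for e in edges} == c.top_dags


def test_prune_for_display_cap_and_expression(bench, bench_result):
    imm, gt, net = bench
    nw = build_dime_network(bench_result, imm)
    pruned = prune_for_display(nw, imm, max_dags=10, min_expression=0.0)
    for rank in {e.cluster_rank for e in pruned.edges}:
        genes = {e.gene for e in pruned.edges if e.cluster_rank == rank}
        assert len(genes) <= 10
    # planted module genes sit near 7; a sky-high threshold drops everything
    assert prune_for_display(nw, imm, min_expression=100.0).edges == []
    # permissive limits leave the network unchanged
    same = prune_for_display(nw, imm, max_dags=10_000, min_expression=-1.0)
    assert set(same.edges) == set(nw.edges)
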