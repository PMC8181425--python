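"""KL-NMF engine: divergence, updates, consensus, model-order selection."""

import numpy as np
import pytest

from dime.errors import DimeError, UsageError
from dime import nmf
from dime.nmf import (
    connectivity_matrix,
    consensus_cophenetic,
    cophenetic_profile,
    kl_divergence,
    nmf_kl,
    select_k,
)


# ----------------------------------------------------------------- divergence


def test_kl_zero_iff_equal():
    X = np.array([[1.0, 2.0], [0.5, 3.0]])
    assert kl_divergence(X, X) == pytest.approx(0.0, abs=1e-12)


def test_kl_scalar_value():
    # 1*log(1/2) - 1 + 2 = 1 - ln 2
    assert kl_divergence([[1.0]], [[2.0]]) == pytest.approx(1 - np.log(2))


def test_kl_zero_entry_convention():
    # 0*log0 = 0, so D = 0 - 0 + 0.5
    assert kl_divergence([[0.0]], [[0.5]]) == pytest.approx(0.5)


def test_kl_shape_mismatch():
    with pytest.raises(DimeError):
        kl_divergence(np.ones((2, 2)), np.ones((2, 3)))


# ------------------------------------------------------------------ factorization


def test_rank1_exact_recovery():
    rng = np.random.default_rng(7)
    w = rng.uniform(0.5, 2.0, size=8)
    h = rng.uniform(0.5, 2.0, size=5)
    X = np.outer(w, h)
    f = nmf_kl(X, 1, seed=0)
    assert f.divergence < 1e-6
    rel = np.linalg.norm(X - f.W @ f.H) / np.linalg.norm(X)
    assert rel < 1e-3


def test_constant_matrix_rank1():
    X = np.full((6, 4), 3.0)
    f = nmf_kl(X, 1, seed=1)
    assert np.allclose(f.W @ f.H, X, rtol=1e-4)


@pytest.mark.parametrize("seed", range(5))
@pytest.mark.parametrize("k", [2, 3])
def test_trace_monotone_and_nonnegative(seed, k):
    rng = np.random.default_rng(seed)
    X = rng.uniform(0.1, 5.0, size=(30, 12))
    f = nmf_kl(X, k, seed=seed)
    trace = np.asarray(f.divergence_trace)
    assert len(trace) == f.n_iter + 1
    assert np.all(np.diff(trace) <= 1e-9)
    assert (f.W >= 0).all() and (f.H >= 0).all()


def test_k_out_of_range():
    X = np.ones((4, 3)) + np.eye(4, 3)
    with pytest.raises(UsageError):
        nmf_kl(X, 5, seed=0)


def test_zero_row_rejected():
    X = np.ones((4, 3))
    X[2] = 0
    with pytest.raises(DimeError, match="2"):
        nmf_kl(X, 2, seed=0)


def test_cross_check_against_reference_nmf():
    """Final divergence within 5% of scikit-learn's KL-NMF on random data."""
    from sklearn.decomposition import NMF

    rng = np.random.default_rng(11)
    for trial in range(10):
        X = rng.uniform(0.1, 4.0, size=(20, 10))
        k = 2 + trial % 2
        ours = min(nmf_kl(X, k, seed=s).divergence for s in range(5))
        ref_model = NMF(
            n_components=k, solver="mu", beta_loss="kullback-leibler",
            init="random", random_state=0, max_iter=2000, tol=1e-6,
        )
        Wr = ref_model.fit_transform(X)
        ref = kl_divergence(X, Wr @ ref_model.components_)
        # no worse than the reference optimum by more than 5% (better is fine)
        assert ours <= ref * 1.05


# ------------------------------------------------------------------- consensus


def test_connectivity_identity_and_ones():
    f = nmf.Factorization(
        W=np.ones((3, 2)), H=np.array([[1.0, 0.0], [0.0, 1.0]]),
        k=2, seed=0, divergence_trace=[0.0], n_iter=0, converged=True,
    )
    assert np.array_equal(connectivity_matrix(f), np.eye(2))
    f.H = np.array([[0.9, 0.8], [0.1, 0.2]])
    assert np.array_equal(connectivity_matrix(f), np.ones((2, 2)))


def test_connectivity_tie_goes_to_first_cluster():
    f = nmf.Factorization(
        W=np.ones((3, 2)), H=np.array([[0.5, 0.9], [0.5, 0.1]]),
        k=2, seed=0, divergence_trace=[0.0], n_iter=0, converged=True,
    )
    # tie column 0 -> cluster 0, same as column 1
    assert np.array_equal(connectivity_matrix(f), np.ones((2, 2)))


def test_consensus_identical_runs_binary():
    rng = np.random.default_rng(2)
    X = np.block([
        [rng.uniform(4, 5, (6, 4)), rng.uniform(0.1, 0.3, (6, 4))],
        [rng.uniform(0.1, 0.3, (6, 4)), rng.uniform(4, 5, (6, 4))],
    ])
    res = consensus_cophenetic(X, 2, n_runs=5, base_seed=0)
    assert res.consensus.shape == (8, 8)
    assert np.allclose(res.consensus, res.consensus.T)
    assert np.allclose(np.diag(res.consensus), 1.0)
    # well-separated blocks: perfectly stable clustering
    assert np.all((res.consensus == 0) | (res.consensus == 1))
    assert res.cophenetic == pytest.approx(1.0, abs=1e-12)


def test_consensus_needs_k_and_runs():
    X = np.ones((4, 4)) + np.eye(4)
    with pytest.raises(UsageError):
        consensus_cophenetic(X, 1, n_runs=5)
    with pytest.raises(UsageError):
        consensus_cophenetic(X, 2, n_runs=1)


def test_planted_two_blocks_prefers_k2():
    rng = np.random.default_rng(5)
    X = np.block([
        [rng.uniform(5, 6, (15, 6)), rng.uniform(0.2, 0.6, (15, 6))],
        [rng.uniform(0.2, 0.6, (15, 6)), rng.uniform(5, 6, (15, 6))],
    ])
    prof = cophenetic_profile(X, k_range=[2, 4], n_runs=10, base_seed=3)
    assert prof[2] >= prof[4]
    assert select_k(X, k_range=[2, 3, 4], n_runs=10, base_seed=3) == 2


def test_select_k_infeasible_range():
    X = np.ones((3, 3)) + np.eye(3)
    with pytest.raises(UsageError):
        select_k(X, k_range=[5], n_runs=3)
    with pytest.raises(UsageError):
        select_k(X, k_range=[], n_runs=3)
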