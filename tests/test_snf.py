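import math

import numpy as np
import pytest

from scsnf.snf import (
    SNFParams,
    affinity_from_distance,
    full_normalize,
    fuse_dataset,
    knn_normalize,
    pairwise_distance,
    snf_fuse,
)


def brute_distance(X):
    n = X.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            D[i, j] = math.sqrt(sum((X[i, k] - X[j, k]) ** 2 for k in range(X.shape[1])))
    return D


def brute_kernel(D, K, mu):
    """Straight-line transcription of the scaled exponential kernel."""
    n = D.shape[0]
    W = np.zeros((n, n))
    means = []
    for i in range(n):
        row = sorted(D[i])[1 : K + 1]
        means.append(sum(row) / K)
    for i in range(n):
        for j in range(n):
            eps = (means[i] + means[j] + D[i, j]) / 3.0
            W[i, j] = math.exp(-D[i, j] ** 2 / (2.0 * (mu * eps) ** 2))
    return (W + W.T) / 2.0


def brute_full_normalize(W):
    n = W.shape[0]
    P = np.zeros_like(W)
    for i in range(n):
        rowsum = sum(W[i, j] for j in range(n) if j != i)
        for j in range(n):
            P[i, j] = 0.5 if i == j else W[i, j] / (2 * rowsum)
    return P


def brute_knn_normalize(W, K):
    n = W.shape[0]
    S = np.zeros_like(W)
    for i in range(n):
        neighbours = sorted(
            (j for j in range(n) if j != i), key=lambda j: (-W[i, j], j)
        )[:K]
        total = sum(W[i, j] for j in neighbours)
        for j in neighbours:
            S[i, j] = W[i, j] / total
    return S


def brute_fuse(Ps, Ss, T):
    """Independent transcription of the cross-diffusion update."""
    status = [P.copy() for P in Ps]
    v = len(status)
    for _ in range(T):
        new = []
        for i in range(v):
            avg = sum(status[j] for j in range(v) if j != i) / (v - 1)
            M = Ss[i] @ avg @ Ss[i].T
            M = (M + M.T) / 2.0
            new.append(brute_full_normalize(M))
        status = new
    fused = sum(status) / v
    return (fused + fused.T) / 2.0


def random_pair(n, f, seed, params):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, f))
    D = pairwise_distance(X)
    W = affinity_from_distance(D, params)
    return W, full_normalize(W), knn_normalize(W, params.K_nn)


class TestPairwiseDistance:
    def test_identical_rows_zero(self):
        X = np.array([[1.0, 2.0], [1.0, 2.0]])
        assert pairwise_distance(X)[0, 1] == 0.0

    def test_3_4_5(self):
        X = np.array([[0.0, 0.0], [3.0, 4.0]])
        assert pairwise_distance(X)[0, 1] == pytest.approx(5.0)

    def test_matches_brute_force(self, rng):
        X = rng.normal(size=(5, 4))
        np.testing.assert_allclose(pairwise_distance(X), brute_distance(X), atol=1e-12)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            pairwise_distance(np.empty((0, 3)))


class TestAffinityKernel:
    def test_zero_distance_gives_one(self, rng):
        X = rng.normal(size=(5, 3))
        X[1] = X[0]
        W = affinity_from_distance(pairwise_distance(X), SNFParams(K_nn=2))
        assert W[0, 1] == pytest.approx(1.0)
        assert np.allclose(np.diag(W), 1.0)

    @pytest.mark.parametrize("mu", [0.3, 0.5, 0.8])
    def test_matches_brute_force_six_subjects(self, rng, mu):
        D = pairwise_distance(rng.normal(size=(6, 4)))
        params = SNFParams(K_nn=2, mu=mu)
        np.testing.assert_allclose(
            affinity_from_distance(D, params), brute_kernel(D, 2, mu), atol=1e-12
        )

    def test_hand_computed_four_subjects(self):
        # distances: chain 0-1-2-3 with hand-set values, K_nn=1
        D = np.array(
            [
                [0.0, 1.0, 2.0, 3.0],
                [1.0, 0.0, 1.0, 2.0],
                [2.0, 1.0, 0.0, 1.0],
                [3.0, 2.0, 1.0, 0.0],
            ]
        )
        params = SNFParams(K_nn=1, mu=0.5)
        # nearest-neighbour means are all 1; eps(0,1) = (1+1+1)/3 = 1
        # W(0,1) = exp(-1 / (2*0.25)) = exp(-2)
        W = affinity_from_distance(D, params)
        assert W[0, 1] == pytest.approx(math.exp(-2.0), abs=1e-10)
        # eps(0,2) = (1+1+2)/3 = 4/3; W(0,2) = exp(-4/(2*(0.5*4/3)^2))
        assert W[0, 2] == pytest.approx(math.exp(-4.0 / (2 * (2.0 / 3.0) ** 2)), abs=1e-10)

    def test_identical_subjects_error(self):
        D = np.zeros((3, 3))
        with pytest.raises(ValueError, match="jitter|duplicate"):
            affinity_from_distance(D, SNFParams(K_nn=1))


class TestNormalizations:
    def test_P_rows_sum_one_diag_half(self, rng):
        W, P, _ = random_pair(8, 5, 0, SNFParams(K_nn=3))
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-10)
        np.testing.assert_array_equal(np.diag(P), 0.5)

    def test_S_rows_sum_one(self, rng):
        _, _, S = random_pair(8, 5, 1, SNFParams(K_nn=3))
        np.testing.assert_allclose(S.sum(axis=1), 1.0, atol=1e-10)

    def test_knn_full_limit_is_offdiag_row_normalization(self, rng):
        W, _, _ = random_pair(6, 4, 2, SNFParams(K_nn=2))
        S = knn_normalize(W, 5)  # K = n-1
        off = W - np.diag(np.diag(W))
        expected = off / off.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(S, expected, atol=1e-12)

    def test_matches_hand_transcription(self, rng):
        W, P, S = random_pair(4, 3, 3, SNFParams(K_nn=2))
        np.testing.assert_allclose(P, brute_full_normalize(W), atol=1e-12)
        np.testing.assert_allclose(S, brute_knn_normalize(W, 2), atol=1e-12)


class TestFusion:
    def make_inputs(self, n=6, seeds=(0, 1), K=2):
        params = SNFParams(K_nn=K, mu=0.5, T=2)
        Ps, Ss = [], []
        for s in seeds:
            _, P, S = random_pair(n, 4, s, params)
            Ps.append(P)
            Ss.append(S)
        return Ps, Ss, params

    def test_matches_transcription_oracle(self):
        Ps, Ss, params = self.make_inputs()
        fused = snf_fuse(Ps, Ss, params)
        np.testing.assert_allclose(fused.matrix, brute_fuse(Ps, Ss, params.T), atol=1e-8)

    def test_three_modalities_match_transcription(self):
        Ps, Ss, params = self.make_inputs(n=7, seeds=(0, 1, 2), K=3)
        fused = snf_fuse(Ps, Ss, params)
        np.testing.assert_allclose(fused.matrix, brute_fuse(Ps, Ss, params.T), atol=1e-8)

    def test_two_modality_T1_closed_form(self):
        Ps, Ss, _ = self.make_inputs()
        params = SNFParams(K_nn=2, mu=0.5, T=1)
        fused = snf_fuse(Ps, Ss, params)

        def step(S, P):
            M = S @ P @ S.T
            return brute_full_normalize((M + M.T) / 2.0)

        closed = (step(Ss[0], Ps[1]) + step(Ss[1], Ps[0])) / 2.0
        closed = (closed + closed.T) / 2.0
        np.testing.assert_allclose(fused.matrix, closed, atol=1e-10)

    def test_symmetric_nonnegative_finite(self):
        Ps, Ss, params = self.make_inputs(n=10, K=3)
        fused = snf_fuse(Ps, Ss, params).matrix
        np.testing.assert_allclose(fused, fused.T, atol=1e-10)
        assert np.all(fused >= 0) and np.all(np.isfinite(fused))

    def test_modality_order_invariance(self):
        Ps, Ss, params = self.make_inputs(n=8, seeds=(0, 1, 2), K=3)
        f1 = snf_fuse(Ps, Ss, params).matrix
        f2 = snf_fuse(Ps[::-1], Ss[::-1], params).matrix
        np.testing.assert_allclose(f1, f2, atol=1e-10)

    def test_permutation_equivariance(self, rng):
        params = SNFParams(K_nn=3, mu=0.5, T=3)
        X1, X2 = rng.normal(size=(10, 5)), rng.normal(size=(10, 4))
        perm = rng.permutation(10)

        def fuse(Xa, Xb):
            Ps, Ss = [], []
            for X in (Xa, Xb):
                W = affinity_from_distance(pairwise_distance(X), params)
                Ps.append(full_normalize(W))
                Ss.append(knn_normalize(W, params.K_nn))
            return snf_fuse(Ps, Ss, params).matrix

        fused = fuse(X1, X2)
        fused_perm = fuse(X1[perm], X2[perm])
        np.testing.assert_allclose(fused_perm, fused[np.ix_(perm, perm)], atol=1e-8)

    def test_dimension_mismatch(self):
        Ps, Ss, params = self.make_inputs()
        Ps[1] = np.eye(5)
        with pytest.raises(ValueError, match="mismatch"):
            snf_fuse(Ps, Ss, params)

    def test_noise_plus_structured_modality_keeps_blocks(self):
        # one modality pure noise, one with two clean blocks: the fused
        # network must keep within-block similarity above between-block
        margins = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            labels = np.repeat([0, 1], 10)
            signal = labels[:, None] * 3.0 + rng.normal(size=(20, 6))
            noise = rng.normal(size=(20, 6))
            params = SNFParams(K_nn=4, mu=0.5, T=5)
            Ps, Ss = [], []
            for X in (signal, noise):
                W = affinity_from_distance(pairwise_distance(X), params)
                Ps.append(full_normalize(W))
                Ss.append(knn_normalize(W, params.K_nn))
            fused = snf_fuse(Ps, Ss, params).matrix
            off = ~np.eye(20, dtype=bool)
            same = labels[:, None] == labels[None, :]
            margins.append(fused[same & off].mean() - fused[~same].mean())
        assert min(margins) > 0
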