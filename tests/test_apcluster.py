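"""Affinity propagation: preference semantics, agreement with the exact
brute-force oracle, planted-structure recovery and invariances."""

import numpy as np
import pytest
from sklearn.cluster import AffinityPropagation as SKAffinityPropagation
from sklearn.metrics import adjusted_rand_score

from traitatlas import (
    APParams,
    ValidationError,
    affinity_propagation,
    agglomerate_exemplars,
    brute_force_exemplars,
    set_preference,
)


def _sym(rng, n, low=0.0, high=1.0):
    a = rng.uniform(low, high, size=(n, n))
    a = (a + a.T) / 2
    return a


class TestSetPreference:
    def test_constant_offdiag(self):
        S = np.full((4, 4), 0.7)
        for q in (0.0, 0.3, 1.0):
            assert np.allclose(np.diag(set_preference(S, q)), 0.7)

    def test_median_of_binary(self):
        S = np.array([[9.0, 0.0], [1.0, 9.0]])
        assert set_preference(S, 0.5)[0, 0] == pytest.approx(0.5)

    def test_quantile_endpoints(self):
        rng = np.random.default_rng(0)
        S = _sym(rng, 6)
        off = S[~np.eye(6, dtype=bool)]
        assert np.diag(set_preference(S, 0.0))[0] == pytest.approx(off.min())
        assert np.diag(set_preference(S, 1.0))[0] == pytest.approx(off.max())

    def test_empty_errors(self):
        with pytest.raises(ValidationError):
            set_preference(np.empty((0, 0)), 0.5)


class TestAffinityPropagation:
    def test_single_item(self):
        res = affinity_propagation(np.array([[0.5]]))
        assert res.n_clusters == 1 and res.exemplars[0] == "0"

    def test_two_block_toy_matches_oracle(self):
        # 4 items: two tight pairs, preference 0.5
        S = np.full((4, 4), 0.1)
        S[0, 1] = S[1, 0] = S[2, 3] = S[3, 2] = 0.9
        np.fill_diagonal(S, 0.5)
        res = affinity_propagation(S, APParams(seed=0))
        oracle = brute_force_exemplars(S)
        assert res.n_clusters == 2
        assert res.labels["0"] == res.labels["1"]
        assert res.labels["2"] == res.labels["3"]
        assert res.net_similarity == pytest.approx(oracle.net_similarity)

    def test_near_optimal_on_random_instances(self):
        rng = np.random.default_rng(100)
        hits = 0
        for _ in range(30):
            n = int(rng.integers(3, 9))
            S = set_preference(_sym(rng, n), 0.5)
            ap = affinity_propagation(S, APParams(seed=1))
            opt = brute_force_exemplars(S)
            assert ap.net_similarity <= opt.net_similarity + 1e-9
            if ap.net_similarity >= 0.95 * opt.net_similarity:
                hits += 1
        assert hits >= 27

    def test_planted_blocks_recovered(self):
        rng = np.random.default_rng(5)
        n, k = 100, 5
        blocks = np.arange(n) % k
        S = np.where(
            blocks[:, None] == blocks[None, :],
            rng.uniform(0.75, 0.85, (n, n)),
            rng.uniform(0.05, 0.15, (n, n)),
        )
        S = (S + S.T) / 2
        res = affinity_propagation(set_preference(S, 0.5), APParams(seed=2))
        labels = [res.labels[str(i)] for i in range(n)]
        assert adjusted_rand_score(blocks, labels) >= 0.9

    def test_seeded_determinism(self):
        rng = np.random.default_rng(9)
        S = set_preference(_sym(rng, 20), 0.5)
        r1 = affinity_propagation(S, APParams(seed=4))
        r2 = affinity_propagation(S, APParams(seed=4))
        assert r1.labels == r2.labels and r1.exemplars == r2.exemplars

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(21)
        S = set_preference(_sym(rng, 12), 0.5)
        perm = rng.permutation(12)
        res = affinity_propagation(S, APParams(jitter_scale=0.0))
        res_p = affinity_propagation(S[np.ix_(perm, perm)], APParams(jitter_scale=0.0))
        base = [res.labels[str(i)] for i in perm]
        permuted = [res_p.labels[str(j)] for j in range(12)]
        assert adjusted_rand_score(base, permuted) == pytest.approx(1.0)

    def test_beats_singleton_solution(self):
        rng = np.random.default_rng(33)
        for seed in range(5):
            S = set_preference(_sym(np.random.default_rng(seed), 15), 0.5)
            res = affinity_propagation(S, APParams(seed=seed))
            singleton_net = float(np.trace(S))
            assert res.net_similarity >= singleton_net - 1e-9

    def test_cluster_count_monotone_in_q(self):
        counts_low, counts_high = [], []
        for seed in range(20):
            S = _sym(np.random.default_rng(seed), 30)
            counts_low.append(
                affinity_propagation(set_preference(S, 0.1), APParams(seed=0)).n_clusters
            )
            counts_high.append(
                affinity_propagation(set_preference(S, 0.9), APParams(seed=0)).n_clusters
            )
        assert np.median(counts_high) >= np.median(counts_low)

    def test_agreement_with_reference_implementation(self):
        """Cross-check against an independent AP implementation on
        well-separated data."""
        rng = np.random.default_rng(8)
        n, k = 60, 3
        blocks = np.arange(n) % k
        S = np.where(
            blocks[:, None] == blocks[None, :],
            rng.uniform(0.8, 0.9, (n, n)),
            rng.uniform(0.0, 0.1, (n, n)),
        )
        S = (S + S.T) / 2
        pref = set_preference(S, 0.5)
        ours = affinity_propagation(pref, APParams(seed=0))
        sk = SKAffinityPropagation(
            affinity="precomputed", damping=0.9, max_iter=1000, random_state=0
        ).fit(np.where(np.eye(n, dtype=bool), pref.diagonal(), S))
        labels = [ours.labels[str(i)] for i in range(n)]
        assert adjusted_rand_score(labels, sk.labels_) == pytest.approx(1.0)


class TestBruteForce:
    def test_single(self):
        res = brute_force_exemplars(np.array([[0.3]]))
        assert res.exemplars == {0: "0"} and res.net_similarity == pytest.approx(0.3)

    def test_pair_merges_when_similar(self):
        S = np.array([[0.1, 0.9], [0.9, 0.1]])
        res = brute_force_exemplars(S)
        # one cluster nets 0.1 + 0.9 = 1.0; two singletons net 0.2
        assert res.n_clusters == 1
        assert res.net_similarity == pytest.approx(1.0)

    def test_size_guard(self):
        with pytest.raises(ValidationError, match="too large"):
            brute_force_exemplars(np.zeros((12, 12)), max_n=10)


class TestAgglomerate:
    def _three_clusters(self):
        S = np.full((6, 6), 0.0)
        for a, b in [(0, 1), (2, 3), (4, 5)]:
            S[a, b] = S[b, a] = 0.9
        S[1, 2] = S[2, 1] = 0.6  # clusters {0,1} and {2,3} closest
        np.fill_diagonal(S, 0.3)
        return S

    def test_identity_at_current_k(self):
        S = self._three_clusters()
        res = affinity_propagation(S, APParams(seed=0))
        merged, tree = agglomerate_exemplars(S, res, res.n_clusters)
        assert merged.labels == res.labels and tree == []

    def test_merge_order_matches_exhaustive(self):
        S = self._three_clusters()
        res = affinity_propagation(S, APParams(seed=0))
        assert res.n_clusters == 3
        merged, tree = agglomerate_exemplars(S, res, 2)
        # the pair bridged by the 0.6 edge merges first
        merged_members = {
            frozenset(i for i, c in merged.labels.items() if c == lab)
            for lab in set(merged.labels.values())
        }
        assert frozenset({"0", "1", "2", "3"}) in merged_members

    def test_k_target_bounds(self):
        S = self._three_clusters()
        res = affinity_propagation(S, APParams(seed=0))
        with pytest.raises(ValidationError):
            agglomerate_exemplars(S, res, res.n_clusters + 1)
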