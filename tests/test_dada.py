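"""Feature grouping, budget apportionment, and diversity-aware selection."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from patchal.dada import (Budget, FeatureMatrix, allocate_budget,
                          cluster_mean_uncertainty, deep_features,
                          fit_reduce_pca, kmeans_cluster, sample_subpool,
                          select_from_features)
from patchal.nar import tiny_cnn, build_trainable
from patchal.synthdata import generate_feature_pool
from patchal.uncertainty import ScoreVector, top_m


def _fm(X, prefix="i"):
    return FeatureMatrix(values=X, item_ids=tuple(f"{prefix}{k:04d}" for k in range(len(X))))


class TestDeepFeatures:
    def test_identical_inputs_identical_rows_and_alignment(self):
        model = build_trainable(tiny_cnn(32), seed=0)
        model.is_trained = True
        x = np.random.default_rng(0).random((1, 32, 32, 3)).astype(np.float32)
        batch = np.concatenate([x, x, np.random.default_rng(1).random((1, 32, 32, 3)).astype(np.float32)])
        fm = deep_features(model, batch, ["a", "b", "c"])
        assert fm.values.shape[0] == 3 and fm.item_ids == ("a", "b", "c")
        assert (fm.values[0] == fm.values[1]).all()
        assert not np.allclose(fm.values[0], fm.values[2])

    def test_untrained_model_rejected(self):
        model = build_trainable(tiny_cnn(32), seed=0)
        with pytest.raises(ValueError):
            deep_features(model, np.zeros((1, 32, 32, 3), dtype=np.float32), ["a"])


class TestPCA:
    def test_full_rank_projection_preserves_distances(self):
        X = np.random.default_rng(0).random((20, 6))
        out = fit_reduce_pca(_fm(X), n_components=6).values
        d_in = np.linalg.norm(X[:, None] - X[None], axis=-1)
        d_out = np.linalg.norm(out[:, None] - out[None], axis=-1)
        assert np.allclose(d_in, d_out, atol=1e-6)

    def test_two_points_one_component(self):
        X = np.array([[0.0, 0.0], [3.0, 4.0]])
        out = fit_reduce_pca(_fm(X), 1).values
        assert out.shape == (2, 1)
        assert abs(abs(out[0, 0] - out[1, 0]) - 5.0) < 1e-9  # all variance kept

    def test_variances_match_covariance_eigensolve(self):
        rng = np.random.default_rng(1)
        X = rng.random((50, 10))
        out = fit_reduce_pca(_fm(X), 3).values
        evals = np.sort(np.linalg.eigvalsh(np.cov(X, rowvar=False)))[::-1]
        got = out.var(axis=0, ddof=1)
        assert np.allclose(got, evals[:3], atol=1e-9)
        assert (np.diff(got) <= 1e-12).all()  # decreasing order

    def test_single_item_rejected(self):
        with pytest.raises(ValueError):
            fit_reduce_pca(_fm(np.ones((1, 4))), 2)


class TestKMeans:
    def test_k1_single_cluster(self):
        a = kmeans_cluster(_fm(np.random.default_rng(0).random((10, 3))), 1, seed=0)
        assert (a.labels == 0).all() and a.k_eff == 1

    def test_two_separated_blobs_recovered(self):
        X, _, modes = generate_feature_pool(200, 4, 2, 50.0, 1.0, 0.5, seed=3)
        a = kmeans_cluster(_fm(X), 2, seed=0)
        # partition identical to blob membership up to label swap
        agree = (a.labels == modes).mean()
        assert agree in (0.0, 1.0) or max(agree, 1 - agree) == 1.0

    def test_k_clamped_to_distinct_points(self):
        X = np.repeat(np.arange(4, dtype=float)[:, None], 2, axis=1)
        X = np.vstack([X, X])  # 8 points, 4 distinct
        a = kmeans_cluster(_fm(X), K=10, seed=0)
        assert a.k_eff == 4
        assert (a.sizes() > 0).all()


class TestClusterMeanUncertainty:
    def test_constant_scores(self):
        a = kmeans_cluster(_fm(np.random.default_rng(0).random((12, 2))), 3, seed=0)
        sv = ScoreVector(scores=np.full(12, 0.7), item_ids=tuple(f"i{k}" for k in range(12)))
        assert np.allclose(cluster_mean_uncertainty(sv, a), 0.7)

    def test_forced_means(self):
        from patchal.dada import ClusterAssignment
        a = ClusterAssignment(labels=np.array([0, 0, 1]), centers=np.zeros((2, 1)))
        sv = ScoreVector(scores=np.array([0.2, 0.4, 0.9]), item_ids=("a", "b", "c"))
        assert np.allclose(cluster_mean_uncertainty(sv, a), [0.3, 0.9])

    def test_matches_groupby_oracle(self):
        rng = np.random.default_rng(4)
        a = kmeans_cluster(_fm(rng.random((40, 3))), 5, seed=1)
        s = rng.random(40)
        sv = ScoreVector(scores=s, item_ids=tuple(f"i{k}" for k in range(40)))
        Z = cluster_mean_uncertainty(sv, a)
        for ci in range(a.k_eff):
            assert Z[ci] == pytest.approx(s[a.labels == ci].mean())


def _budget_oracle(Z, sizes, Q):
    """Independent exact-rational apportionment with cap-and-redistribute."""
    K = len(Z)
    total = min(Q, sum(sizes))
    alloc = [None] * K
    active = list(range(K))
    remaining = total
    zsum = sum(Z)
    weights = [Fraction(1, K)] * K if zsum == 0 else [Fraction(z) for z in Z]
    while remaining > 0 and active:
        wsum = sum(weights[i] for i in active)
        if wsum == 0:
            quotas = {i: Fraction(remaining, len(active)) for i in active}
        else:
            quotas = {i: Fraction(remaining) * weights[i] / wsum for i in active}
        base = {i: int(quotas[i]) for i in active}
        left = remaining - sum(base.values())
        order = sorted(active, key=lambda i: (-(quotas[i] - base[i]), i))
        for i in order[:left]:
            base[i] += 1
        over = [i for i in active if base[i] > sizes[i]]
        if not over:
            for i in active:
                alloc[i] = base[i]
            break
        for i in over:
            alloc[i] = sizes[i]
            active.remove(i)
        remaining = total - sum(a for a in alloc if a is not None)
    for i in range(K):
        if alloc[i] is None:
            alloc[i] = 0
    return alloc


class TestAllocateBudget:
    def test_exact_fraction_example(self):
        b = allocate_budget(np.array([0.3, 0.1, 0.6]), np.array([100, 100, 100]), 10)
        assert list(b.acq_size) == [3, 1, 6]

    def test_symmetric_split(self):
        b = allocate_budget(np.ones(4), np.full(4, 50), 12)
        assert list(b.acq_size) == [3, 3, 3, 3]

    def test_tie_goes_to_lowest_index(self):
        b = allocate_budget(np.array([0.5, 0.5]), np.array([10, 10]), 5)
        assert list(b.acq_size) == [3, 2]

    def test_zero_uncertainty_uniform_fallback(self):
        b = allocate_budget(np.zeros(3), np.array([10, 10, 10]), 6)
        assert list(b.acq_size) == [2, 2, 2]

    def test_cap_and_redistribute_against_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(300):
            K = int(rng.integers(1, 5))
            Q = int(rng.integers(0, 13))
            Z = rng.integers(0, 5, size=K).astype(float) / 4
            sizes = rng.integers(1, 8, size=K)
            got = list(allocate_budget(Z, sizes, Q).acq_size)
            expect = _budget_oracle(list(Z), list(sizes), Q)
            assert got == expect, (Z, sizes, Q, got, expect)
            assert sum(got) == min(Q, sizes.sum())
            assert all(g <= s for g, s in zip(got, sizes))

    @settings(derandomize=True, max_examples=80, deadline=None)
    @given(st.integers(0, 10_000))
    def test_budget_conservation_property(self, seed):
        rng = np.random.default_rng(seed)
        K = int(rng.integers(1, 12))
        Z = rng.random(K)
        sizes = rng.integers(1, 40, size=K)
        Q = int(rng.integers(0, 120))
        b = allocate_budget(Z, sizes, Q)
        assert b.acq_size.sum() == min(Q, sizes.sum())
        assert (b.acq_size <= sizes).all() and (b.acq_size >= 0).all()


class TestSampleSubpool:
    def test_clamps_to_pool(self):
        ids = {f"i{k}" for k in range(100)}
        assert sample_subpool(ids, 2000, np.random.default_rng(0)) == sorted(ids)

    def test_draws_distinct_ids(self):
        ids = {f"i{k:05d}" for k in range(5000)}
        got = sample_subpool(ids, 2000, np.random.default_rng(1))
        assert len(got) == 2000 and len(set(got)) == 2000

    def test_seeded_determinism(self):
        ids = {f"i{k}" for k in range(500)}
        a = sample_subpool(ids, 100, np.random.default_rng(9))
        b = sample_subpool(ids, 100, np.random.default_rng(9))
        assert a == b

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            sample_subpool(set(), 10, np.random.default_rng(0))


class TestSelectFromFeatures:
    def _pool(self, seed, n=400, modes=4):
        X, _, mode_ids = generate_feature_pool(n, 16, modes, 12.0, 1.0, 0.16, seed=seed)
        ids = tuple(f"i{k:04d}" for k in range(n))
        rng = np.random.default_rng(seed + 1000)
        sv = ScoreVector(scores=rng.random(n), item_ids=ids)
        return _fm(X), sv, mode_ids

    def test_k1_equals_plain_topq(self):
        fm, sv, _ = self._pool(0)
        rec = select_from_features(fm, sv, Q=20, K=1, pca_components=8, seed=0)
        assert set(rec.selected_ids) == set(top_m(sv, 20))

    def test_budget_exhaustion_selects_everything(self):
        fm, sv, _ = self._pool(1, n=30)
        rec = select_from_features(fm, sv, Q=100, K=4, pca_components=8, seed=0)
        assert set(rec.selected_ids) == set(fm.item_ids)

    def test_every_mode_contributes_when_budgets_allow(self):
        fm, sv, mode_ids = self._pool(2, n=400, modes=4)
        rec = select_from_features(fm, sv, Q=8, K=4, pca_components=8, seed=0)
        idx = {i: k for k, i in enumerate(fm.item_ids)}
        covered = {mode_ids[idx[i]] for i in rec.selected_ids}
        assert covered == set(range(4))

    def test_within_cluster_score_dominance(self):
        fm, sv, _ = self._pool(3)
        rec = select_from_features(fm, sv, Q=40, K=6, pca_components=8, seed=1)
        score, cluster = rec.scores, rec.cluster_of
        chosen = set(rec.selected_ids)
        by_cluster: dict[int, list[str]] = {}
        for pid in fm.item_ids:
            by_cluster.setdefault(cluster[pid], []).append(pid)
        for ci, members in by_cluster.items():
            sel = [m for m in members if m in chosen]
            unsel = [m for m in members if m not in chosen]
            if sel and unsel:
                assert min(score[m] for m in sel) >= max(score[m] for m in unsel) - 1e-12

    def test_provenance_is_complete(self):
        fm, sv, _ = self._pool(4, n=100)
        rec = select_from_features(fm, sv, Q=10, K=3, pca_components=4, seed=2)
        frame = rec.to_frame()
        assert len(frame) == 100
        assert frame["selected"].sum() == 10
        assert set(frame.columns) == {"iteration", "id", "cluster", "score", "selected"}
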