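"""Non-parametric 1-D statistical mapping: t-curves, thresholds, clusters."""

from itertools import combinations

import numpy as np
import pytest

from gripcurve import (
    ParameterError,
    form_clusters,
    permutation_threshold,
    pointwise_t,
    snpm_test,
)


def brute_force_enumeration(X, nA, alpha, tau):
    """Independent oracle: enumerate every choice of nA rows as group A,
    compute the max-|t| and max-cluster-extent null distributions with plain
    loops, and return (t_crit, cluster p-values for the observed labeling).

    Deliberately written without reference to the package internals: scipy-free
    two-sample t per grid point, index-run clusters with linear interpolation.
    """
    n = X.shape[0]

    def tcurve(idx_a):
        A = X[list(idx_a)]
        B = X[[i for i in range(n) if i not in idx_a]]
        na, nb = len(A), len(B)
        va = A.var(axis=0, ddof=1)
        vb = B.var(axis=0, ddof=1)
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        return (A.mean(axis=0) - B.mean(axis=0)) / np.sqrt(sp2 * (1 / na + 1 / nb))

    def extents(tc, thr):
        a = np.abs(tc)
        out = []
        run = None
        for k, v in enumerate(a):
            if v >= thr and run is None:
                run = k
            if v < thr and run is not None:
                out.append((run, k - 1))
                run = None
        if run is not None:
            out.append((run, a.size - 1))
        res = []
        for i, j in out:
            start = tau[0] if i == 0 else tau[i - 1] + (thr - a[i - 1]) / (a[i] - a[i - 1]) * (tau[i] - tau[i - 1])
            end = tau[-1] if j == a.size - 1 else tau[j] + (a[j] - thr) / (a[j] - a[j + 1]) * (tau[j + 1] - tau[j])
            res.append(100 * (end - start))
        return res

    all_sets = list(combinations(range(n), nA))
    max_ts = sorted(np.abs(tcurve(s)).max() for s in all_sets)
    N = len(all_sets)
    t_crit = max_ts[int(np.ceil((1 - alpha) * N)) - 1]
    obs_ext = extents(tcurve(tuple(range(nA))), t_crit)
    null_max_ext = [max(extents(tcurve(s), t_crit), default=0.0) for s in all_sets]
    ps = [
        max(np.mean([e >= w for e in null_max_ext]), 1.0 / N) for w in obs_ext
    ]
    return t_crit, obs_ext, ps


class TestPointwiseT:
    def test_zero_for_identical_groups(self, rng):
        A = rng.normal(size=(5, 20))
        t = pointwise_t(A, A.copy())
        assert np.allclose(t, 0.0, atol=1e-12)

    def test_textbook_formula_spot_check(self, rng):
        # constant offset with known pooled SD
        A = rng.normal(size=(6, 10))
        B = A[:4] * 1.0
        B = rng.normal(size=(4, 10))
        t = pointwise_t(A, B)
        k = 3
        a, b = A[:, k], B[:, k]
        sp = np.sqrt(((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / (a.size + b.size - 2))
        expected = (a.mean() - b.mean()) / (sp * np.sqrt(1 / a.size + 1 / b.size))
        assert t[k] == pytest.approx(expected, rel=1e-12)

    def test_antisymmetric_under_group_swap(self, rng):
        A = rng.normal(size=(4, 15))
        B = rng.normal(size=(5, 15))
        assert np.allclose(pointwise_t(A, B), -pointwise_t(B, A), atol=1e-12)

    def test_small_group_rejected(self, rng):
        with pytest.raises(ParameterError):
            pointwise_t(rng.normal(size=(1, 5)), rng.normal(size=(4, 5)))

    def test_constant_unequal_groups_rejected(self):
        A = np.ones((3, 4))
        B = np.zeros((3, 4))
        with pytest.raises(ParameterError):
            pointwise_t(A, B)


class TestPermutationThreshold:
    def test_small_design_is_fully_enumerated(self, rng):
        X = rng.normal(size=(7, 12))
        labels = np.array(["A"] * 4 + ["B"] * 3)
        t_crit, dist, enumerated = permutation_threshold(X, labels, n_perm=10000)
        assert enumerated and dist.size == 35  # C(7, 4)

    def test_enumerated_mode_is_seed_independent(self, rng):
        X = rng.normal(size=(7, 12))
        labels = np.array(["A"] * 4 + ["B"] * 3)
        t1, d1, _ = permutation_threshold(X, labels, seed=1)
        t2, d2, _ = permutation_threshold(X, labels, seed=999)
        assert t1 == t2 and np.array_equal(np.sort(d1), np.sort(d2))

    def test_sampled_mode_deterministic_given_seed(self, rng):
        X = rng.normal(size=(24, 12))
        labels = np.array(["A"] * 12 + ["B"] * 12)
        t1, _, e1 = permutation_threshold(X, labels, n_perm=500, seed=7)
        t2, _, _ = permutation_threshold(X, labels, n_perm=500, seed=7)
        assert not e1 and t1 == t2

    def test_invalid_alpha_rejected(self, rng):
        X = rng.normal(size=(8, 5))
        labels = np.array(["A"] * 4 + ["B"] * 4)
        with pytest.raises(ParameterError):
            permutation_threshold(X, labels, alpha=1.5)


class TestFormClusters:
    tau = np.linspace(0, 1, 101)

    def test_no_clusters_below_threshold(self):
        assert form_clusters(np.zeros(101), 3.0, self.tau) == []

    def test_full_segment_cluster(self):
        t = np.full(101, 4.2)
        clusters = form_clusters(t, 3.0, self.tau)
        assert len(clusters) == 1
        start, end, extent, mx = clusters[0]
        assert (start, end, extent) == (0.0, 100.0, 100.0)
        assert mx == 4.2

    def test_interpolated_boundaries_match_analytic_crossing(self):
        # piecewise-linear |t| rising through the threshold between grid points
        tau = np.linspace(0, 1, 11)
        t = np.array([0, 1, 2, 3, 4, 5, 4, 3, 2, 1, 0], dtype=float)
        thr = 3.5
        clusters = form_clusters(t, thr, tau)
        assert len(clusters) == 1
        start, end, extent, _ = clusters[0]
        # crossing of the line from (0.3, 3) to (0.4, 4) at 3.5 is tau=0.35
        assert start == pytest.approx(35.0, abs=1e-9)
        assert end == pytest.approx(65.0, abs=1e-9)
        assert extent == pytest.approx(30.0, abs=1e-9)

    def test_negative_t_counts_via_absolute_value(self):
        t = np.where(np.arange(101) < 50, -5.0, 0.0)
        clusters = form_clusters(t, 3.0, self.tau)
        assert len(clusters) == 1
        assert clusters[0][3] == 5.0


class TestSnPMTest:
    def test_matches_independent_enumeration_oracle(self, rng):
        X = rng.normal(size=(7, 25))
        X[:4] += np.linspace(0, 2.5, 25)  # localized effect in group A
        res = snpm_test(X[:4], X[4:], alpha=0.05, n_perm=10000)
        assert res.enumerated and res.n_perm == 35
        t_crit, obs_ext, ps = brute_force_enumeration(
            X, 4, 0.05, np.linspace(0, 1, 25)
        )
        assert res.t_crit == pytest.approx(t_crit, abs=1e-12)
        assert len(res.clusters) == len(obs_ext)
        for c, ext, p in zip(res.clusters, obs_ext, ps):
            assert c.extent_pct == pytest.approx(ext, abs=1e-9)
            assert c.p == pytest.approx(p, abs=1e-12)

    def test_saturated_effect_gives_full_segment_cluster_with_tiny_p(self, rng):
        # a large amplitude shift yields one cluster spanning the whole
        # segment; its p is the (small) fraction of relabelings that also
        # reach a full-extent cluster, bounded below by the 1/N floor
        A = rng.normal(size=(8, 40)) + 30.0
        B = rng.normal(size=(8, 40))
        res = snpm_test(A, B, alpha=0.05, n_perm=2000, seed=3)
        assert len(res.clusters) == 1
        c = res.clusters[0]
        assert (c.start_pct, c.end_pct) == (0.0, 100.0)
        assert 1.0 / res.n_perm <= c.p <= 0.02

    def test_group_swap_leaves_inference_unchanged(self, rng):
        X = rng.normal(size=(8, 30))
        X[:4] += 1.0
        r1 = snpm_test(X[:4], X[4:], n_perm=10000)  # C(8,4)=70, enumerated
        r2 = snpm_test(X[4:], X[:4], n_perm=10000)
        assert np.allclose(r1.t_curve, -r2.t_curve, atol=1e-9)
        assert r1.t_crit == pytest.approx(r2.t_crit, rel=1e-9)
        assert len(r1.clusters) == len(r2.clusters)
        for c1, c2 in zip(r1.clusters, r2.clusters):
            assert c1.start_pct == pytest.approx(c2.start_pct, abs=1e-6)
            assert c1.p == pytest.approx(c2.p, abs=1e-12)

    def test_lower_alpha_never_adds_significant_clusters(self, rng):
        X = rng.normal(size=(10, 30))
        X[:5, 10:20] += 1.2
        counts = []
        for alpha in (0.10, 0.05, 0.01):
            res = snpm_test(X[:5], X[5:], alpha=alpha, n_perm=2000, seed=5)
            counts.append(len(res.significant_clusters))
        assert counts[0] >= counts[1] >= counts[2]

    def test_clusters_are_disjoint_and_ordered(self, rng):
        X = rng.normal(size=(12, 60))
        X[:6, 5:15] += 1.5
        X[:6, 40:50] -= 1.5
        res = snpm_test(X[:6], X[6:], n_perm=2000, seed=9)
        bounds = [(c.start_pct, c.end_pct) for c in res.clusters]
        for (s1, e1), (s2, e2) in zip(bounds, bounds[1:]):
            assert e1 < s2
        for c in res.clusters:
            assert c.max_abs_t >= res.t_crit
            assert c.extent_pct == pytest.approx(c.end_pct - c.start_pct, abs=1e-9)
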