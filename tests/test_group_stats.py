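"""Mann-Whitney, Hodges-Lehmann and max|Z| family-wise adjustment."""

from itertools import combinations

import numpy as np
import pytest
from scipy import stats as sps

from gripcurve import (
    compare_descriptors,
    hodges_lehmann,
    mann_whitney,
    maxz_adjust,
)
from gripcurve.descriptors import DESCRIPTOR_NAMES
import pandas as pd


def brute_force_u(x, y):
    """O(n^2) pair-counting oracle: #(x > y) + half ties."""
    u = 0.0
    for xi in x:
        for yj in y:
            if xi > yj:
                u += 1.0
            elif xi == yj:
                u += 0.5
    return u


class TestMannWhitney:
    def test_complete_separation(self):
        U, Z, p, r = mann_whitney([1, 2, 3], [4, 5, 6])
        assert U == 0.0
        assert r == -1.0
        assert Z < 0 and p < 0.1

    def test_identical_samples_are_null(self):
        U, Z, p, r = mann_whitney([1, 2, 3], [1, 2, 3])
        assert r == 0.0
        assert p == pytest.approx(1.0, abs=0.05)

    def test_all_values_identical_degenerate(self):
        U, Z, p, r = mann_whitney([5, 5, 5], [5, 5])
        assert p == 1.0 and Z == 0.0

    def test_u_matches_pair_counting_oracle(self, rng):
        for _ in range(25):
            x = rng.integers(0, 8, size=rng.integers(2, 10)).astype(float)
            y = rng.integers(0, 8, size=rng.integers(2, 10)).astype(float)
            U, _, _, r = mann_whitney(x, y)
            assert U == brute_force_u(x, y)
            assert r == pytest.approx(2 * U / (x.size * y.size) - 1, rel=1e-12)

    def test_p_close_to_scipy_asymptotic(self, rng):
        x = rng.normal(size=20)
        y = rng.normal(size=15) + 0.8
        _, _, p, _ = mann_whitney(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert p == pytest.approx(ref.pvalue, rel=1e-6)


class TestHodgesLehmann:
    def test_single_pair_degenerate_ci(self):
        hl, lo, hi = hodges_lehmann([5.0], [3.0])
        assert (hl, lo, hi) == (2.0, 2.0, 2.0)

    def test_exact_shift_recovered(self, rng):
        y = rng.normal(size=12)
        x = y + 3.25
        hl, lo, hi = hodges_lehmann(x, y)
        assert hl == pytest.approx(3.25, abs=1e-12)
        assert lo <= hl <= hi

    def test_matches_enumerated_difference_list(self, rng):
        x = rng.normal(size=9)
        y = rng.normal(size=7)
        hl, _, _ = hodges_lehmann(x, y)
        diffs = sorted(xi - yj for xi in x for yj in y)
        assert hl == pytest.approx(np.median(diffs), abs=1e-12)

    def test_location_equivariance(self, rng):
        x = rng.normal(size=8)
        y = rng.normal(size=6)
        base = hodges_lehmann(x, y)
        shifted = hodges_lehmann(x + 5.0, y)
        assert shifted[0] == pytest.approx(base[0] + 5.0, abs=1e-12)
        assert shifted[1] == pytest.approx(base[1] + 5.0, abs=1e-12)
        assert shifted[2] == pytest.approx(base[2] + 5.0, abs=1e-12)

    def test_ci_coverage_under_shift_model(self, rng):
        # nominal 95 % CI for a pure location shift: empirical coverage close
        n_sim, hits = 500, 0
        delta = 1.0
        for _ in range(n_sim):
            y = rng.normal(size=15)
            x = rng.normal(size=15) + delta
            _, lo, hi = hodges_lehmann(x, y)
            hits += lo <= delta <= hi
        assert 0.92 <= hits / n_sim <= 0.98


class TestMaxZAdjust:
    def _enumeration_oracle(self, values, nx):
        """Full enumeration of group-x memberships for the max|Z| null."""
        n = values.shape[0]

        def absz(col, members):
            ranks = sps.rankdata(col)
            rx = ranks[list(members)].sum()
            U = rx - nx * (nx + 1) / 2.0
            m = n - nx
            _, counts = np.unique(col, return_counts=True)
            tie = np.sum(counts**3 - counts) / (n * (n - 1.0))
            var = nx * m / 12.0 * (n + 1.0 - tie)
            if var <= 0:
                return 0.0
            return max(abs(U - nx * m / 2.0) - 0.5, 0.0) / np.sqrt(var)

        sets = list(combinations(range(n), nx))
        table = np.array(
            [[absz(values[:, j], s) for j in range(values.shape[1])] for s in sets]
        )
        obs = table[sets.index(tuple(range(nx)))]
        maxes = table.max(axis=1)
        return np.array(
            [np.mean(maxes >= obs[j] - 1e-12) for j in range(values.shape[1])]
        )

    def test_single_descriptor_reduces_to_permutation_p(self, rng):
        vals = rng.normal(size=(7, 1))
        vals[:4] += 1.0
        labels = np.array(["x"] * 4 + ["y"] * 3)
        p_adj, p_perm = maxz_adjust(vals, labels, n_perm=10000)
        assert p_adj[0] == pytest.approx(p_perm[0], abs=1e-12)

    def test_duplicated_descriptors_share_p_adj(self, rng):
        col = rng.normal(size=(8, 1))
        col[:4] += 1.5
        vals = np.hstack([col, col])
        labels = np.array(["x"] * 4 + ["y"] * 4)
        p_adj, _ = maxz_adjust(vals, labels, n_perm=10000)
        assert p_adj[0] == p_adj[1]

    def test_matches_full_enumeration_oracle(self, rng):
        vals = rng.normal(size=(7, 2))
        vals[:4, 0] += 2.0
        labels = np.array(["x"] * 4 + ["y"] * 3)
        p_adj, _ = maxz_adjust(vals, labels, n_perm=10000)  # C(7,4)=35 enumerated
        oracle = self._enumeration_oracle(vals, 4)
        assert np.allclose(p_adj, np.maximum(oracle, 1 / 35), atol=1e-12)

    def test_adjustment_dominates_unadjusted(self, rng):
        vals = rng.normal(size=(20, 5))
        vals[:10, :2] += 0.8
        labels = np.array(["x"] * 10 + ["y"] * 10)
        p_adj, p_perm = maxz_adjust(vals, labels, n_perm=2000, seed=4)
        assert np.all(p_adj >= p_perm - 1e-12)


class TestCompareDescriptors:
    def _table(self, rng, n_f=12, n_m=10, shift=0.0):
        rows = []
        for i in range(n_f + n_m):
            group = "F" if i < n_f else "M"
            base = rng.normal(size=len(DESCRIPTOR_NAMES))
            if group == "M":
                base += shift
            rows.append(
                {"participant": f"P{i}", "group": group}
                | dict(zip(DESCRIPTOR_NAMES, base))
            )
        return pd.DataFrame(rows)

    def test_one_row_per_descriptor(self, rng):
        out = compare_descriptors(self._table(rng), n_perm=500, seed=0)
        assert list(out["descriptor"]) == list(DESCRIPTOR_NAMES)
        assert np.all(out["p_adj"] >= out["p"] - 1e-12)
        assert np.all((out["ci_lo"] <= out["hl"]) & (out["hl"] <= out["ci_hi"]))

    def test_identical_groups_are_null(self, rng):
        table = self._table(rng, n_f=8, n_m=8)
        table.loc[table.group == "M", DESCRIPTOR_NAMES] = table.loc[
            table.group == "F", DESCRIPTOR_NAMES
        ].to_numpy()
        out = compare_descriptors(table, n_perm=500, seed=1)
        assert np.allclose(out["stat"], 0.0, atol=1e-12)
        assert np.all(out["p_adj"] > 0.9)

    def test_nan_drops_participant_for_that_descriptor_only(self, rng):
        table = self._table(rng, shift=1.0)
        table.loc[0, "FI"] = np.nan
        out = compare_descriptors(table, n_perm=500, seed=2)
        assert len(out) == len(DESCRIPTOR_NAMES)
        assert np.isfinite(out["hl"]).all()

    def test_amplitude_only_cohort_pattern(self):
        # large synthetic amplitude effect: force descriptors significant,
        # timing and fatigability descriptors not
        from gripcurve import AnalysisConfig, GeneratorConfig, HandgripAnalysis

        gen = GeneratorConfig(
            n_per_group={"F": 20, "M": 20},
            amp_mean_by_group={"F": 15.0, "M": 24.0},
            tau_rise_mean_by_group={"F": 0.22, "M": 0.22},
            decay_frac_by_group={"F": 0.25, "M": 0.25},
            seed=31,
        )
        ana = AnalysisConfig(n_perm=1000, seed=31)
        res = HandgripAnalysis.from_simulation(gen, ana).fit()
        out = res.descriptor_comparison().set_index("descriptor")
        for name in ("F_max", "F_63", "F_final"):
            assert out.loc[name, "p_adj"] <= 0.05
            assert out.loc[name, "stat"] < 0  # F smaller than M
        for name in ("t_max", "t_63", "FI"):
            assert out.loc[name, "p_adj"] > 0.05
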