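"""Non-parametric 1-D statistical mapping for two-group curve comparisons.

At every point of the normalized-time grid a pooled-variance two-sample t
statistic is computed, giving a t-curve over the segment. Inference is by
permutation of group labels: the critical threshold is the (1 - alpha)
quantile of the permutation distribution of the maximum absolute t over the
grid (family-wise control across time), and each supra-threshold cluster
receives a p-value from the permutation distribution of the maximal cluster
extent at that same threshold. When the number of distinct relabelings is
small enough they are enumerated exhaustively and the test is exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import ceil, comb

import numpy as np

from .errors import ParameterError

_VAR_TOL = 1e-24


@dataclass(frozen=True)
class SnPMCluster:
    """One contiguous supra-threshold region, in percent of normalized time."""

    p: float
    start_pct: float
    end_pct: float
    extent_pct: float
    max_abs_t: float


@dataclass
class SnPMResult:
    """Outcome of one two-group curve contrast."""

    t_curve: np.ndarray
    t_crit: float
    alpha: float
    n_perm: int  # number of relabelings actually used (N)
    enumerated: bool
    clusters: list[SnPMCluster] = field(default_factory=list)
    segment: str = ""
    family: str = ""

    @property
    def significant_clusters(self) -> list[SnPMCluster]:
        return [c for c in self.clusters if c.p <= self.alpha]


def pointwise_t(groupA: np.ndarray, groupB: np.ndarray) -> np.ndarray:
    """Pooled-variance two-sample t statistic at each grid point.

    Sign convention: positive where mean(A) > mean(B). A grid point where
    both groups are constant and identical yields t = 0; constant but
    unequal groups are an error (zero variance with a real difference).
    """
    A = np.atleast_2d(np.asarray(groupA, dtype=float))
    B = np.atleast_2d(np.asarray(groupB, dtype=float))
    nA, nB = A.shape[0], B.shape[0]
    if nA < 2 or nB < 2:
        raise ParameterError("each group needs at least 2 curves")
    diff = A.mean(axis=0) - B.mean(axis=0)
    sp2 = ((nA - 1) * A.var(axis=0, ddof=1) + (nB - 1) * B.var(axis=0, ddof=1)) / (
        nA + nB - 2
    )
    se2 = sp2 * (1.0 / nA + 1.0 / nB)
    t = np.zeros_like(diff)
    ok = se2 > _VAR_TOL
    t[ok] = diff[ok] / np.sqrt(se2[ok])
    bad = ~ok & (np.abs(diff) > 1e-12)
    if np.any(bad):
        raise ParameterError("zero pooled variance with unequal means")
    return t


def _relabelings(
    n: int, nA: int, n_perm: int, rng: np.random.Generator | None
) -> tuple[np.ndarray, bool]:
    """Boolean membership matrix (N x n, True = group A); row 0 is observed.

    Exhaustive if C(n, nA) <= n_perm, otherwise the observed labeling plus
    n_perm - 1 random relabelings.
    """
    total = comb(n, nA)
    if total <= n_perm:
        M = np.zeros((total, n), dtype=bool)
        for r, idx in enumerate(combinations(range(n), nA)):
            M[r, list(idx)] = True
        # move the observed labeling (first nA indices) to row 0
        obs = np.zeros(n, dtype=bool)
        obs[:nA] = True
        row = int(np.nonzero((M == obs).all(axis=1))[0][0])
        if row != 0:
            M[[0, row]] = M[[row, 0]]
        return M, True
    if rng is None:
        raise ParameterError("a random generator is required for sampled permutations")
    M = np.zeros((n_perm, n), dtype=bool)
    M[0, :nA] = True
    for r in range(1, n_perm):
        M[r, rng.permutation(n)[:nA]] = True
    return M, False


def _t_matrix(X: np.ndarray, M: np.ndarray) -> np.ndarray:
    """t-curves for every relabeling in M (vectorized over relabelings)."""
    n, _ = X.shape
    nA = int(M[0].sum())
    nB = n - nA
    tot = X.sum(axis=0)
    tot2 = (X**2).sum(axis=0)
    G = M.astype(float)
    sA = G @ X
    s2A = G @ (X**2)
    meanA = sA / nA
    meanB = (tot - sA) / nB
    ssA = s2A - sA**2 / nA
    ssB = (tot2 - s2A) - (tot - sA) ** 2 / nB
    sp2 = (ssA + ssB) / (n - 2)
    se2 = sp2 * (1.0 / nA + 1.0 / nB)
    diff = meanA - meanB
    with np.errstate(divide="ignore", invalid="ignore"):
        T = np.where(se2 > _VAR_TOL, diff / np.sqrt(se2), 0.0)
    return T


def permutation_threshold(
    curves: np.ndarray,
    labels: np.ndarray,
    alpha: float = 0.05,
    n_perm: int = 10000,
    seed: int | np.random.Generator | None = None,
) -> tuple[float, np.ndarray, bool]:
    """Critical max-|t| threshold from the permutation distribution.

    Returns ``(t_crit, max_t_distribution, enumerated)`` where ``t_crit`` is
    the ceil((1 - alpha) * N)-th order statistic of the N max-|t| values (the
    observed labeling always participates in its own null).
    """
    if not 0 < alpha < 1:
        raise ParameterError("alpha must be in (0, 1)")
    X, nA = _stack(curves, labels)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    M, enumerated = _relabelings(X.shape[0], nA, n_perm, rng)
    T = _t_matrix(X, M)
    max_t = np.abs(T).max(axis=1)
    t_crit = float(np.sort(max_t)[ceil((1 - alpha) * max_t.size) - 1])
    return t_crit, max_t, enumerated


def _stack(curves: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, int]:
    """Reorder rows so group-A members come first; A = first label seen."""
    labels = np.asarray(labels)
    curves = np.asarray(curves, dtype=float)
    if curves.shape[0] != labels.size:
        raise ParameterError("labels must match the number of curves")
    uniq = list(dict.fromkeys(labels.tolist()))
    if len(uniq) != 2:
        raise ParameterError("exactly two group labels are required")
    a_mask = labels == uniq[0]
    nA = int(a_mask.sum())
    if nA < 2 or labels.size - nA < 2:
        raise ParameterError("each group needs at least 2 curves")
    return np.vstack([curves[a_mask], curves[~a_mask]]), nA


def form_clusters(
    t_curve: np.ndarray, t_crit: float, tau: np.ndarray
) -> list[tuple[float, float, float, float]]:
    """Maximal supra-threshold runs as (start_pct, end_pct, extent_pct, max|t|).

    Cluster boundaries are refined by linearly interpolating |t| to the exact
    crossing of ``t_crit`` between grid points, so extents are continuous in
    normalized time rather than multiples of the grid step.
    """
    if t_crit <= 0:
        raise ParameterError("t_crit must be positive")
    a = np.abs(np.asarray(t_curve, dtype=float))
    tau = np.asarray(tau, dtype=float)
    supra = a >= t_crit
    if not supra.any():
        return []
    edges = np.diff(supra.astype(int))
    starts = list(np.nonzero(edges == 1)[0] + 1)
    ends = list(np.nonzero(edges == -1)[0])
    if supra[0]:
        starts.insert(0, 0)
    if supra[-1]:
        ends.append(supra.size - 1)
    out = []
    for i, j in zip(starts, ends):
        if i > 0:
            frac = (t_crit - a[i - 1]) / (a[i] - a[i - 1])
            start = tau[i - 1] + frac * (tau[i] - tau[i - 1])
        else:
            start = tau[0]
        if j < a.size - 1:
            frac = (a[j] - t_crit) / (a[j] - a[j + 1])
            end = tau[j] + frac * (tau[j + 1] - tau[j])
        else:
            end = tau[-1]
        out.append(
            (100.0 * start, 100.0 * end, 100.0 * (end - start), float(a[i : j + 1].max()))
        )
    return out


def _max_cluster_extent(t_row: np.ndarray, t_crit: float, tau: np.ndarray) -> float:
    clusters = form_clusters(t_row, t_crit, tau)
    return max((c[2] for c in clusters), default=0.0)


def snpm_test(
    groupA: np.ndarray,
    groupB: np.ndarray,
    alpha: float = 0.05,
    n_perm: int = 10000,
    seed: int | np.random.Generator | None = None,
    tau: np.ndarray | None = None,
    segment: str = "",
    family: str = "",
) -> SnPMResult:
    """Full two-group SnPM contrast on one segment.

    Cluster-level p-values are the proportion of relabelings whose largest
    supra-threshold cluster extent (at the observed ``t_crit``) is at least
    the observed cluster's extent, floored at 1/N. All clusters are reported;
    ``significant_clusters`` filters at ``alpha``.
    """
    A = np.atleast_2d(np.asarray(groupA, dtype=float))
    B = np.atleast_2d(np.asarray(groupB, dtype=float))
    X = np.vstack([A, B])
    labels = np.array(["A"] * A.shape[0] + ["B"] * B.shape[0])
    if tau is None:
        tau = np.linspace(0.0, 1.0, X.shape[1])
    if not 0 < alpha < 1:
        raise ParameterError("alpha must be in (0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    M, enumerated = _relabelings(X.shape[0], A.shape[0], n_perm, rng)
    T = _t_matrix(X, M)
    pointwise_t(A, B)  # validates sizes and degenerate-variance points
    # the observed t-curve is row 0 of the permutation matrix, so that its
    # max-|t| is numerically identical to its own entry in the null
    t_obs = T[0]
    max_t = np.abs(T).max(axis=1)
    N = max_t.size
    t_crit = float(np.sort(max_t)[ceil((1 - alpha) * N) - 1])

    clusters: list[SnPMCluster] = []
    obs = form_clusters(t_obs, t_crit, tau) if t_crit > 0 else []
    if obs:
        # null distribution of the maximal cluster extent; rows that never
        # cross the threshold contribute extent 0 and are skipped
        crossing = np.nonzero(max_t >= t_crit)[0]
        null_extents = np.zeros(N)
        for r in crossing:
            null_extents[r] = _max_cluster_extent(T[r], t_crit, tau)
        for start, end, extent, peak_t in obs:
            p = max(float(np.mean(null_extents >= extent)), 1.0 / N)
            clusters.append(SnPMCluster(p, start, end, extent, peak_t))
    return SnPMResult(
        t_curve=t_obs,
        t_crit=t_crit,
        alpha=alpha,
        n_perm=N,
        enumerated=enumerated,
        clusters=clusters,
        segment=segment,
        family=family,
    )
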