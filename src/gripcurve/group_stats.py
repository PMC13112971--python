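"""Non-parametric two-group comparison of the discrete descriptors.

Each descriptor is compared with a Mann-Whitney U test (mid-ranks for ties,
tie-corrected normal approximation with continuity correction). The effect
size is the rank-biserial correlation r = 2U/(n_x n_y) - 1 with
U = #(x_i > y_j) + half-ties, so r is negative when the first group tends to
be smaller. The location shift is estimated by the Hodges-Lehmann median of
pairwise differences with a Moses order-statistic confidence interval.
Family-wise error across the descriptor family is controlled by the max|Z|
permutation adjustment: each descriptor's observed |Z| is referred to the
permutation distribution of the maximum |Z| over all descriptors.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb, floor
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError
from .descriptors import DESCRIPTOR_NAMES


@dataclass
class GroupComparison:
    """One descriptor's two-group comparison (first group minus second)."""

    descriptor: str
    median_x: float
    iqr_x: tuple[float, float]
    median_y: float
    iqr_y: tuple[float, float]
    stat: float  # rank-biserial correlation
    p: float
    p_adj: float
    hl: float
    ci_lo: float
    ci_hi: float


def _rank_stats(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """U (greater-than convention), tie-corrected Z and two-sided p."""
    n, m = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    rx = ranks[:n].sum()
    U = rx - n * (n + 1) / 2.0  # = #(x > y) + 0.5 * ties
    mu = n * m / 2.0
    N = n + m
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (N * (N - 1.0)) if N > 1 else 0.0
    var = n * m / 12.0 * (N + 1.0 - tie_term)
    if var <= 0:
        return U, 0.0, 1.0  # all values identical
    # continuity correction toward the null
    shift = np.clip(abs(U - mu) - 0.5, 0.0, None)
    Z = np.sign(U - mu) * shift / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(Z))
    return U, float(Z), float(min(p, 1.0))


def mann_whitney(x, y) -> tuple[float, float, float, float]:
    """Mann-Whitney U test of two samples.

    Returns ``(U, Z, p, r)``: the U statistic under the greater-than
    convention, the tie-corrected continuity-corrected normal deviate, the
    two-sided p-value, and the rank-biserial effect size
    ``r = 2U/(n_x n_y) - 1`` (negative when x tends to be smaller than y).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ParameterError("both samples must be non-empty")
    U, Z, p = _rank_stats(x, y)
    r = 2.0 * U / (x.size * y.size) - 1.0
    return float(U), Z, p, float(r)


def hodges_lehmann(x, y, conf: float = 0.95) -> tuple[float, float, float]:
    """Hodges-Lehmann shift estimate with a Moses order-statistic CI.

    The estimate is the median of all n*m pairwise differences x_i - y_j;
    the CI endpoints are the k-th smallest and k-th largest differences with
    k from the normal approximation to the Mann-Whitney null distribution.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ParameterError("both samples must be non-empty")
    diffs = np.sort(np.subtract.outer(x, y).ravel())
    hl = float(np.median(diffs))
    n, m = x.size, y.size
    nm = n * m
    z = stats.norm.ppf(0.5 + conf / 2.0)
    k = int(floor(nm / 2.0 - z * np.sqrt(nm * (n + m + 1) / 12.0)))
    k = max(k, 0)
    lo = diffs[min(k, nm - 1)]
    hi = diffs[max(nm - 1 - k, 0)]
    return hl, float(lo), float(hi)


def _z_for_membership(
    ranks: np.ndarray, member: np.ndarray, n: int, m: int, var: float
) -> np.ndarray:
    """|Z| for each boolean membership row (vectorized over permutations)."""
    rx = member @ ranks
    U = rx - n * (n + 1) / 2.0
    mu = n * m / 2.0
    if var <= 0:
        return np.zeros(member.shape[0])
    shift = np.clip(np.abs(U - mu) - 0.5, 0.0, None)
    return shift / np.sqrt(var)


def maxz_adjust(
    values: np.ndarray,
    labels: np.ndarray,
    n_perm: int = 10000,
    seed: int | np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Family-wise adjusted p-values via the max|Z| permutation distribution.

    Parameters
    ----------
    values : (participants, descriptors) array, NaN allowed per cell.
    labels : group label per participant (exactly two levels; the first
        label seen defines group x).

    Returns
    -------
    (p_adj, p_perm) : adjusted and per-descriptor unadjusted permutation
        p-values. ``p_adj[j]`` is the proportion of relabelings whose maximum
        |Z| across descriptors reaches the observed |Z_j|; the observed
        labeling is always included, so p-values are floored at 1/N.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.ndim != 2:
        raise ParameterError("values must be 2-D (participants x descriptors)")
    uniq = list(dict.fromkeys(labels.tolist()))
    if len(uniq) != 2:
        raise ParameterError("exactly two group labels are required")
    x_mask = labels == uniq[0]
    n_total = labels.size
    nx = int(x_mask.sum())
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    # relabelings as boolean membership of group x; observed first
    total = comb(n_total, nx)
    if total <= n_perm:
        M = np.zeros((total, n_total), dtype=bool)
        for r, idx in enumerate(combinations(range(n_total), nx)):
            M[r, list(idx)] = True
        row = int(np.nonzero((M == x_mask).all(axis=1))[0][0])
        if row != 0:
            M[[0, row]] = M[[row, 0]]
    else:
        M = np.zeros((n_perm, n_total), dtype=bool)
        M[0] = x_mask
        for r in range(1, n_perm):
            M[r, rng.permutation(n_total)[:nx]] = True
    N = M.shape[0]

    n_desc = values.shape[1]
    absZ = np.zeros((N, n_desc))
    for j in range(n_desc):
        col = values[:, j]
        ok = np.isfinite(col)
        if ok.sum() < 2 or np.unique(col[ok]).size == 1:
            continue  # constant or empty column: |Z| := 0 everywhere
        ranks = stats.rankdata(col[ok])
        Mj = M[:, ok]
        nj = Mj[0].sum()
        mj = ok.sum() - nj
        if nj < 1 or mj < 1:
            continue
        Nj = nj + mj
        _, counts = np.unique(col[ok], return_counts=True)
        tie_term = np.sum(counts**3 - counts) / (Nj * (Nj - 1.0))
        var = nj * mj / 12.0 * (Nj + 1.0 - tie_term)
        # rows must keep group sizes within the non-missing subset; with
        # missing data a relabeling may shift sizes, so recompute per row
        sizes = Mj.sum(axis=1)
        absZ[:, j] = _z_for_membership(ranks, Mj.astype(float), nj, mj, var)
        absZ[sizes != nj, j] = np.nan
    max_z = np.nanmax(absZ, axis=1)
    obs = absZ[0]
    valid = np.isfinite(absZ)
    p_adj = np.empty(n_desc)
    p_perm = np.empty(n_desc)
    for j in range(n_desc):
        p_adj[j] = max(np.mean(max_z >= obs[j] - 1e-12), 1.0 / N)
        zj = absZ[valid[:, j], j]
        p_perm[j] = max(np.mean(zj >= obs[j] - 1e-12), 1.0 / zj.size)
    return p_adj, p_perm


def _iqr(v: np.ndarray) -> tuple[float, float]:
    q1, q3 = np.percentile(v, [25, 75])
    return float(q1), float(q3)


def compare_descriptors(
    table: pd.DataFrame,
    group_col: str = "group",
    descriptors: tuple[str, ...] = DESCRIPTOR_NAMES,
    n_perm: int = 10000,
    seed: int | np.random.Generator | None = None,
    conf: float = 0.95,
) -> pd.DataFrame:
    """Two-group comparison of every descriptor, family-wise adjusted.

    ``table`` holds one row per participant with a group column and one
    column per descriptor. Participants with a missing value are dropped for
    that descriptor only. The sign convention is first group (sorted label
    order) minus second. ``p_adj`` is reported as the larger of the max|Z|
    permutation proportion and the unadjusted p, so adjustment can never
    appear anti-conservative.
    """
    groups = sorted(table[group_col].unique())
    if len(groups) != 2:
        raise ParameterError("exactly two groups are required")
    gx, gy = groups
    labels = table[group_col].to_numpy()
    order = np.argsort(labels != gx, kind="stable")  # gx first for maxz rows
    sub = table.iloc[order]
    labels = sub[group_col].to_numpy()
    values = sub[list(descriptors)].to_numpy(dtype=float)
    p_adj_perm, _ = maxz_adjust(values, labels, n_perm=n_perm, seed=seed)

    rows = []
    for j, name in enumerate(descriptors):
        col = values[:, j]
        ok = np.isfinite(col)
        x = col[ok & (labels == gx)]
        y = col[ok & (labels == gy)]
        _, _, p, r = mann_whitney(x, y)
        hl, lo, hi = hodges_lehmann(x, y, conf=conf)
        rows.append(
            GroupComparison(
                descriptor=name,
                median_x=float(np.median(x)),
                iqr_x=_iqr(x),
                median_y=float(np.median(y)),
                iqr_y=_iqr(y),
                stat=r,
                p=p,
                p_adj=float(min(max(p_adj_perm[j], p), 1.0)),
                hl=hl,
                ci_lo=lo,
                ci_hi=hi,
            )
        )
    return pd.DataFrame(
        {
            "descriptor": [c.descriptor for c in rows],
            f"median_{gx}": [c.median_x for c in rows],
            f"iqr_lo_{gx}": [c.iqr_x[0] for c in rows],
            f"iqr_hi_{gx}": [c.iqr_x[1] for c in rows],
            f"median_{gy}": [c.median_y for c in rows],
            f"iqr_lo_{gy}": [c.iqr_y[0] for c in rows],
            f"iqr_hi_{gy}": [c.iqr_y[1] for c in rows],
            "stat": [c.stat for c in rows],
            "p": [c.p for c in rows],
            "p_adj": [c.p_adj for c in rows],
            "hl": [c.hl for c in rows],
            "ci_lo": [c.ci_lo for c in rows],
            "ci_hi": [c.ci_hi for c in rows],
        }
    )
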