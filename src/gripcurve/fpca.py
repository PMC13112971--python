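"""Per-participant functional PCA over the three trial curves of a segment.

With only three curves, centering by their pointwise mean leaves a matrix of
rank at most two, so the first two principal components always explain 100 %
of the trial-to-trial variance; what matters is how that variance splits
(PC1 dominance) and how large it is relative to the signal (score SDs and
within-participant RMSD). These consistency metrics justify -- or refute --
collapsing the three trials into one mean curve per participant.

The inner product is plain Euclidean on the common normalized-time grid;
on a uniform grid this is quadrature FPCA with uniform weights up to a
constant factor, which cancels in all variance shares.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

_DEGENERATE_TOL = 1e-12


@dataclass
class FPCAParticipantResult:
    """Consistency metrics of one participant on one (segment, family)."""

    participant: str
    segment: str
    family: str
    scores: np.ndarray  # 3 x 2, trial scores on PC1/PC2 (centered: columns sum to 0)
    pc1_var: float  # percent of trial-to-trial variance
    pc2_var: float
    fpca1_std: float  # SD (ddof=1) of the three PC1 scores, units of y
    fpca2_std: float
    rmsd: float  # mean over trials of RMS deviation from the mean curve
    rmsd_p: float  # rmsd as percent of peak force


@dataclass
class FPCAGroupSummary:
    """One row of the consistency table: medians/means across a group."""

    segment: str
    family: str
    group: str
    fpca1_std: float
    fpca2_std: float
    rmsd: float
    rmsd_p: float
    pc1_var: float
    pc2_var: float


def within_participant_rmsd(
    curves: np.ndarray, mean: np.ndarray, peak: float
) -> tuple[float, float]:
    """Average over trials of the RMS deviation from the mean curve.

    ``peak`` is the participant's peak force for raw curves, or 1 for
    peak-normalized curves; ``rmsd_p`` expresses the deviation as a
    percentage of it.
    """
    if peak <= 0:
        raise ValueError("peak must be positive")
    dev = curves - mean
    rmsd = float(np.mean(np.sqrt(np.mean(dev**2, axis=1))))
    return rmsd, 100.0 * rmsd / peak


def participant_fpca(
    curves: np.ndarray,
    *,
    participant: str = "",
    segment: str = "global",
    family: str = "raw",
    peak: float | None = None,
) -> FPCAParticipantResult:
    """FPCA of one participant's three trial curves on a common grid.

    The 3 x Q matrix is centered by its pointwise mean and decomposed by SVD;
    component k explains ``sigma_k^2 / sum sigma^2`` of the variance, and the
    trial scores are the Euclidean projections on the right singular vectors.
    Three identical trials (zero variance) are reported as the degenerate
    perfectly-consistent case: PC1 = 100 %, PC2 = 0 %, zero score SDs.
    """
    Y = np.asarray(curves, dtype=float)
    if Y.ndim != 2 or Y.shape[0] != 3:
        raise ValueError("expected a 3 x Q matrix of trial curves")
    mean = Y.mean(axis=0)
    if peak is None:
        peak = float(mean.max())
    rmsd, rmsd_p = within_participant_rmsd(Y, mean, peak)

    Yc = Y - mean
    total = float(np.sum(Yc**2))
    if total < _DEGENERATE_TOL * max(1.0, float(np.sum(Y**2))):
        scores = np.zeros((3, 2))
        return FPCAParticipantResult(
            participant, segment, family, scores,
            pc1_var=100.0, pc2_var=0.0, fpca1_std=0.0, fpca2_std=0.0,
            rmsd=rmsd, rmsd_p=rmsd_p,
        )
    _, s, Vt = np.linalg.svd(Yc, full_matrices=False)
    shares = 100.0 * s**2 / np.sum(s**2)
    scores = Yc @ Vt[:2].T
    stds = scores.std(axis=0, ddof=1)
    return FPCAParticipantResult(
        participant, segment, family, scores,
        pc1_var=float(shares[0]), pc2_var=float(shares[1]),
        fpca1_std=float(stds[0]), fpca2_std=float(stds[1]),
        rmsd=rmsd, rmsd_p=rmsd_p,
    )


def group_summary(
    results: list[FPCAParticipantResult], group: str
) -> FPCAGroupSummary:
    """Summarize one (segment, family) cell across the participants of a group.

    Medians for variance shares and score SDs; means for RMSD and its
    percentage form (the distributional conventions of the consistency table).
    """
    if not results:
        raise ValueError("empty group")
    seg = {r.segment for r in results}
    fam = {r.family for r in results}
    if len(seg) != 1 or len(fam) != 1:
        raise ValueError("results mix segments or families")
    return FPCAGroupSummary(
        segment=seg.pop(),
        family=fam.pop(),
        group=group,
        fpca1_std=float(np.median([r.fpca1_std for r in results])),
        fpca2_std=float(np.median([r.fpca2_std for r in results])),
        rmsd=float(np.mean([r.rmsd for r in results])),
        rmsd_p=float(np.mean([r.rmsd_p for r in results])),
        pc1_var=float(np.median([r.pc1_var for r in results])),
        pc2_var=float(np.median([r.pc2_var for r in results])),
    )


def consistency_table(
    results: list[FPCAParticipantResult], groups: dict[str, str]
) -> pd.DataFrame:
    """Build the full consistency table: one row per (segment, family, group).

    ``groups`` maps participant id to group label. Row order follows the
    canonical segment order and sorted group labels.
    """
    from .segmentation import SEGMENTS

    rows = []
    families = sorted({r.family for r in results})
    for family in families:
        for segment in SEGMENTS:
            cell = [r for r in results if r.family == family and r.segment == segment]
            if not cell:
                continue
            for group in sorted({groups[r.participant] for r in cell}):
                members = [r for r in cell if groups[r.participant] == group]
                s = group_summary(members, group)
                rows.append(
                    {
                        "segment": s.segment,
                        "family": s.family,
                        "group": s.group,
                        "fpca1_std": s.fpca1_std,
                        "fpca2_std": s.fpca2_std,
                        "rmsd": s.rmsd,
                        "rmsd_p": s.rmsd_p,
                        "pc1_var": s.pc1_var,
                        "pc2_var": s.pc2_var,
                    }
                )
    return pd.DataFrame(rows)
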