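"""Physiologic segmentation of the mean handgrip curve.

The force-time profile is cut at five key instants -- onset, onset + 250 ms,
the first crossing of 63.2 % of peak force (the time-constant point of a
first-order step response), the peak, and the end of the test -- into four
segments plus the global curve. Each segment is then resampled onto a common
normalized-time grid tau in [0, 1] so that cluster locations can be reported
as a percentage of the segment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import SegmentationError
from .preprocess import ForceTrace

#: Segment labels, in anatomical order. ``onset_250`` is the early explosive
#: window; it overlaps ``onset_t63`` (both start at onset), while
#: ``onset_t63``, ``t63_tmax`` and ``tmax_tfinal`` partition the curve.
SEGMENTS = ("onset_250", "onset_t63", "t63_tmax", "tmax_tfinal", "global")

#: Curve families analyzed per segment: raw force, peak-normalized force,
#: and the time derivatives of each.
FAMILIES = ("raw", "norm", "draw", "dnorm")

F63_FRACTION = 0.632  # printed definition of the quasi time-constant point


@dataclass(frozen=True)
class KeyInstants:
    """The five anchor times and forces of one mean curve (seconds, kgf)."""

    t_onset: float
    t_250: float
    t_63: float
    t_max: float
    t_final: float
    F_onset: float
    F_250: float
    F_63: float
    F_max: float
    F_final: float

    def __post_init__(self) -> None:
        if not (self.t_onset < self.t_63 < self.t_max <= self.t_final):
            raise SegmentationError(
                f"key instants out of order: onset={self.t_onset}, "
                f"t63={self.t_63}, tmax={self.t_max}, tfinal={self.t_final}"
            )
        if not self.t_onset < self.t_250:
            raise SegmentationError("t_250 must follow onset")


@dataclass
class SegmentCurve:
    """One segment of one curve expressed on the normalized-time grid."""

    label: str
    tau: np.ndarray
    y: np.ndarray
    family: str
    participant: str = ""

    def __post_init__(self) -> None:
        if self.label not in SEGMENTS:
            raise ValueError(f"unknown segment label {self.label!r}")
        if self.family not in FAMILIES:
            raise ValueError(f"unknown curve family {self.family!r}")


def key_instants(trace: ForceTrace, onset: tuple[float, float]) -> KeyInstants:
    """Locate the five key instants of a mean curve.

    ``t_63`` is the first (linearly interpolated) crossing of
    ``0.632 * F_max`` at or after onset; ``t_max`` is the first maximum;
    ``t_250`` is onset + 250 ms. A ``t_250`` beyond the peak is reported with
    a warning but kept, since the early explosive window is defined by the
    clock, not by the curve.
    """
    t_onset, f_onset = onset
    t, f = trace.t, trace.f
    i_on = int(np.searchsorted(t, t_onset - 1e-12))
    imax = int(np.argmax(f))  # first maximum on ties
    F_max = float(f[imax])
    t_max = float(t[imax])
    t_final = float(t[-1])
    F_final = float(f[-1])

    target = F63_FRACTION * F_max
    above = np.nonzero(f[i_on:] >= target)[0]
    if above.size == 0:
        raise SegmentationError("curve never reaches 63.2% of its peak")
    k = i_on + int(above[0])
    if k == i_on:
        t_63 = float(t[k])
    else:
        # linear interpolation to the exact crossing
        frac = (target - f[k - 1]) / (f[k] - f[k - 1])
        t_63 = float(t[k - 1] + frac / trace.fs)

    t_250 = t_onset + 0.250
    if t_250 > t_final:
        raise SegmentationError("onset + 250 ms exceeds the recording")
    if t_250 > t_max:
        warnings.warn(
            "onset + 250 ms falls beyond the peak; early window kept as defined",
            stacklevel=2,
        )
    F_250 = float(np.interp(t_250, t, f))
    return KeyInstants(
        t_onset=float(t_onset),
        t_250=t_250,
        t_63=t_63,
        t_max=t_max,
        t_final=t_final,
        F_onset=float(f_onset),
        F_250=F_250,
        F_63=float(target),
        F_max=F_max,
        F_final=F_final,
    )


_BOUNDS = {
    "onset_250": ("t_onset", "t_250"),
    "onset_t63": ("t_onset", "t_63"),
    "t63_tmax": ("t_63", "t_max"),
    "tmax_tfinal": ("t_max", "t_final"),
    "global": ("t_onset", "t_final"),
}


def extract_segment(
    trace: ForceTrace, ki: KeyInstants, label: str
) -> tuple[np.ndarray, np.ndarray]:
    """Slice one segment out of a curve, inclusive of both boundaries.

    Boundary instants that fall between samples are included with linearly
    interpolated values, so adjacent segments share their boundary point
    exactly.
    """
    try:
        a_name, b_name = _BOUNDS[label]
    except KeyError:
        raise SegmentationError(f"unknown segment label {label!r}") from None
    ta, tb = getattr(ki, a_name), getattr(ki, b_name)
    if not tb > ta:
        raise SegmentationError(f"segment {label!r} is empty ({ta} >= {tb})")
    t, f = trace.t, trace.f
    eps = 1e-9 / trace.fs
    inside = (t > ta + eps) & (t < tb - eps)
    ts = np.concatenate(([ta], t[inside], [tb]))
    ys = np.concatenate(
        ([np.interp(ta, t, f)], f[inside], [np.interp(tb, t, f)])
    )
    return ts, ys


def to_normalized_time(
    seg: tuple[np.ndarray, np.ndarray],
    Q: int = 101,
    *,
    label: str = "global",
    family: str = "raw",
    participant: str = "",
) -> SegmentCurve:
    """Resample a raw time slice onto Q equispaced points of tau in [0, 1]."""
    ts, ys = seg
    if ts.size < 2:
        raise SegmentationError("segment has fewer than 2 points")
    span = ts[-1] - ts[0]
    if span <= 0:
        raise SegmentationError("degenerate segment (zero time span)")
    tau = np.linspace(0.0, 1.0, Q)
    y = np.interp(tau, (ts - ts[0]) / span, ys)
    # guard against round-off at the endpoints
    y[0], y[-1] = ys[0], ys[-1]
    return SegmentCurve(label=label, tau=tau, y=y, family=family, participant=participant)


def derivative_curve(trace: ForceTrace) -> ForceTrace:
    """First time derivative on the original seconds grid.

    Central differences in the interior, one-sided at the ends. Units are
    kgf/s for raw curves and 1/s for peak-normalized curves. Derivatives are
    taken before normalized-time resampling so these units are preserved;
    the parent curve's key instants are reused to cut the derivative.
    """
    if trace.n_samples < 3:
        raise SegmentationError("need at least 3 samples to differentiate")
    df = np.gradient(trace.f, 1.0 / trace.fs)
    return ForceTrace(
        t=trace.t,
        f=df,
        fs=trace.fs,
        participant=trace.participant,
        trial=trace.trial,
        normalized=False,
    )
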