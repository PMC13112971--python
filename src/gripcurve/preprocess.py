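"""Preprocessing of raw handgrip force-time trials.

Implements the steps applied to every trial before any functional analysis:
zero-lag Butterworth low-pass filtering, detection of force onset as the start
of a sustained rise, the three-valid-trials rule, onset-aligned averaging into
one mean curve per participant, and peak-force normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .errors import InvalidTrialError, ParameterError, ParticipantExcludedError

_GRID_TOL = 1e-9  # allowed deviation (s) from a uniform 1/fs grid


@dataclass
class ForceTrace:
    """A uniformly sampled force-time curve.

    Parameters
    ----------
    t : ndarray
        Sample times in seconds, strictly increasing with uniform spacing
        ``1/fs``.
    f : ndarray
        Force at each sample, in kgf (dimensionless if ``normalized``).
    fs : float
        Sampling rate in Hz.
    participant : str
        Participant identifier.
    trial : int | str | None
        Trial index, or ``"mean"`` for a trial-averaged curve.
    normalized : bool
        Whether ``f`` has been divided by its peak (max(f) == 1).
    """

    t: np.ndarray
    f: np.ndarray
    fs: float
    participant: str = ""
    trial: int | str | None = None
    normalized: bool = False

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.f = np.asarray(self.f, dtype=float)
        if self.t.ndim != 1 or self.t.shape != self.f.shape:
            raise ValueError("t and f must be 1-D arrays of equal length")
        if self.t.size >= 2:
            dt = np.diff(self.t)
            if np.any(np.abs(dt - 1.0 / self.fs) > _GRID_TOL):
                raise ValueError("time grid is not uniform at spacing 1/fs")
        if not np.all(np.isfinite(self.f)):
            raise ValueError("force contains non-finite values")
        if self.normalized and abs(self.f.max() - 1.0) > _GRID_TOL:
            raise ValueError("normalized trace must have max(f) == 1")

    @property
    def n_samples(self) -> int:
        return self.t.size

    @property
    def duration(self) -> float:
        """Total span covered by the samples, in seconds (n/fs)."""
        return self.t.size / self.fs

    @property
    def peak(self) -> float:
        return float(self.f.max())


@dataclass
class TrialSet:
    """Exactly three valid trials of one participant, plus their mean curve."""

    participant: str
    group: str
    trials: list[ForceTrace]
    onsets: list[tuple[float, float]] = field(default_factory=list)
    mean: ForceTrace | None = None

    def __post_init__(self) -> None:
        if len(self.trials) != 3:
            raise ValueError("TrialSet requires exactly 3 trials")
        fs = {tr.fs for tr in self.trials}
        if len(fs) != 1:
            raise ValueError("all trials must share the sampling rate")


def butterworth_zero_lag(
    trace: ForceTrace, order: int = 4, cutoff_hz: float = 20.0
) -> ForceTrace:
    """Low-pass filter a trace with a zero-phase Butterworth filter.

    The filter of the given ``order`` is designed once and applied
    forward-backward (``filtfilt``), which cancels the phase response; the
    effective magnitude response is the squared one-pass response. Edges are
    handled by even (reflective) padding so the t=0 region carries no startup
    transient.
    """
    nyquist = trace.fs / 2.0
    if not 0 < cutoff_hz < nyquist:
        raise ParameterError(
            f"cutoff {cutoff_hz} Hz must lie in (0, Nyquist={nyquist} Hz)"
        )
    b, a = signal.butter(order, cutoff_hz / nyquist, btype="low")
    filtered = signal.filtfilt(b, a, trace.f, padtype="even")
    return replace(trace, f=filtered, normalized=False)


def detect_onset(
    trace: ForceTrace,
    sustain_ms: float = 30.0,
    slope_tol: float | None = None,
) -> tuple[float, float]:
    """Locate force onset as the earliest start of a sustained rise.

    Onset is the earliest sample ``t0`` at which force starts to increase
    (positive discrete slope) such that (a) the slope stays non-negative over
    the following ``sustain_ms`` window, and (b) it never drops below
    ``-slope_tol`` (kgf/s) between ``t0`` and the first sample at which force
    reaches 90 % of its peak. Requiring a strictly positive first increment
    anchors the onset to the actual start of the rise rather than to a flat
    baseline, whose zero slope is also "non-negative".

    Parameters
    ----------
    trace : ForceTrace
        Filtered trial.
    sustain_ms : float
        Length of the mandatory non-negative-slope window (default 30 ms,
        i.e. 3 inter-sample slopes at 100 Hz).
    slope_tol : float, optional
        Tolerated transient negative slope in kgf/s on the way to 90 % of
        peak. Defaults to ``0.02 * peak`` per second.

    Returns
    -------
    (t_onset, f_onset)

    Raises
    ------
    InvalidTrialError
        If the peak is not positive or no sample qualifies.
    """
    f = trace.f
    peak = f.max()
    if peak <= 0:
        raise InvalidTrialError("peak force is not positive")
    if slope_tol is None:
        slope_tol = 0.02 * peak
    d = np.diff(f)  # per-sample increments
    tol_per_sample = slope_tol / trace.fs
    n_sustain = max(1, round(sustain_ms / 1000.0 * trace.fs))

    j = int(np.argmax(f >= 0.9 * peak))  # first sample at 90 % of peak

    # (a) all of d[i : i+n_sustain] >= 0, via a running window product
    nonneg = d >= 0
    if d.size < n_sustain:
        raise InvalidTrialError("trial too short for the sustain window")
    win_ok = (
        np.convolve(nonneg.astype(int), np.ones(n_sustain, dtype=int), "valid")
        == n_sustain
    )
    # (b) d[k] >= -tol for all k in [i, j): suffix-AND over d[:j]
    above_tol = d[:j] >= -tol_per_sample
    suffix_ok = np.ones(j + 1, dtype=bool)
    if j > 0:
        suffix_ok[:j] = np.logical_and.accumulate(above_tol[::-1])[::-1]

    limit = min(j, win_ok.size)  # onset must precede the 90 % crossing
    for i in range(limit + (1 if j == 0 else 0)):
        if i < win_ok.size and d[i] > 0 and win_ok[i] and suffix_ok[i]:
            return float(trace.t[i]), float(f[i])
    raise InvalidTrialError("no sustained-rise onset found")


def validate_trials(
    raw_trials: list[ForceTrace],
    participant: str = "",
    group: str = "",
    expected_duration: float = 15.0,
    sustain_ms: float = 30.0,
    slope_tol: float | None = None,
) -> TrialSet:
    """Apply the three-valid-trials rule.

    A trial is valid when an onset is detectable, its peak is positive, and it
    covers the full test duration. Participants without exactly three valid
    trials are excluded.

    Raises
    ------
    ParticipantExcludedError
        With one reason per failing trial (or a count mismatch).
    """
    reasons: list[str] = []
    onsets: list[tuple[float, float]] = []
    if len(raw_trials) != 3:
        raise ParticipantExcludedError(
            participant, [f"{len(raw_trials)} trials supplied, 3 required"]
        )
    half_sample = 0.5 / raw_trials[0].fs
    for k, tr in enumerate(raw_trials):
        trial_id = tr.trial if tr.trial is not None else k
        if abs(tr.duration - expected_duration) > half_sample:
            reasons.append(
                f"trial {trial_id}: duration {tr.duration:.2f}s != {expected_duration}s"
            )
            continue
        try:
            onsets.append(detect_onset(tr, sustain_ms=sustain_ms, slope_tol=slope_tol))
        except InvalidTrialError as exc:
            reasons.append(f"trial {trial_id}: {exc}")
    if reasons:
        raise ParticipantExcludedError(participant, reasons)
    return TrialSet(participant=participant, group=group, trials=list(raw_trials), onsets=onsets)


def mean_curve(ts: TrialSet) -> ForceTrace:
    """Average the three trials after aligning their onsets at t = 0.

    Each trial is shifted so its detected onset sits at time zero, all three
    are truncated to the shortest common post-onset length, and the force is
    averaged pointwise. Because onsets sit on the sampling grid, no
    interpolation is involved.
    """
    if len(ts.onsets) != 3:
        ts.onsets = [detect_onset(tr) for tr in ts.trials]
    fs = ts.trials[0].fs
    slices = []
    for tr, (t0, _) in zip(ts.trials, ts.onsets):
        i0 = int(round((t0 - tr.t[0]) * fs))
        slices.append(tr.f[i0:])
    n = min(s.size for s in slices)
    f_mean = np.mean([s[:n] for s in slices], axis=0)
    t = np.arange(n) / fs
    mean = ForceTrace(
        t=t, f=f_mean, fs=fs, participant=ts.participant, trial="mean"
    )
    ts.mean = mean
    return mean


def normalize_to_peak(trace: ForceTrace) -> ForceTrace:
    """Divide the curve by its peak force so max(f) == 1."""
    peak = trace.f.max()
    if peak <= 0:
        raise InvalidTrialError("cannot normalize a trace with non-positive peak")
    return replace(trace, f=trace.f / peak, normalized=True)
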