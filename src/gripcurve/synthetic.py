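"""Synthetic handgrip-strength cohort generator.

Emulates a maximal isometric grip protocol: each participant performs three
15 s trials sampled at 100 Hz. A trial is zero force until onset, a
first-order (saturating-exponential) rise to the peak, then a slow linear
decay, plus band-limited tremor noise. Group effects are configurable in
amplitude, rise time constant, and decay fraction; when the rise and decay
parameters are identical across groups the generator is in "amplitude-only"
mode, in which the peak-normalized expected curves of all groups coincide.

Defaults are anchored to published grip-dynamometry ranges for older adults
(peak force around 15 kgf for women and 25 kgf for men, time constants of
0.20-0.24 s, a quarter of peak force lost over the 15 s hold).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .errors import ConfigError
from .preprocess import ForceTrace


def _default_groups() -> dict[str, int]:
    return {"F": 44, "M": 13}


def _per_group(value, groups: list[str], name: str) -> dict[str, float]:
    """Resolve a per-group parameter: scalars broadcast; the stock F/M default
    broadcasts its mean when the cohort uses other group labels."""
    if isinstance(value, (int, float)):
        return {g: float(value) for g in groups}
    if set(value) >= set(groups):
        return {g: float(value[g]) for g in groups}
    if set(value) == {"F", "M"}:  # untouched default with custom group labels
        mid = float(np.mean(list(value.values())))
        return {g: mid for g in groups}
    raise ConfigError(f"{name} keys must cover the groups in n_per_group")


@dataclass
class GeneratorConfig:
    """Cohort-level simulation parameters.

    Per-group dictionaries must share the same keys; group order follows the
    dictionary insertion order. Coefficients of variation (CV) act on
    lognormal draws, so zero CV collapses to the group mean.
    """

    n_per_group: dict[str, int] = field(default_factory=_default_groups)
    fs: float = 100.0
    duration: float = 15.0
    amp_mean_by_group: dict[str, float] = field(
        default_factory=lambda: {"F": 15.2, "M": 25.0}
    )
    amp_cv: float = 0.20
    tau_rise_mean_by_group: dict[str, float] = field(
        default_factory=lambda: {"F": 0.20, "M": 0.24}
    )
    tau_cv: float = 0.20
    onset_delay_range: tuple[float, float] = (0.5, 1.5)
    decay_frac_by_group: dict[str, float] = field(
        default_factory=lambda: {"F": 0.23, "M": 0.27}
    )
    decay_cv: float = 0.15
    trial_amp_jitter_cv: float = 0.03
    trial_onset_jitter_sd: float = 0.05
    noise_sd: float = 0.15
    noise_cutoff: float = 8.0
    rise_time_mean: float = 1.7  # mean of t_peak - t_onset, s (all groups)
    rise_time_cv: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        groups = list(self.n_per_group)
        self.amp_mean_by_group = _per_group(self.amp_mean_by_group, groups, "amp_mean_by_group")
        self.tau_rise_mean_by_group = _per_group(
            self.tau_rise_mean_by_group, groups, "tau_rise_mean_by_group"
        )
        self.decay_frac_by_group = _per_group(
            self.decay_frac_by_group, groups, "decay_frac_by_group"
        )
        if self.fs <= 0 or self.duration <= 0:
            raise ConfigError("fs and duration must be positive")
        if min(self.amp_cv, self.tau_cv, self.decay_cv, self.trial_amp_jitter_cv) < 0:
            raise ConfigError("coefficients of variation must be >= 0")
        if self.trial_onset_jitter_sd < 0 or self.noise_sd < 0:
            raise ConfigError("jitter/noise SDs must be >= 0")
        for g, dfrac in self.decay_frac_by_group.items():
            if not 0 <= dfrac < 1:
                raise ConfigError(f"decay_frac for group {g!r} must be in [0, 1)")
        lo, hi = self.onset_delay_range
        if not 0 < lo <= hi:
            raise ConfigError("onset_delay_range must satisfy 0 < lo <= hi")
        if any(n <= 0 for n in self.n_per_group.values()):
            raise ConfigError("group sizes must be positive")
        if not 0 < self.noise_cutoff < self.fs / 2:
            raise ConfigError("noise_cutoff must lie in (0, Nyquist)")

    @property
    def amplitude_only(self) -> bool:
        """True when only amplitude differs across groups (identical shape)."""
        taus = set(self.tau_rise_mean_by_group.values())
        decays = set(self.decay_frac_by_group.values())
        return len(taus) == 1 and len(decays) == 1


@dataclass(frozen=True)
class ParticipantParams:
    """Ground-truth curve parameters of one simulated participant."""

    id: str
    group: str
    amp: float  # asymptotic force of the rise, kgf
    tau_rise: float  # first-order time constant, s
    t_onset: float  # s
    t_peak: float  # s
    decay_frac: float  # fraction of peak force lost by the end of the test

    def __post_init__(self) -> None:
        if not (0 < self.t_onset < self.t_peak):
            raise ConfigError("need 0 < t_onset < t_peak")
        if self.amp <= 0 or self.tau_rise <= 0:
            raise ConfigError("amp and tau_rise must be positive")


def _lognormal(rng: np.random.Generator, mean: float, cv: float, size: int) -> np.ndarray:
    """Lognormal draws with the given arithmetic mean and CV (CV=0 -> constant)."""
    if cv == 0:
        return np.full(size, mean)
    sigma2 = np.log1p(cv**2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), size)


def draw_participants(config: GeneratorConfig) -> list[ParticipantParams]:
    """Draw per-participant parameters for the whole cohort (deterministic in seed)."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    out: list[ParticipantParams] = []
    for group, n in config.n_per_group.items():
        amps = _lognormal(rng, config.amp_mean_by_group[group], config.amp_cv, n)
        taus = _lognormal(rng, config.tau_rise_mean_by_group[group], config.tau_cv, n)
        lo, hi = config.onset_delay_range
        onsets = rng.uniform(lo, hi, n)
        decays = np.clip(
            _lognormal(rng, config.decay_frac_by_group[group], config.decay_cv, n),
            0.0,
            0.95,
        )
        rise_times = _lognormal(rng, config.rise_time_mean, config.rise_time_cv, n)
        for i in range(n):
            # time to peak is drawn independently of the rise time constant
            # (both sexes reach their peak at similar times even when their
            # early-rise kinetics differ), but never so early that the
            # exponential rise is cut before ~98 % of its asymptote
            t_peak = onsets[i] + max(rise_times[i], 4.0 * taus[i])
            t_peak = min(t_peak, config.duration - 1.0)
            out.append(
                ParticipantParams(
                    id=f"{group}{i + 1:03d}",
                    group=group,
                    amp=float(amps[i]),
                    tau_rise=float(taus[i]),
                    t_onset=float(onsets[i]),
                    t_peak=float(t_peak),
                    decay_frac=float(decays[i]),
                )
            )
    return out


def _trial_rng(config: GeneratorConfig, params: ParticipantParams, trial_index: int):
    ident = zlib.crc32(params.id.encode())
    return np.random.default_rng(
        np.random.SeedSequence([config.seed, 1, ident, trial_index])
    )


def generate_trial(
    params: ParticipantParams, trial_index: int, config: GeneratorConfig
) -> ForceTrace:
    """Simulate one trial of one participant.

    The noiseless template is zero before the (jittered) onset, a saturating
    exponential ``A' * (1 - exp(-(t - t0')/tau))`` up to the peak instant,
    then a linear decay losing ``decay_frac`` of the attained peak force by
    the end of the test. Tremor is additive Gaussian noise low-pass filtered
    at ``noise_cutoff`` (the stated SD is the pre-filter white-noise SD).
    Force is clipped at zero.
    """
    rng = _trial_rng(config, params, trial_index)
    # trial-to-trial jitter on amplitude (lognormal, mean-preserving) and onset
    if config.trial_amp_jitter_cv > 0:
        s2 = np.log1p(config.trial_amp_jitter_cv**2)
        amp = params.amp * rng.lognormal(-s2 / 2.0, np.sqrt(s2))
    else:
        amp = params.amp
    t0 = params.t_onset + (
        rng.normal(0.0, config.trial_onset_jitter_sd)
        if config.trial_onset_jitter_sd > 0
        else 0.0
    )
    t0 = float(np.clip(t0, 1.0 / config.fs, params.t_peak - 2.0 / config.fs))

    n = int(round(config.duration * config.fs))
    t = np.arange(n) / config.fs
    f = np.zeros(n)
    rise = (t >= t0) & (t <= params.t_peak)
    f[rise] = amp * (1.0 - np.exp(-(t[rise] - t0) / params.tau_rise))
    f_peak = amp * (1.0 - np.exp(-(params.t_peak - t0) / params.tau_rise))
    after = t > params.t_peak
    end_force = (1.0 - params.decay_frac) * f_peak
    span = config.duration - params.t_peak
    f[after] = f_peak + (t[after] - params.t_peak) * (end_force - f_peak) / span

    if config.noise_sd > 0:
        white = rng.normal(0.0, config.noise_sd, n)
        b, a = signal.butter(4, config.noise_cutoff / (config.fs / 2.0), "low")
        f = f + signal.filtfilt(b, a, white, padtype="even")
    f = np.clip(f, 0.0, None)
    return ForceTrace(
        t=t, f=f, fs=config.fs, participant=params.id, trial=trial_index
    )


def generate_cohort(config: GeneratorConfig) -> pd.DataFrame:
    """Simulate the full cohort: three trials per participant, long format.

    Returns a DataFrame with columns ``participant, group, trial, t, force``,
    byte-identical for identical (config, seed).
    """
    rows = []
    for params in draw_participants(config):
        for trial in range(3):
            trace = generate_trial(params, trial, config)
            rows.append(
                pd.DataFrame(
                    {
                        "participant": params.id,
                        "group": params.group,
                        "trial": trial,
                        "t": trace.t,
                        "force": trace.f,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)
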