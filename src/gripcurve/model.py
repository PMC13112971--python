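"""Model/Results interface for the full handgrip-curve analysis.

``HandgripAnalysis`` is built from a long-format trial table (one row per
sample: participant, group, trial, t, force); ``fit()`` runs the whole
pipeline -- filtering, onset detection, trial validation, mean curves,
segmentation, per-participant FPCA consistency, SnPM group contrasts,
discrete descriptors and their family-wise-adjusted comparison -- and
returns a ``HandgripResults`` carrying every table plus a text ``summary()``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import descriptors as desc_mod
from . import fpca as fpca_mod
from . import snpm as snpm_mod
from .errors import ConfigError, ParticipantExcludedError, SegmentationError
from .preprocess import (
    ForceTrace,
    TrialSet,
    butterworth_zero_lag,
    mean_curve,
    normalize_to_peak,
    validate_trials,
)
from .segmentation import (
    FAMILIES,
    SEGMENTS,
    derivative_curve,
    extract_segment,
    key_instants,
    to_normalized_time,
)

logger = logging.getLogger("gripcurve")


@dataclass
class AnalysisConfig:
    """All tunable parameters of the analysis, defaulted to protocol values."""

    fs: float = 100.0
    expected_duration: float = 15.0
    filter_order: int = 4
    filter_cutoff_hz: float = 20.0
    onset_sustain_ms: float = 30.0
    onset_slope_tol: float | None = None  # kgf/s; None -> 2 % of peak per s
    q: int = 101  # normalized-time grid points per segment
    alpha: float = 0.05
    n_perm: int = 10000
    seed: int = 0
    families: tuple[str, ...] = FAMILIES
    segments: tuple[str, ...] = SEGMENTS

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must be in (0, 1)")
        if self.n_perm < 2 or self.q < 2:
            raise ConfigError("n_perm and q must be >= 2")
        bad = set(self.families) - set(FAMILIES)
        if bad:
            raise ConfigError(f"unknown curve families {sorted(bad)}")
        bad = set(self.segments) - set(SEGMENTS)
        if bad:
            raise ConfigError(f"unknown segments {sorted(bad)}")


@dataclass
class ParticipantCurves:
    """Aligned per-participant curves and their key instants."""

    participant: str
    group: str
    trial_set: TrialSet
    mean_raw: ForceTrace
    mean_norm: ForceTrace
    instants: object  # KeyInstants of the mean raw curve


class HandgripAnalysis:
    """Two-group functional analysis of handgrip force-time curves.

    Parameters
    ----------
    data : DataFrame
        Long format with columns ``participant, group, trial, t, force``.
    config : AnalysisConfig, optional
    """

    def __init__(self, data: pd.DataFrame, config: AnalysisConfig | None = None):
        required = {"participant", "group", "trial", "t", "force"}
        missing = required - set(data.columns)
        if missing:
            raise ConfigError(f"input table lacks columns {sorted(missing)}")
        self.data = data
        self.config = config or AnalysisConfig()

    @classmethod
    def from_csv(cls, path, config: AnalysisConfig | None = None) -> "HandgripAnalysis":
        from .pipeline import read_trials_frame

        return cls(read_trials_frame(path), config=config)

    @classmethod
    def from_simulation(cls, gen_config, config: AnalysisConfig | None = None):
        from .synthetic import generate_cohort

        return cls(generate_cohort(gen_config), config=config)

    # ------------------------------------------------------------------

    def _traces(self) -> dict[str, tuple[str, list[ForceTrace]]]:
        out: dict[str, tuple[str, list[ForceTrace]]] = {}
        for (pid, group), sub in self.data.groupby(["participant", "group"], sort=True):
            trials = []
            for trial, tsub in sub.groupby("trial", sort=True):
                trials.append(
                    ForceTrace(
                        t=tsub["t"].to_numpy(),
                        f=tsub["force"].to_numpy(),
                        fs=self.config.fs,
                        participant=str(pid),
                        trial=trial,
                    )
                )
            out[str(pid)] = (str(group), trials)
        return out

    def fit(self) -> "HandgripResults":
        cfg = self.config
        curves: list[ParticipantCurves] = []
        exclusions: list[tuple[str, str]] = []
        for pid, (group, trials) in self._traces().items():
            filtered = [
                butterworth_zero_lag(tr, cfg.filter_order, cfg.filter_cutoff_hz)
                for tr in trials
            ]
            try:
                ts = validate_trials(
                    filtered,
                    participant=pid,
                    group=group,
                    expected_duration=cfg.expected_duration,
                    sustain_ms=cfg.onset_sustain_ms,
                    slope_tol=cfg.onset_slope_tol,
                )
                m = mean_curve(ts)
                ki = key_instants(m, onset=(float(m.t[0]), float(m.f[0])))
            except (ParticipantExcludedError, SegmentationError) as exc:
                reason = "; ".join(getattr(exc, "reasons", [str(exc)]))
                exclusions.append((pid, reason))
                logger.info("excluded %s: %s", pid, reason)
                continue
            curves.append(
                ParticipantCurves(
                    participant=pid,
                    group=group,
                    trial_set=ts,
                    mean_raw=m,
                    mean_norm=normalize_to_peak(m),
                    instants=ki,
                )
            )
        if not curves:
            raise ConfigError("no participant passed trial validation")
        return HandgripResults(model=self, participants=curves, exclusions=exclusions)


@dataclass
class HandgripResults:
    """Fitted pipeline: all per-participant curves and cohort-level tables."""

    model: HandgripAnalysis
    participants: list[ParticipantCurves]
    exclusions: list[tuple[str, str]]
    _cache: dict = field(default_factory=dict, repr=False)

    # -------------------------------------------------- basic tables --

    @property
    def config(self) -> AnalysisConfig:
        return self.model.config

    @property
    def groups(self) -> list[str]:
        return sorted({p.group for p in self.participants})

    def key_instants_table(self) -> pd.DataFrame:
        rows = []
        for p in self.participants:
            ki = p.instants
            rows.append(
                {
                    "participant": p.participant,
                    "group": p.group,
                    "t_onset": ki.t_onset,
                    "t_250": ki.t_250,
                    "t_63": ki.t_63,
                    "t_max": ki.t_max,
                    "t_final": ki.t_final,
                    "F_onset": ki.F_onset,
                    "F_250": ki.F_250,
                    "F_63": ki.F_63,
                    "F_max": ki.F_max,
                    "F_final": ki.F_final,
                }
            )
        return pd.DataFrame(rows)

    # ------------------------------------------------- segment curves --

    def _family_trace(self, p: ParticipantCurves, family: str) -> ForceTrace:
        if family == "raw":
            return p.mean_raw
        if family == "norm":
            return p.mean_norm
        if family == "draw":
            return derivative_curve(p.mean_raw)
        if family == "dnorm":
            return derivative_curve(p.mean_norm)
        raise ConfigError(f"unknown family {family!r}")

    def segment_matrix(self, segment: str, family: str) -> tuple[np.ndarray, np.ndarray]:
        """(participants x Q values, labels) for one (segment, family) cell."""
        key = ("segmat", segment, family)
        if key not in self._cache:
            rows, labels = [], []
            for p in self.participants:
                trace = self._family_trace(p, family)
                seg = extract_segment(trace, p.instants, segment)
                sc = to_normalized_time(
                    seg, self.config.q, label=segment, family=family,
                    participant=p.participant,
                )
                rows.append(sc.y)
                labels.append(p.group)
            self._cache[key] = (np.vstack(rows), np.array(labels))
        return self._cache[key]

    # ---------------------------------------------------------- FPCA --

    def _aligned_trials(self, p: ParticipantCurves) -> np.ndarray:
        """The three trials onset-aligned and truncated like the mean curve."""
        fs = self.config.fs
        n = p.mean_raw.n_samples
        out = []
        for tr, (t0, _) in zip(p.trial_set.trials, p.trial_set.onsets):
            i0 = int(round((t0 - tr.t[0]) * fs))
            out.append(tr.f[i0 : i0 + n])
        return np.vstack(out)

    def fpca_results(self) -> list[fpca_mod.FPCAParticipantResult]:
        key = "fpca"
        if key not in self._cache:
            cfg = self.config
            results = []
            for p in self.participants:
                aligned = self._aligned_trials(p)
                t = p.mean_raw.t
                for family in ("raw", "norm"):
                    if family == "norm":
                        trials_f = aligned / aligned.max(axis=1, keepdims=True)
                        peak = 1.0
                    else:
                        trials_f = aligned
                        peak = p.instants.F_max
                    for segment in cfg.segments:
                        segs = []
                        for row in trials_f:
                            trace = replace(p.mean_raw, f=row, normalized=False)
                            seg = extract_segment(trace, p.instants, segment)
                            segs.append(
                                to_normalized_time(
                                    seg, cfg.q, label=segment, family=family
                                ).y
                            )
                        results.append(
                            fpca_mod.participant_fpca(
                                np.vstack(segs),
                                participant=p.participant,
                                segment=segment,
                                family=family,
                                peak=peak,
                            )
                        )
            self._cache[key] = results
        return self._cache[key]

    def fpca_summary(self) -> pd.DataFrame:
        groups = {p.participant: p.group for p in self.participants}
        return fpca_mod.consistency_table(self.fpca_results(), groups)

    # ---------------------------------------------------------- SnPM --

    def snpm(self, segment: str, family: str) -> snpm_mod.SnPMResult:
        """SnPM contrast (first group minus second) for one segment/family."""
        key = ("snpm", segment, family)
        if key not in self._cache:
            X, labels = self.segment_matrix(segment, family)
            gx, gy = self.groups
            seed = np.random.SeedSequence(
                [self.config.seed, 2, SEGMENTS.index(segment), FAMILIES.index(family)]
            )
            res = snpm_mod.snpm_test(
                X[labels == gx],
                X[labels == gy],
                alpha=self.config.alpha,
                n_perm=self.config.n_perm,
                seed=np.random.default_rng(seed),
                segment=segment,
                family=family,
            )
            self._cache[key] = res
        return self._cache[key]

    def snpm_table(self) -> pd.DataFrame:
        """All requested contrasts, one row per cluster (or one empty row)."""
        rows = []
        for family in self.config.families:
            for segment in self.config.segments:
                res = self.snpm(segment, family)
                if not res.clusters:
                    rows.append(
                        {
                            "segment": segment,
                            "family": family,
                            "n_clusters": 0,
                            "p": np.nan,
                            "start_pct": np.nan,
                            "end_pct": np.nan,
                            "extent_pct": np.nan,
                            "max_abs_t": np.nan,
                            "t_crit": res.t_crit,
                        }
                    )
                for c in res.clusters:
                    rows.append(
                        {
                            "segment": segment,
                            "family": family,
                            "n_clusters": len(res.clusters),
                            "p": c.p,
                            "start_pct": c.start_pct,
                            "end_pct": c.end_pct,
                            "extent_pct": c.extent_pct,
                            "max_abs_t": c.max_abs_t,
                            "t_crit": res.t_crit,
                        }
                    )
        return pd.DataFrame(rows)

    # --------------------------------------------------- descriptors --

    def descriptor_table(self) -> pd.DataFrame:
        key = "descriptors"
        if key not in self._cache:
            rows = [
                desc_mod.compute_descriptors(
                    p.mean_raw, p.instants, participant=p.participant, group=p.group
                )
                for p in self.participants
            ]
            self._cache[key] = desc_mod.descriptor_table(rows)
        return self._cache[key]

    def descriptor_comparison(self) -> pd.DataFrame:
        from .group_stats import compare_descriptors

        key = "comparison"
        if key not in self._cache:
            seed = np.random.SeedSequence([self.config.seed, 3])
            self._cache[key] = compare_descriptors(
                self.descriptor_table(),
                n_perm=self.config.n_perm,
                seed=np.random.default_rng(seed),
            )
        return self._cache[key]

    # -------------------------------------------------------- report --

    def summary(self) -> str:
        gx_gy = self.groups
        counts = {
            g: sum(p.group == g for p in self.participants) for g in gx_gy
        }
        lines = [
            "Handgrip force-time functional analysis",
            "=" * 47,
            f"participants: {len(self.participants)} "
            + ", ".join(f"{g}={n}" for g, n in counts.items())
            + f"; excluded: {len(self.exclusions)}",
            f"alpha={self.config.alpha}, permutations={self.config.n_perm}, "
            f"grid Q={self.config.q}",
            "",
            "SnPM clusters (contrast: "
            + " - ".join(gx_gy)
            + ")",
            "-" * 47,
        ]
        snpm_df = self.snpm_table()
        with pd.option_context("display.width", 120):
            lines.append(snpm_df.to_string(index=False, float_format="%.4g"))
            lines.append("")
            lines.append("Descriptor comparison")
            lines.append("-" * 47)
            lines.append(
                self.descriptor_comparison().to_string(index=False, float_format="%.4g")
            )
        return "\n".join(lines)
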