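# Methods

This note documents the statistical and numerical conventions of
`gripcurve`: what each stage computes, which parameters matter, what the
synthetic cohort emulates (and does not), and where genuinely open design
choices were settled.

## Signal model and preprocessing

A trial is a uniformly sampled force–time curve (default 100 Hz, 15 s,
1500 samples, force in kgf). Preprocessing follows movement-science
convention:

- **Filtering.** A low-pass Butterworth filter of order 4 with a 20 Hz
  cutoff, applied forward–backward (`filtfilt`) so the phase response
  cancels; the effective magnitude response is the squared one-pass
  response. We read "4th-order, zero-lag" as *design order 4 applied
  bidirectionally*, the common convention in movement science. Edges use
  even (reflective) padding to avoid startup transients at t = 0.
  Note that zero-phase filtering is non-causal: a step-like onset is
  smeared symmetrically, so the filtered curve genuinely begins to rise
  about 2 samples (20 ms) before the underlying event. Onset estimates on
  filtered data inherit that bias; it is common to both groups and cancels
  in contrasts.
- **Onset detection.** The earliest sample at which force starts to
  increase (strictly positive first increment) such that the slope stays
  non-negative for the following 30 ms (3 increments at 100 Hz) and never
  drops below `-slope_tol` until the curve first reaches 90 % of its peak.
  `slope_tol` defaults to 2 % of peak force per second. The strict first
  increment is needed because a flat baseline has non-negative (zero)
  slope everywhere and would otherwise qualify from the first sample.
- **Validity.** A participant enters the analysis only with exactly three
  valid trials: detectable onset, positive peak, full nominal duration
  (±half a sample). Exclusions are logged, never silently dropped.
- **Mean curve.** Trials are shifted so their onsets coincide at t = 0
  (onsets lie on the sampling grid, so no interpolation is involved),
  truncated to the shortest common post-onset length, and averaged
  pointwise. Averaging precedes normalization: the mean curve is
  normalized by *its own* peak, because the group inference operates on
  mean curves. Unaligned averaging would smear exactly the early phase the
  analysis is most interested in.

## Segmentation

Five key instants anchor the curve: onset; onset + 250 ms (the early
explosive window, defined by the clock); the first linearly interpolated
crossing of 0.632·F_max (the time-constant point of a first-order step
response — encoded as the printed 0.632, not 1 − 1/e); the first maximum;
and the final sample. Segments `onset_t63`, `t63_tmax` and `tmax_tfinal`
partition [t_onset, t_final] with shared endpoints; `onset_250` is an
overlapping early window, and `global` spans the whole curve. Note that
t_250 and t_63 have no fixed order: with rise time constants near 0.2 s
the 63.2 % crossing often precedes 250 ms.

Each segment is resampled by linear interpolation onto Q = 101 equispaced
points of τ ∈ [0, 1] (1 % resolution, matching percentage reporting).
Derivatives are central differences on the original seconds grid (exact
for linear data), computed *before* τ-resampling so their units stay
kgf/s (raw) or 1/s (normalized); the parent force curve's instants cut
the derivative.

## FPCA trial consistency

FPCA is fit per participant on their three trial curves of each segment
(onset-aligned, truncated like the mean curve; raw, and each trial divided
by its own peak for the normalized family). Centering three curves by
their pointwise mean leaves rank ≤ 2, so PC1 + PC2 always explain 100 % of
the trial-to-trial variance — this identity is asserted to 1e-6 for every
participant. The inner product is plain Euclidean on the common grid
(uniform-weight quadrature; weights cancel in variance shares). Scores are
projections on the right singular vectors; `fpca{k}_std` is the
sample SD (n − 1) of the three scores. Identical trials are the degenerate
perfectly-consistent case, reported as (100 %, 0 %) with zero score SDs.
Within-participant RMSD is the trial-average RMS deviation from the mean
curve, also expressed as a percentage of peak force (peak = 1 for the
normalized family). Cohort summaries use medians for variance shares and
score SDs, means for RMSD — the median/mean conventions of consistency
reporting; the summary statistic for score SDs is a reconstruction, since
only the variance (median) and RMSD (mean) conventions are pinned down.

## SnPM

At each of the Q grid points a pooled-variance two-sample t statistic is
computed (the standard two-sample SPM{t}; sign = first group minus
second). Inference is by permutation of group labels:

- If the number of distinct relabelings C(n, n_A) does not exceed
  `n_perm`, all are enumerated and the test is exact; otherwise the
  observed labeling plus `n_perm − 1` random relabelings are used. The
  observed labeling always participates in its own null.
- `t_crit` is the ceil((1 − α)·N)-th order statistic of the N max-|t|
  values (two-tailed inference via |t|; α defaults to 0.05).
- Clusters are maximal runs with |t| ≥ t_crit; boundaries are refined by
  linear interpolation of |t| to the exact threshold crossing, so starts,
  ends and extents are continuous percentages of normalized time.
- Each cluster's p is the proportion of relabelings whose *largest*
  supra-threshold cluster extent (at the same t_crit) reaches the observed
  cluster's extent, floored at 1/N. Cluster extent is the dominant
  non-parametric SPM cluster metric. A consequence worth knowing: under a
  very large effect many relabelings also reach full-extent clusters, so
  the p of a 0–100 % cluster is the extent-tie proportion, slightly above
  the 1/N floor.
- Degenerate grid points where both groups are constant and equal give
  t = 0; constant-but-unequal points are an error (cannot arise with
  continuous data).
- For numerical consistency, the observed t-curve is row 0 of the same
  vectorized permutation computation that builds the null, so an observed
  max-|t| exactly equal to `t_crit` is never lost to summation-order
  round-off.

## Discrete descriptors and group comparison

Descriptors are computed on the filtered, onset-aligned mean curve — the
same curve the SnPM uses — with off-grid instants (t_250, t_63) evaluated
by linear interpolation. Rates: RFD250 = (F(250 ms) − F_onset)/0.250,
RFD1 = (F63 − F_onset)/(t63 − t_onset), RFD2 = (F_max − F63)/(t_max − t63),
RFD3 = (F_final − F_max)/(t_final − t_max) (zero by convention when the
peak sits at the last sample). The fatigability index uses the trapezoidal
rule for Area₂ (exact for the generator's linear decay, which makes the
closed-form oracles clean). Timing descriptors are reported relative to
onset, so they are invariant to where the curve sits on the clock.

Group comparison per descriptor: Mann–Whitney U with mid-ranks,
tie-corrected variance, continuity correction, two-sided normal p
(appropriate at cohort sizes of tens). The "observed stat" is the
rank-biserial correlation r = 2U/(n_x·n_y) − 1 with U counting
(x > y) pairs plus half-ties, so r < 0 when the first group tends smaller.
The location shift is the Hodges–Lehmann median of all pairwise
differences with Moses order-statistic 95 % CIs. Family-wise control uses
the max|Z| permutation distribution across the ten descriptors; the
reported adjusted p is the larger of the permutation proportion and the
unadjusted p, so adjustment can never appear anti-conservative. With
missing descriptor values a participant is dropped for that descriptor
only; permutations that change the group split within the non-missing
subset are excluded from that descriptor's null.

## Synthetic cohort generator

Each participant has a parameter vector (amplitude A, rise time constant
τ, onset delay, time-to-peak, decay fraction); each trial perturbs
amplitude (mean-preserving lognormal, CV 3 %) and onset (Gaussian,
SD 50 ms) and adds Gaussian noise low-pass filtered at 8 Hz
(tremor-band; the stated SD is the pre-filter white-noise SD). The
noiseless template is zero to onset, A·(1 − exp(−(t − t₀)/τ)) to the peak
instant, then linear decay losing `decay_frac` of the attained peak by
15 s, clipped at zero.

Defaults emulate an older-adult two-sex cohort at published magnitudes:
44 F / 13 M; amplitude means 15.2 / 25.0 kgf (CV 0.20); τ means
0.20 / 0.24 s (CV 0.20); onset uniform in 0.5–1.5 s; decay fractions
0.23 / 0.27 (CV 0.15); time-to-peak lognormal with mean 1.7 s and CV 0.35,
drawn independently of τ (the sexes reach peak force at similar times even
when early-rise kinetics differ) and floored at 4τ so the exponential rise
is essentially complete. These are plausibility anchors, not fitted
values.

**Amplitude-only mode** (identical τ and decay distributions across
groups, amplitudes differing) realizes the magnitude-vs-shape dichotomy:
peak-normalized expected curves are then identical across groups. One
caveat matters: the additive tremor noise has an absolute (kgf) scale, so
its *relative* level differs between amplitude groups, and peak
normalization of noisy curves carries a small level-dependent bias
(the peak estimate is inflated by noise). At large n this ~0.1–0.3 %
systematic shape difference is real and detectable. The
magnitude-vs-shape validation therefore runs the amplitude-only cohort
with measurement noise off (trial-to-trial jitter retained — both jitter
components are scale-free), which is the exact realization of "identical
shape".

What the generator does *not* emulate: reaction time, verbal-encouragement
dynamics, device noise spectra, oscillatory force decay, multi-peak
curves, or any dependence of variability on age or health status. Passing
tests on this cohort demonstrate the pipeline's statistical properties
(exactness, type-I control, sensitivity to the programmed effects), not
that real grip curves follow the first-order model.

## Validation summary

The test suite checks, among others: exact agreement of the SnPM threshold
and cluster p-values with an independently coded full enumeration
(n = 4 + 3, 35 relabelings); family-wise type-I error of the global raw
contrast within [0.03, 0.07] over 500 null cohorts (n = 15 + 15, 1000
permutations, α = 0.05); the magnitude-vs-shape dissociation (raw
near-total cluster and no normalized cluster in ≥ 90 % of 50 amplitude-only
cohorts at n = 40 + 40); FPCA rank identity for every participant;
descriptor closed forms; Mann–Whitney/Hodges–Lehmann brute-force oracles
and 95 % CI coverage within ±3 % over 500 shift-model simulations; onset
recovery within one sample on noiseless trials. Simulation sizes were
chosen to give stable Monte Carlo estimates at interactive runtimes; the
acceptance script (`scripts/acceptance.py`) re-runs the default cohort
end-to-end with 10 000 permutations.

## Known limitations

- Cluster inference uses extent only; no combined extent-height metric.
- The unadjusted descriptor p is asymptotic (normal approximation), not
  exact, matching the Z-based family-wise adjustment.
- The onset detector is tuned for monotone-rise curves; signals with long
  sub-threshold creep before the rise will be assigned the creep start if
  it never violates the slope tolerance.
- Trials are registered by onset shift only; no time warping, so
  between-trial differences in rise speed appear as amplitude variance in
  the FPCA rather than phase variance.
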