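# gripcurve

Functional analysis of time-dependent handgrip-strength curves, HGS(t).

Peak grip force is a workhorse biomarker of muscle function in older adults,
but a single number ignores *how* force is produced: how fast it rises in the
first 250 ms, when it reaches the quasi time constant point (63.2 % of peak),
how well it is sustained over a 15 s maximal hold. `gripcurve` implements a
complete functional pipeline for two-group comparisons of such curves:

1. **Preprocessing** — 4th-order zero-lag Butterworth low-pass (20 Hz),
   onset detection as the earliest sustained rise (non-negative slope for
   30 ms, continuing within tolerance to 90 % of peak), the
   three-valid-trials rule, onset-aligned trial averaging, peak
   normalization.
2. **Segmentation** — key instants *t*onset, *t*250, *t*63, *t*max,
   *t*final cut each mean curve (and its derivative) into four physiologic
   segments plus the global curve, each resampled to normalized time
   τ ∈ [0, 1].
3. **FPCA trial consistency** — per-participant functional PCA of the three
   trial curves. Three centered curves have rank ≤ 2, so PC1 + PC2 always
   explain 100 % of trial-to-trial variance; PC1 dominance and low
   within-participant RMSD justify using the mean curve.
4. **SnPM** — non-parametric 1-D statistical mapping: a pointwise
   two-sample t-curve, a permutation max-|t| threshold (family-wise control
   over time), supra-threshold clusters with permutation p-values based on
   cluster extent. Exact enumeration is used automatically when the design
   is small enough.
5. **Discrete descriptors** — F<sub>max</sub>, t<sub>max</sub>,
   F<sub>63</sub>, t<sub>63</sub>, F<sub>final</sub>, RFD250, RFD1, RFD2,
   RFD3 and the static fatigability index
   FI = 100·(Area₁ − Area₂)/Area₁, compared across groups with
   Mann–Whitney U tests, rank-biserial effect sizes, max|Z| family-wise
   adjustment, and Hodges–Lehmann shift estimates with Moses 95 % CIs.
6. **Synthetic cohorts** — a generator of three-trial 100 Hz / 15 s
   recordings (first-order rise, linear decay, band-limited tremor noise,
   trial-to-trial jitter) with configurable group effects in amplitude,
   rise kinetics and decay, including an *amplitude-only* mode in which the
   groups share the exact same expected shape.

The central scientific use of the raw/normalized contrast pair: if two
groups differ in the **raw** curves but not in the **peak-normalized**
curves, the difference is one of magnitude (capacity), not of neuromuscular
strategy (shape/timing).

## Worked example

```python
import gripcurve as gc

model = gc.HandgripAnalysis.from_simulation(
    gc.GeneratorConfig(n_per_group={"F": 12, "M": 8}, seed=42),
    gc.AnalysisConfig(n_perm=2000, seed=42),
)
results = model.fit()
print(results.summary())
```

Output (abridged):

```
Handgrip force-time functional analysis
===============================================
participants: 20 F=12, M=8; excluded: 0
alpha=0.05, permutations=2000, grid Q=101

SnPM clusters (contrast: F - M)
-----------------------------------------------
    segment family  n_clusters      p  start_pct  end_pct  extent_pct  max_abs_t  t_crit
  onset_250    raw           1  0.007      12.21      100       87.79      4.682   2.812
     global    raw           1  0.007     0.1378      100       99.86      6.651   2.475
  onset_250   norm           0    NaN        NaN      NaN         NaN        NaN   2.825
...
Descriptor comparison
-----------------------------------------------
descriptor  median_F  ...  median_M  ...    stat         p  p_adj       hl    ci_lo   ci_hi
     F_max     15.25  ...     24.35  ... -0.9375 0.0005964  0.001   -9.895   -12.77  -6.123
    RFD250     41.73  ...     63.86  ... -0.8333  0.002308  0.005    -23.6   -34.47  -11.51
```

Reading it: the raw global contrast shows one near-total cluster (men's
absolute force exceeds women's over ~99.9 % of normalized time,
p = 0.007), while the early normalized segments show no cluster — the
simulated difference is amplitude-driven. `F_max` differs by a
Hodges–Lehmann shift of −9.9 kgf (95 % CI [−12.8, −6.1]) with family-wise
adjusted p = 0.001.

The same pipeline runs from the shell:

```bash
gripcurve simulate --seed 1 --out trials.csv
gripcurve analyze --in trials.csv --out-dir out/ --figures
gripcurve full --seed 1 --out-dir out/      # simulate + analyze in one step
```

All outputs are plain CSVs (`key_instants.csv`, `fpca_consistency.csv`,
`snpm_clusters.csv`, `descriptors.csv`, `descriptor_comparison.csv`,
`mean_curves.csv`, and per-(segment, family) curve matrices under
`segments/`) plus a `run.log` listing any excluded participants.

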