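# Methods

## Estimators

All three entropy estimators share one geometric pipeline. A series
`x_0 … x_{N−1}` is delay-embedded into template vectors
`X_i = [x_i, x_{i+τ}, …, x_{i+(m−1)τ}]`, and Chebyshev (infinity-norm)
distances are computed for every unordered pair `i < j` (self-pairs
excluded). Two conventions matter and are fixed package-wide:

- **Template count.** `i` runs over `0 … N − mτ − 1` at *both* dimensions
  `m` and `m + 1`. This is the Richman–Moorman convention: the two SampEn
  pair counts then range over identical index sets, their normalizations
  cancel, and the count at dimension `m + 1` uses every available
  template. The public `embed` operation applies the same count, so its
  output at dimension `m` is one vector short of the maximum.
- **Match rule.** SampEn counts pairs with distance *strictly below*
  `r = r_fraction · SD` (population SD of the series actually analysed).
  Ties at exactly `r` have measure zero for real data. For the degenerate
  zero-variance case (`r = 0`, e.g. a constant series) exact coincidences
  (`d = 0`) count as matches — the `r → 0+` limit — so a constant series
  has SampEn 0 rather than an undefined value; the same limit applies to
  the fuzzy membership.

**SampEn** is `−ln[n_p(m+1)/n_p(m)]`. If either count is zero the
estimate is returned as an explicit undefined marker (NaN value, reason
string, `defined=False`); downstream group summaries and contrasts skip
and count such estimates instead of averaging a sentinel.

**FuzzyEn** uses the similarity degree `exp(−d^n / r)` with `n = 2`
(default) and completes the double sum with `1/(count)` and
`1/(count − 1)` factors so `φ^k` is a mean over ordered pairs; by
symmetry this equals the mean over unordered pairs. The global variant is
implemented: no local trend removal, so FuzzyEn is comparable to SampEn
at the same `m`. Note the default membership is *not* scale invariant
(the exponent `d²/r` has units of amplitude); it is shift invariant only.
The dimensionless form `exp(−(d/r)^n)`, which is fully affine invariant,
is available via `fuzzy_membership="exp_d_over_r_n"`. Because of this
amplitude sensitivity, the synthetic noise generators normalise pink and
brown noise to unit-order expected variance so that amplitudes are
comparable with standard-Gaussian white noise; logistic-map series stay
in the map's natural (0, 1) range.

**DistEn** histograms the dimension-`m` distances on `M = 512` equispaced
bins spanning `[min d, max d]` (rightmost edge inclusive) and returns the
Shannon entropy in bits divided by `log2 M`, hence values in `[0, 1]`,
with `0·log 0 ≡ 0`. When all distances are equal the distribution is a
point mass and DistEn is 0. At `m = 1` templates are scalars and
distances are plain absolute differences. `M` is kept at 512 at every
scale of the multiscale profile.

## Multiscale profiles

The scale-`τ` representation is obtained by a zero-phase low-pass
Butterworth filter at cutoff `0.5/τ` cycles/sample — applied forward and
backward (`sosfiltfilt`), with reflection padding of `3 × order` samples
per end — *without* decimation; entropy at scale `τ` is then estimated
with embedding delay `τ`, so template windows span the same physical time
as classical coarse-graining while all samples contribute pairs. Scale 1
bypasses filtering and equals the base estimator exactly.

Two open design parameters are config-exposed with these defaults:

- **Filter order 6** (12-pole effective magnitude response after the
  forward-backward pass). The motivation for the Butterworth path over
  the moving average is its sharp transition band; a steep filter
  maximises that advantage while remaining stable on 512-sample records
  at the smallest normalized cutoff used (1/20).
- **Tolerance per scale** (`r_mode="per_scale"`): `r` is recomputed as
  `r_fraction · SD(filtered series)` at each scale, since filtering
  shrinks variance; `r_mode="global"` freezes the absolute tolerance
  computed from the raw series.

The classical moving-average coarse-graining (non-overlapping block means
of `τ` samples, output length `⌊N/τ⌋`, delay-1 embedding) is retained as
`filter_kind="moving_average_decimate"`. On a period-4 signal it
produces the known artifact: at `τ` a multiple of 4 each block average is
constant, DistEn collapses to 0, and the profile oscillates with period
4 across `τ` — the acceptance suite detects this as the fraction of
non-DC profile power at periods 4 and 2 (fundamental plus harmonic),
which is > 0.5 for the moving-average path and < 0.2 for the Butterworth
path.

## Synthetic benchmark bank

Five processes, 30 series × 512 samples each by default, one sub-seed per
series (`seed + index`): Gaussian white noise; pink noise by frequency-
domain `1/√f` amplitude shaping of a white spectrum (exact target slope,
no filter warm-up, mean removed, deterministic variance normalisation);
brown noise as a cumulative sum of white noise (scaled by
`√((n+1)/2)` so its index-averaged variance is ~1); and logistic-map
series `x(k+1) = ω x(k)(1 − x(k))` in the chaotic (ω = 4) and periodic
(ω = 3.5, attracting 4-cycle) regimes, with the initial condition drawn
uniformly in (0.1, 0.9) and 1000 transient iterations discarded — ample,
since the ω = 3.5 cycle attracts with multiplier |λ| ≈ 0.03 per period.

A consequence worth stating: after the transient the ω = 3.5 orbit is
periodic to machine precision, every template match is an exact
same-phase coincidence, the smallest cross-phase distance (0.048 in map
units) exceeds the tolerance 0.2·SD ≈ 0.042, and with the shared-index
count convention `n_p(m+1) = n_p(m)`. The periodic series' SampEn is
therefore exactly 0, and the periodic/white SampEn ratio computes to 0%
(the corresponding FuzzyEn ratio computes to ≈0.8%, and the DistEn ratio
to ≈0.28). The acceptance suite asserts both ratio bands, and the SampEn
clause is expected to fail by this analysis.

## Synthetic RRI cohort

The cohort generator is an explicitly synthetic stand-in for restricted
clinical recordings; it reproduces directional contrasts, not absolute
physiological entropy values. Each recording is

```
RRI(k) = mean_rri + sd · [ w·white(k) + s·corr(k) + c·chaotic(k) ]
```

with every component standardized to unit sample SD and `w² + s² + c² =
1`, so the SD (default 45 ms around 900 ms; SD << mean/4, hence RRI > 0)
is matched across all cells. `corr` is 1/f^β correlated Gaussian noise
(default β = 1). The presets encode two mechanisms:

- **Posture** (sympatho/vagal shift): sitting raises the correlated
  weight at the expense of the white one — supine (w, s) = (0.80, 0.60),
  sitting (0.46, 0.888). Because a 1/f process has essentially the same
  distance-distribution entropy as white noise while being much more
  predictable, this shift lowers SampEn/FuzzyEn without moving DistEn —
  the premise that a postural autonomic shift changes randomness, not
  complexity. (With β = 2, Brownian-like, the shift would drag DistEn
  along; β is exposed via `params["symp_beta"]`.)
- **Group** (impaired integrative control): the SCI presets swap part of
  the white amplitude for a standardized chaotic logistic (ω = 4)
  component at equal total variance — supine c = 0.70, sitting c = 0.4025
  (the unit-variance budget with s = 0.888 caps c below 0.46 in sitting).
  The broadband chaotic component flattens the distance distribution,
  raising DistEn by ~1% while leaving SampEn/FuzzyEn statistically
  indistinguishable from the able-bodied preset at matched SD.

The preset weights were calibrated once, against replicate cohorts at
these defaults, to reproduce the directional signature (posture detected
by SampEn/FuzzyEn but not DistEn; group detected by DistEn but not
SampEn/FuzzyEn, evaluated in the supine posture where the chaotic weight
is not budget-limited) and then frozen. What the cohort does *not*
emulate: respiratory sinus arrhythmia and Mayer-wave oscillatory
structure, within-subject correlation across postures, non-stationarity,
ectopy, or any claim about the physiological origin of the chaotic
component. Passing cohort tests therefore show that the analysis pipeline
recovers a known planted signature at realistic SD and sample sizes — not
that real SCI cohorts behave this way.

The default cohort layout is 34 AB and 14 SCI subjects with the supine
recording missing in two SCI subjects (typical of the study design the
pipeline targets), one derived sub-seed per recording.

## Cohort statistics

Entropy (or a multiscale profile) is computed per recording and compared
scale by scale: supine vs sitting within group by the Wilcoxon
signed-rank test on subjects with both recordings; AB vs SCI within
posture by the Wilcoxon rank-sum test. Undefined estimates are excluded
listwise per contrast and counted. Scale-1 contrasts form one family of
a-posteriori comparisons and are Benjamini–Hochberg FDR adjusted;
contrasts at τ ≥ 2 test distinct per-scale null hypotheses and are
reported unadjusted. All tests are two-sided.

The signed-rank null is enumerated exactly for up to 25 non-zero
differences — including midrank ties, via an integer dynamic program over
doubled midranks (scipy's exact path assumes untied ranks) — and above
that scipy's tie-corrected normal approximation is used (no continuity
correction, matching the reference implementation the tests cross-check
against). The rank-sum test uses scipy's exact enumeration when the
smaller group has ≤ 10 observations and the pooled sample is tie-free,
and the tie-corrected asymptotic otherwise. The omnibus longitudinal
model (linear mixed effects) is deliberately out of scope:
`cohort_estimates` exports the tidy long-format table (subject, group,
posture, method, m, τ, value) that any general statistics package can fit
directly.

Simulation checks use the exact tests' achievable significance levels:
at 10 vs 10 the exact two-sided rank-sum test's largest level below 0.05
is ≈ 0.043, so the empirical type-I rate sits slightly below nominal
(≈ 4%); the acceptance suite runs 600 identical-preset replications so
the binomial Monte-Carlo error (~0.8 pp) is small against the ±3 pp
tolerance.

## RRI cleaning and segmentation

Ectopic-beat editing is automated as an explicit rule (visual editing is
not reproducible): a beat is *removed* — not interpolated — when it
deviates by more than 25% from the median of its centred 5-beat window
(window shrunk at the edges). Removing more than 10% of beats flags the
series low-quality and logs a warning. The rule requires all-positive
millisecond data; zero-centred synthetic series pass through the CLI
untouched. Analysis then uses a fixed window of consecutive cleaned beats
(default: the first 512; a centred policy is available).

## Problem sizes and numerical notes

Default experiment sizes — 30 series per process, 512 samples, scales
1–20, cohorts of 34 + 14 subjects, 600-replication calibration runs — are
the package's standard desk-scale study; the full benchmark summary
(`hrvent reproduce-bank`) completes in about a minute on one CPU. All
generators are bit-reproducible from their seeds. Distances use scipy's
`pdist`; estimator equality against naive double-loop references holds to
1e-12. The qualitative multiscale trend checks operationalize "increases/
decreases with scale" as a Spearman correlation of the group-mean profile
with τ beyond ±0.95 (starting at τ = 5 for the chaotic series, whose
entropy first jumps when filtering destroys determinism) together with an
endpoint comparison; the random-walk rise is asserted at m = 1, where it
is monotone throughout the scale range at these record lengths.
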