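# Methods

This note documents the models, parameter choices, numerical conventions
and known limitations of `afcf`. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## The meta-level detection model

The package operates one level above individual AFib detectors. Each
record (a ~30 s single-lead ECG strip, represented here only by its RR
series and/or by detector outputs) carries a vector of *meta-features*:
categorical rhythm calls from base algorithms (AFib / non-AFib / noisy),
continuous scores in [0, 1], and numeric RR/HRV features. A meta-level
random forest is trained on these with expert labels, on the hypothesis
that different detectors err on different subsets of patients, so their
joint output carries more information than any single one.

Noisy-labeled records are excluded from ranking and (by default) from
fusion training, leaving a binary AFib/non-AFib problem; a flag remaps
noisy to non-AFib instead. The positive class is AFib everywhere.

## RR/HRV features

Conventions: heart rate per beat is 60000/RR_ms; standard deviations use
the n−1 denominator; onset times are prefix sums of intervals, so all
features are invariant to absolute start time; undefined values are NaN
sentinels with warnings, never infinities.

* **pNN50** is the standard definition — the percentage of successive
  RR-difference magnitudes exceeding 50 ms. (A gloss of it as a
  percentage of *intervals* larger than 50 ms circulates in the applied
  literature; that reading is a typo and is not implemented.)
* **RMSSD/RMeSSD (lag k ∈ {1,2,3})**: root mean (median) of squared
  lag-k differences. The duplicated names between the two published
  feature sets (RMSSD vs RMSSD1, COSEn1 vs COSEn2) differ in their
  sources only through different QRS detectors; this package computes
  them once on the same RR stream, so they coincide by construction.
* **Spectral LF/HF**: Lomb–Scargle periodogram of the unevenly sampled
  tachogram (no resampling artifacts), trapezoid-integrated over
  0.04–0.15 Hz and 0.15–0.40 Hz, on a 0.001 Hz grid. Raw band powers,
  normalized LFn/HFn = band/(LF+HF), and the raw ratio LF/HF are all
  reported. Records under 30 beats or 60 s are flagged unreliable rather
  than refused.
* **COSEn**: SampEn(m, r) + ln(2r) − ln(m̄RR), with Chebyshev template
  matching (d ≤ r), self-matches excluded, and n−m templates at both
  lengths m and m+1 (so a constant series gives SampEn exactly 0).
  Defaults m = 1, r = 30 ms — the established convention for short
  AF-screening RR strips; both are exposed.
* **NFEn**: fuzzy entropy of the mean-normalized series (hence scale
  invariant), templates centred on their own means, exponential
  membership exp(−(d/r)^2), r = 0.2 × SD of the normalized series.
  m, r and the exponent are exposed. A zero-variance series has no
  usable tolerance and yields the NaN sentinel.
* **MAD**: per-beat heart rate in sliding 3-beat windows; the feature is
  the median of the in-window sample SDs. The verbal definition this
  implements ("variation of heart rate over three adjacent RR segments")
  admits other readings — e.g. disjoint windows, which a knob enables —
  and the choice is fixed here as documented rather than resolvable from
  any source.
* **AFEv**: a 13-segment ΔRR Lorenz-plot evidence score in the style of
  the implantable-monitor AF detectors:
  Irregularity (occupied 40 ms bins outside the origin) − OriginCount
  (points with both |ΔRR| ≤ 80 ms) − 2 × PAC (excess of points in
  quadrants II+IV over I+III, the short-long alternation signature of
  atrial ectopy). The published mask geometry is proprietary-era detail
  not fully specified in the open literature; the mask here (origin box
  ±80 ms, four axis strips, near/far quadrants split at 440 ms, clip at
  ±1000 ms) is this package's documented rendition, validated by the
  qualitative properties that define the feature: origin-dominated
  series score ≤ 0, AF series outscore sinus series, and bigeminy is
  penalized relative to pure irregularity.
* **CNNout/RNNout** are softmax outputs of trained neural networks
  external to this package; they enter only as user-supplied columns or
  synthetic stand-ins and are never computed from RR data.

## Ranking

A single random forest (500 trees by default, entropy impurity, ⌊√p⌋
features per split, full-size bootstrap with replacement, grown to
purity) is fit once; each meta-feature's importance is the mean, over
trees, of the OOB error increase when that feature's values are permuted
within the tree's OOB set (classic per-tree Breiman permutation, not a
single global permutation — this matches the out-of-bag wording of the
forest literature and keeps every comparison honest to the tree's own
holdout). A categorical vote expands to an (is_AFib, is_noisy) indicator
pair; both indicators are permuted with one shared row permutation so
the *feature*, not a half of its encoding, is randomized. The
permutation RNG is independent of the forest RNG; both derive from one
master seed, so rankings are byte-reproducible. Ties are broken by
lexicographic feature name.

## Fusion forest

Hyperparameters (all overridable, defaults are the method): 500 trees,
**1** feature per split (maximal tree decorrelation), full-size
bootstrap with replacement, cross-entropy splits, growth to purity.
The forest's probability output is the tree-vote ratio, so every value
is an exact multiple of 1/500; sklearn's averaged leaf-probability
`predict_proba` is deliberately not used. With an even tree count exact
0.5 ties occur; ties call AFib, since in screening a missed AFib costs
more than a false alarm. The same convention applies to leaf-level count
ties. One sklearn nuance: its single-feature sampler skips features that
are constant within a node, so a node with identical encoded rows and
mixed labels terminates as a majority leaf rather than looping.

Vote encoding uses an indicator pair per categorical column (rather than
integer codes) so a single-feature split can isolate either the AFib or
the noisy signal.

**Feature-count selection**: for each k in a grid, the fusion forest is
scored by F1 over 5× repeated stratified 10-fold CV; the chosen k is the
smallest whose mean F1 is within one SD (of the best k's fold scores) of
the best mean. A pure argmax is unstable fold-to-fold; the one-SD rule
encodes the observation that beyond some k more features stop helping.
Degenerate single-class folds trigger a logged re-draw with a fresh
sub-seed.

**Persistence** is versioned JSON text (per-tree child/feature/threshold
arrays plus each leaf's vote). Prediction always runs on these arrays,
so a reloaded model is bit-identical to the in-memory one.

## Evaluation

Confusion counts with AFib positive; sensitivity, specificity, PPV, NPV
and F1 at full precision (rounding only at presentation, 3 d.p.).
F1 is computed as 2TP/(2TP+FP+FN), which equals the PPV/sensitivity
harmonic mean wherever both are defined but survives an undefined PPV.
ROC uses the "positive when score ≥ t" convention with t swept over the
distinct scores; AUC is the trapezoidal area, which equals pairwise
concordance P(s⁺>s⁻)+½P(s⁺=s⁻) — the test suite verifies this identity
against an O(n²) oracle. Categorical algorithms contribute a single
(sensitivity, specificity) operating point rather than a curve.

## Workload model

Daily screening burden at volume V and prevalence π: n₊ = round(Vπ),
n₋ = V − n₊; an algorithm with false-positive rate f₊ and false-negative
rate f₋ produces round(n₋ f₊) false positives and round(n₊ f₋) false
negatives per day, with round = half away from zero applied to **each
algorithm's count before differencing**. Per-term rounding is the
convention a screening service observes (two integer caseloads, then a
difference) and is the only convention consistent with treating each
algorithm's burden as a reportable integer; differencing exact products
first can differ by one case.

## Synthetic generators

What they emulate: 30 s records; a 2,532-record training distribution
(2,317 non-AFib / 137 AFib / 78 noisy) and a 4,644-record test
distribution (777 AFib / 3,867 non-AFib), honored *exactly* in
exact-count mode so fixtures match the reference distributions verbatim;
six categorical voters with skills in the range of strong published
detectors plus one continuous scorer; correlated voter errors.

* **Sinus RR**: mean 800 ms plus a 0.095 Hz (Mayer-wave band, 30 ms) and
  a 0.25 Hz (respiratory, 25 ms) sinusoid and 5 ms white jitter. The LF
  component is physiologically standard and also keeps lag-1
  autocorrelation high: at 800 ms intervals, respiration alone is
  sampled only ~5 beats per cycle (phase step 72°, autocorrelation
  ≈ 0.31), which would understate the serial correlation of real sinus
  rhythm.
* **AF RR**: i.i.d. log-normal, mean 700 ms, CV 0.24 — serially
  uncorrelated with high dispersion; no atrioventricular-conduction
  modelling. Slow AF uses a shifted log-normal with a hard 1010 ms
  floor, so every beat is below 59.5 bpm by construction. Noisy AF
  corrupts the stream with beat splits/merges at rate 0.08, emulating
  QRS-detection errors.
* **Ensembles**: each record has a latent difficulty zᵢ ~ N(0,1); voter
  j is correct with probability sigmoid(logit(skill_jc) − w·zᵢ). The
  shared zᵢ induces inter-voter error correlation with one
  interpretable knob w (default 1), chosen over an explicit error
  covariance for transparency. Incorrect calls go to the opposing
  rhythm class 90% of the time, noisy 10%. The continuous scorer mixes
  Beta(8,2)/Beta(2,8) class-conditional scores through the same
  difficulty channel.
* **Complementary experts**: seven voters over a uniform 7-way
  subpopulation split, correct with probability 0.98 locally and 0.70
  elsewhere; binary labels at prevalence 0.35 (high enough for stable
  F1 at n = 2000, low enough to retain class imbalance). This is the
  cleanest scenario in which fusing complementary detectors should beat
  each one individually.

What passing tests on synthetic data do **not** show: real detector
outputs are not conditionally independent given a scalar difficulty;
real RR streams carry ectopy, flutter and noise structure the log-normal
model lacks; and synthetic voters have no shared systematic blind spots
(e.g. atrial flutter). Synthetic-ensemble fusion metrics are therefore
optimistic relative to real meta-tables and are used to validate
mechanics and qualitative claims, not clinical performance.

## Problem sizes and determinism

Default experiment sizes used by the test suite and acceptance script —
ensembles of 2,532/4,644 records, 500-tree forests, 50–100 seed
replications for distributional properties, 2,000-record
complementary-experts runs — were chosen as the smallest sizes at which
the measured properties are stable across seeds. Every stochastic
component draws from `numpy.random.default_rng` streams spawned from one
master seed (forest seeds are reduced below 2³¹ for sklearn); equal
seeds give byte-identical rankings, models and generated data.

## Known limitations

* The replay of a real study's supplementary files exercises the reader
  and evaluation paths only when those files are supplied by the user;
  they are not redistributable with the package.
* The fusion forest trains on fully materialized tables; no
  out-of-core path.
* No probability calibration and no confidence intervals on metrics.
* The MAD and AFEv definitions are documented interpretations of
  under-specified published descriptions (see above); alternative
  readings would change feature values but not the pipeline contracts.
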