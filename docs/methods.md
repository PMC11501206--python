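# Methods

## Scope and data model

`epiphen` quantifies epilepsy phenotypes from rodent 4-channel video-EEG
(bilateral hippocampus, frontal and occipital cortex screws; 500 Hz,
band-passed 1–100 Hz) together with day-binned seizure diaries and
immunohistochemistry images.  All internal times are seconds from
recording start; signals are microvolts.  The on-disk formats are 16-bit
EDF (one-second records, per-channel symmetric physical range), CSV for
annotations/diaries, JSON for manifests and reports, and 16-bit TIFF/PNG
for images.

The amplitude measure used throughout is the **peak-to-trough
excursion** — the vertical distance between consecutive local extrema of
the raw trace.  Its mean over a window is the amplitude envelope.  This
estimator counts every turning point, so broadband noise dilutes it; all
thresholds that use it are ratios against a baseline measured with the
same estimator, which cancels the dilution.

## Seizure detection

A seizure is a period of rhythmic (>3 Hz) deflections exceeding
`amp_k = 2` baseline SDs lasting at least `min_dur_s = 10` s.  The
implementation:

1. **Baseline** (`baseline_stats`): per-channel mean µ, SD σ and mean
   peak-to-trough amplitude over a designated artifact-free window (for
   SE-day recordings, the hour before the injection marker; the window is
   refused if it overlaps an annotated event, and a zero-SD baseline
   blocks detection).
2. **Deflections**: local extrema with |x−µ| > 2σ, kept only when they
   alternate sides of the mean — a DC shift or one-sided drift therefore
   never registers as rhythm.
3. **Rhythmicity**: a sample is *active* when the centered 1-s window
   holds more than `2 × rhythm_hz` deflections.  One rhythm cycle
   contributes two alternating deflections (one above, one below the
   mean), so this is exactly "rhythm frequency > 3 Hz": a 2-Hz rhythm
   yields 4 deflections/s and stays below the cutoff, a 4-Hz rhythm
   yields 8 and exceeds it.
4. **Events**: per-channel active spans are merged across gaps
   < `merge_gap_s = 2` s (prevents fragmentation of one discharge),
   combined across channels (default rule `any`; `all` is available and
   used for SE), and spans shorter than 10 s are discarded.

On synthetic recordings with injected events at ≥5 SD, ≥5 Hz, ≥12 s the
detector reaches recall and precision 1.0 with mean onset error ≈0.1 s,
and produces no events on event-free background (the suites in
`epiphen.validation` and the acceptance script recompute this).

## Status epilepticus

SE onset is the start of the first merged detected span persisting more
than 5 min during which the 10-s envelope exceeds 3× the baseline mean
peak-to-trough amplitude on all four channels (≥90% of the first five
minutes, tolerating single-window flicker).  The per-channel reference is
the **first-hour peak envelope** over [onset, onset+3600 s].  SE ends at
the earliest time from which the envelope on at least three channels
stays at or below 50% of that channel's reference continuously for at
least 10 min; the reported end is the start of that sustained depression,
so a 5-min dip followed by recovery does not terminate the episode.  If
no such time exists the episode is unresolved and the end is the
recording end.  The alternative reading of the end criterion — envelope
down to twice the *pre-SE baseline* amplitude — is available via
`end_mode="twice_baseline"`; the two are not numerically identical and
the 50%-of-peak reading is the default.

Band power integrates the Welch PSD (2-s segments, 50% overlap,
0.5-Hz resolution) over delta 1–4, theta 4–8, beta 8–30, low-gamma 30–80
and high-gamma 80–100 Hz in 20-min bins plus a baseline bin.  The
low-gamma lower edge is taken as 30 Hz, contiguous with beta.

## Postictal depression

`A_pre` is the mean peak-to-trough amplitude over [onset−30 s,
onset−25 s]; the result is unscorable if that window leaves the recording
or overlaps another seizure.  The post-ictal search span is 3 min after
the seizure offset, tiled by consecutive 5-s windows; the minimal window
locates the maximal depression, the depression episode is the contiguous
run of windows below 75% of `A_pre` around it, and `A_post` is the mean
amplitude over that episode.  PID is scored when `A_post < 0.5 × A_pre`
(strict: a drop to exactly half is not "more than half").

Two estimator choices matter here and were made deliberately.  First,
taking `A_post` as the *minimum* window value directly would inherit the
downward bias of an order statistic over noisy window means (~6–8% for
the default background), enough to misclassify suppressions near the 50%
boundary; averaging over the located depression episode removes that bias
while still measuring "the amplitude during the maximal depression".
Second, postictal suppression is generalized, so amplitudes are averaged
across channels by default; a single 5-s pre-ictal window on one channel
has ~4% sampling noise under a 1/f² background, and the cross-channel
average halves it.  Single-channel scoring remains available.  With both
choices the measured ratio recovers the true suppression scale to ~2%,
and classification at scales 0.45/0.55 is reliable.

## Seizure diaries and clusters

Events are binned into 24-h days from recording start (recordings start
mid-day, so calendar midnight is not used); bins are half-open, an event
at exactly 86400 s belongs to day 1.  Summaries: total, seizures/day
(subjects with zero seizures keep frequency 0), days with seizures, and
the maximum seizure-free interval (longest run of zero-count days).
Per-seizure durations are summarized both per mouse (mean per animal) and
pooled (every seizure a data point); zero-seizure subjects are excluded
from duration means.

A **cluster** is a maximal run of ≥2 consecutive days each with
≥3 seizures (the threshold and run length are configurable; a ">3"
variant of the day threshold exists in the field's usage and is exposed
as a parameter).  The intercluster interval counts whole days strictly
between consecutive clusters; the maximum interval is reported only when
at least two clusters fall inside the recording period, otherwise it is
missing — with 3-week recordings a single long inter-cluster gap is often
not captured, and treating it as missing rather than censored-at-21-days
avoids biasing group comparisons.

## Histology quantification

Area fraction is the percentage of ROI pixels strictly above the chosen
threshold (thresholds are visual, stain-specific choices and therefore
inputs, not automated).  Particles are 8-connected components (the
ImageJ default) of suprathreshold ROI pixels; component area is pixel
count × pixel-size²; components below 10 µm² are not counted, and
components containing an ROI-border pixel (image edge or 8-adjacent to a
non-ROI pixel) are excluded as potentially cut — the completeness rule.
Border exclusion applies to counting only, not to area fraction.
Touching cells merge into one component; the manual splitting of clusters
done by a human rater is a documented limitation.  Per-animal values are
means over 3–4 sections per region, optionally grouped by dorsal/ventral
level.

## Statistics

* **Fisher's exact test** (scipy): two-sided by summing hypergeometric
  probabilities at most that of the observed table; mid-p is not used.
  Tests verify exact agreement with a full integer-arithmetic enumeration
  oracle for every table with total ≤30 and samples with margins ≤30.
* **Two-group comparisons**: Student's t, Welch's t, or Mann-Whitney U;
  `auto` mode applies the selection rule: parametric if both samples pass
  normality (D'Agostino-Pearson; Shapiro-Wilk below n=8), Student if an
  F test accepts equal variances, Welch otherwise; non-parametric when
  normality fails.
* **Two-way ANOVA**: OLS with genotype × sex interaction, Type II sums of
  squares (standard for unbalanced observational cells; balanced designs
  make the SS types coincide, which the oracle test exploits).  Tukey HSD
  over the four cells uses the model residual mean square with the
  studentized-range distribution (Tukey-Kramer for unequal cells); with
  zero residual variance the F statistics are reported as undefined.
* **Kruskal-Wallis** with tie correction, followed by Dunn's z tests on
  mean ranks with the pooled tie term, Bonferroni-adjusted over the
  number of pairs (configurable).
* **ROUT outlier removal**, specialized to the constant-location model
  the phenotype tables need: robust center = median, robust scale =
  68.27th percentile of absolute residuals with an n/(n−1) small-sample
  correction, residual t scores (df = n−1) screened by a step-down FDR at
  rate Q = 1% from the most extreme point inward.  On clean Gaussian
  samples (n = 20) the false-flag rate is ≈0.9% ≤ 2Q.  Full
  robust-regression ROUT is out of scope.
* **Percentages** are rounded half-up to one decimal, matching how
  results tables print proportions.

## Synthetic data: what it emulates and what it does not

The generator produces the statistical structure the analyses assume,
with exact truth:

* **Background EEG**: Gaussian noise with power spectral density
  ∝ 1/f^β band-limited to 1–100 Hz, scaled to an exact per-channel SD
  (default 20 µV — no physical amplitude is implied by the montage; it is
  a free scale).  The default slope is β = 2, the Brownian-like falloff
  typical of mammalian EEG/LFP.  β = 1 exactly is not usable for
  false-positive testing: by the Rice crossing-rate argument such a
  background crosses ±2 SD on alternating sides ~3–4 times per second, so
  the 2σ/3 Hz/10 s seizure definition would fire on noise continuously —
  a property of the definition, not of any particular detector.
* **Seizures**: sinusoids (default 6 Hz) with 0.5-s raised-cosine ramps;
  peak deflection = `amp_mult` × background SD, so peak-to-trough is
  twice that.  Unambiguous rhythmicity and amplitude, not biophysically
  realistic ictal morphology.
* **SE**: a continuous oscillatory phase (default 15 SD) followed by a
  step-down to decaying intermittent spike bursts; the step time is the
  exact true end.  One SE per recording.
* **Suppressions**: the signal is multiplied by `scale ∈ [0, 1)` over an
  interval on all channels.
* **Diaries**: per-day counts are Poisson (the simplest count model) at a
  base rate off-cluster and an elevated rate on designated cluster days;
  per-seizure durations are gamma (mean ≈45 s, SD ≈15 s, the scale of
  chronic convulsive seizures).  The cluster-recovery suite uses a quiet
  background (0.3/day) and cluster mean 10/day over 3 days: exact
  day-range matching requires that flanking days essentially never reach
  3 seizures and cluster days essentially always do, which is a
  high-contrast regime by construction.
* **Images**: disc-like blobs of exact pixel count (nearest-n-pixels
  rasterization, areas converted through the pixel size) placed
  non-adjacently on a noisy background whose intensities stay strictly
  below the foreground, so area-fraction and particle-count truth are
  exact.  Border-touching blobs can be placed deliberately to exercise
  the completeness rule.

Passing these suites shows the estimators recover the quantities their
definitions target under clean, known-truth conditions; it does not show
robustness to artifacts (chewing, movement), electrode drift,
non-stationary backgrounds, realistic ictal waveforms, or stain-specific
segmentation difficulty, none of which the generator emulates.

## Problem sizes and numerical choices

The validation suites run at: 50 hour-long recordings (plus 20 background
hours) for the detector; 20 SE episodes with continuous phases uniform in
20–90 min; 15 suppression cases over scales {0.2, 0.4, 0.45, 0.55, 0.7};
100 diaries; 100 random 32×32 images against a flood-fill oracle; 10,000
ROUT repetitions.  Envelope windows are 10 s with 1-s hops (SE) and 5-s
tiles (PID); detection activity uses a centered 1-s window evaluated per
sample.  The "first 2 h" seizure-count interval is closed on the right;
day bins are half-open; all tie-breaks and boundary conventions are fixed
in code and tested.  Fixed seeds make every generator call and every
pipeline run byte-reproducible.

## Known limitations

* The detector is threshold-based by design; it is not an artifact-robust
  or learned classifier, and baseline windows must be chosen artifact-free.
* SE onset/end depend on envelope windows; reported ends carry a few
  seconds of systematic earliness (window centering), well inside the
  ±1 min recovery target.
* Cluster metrics censor at the recording boundary; intercluster
  intervals require two captured clusters.
* Particle counting cannot split touching cells.
* Repeated-measures ANOVA for power-over-time is not implemented; band
  power tables are exported for external analysis.
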