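# Methods

## The measurement pipeline

The analysis chain mirrors standard practice for through-skull widefield
GCaMP imaging with an isosbestic reference channel.

**Hemodynamic correction.** Blood-volume and absorption changes modulate both
excitation channels; neural calcium modulates only the 470-nm channel. Both
channels are converted to ΔF/F against the per-pixel whole-session median, the
reference is smoothed with a centered 400-ms moving average
(round(0.4 × 11.7) = 5 frames, shrinking windows at the edges), and the
signal is regressed on the smoothed reference per pixel (OLS with intercept,
signal as response). Subtracting the fitted value removes the shared
component; the residual is the corrected trace. This direction of regression
is the only one for which the subtraction is an OLS residual, which is how
the stated goal — scale the reference to match the signal, then subtract —
is realized. A constant reference leaves the slope undefined; the signal is
mean-centered instead and a warning is raised. Pixels with non-positive
baseline are masked out of all downstream averages rather than imputed.

**Parcellation.** Subdivision traces are pixel means; grouped-region traces
are unweighted means of their constituent subdivision traces (not
pixel-weighted), exactly as the grouping is defined. The packaged synthetic
atlas is a schematic raster (one strip per subdivision per hemisphere); real
studies supply their own registered label image. Skull-landmark registration
is out of scope.

**Events.** Region traces are z-scored over the whole session (the "2 SD"
criterion is a fixed threshold on the session z-score, not a rolling SD),
median-filtered with a 5-point kernel (reflected edges), and scanned for
local maxima above 2 SD with `scipy.signal.find_peaks`; the event amplitude
is the peak's topographic prominence with an unbounded window, the find-peaks
default. Amplitudes are binned [2.0, 2.5), [2.5, 3.0), … with the final
listed interval open above; relative frequencies are normalized within each
subject × region × condition cell. Prominences below the first edge can
occur (a peak whose height clears 2 SD but which rides an elevated stretch);
they are excluded from histograms with a warning. Event analyses use
post-administration sessions.

**Decoding.** Bins are 10-s means (round(10 × 11.7) = 117 frames per bin,
at most 60 bins per session; the last bin averages the frames it has). The
classifier follows the stated configuration — SVC with C = 30, RBF kernel,
gamma = scale — with stratified 80/20 splits and per-column standardization
fit on the training split. Accuracy is averaged over resampled splits
(10,000 by default; tests and the pipeline scale this down). Chance
calibration permutes the labels freshly on every resample: a single fixed
permutation is not a valid null, because chance label–feature associations of
one finite dataset appear in both the train and test rows and inflate
held-out accuracy above 1/k (we measured ≈ 38% for three balanced classes at
180 rows). Decoders are per-subject; pre vs post is a two-sided paired
t-test over the seven subjects.

**Networks.** Z-scored traces are averaged over one-second blocks delimited
by time boundaries (600 blocks of 11–12 frames for a 600-s session at
11.7 fps), Pearson-correlated, and thresholded at |r| ≥ 0.8 (ties at exactly
0.8 are included; the absolute-value rule admits strong negative
correlations). Graphs are binary; edge weights are treated as visualization
only. The five node metrics are implemented from their defining formulas —
degree; clustering = 2·triangles/k(k−1); local efficiency = mean inverse
shortest-path length among a node's neighbours within their induced subgraph;
betweenness by Brandes' algorithm, endpoints excluded, normalized by
(n−1)(n−2)/2; closeness in the Wasserman–Faust form
((R−1)/(n−1))·(R−1)/Σd over the reachable set, zero for isolated nodes —
and verified in the tests against both networkx and an independent
brute-force oracle (Floyd–Warshall distances plus exhaustive shortest-path
enumeration). Network analysis uses post-administration sessions.

**Group statistics.** The Friedman statistic uses within-subject mean ranks
with the tie-correction divisor 1 − Σ(t³−t)/(nk(k²−1)) and a chi-square
(k−1 df) p-value; an all-tied table reports Q = 0, p = 1. Dunn's post hoc is
the Friedman (within-subject rank) variant,
z = (R̄ₐ − R̄_b)/√(k(k+1)/6n), two-sided, Bonferroni-adjusted over the
requested contrasts (the two drug-vs-saline contrasts by default; the family
is configurable, and per-bin/per-region results are reported uncorrected
beyond that). The chi-square/normal approximations to these discrete rank
nulls are accurate in the inferential tail (p ≲ 0.05) but deviate from exact
permutation p-values by up to ~0.1 in the mid-range at small n — a property
of the asymptotic formulas, not of this implementation, which matches
`scipy.stats.friedmanchisquare` exactly. The calibration tests therefore
compare against 20,000-rep permutation oracles on fixtures in the tail
regime, and verify the 5% ± 2% type-I rate at α = 0.05 on null 7 × 3 tables.

## The synthetic-study generator

The generator emulates the study design — 7 subjects × 3 consecutive days,
drug order a uniformly random permutation per subject, one 600-s pre- and one
post-administration session per day at 11.7 fps per channel — with a
counter-based seed scheme (`SeedSequence(master, spawn_key=(subject, day,
phase))`) so any session is reproducible in isolation.

**Trace model.** Each region trace is the sum of (i) a calcium-event train:
Poisson-timed causal exponential transients (decay τ = 0.3 s, matching the
fast kinetics of jGCaMP8m population signals) whose amplitudes follow a
lognormal law (median 2.0 SD, σ = 0.15) truncated below 2 SD so every planted
event clears the detection threshold in the noise-free limit; (ii) a
correlated slow Gaussian latent (AR(1), τ = 16 s, inter-regional correlation
0.80, homotopic 0.85); and (iii) white noise (SD 0.10). Event *times* come
from a global candidate train that each region joins with probability 0.87
(a region's event stream is 84% globally driven) — in widefield recordings
the dominant events are cortex-wide, and shared timing is what carries
inter-regional correlation at 1-s resolution; amplitudes are drawn
independently per region.

**Amplitude calibration.** Planted amplitudes are defined in the units the
detector reports: the session z-score of the median-filtered trace. Two
calibrations make this identification hold. The 5-point median filter
attenuates the peak of an isolated exponential transient by exactly
exp(−2/(fps·τ)) (the filtered peak is the second decay sample), so kernels
are rendered with peaks pre-scaled by the inverse. And the baseline
(latent + noise) variance is sized analytically (Campbell's theorem for the
shot-noise train, saline parameter set) so total frame variance is 1 and the
session z-score is approximately the identity. Without both calibrations no
planted amplitude maps onto a measured prominence and the generator could
not serve as detector ground truth.

**Planted drug effects** (post-administration sessions only; pre sessions use
the saline parameter set for every condition, and an optional per-day
baseline term exists but defaults to off):

* *Left somatosensory low-amplitude suppression.* Events in the 2.0–2.5 SD
  class are kept with probability `low_amp_scale_leftS` (0.5 for both drugs).
  The variance this removes returns as uncorrelated noise so that the session
  z-score is neutral with respect to condition. Thinning genuinely lowers
  left-S's shared-event covariance with other regions; because the saline
  correlations sit below the 0.8 edge threshold, left-S degree is at floor in
  every condition and its network metrics show no condition effect, matching
  the asymmetry the analyses are meant to recover.
* *Right somatosensory coupling gain.* `rightS_coupling_gain` (0.13 for both
  drugs) adds to right-S's participation probability in the global event
  train. Its event times become more shared while its event rate, amplitude
  law and prominence statistics are untouched — the drug re-times right-S
  activity rather than re-scaling it — so right-S correlations with every
  region rise (pushing its edges over the 0.8 threshold) with no side effect
  on its amplitude histogram. The two drugs carry equal effect sizes: at
  n = 7, k = 3 a consistently weaker drug has its mean rank pinned at 2 and
  can never reach Bonferroni-adjusted Dunn significance, so unequal planted
  effects would make the weaker drug's contrast unrecoverable by
  construction.

**Rates.** The planted rate is 16.5 events/min per region. Detection through
a 2-SD height criterion on a mean-zero, positively skewed trace necessarily
censors events whose launch level is low (the between-event baseline sits
below the session mean); about 45% of planted events are detected, giving
~7 detected events/min — the event counts a 10-min session of this
preparation yields. The recall contract (≥ 95% of planted ≥ 2.5 SD events
recovered within ±1 frame) is validated at a planted rate where transients
are resolvable (6/min): at the study rate, ~7% of planted events fall within
the 5-frame median window of a larger event and are physically a single
transient.

**Movie rendering.** Signal-channel pixels are baseline × (1 + 0.02·trace +
2·artifact); reference pixels are baseline × (1 + 1·artifact); both carry
white pixel noise and are interleaved with per-frame channel tags. The
artifact is a slow AR(1) ΔF/F process (SD 0.02, τ = 10 s by default) shared
by both channels with channel-specific gains — a hemodynamic stand-in, not
an optics model (no PSF, autofluorescence or vessel structure). Default
rendering is 128 × 128; a 512 × 512 mode exercises the ×4 downsampler;
tests use smaller rasters for speed.

## What the synthetic data does and does not show

Passing tests demonstrate that the pipeline recovers, at the study's own
scale (n = 7, one session per condition), planted effects of the kind and
approximate size the study reports, with calibrated false-positive behaviour
on unplanted region–metric pairs. They do not certify performance on real
recordings: the generator has no motion, photobleaching, vessel artifacts,
behavioural state structure, day effects (off by default) or heterogeneous
per-region kinetics, and its saline connectivity sits in a sparse-graph
regime (edge fractions near zero at |r| ≥ 0.8) rather than the ~50% edge
fraction real recordings of this preparation show. The threshold-straddling
placement of correlations, not the absolute edge fraction, is what the
recovery tests exercise.

## Numerical and design choices

* Frame counts are round(fps × seconds); 11.7 fps × 600 s = 7020 frames.
  Bin geometry accepts any frame count near this (7016-frame sessions give
  the same 60 bins).
* Decoder resamples default to 10,000 (the study's figure) but every test
  and the pipeline run far fewer; accuracy SE scales as 1/√resamples.
* Stage outputs are long-format CSV plus JSON summaries; every run records a
  config hash and master seed, and identical config + seed reproduce
  byte-identical summaries.
* Degenerate inputs fail loudly: non-alternating channel tags name the frame,
  empty regions name the region, zero-variance traces raise, all-tied rank
  tables report Q = 0 / p = 1, zero-variance paired differences report
  t = ±∞ with p = 0.
* The two drugs are distributionally identical under the default effects, so
  a thioperamide-vs-pitolisant decoder sits at chance; saline-vs-drug
  decodability (through the left-S mean shift and right-S coupling) is what
  drives post > pre decoding accuracy.
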