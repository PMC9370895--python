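# Methods

## Signal model and processing chain

The pipeline assumes surface EMG of cyclic locomotion: each muscle's
activity is an amplitude-modulated broadband carrier whose modulation
envelope repeats (with variability) every gait cycle. Processing order is
fixed:

1. **Band-pass 30–400 Hz**, 4th-order Butterworth run forward–backward
   (zero phase). The family/order of this stage is a package choice; it
   mirrors the explicitly 4th-order zero-phase low-pass used for the
   envelope, and zero-phase filtering is required so that burst timing is
   comparable against the touchdown events.
2. **Spectral artifact detection**: Welch periodograms with 1-s windows and
   50% overlap; a bin is a peak when its power exceeds 10× the median of a
   ±10 Hz neighborhood, and a frequency is an artifact when the peak is
   present in all retained channels (within one bin; the channel fraction is
   configurable). Physiological EMG is broadband, so a narrowband component
   shared by every channel is instrumental (mains hum, sensor interference).
   Detected frequencies are removed with a zero-phase second-order IIR
   notch, Q = 30 by default.
3. **Segmentation and stride quality control**: cycles are cut at
   touchdowns; each cycle × muscle envelope is correlated with the
   all-cycle ensemble average and a cycle is flagged when its *minimum*
   Pearson r across muscles is strictly below 0.6 — a single corrupted
   channel taints the stride, which is deliberately conservative. In the
   non-interactive default, flagged cycles are excluded automatically. A
   subject whose excluded fraction exceeds 0.5 is marked excluded and
   yields no indicators.
4. **Envelopes**: full-wave rectification, then 4th-order zero-phase
   Butterworth low-pass at 10 Hz. Tiny negative ringing is clipped to 0.
5. **Time normalization**: each cycle is linearly interpolated over
   normalized phase to 200 points (linear interpolation is monotone and
   cannot overshoot a non-negative envelope).
6. **Amplitude normalization**: each muscle is divided by its maximum over
   all strides of all speed conditions of the subject, so weights are
   comparable across subjects. An all-zero muscle is flagged and excluded
   instead of raising.

## Motor modules

The m × t matrix (cycles concatenated along time) is factorized with the
multiplicative-update NMF (squared-error objective, max 1000 iterations,
relative tolerance 1e-6), 10 random restarts, keeping the lowest-RMSE
solution; the restart loop is seeded, so results are reproducible. For
reporting, each pattern is rescaled to unit maximum with the inverse scale
absorbed into the weights. VAF is computed as 1 − SSE/SST with SST about
row (muscle) means — the "variance accounted for" reading of R².
Model-order selection offers three criteria: *best linear fit* (smallest n
such that a least-squares line through {(k, VAF(k)) : k = n..8} leaves a
residual mean square < 1e-4; VAF(n) is computed on the same concatenated
matrix the factorization sees, with 3 restarts per n to keep the 8-point
scan affordable), *VAF threshold* (smallest n with VAF ≥ 0.90), and
*fixed* (default 4, the count typically reported for reduced muscle sets
in locomotion). Ties in the linear-fit criterion go to the smallest n; the
two-point tail fit is the fallback since its residual is ~0 by
construction.

FWHM counts phase samples strictly above half of the pattern maximum
(× 100/200), summing multiple bursts. The center of activity places sample
t (1-based) at angle 2π(t−1)/200 and takes the four-quadrant angle of the
activation-weighted resultant, reported in % of cycle; when the resultant
is < 1e-9 of the total activation (uniform pattern) the CoA is undefined
and flagged rather than reported.

## Module matching

Modules live in a 2m feature space (m weights + the pattern resampled to m
points), Z-scored with the *reference* cohort's per-feature mean/sd (the
reference space stays fixed when new subjects are scored; degenerate sd = 0
features are dropped and recorded). Reference prototypes are k-means
centers (20 seeded restarts), relabeled 1..k by the CoA of each cluster's
mean member pattern so module 1 is the earliest burst. "Average Euclidean
distance" over features is read as the mean per-feature absolute deviation
from the center and the max threshold as the largest per-feature deviation:
a module is assigned to its nearest cluster only when mean ≤ 0.8 and
max ≤ 2.0, otherwise it is unclassified. (A single 2m-dimensional distance
has no per-feature maximum, so the two thresholds only make sense read
per-feature.) Pattern similarity is Pearson r, weight similarity the
cosine.

## Spinal maps

The innervation chart discretizes the myotomal anatomy into 6 slices per
segment L2–S2 (36 subsegments). Each subsegment's activation is the mean
cycle-averaged mV envelope of the muscles it innervates; missing muscles
shrink the divisor with a warning. The shipped default chart uses
conventional myotome ranges for the 8 standard muscles (Sol, GaLa, SeTe,
BiFe: L5–S2; TiAn: L4–L5; ReFe, VaLa, VaMe: L2–L4) with uniform
within-segment innervation; slice-level fractions are not anatomical claims
and the chart file is user-replaceable data. Group waveforms: lumbar =
L3 + L4 segment means, sacral = S1 + S2; L5 is excluded to limit overlap
between the groups and L2 because it contains far fewer motoneurons than
L3–L4. Timing of maximal activation breaks ties toward the earliest phase
and is circular downstream. The co-activation index normalizes each group
waveform to unit maximum and averages ((H+L)/2)·(L/H) over the cycle, with
zero contribution where H = 0 (the continuous limit).

## Reference sets

A reference set stores the cluster model, per-speed ensemble-average
lumbar/sacral waveforms, and median/quartile distributions of every
indicator, serialized as a directory of YAML/CSV with a schema tag. Sides
are pooled; age grouping is metadata only. Building requires ≥ 2 subjects
with a consistent muscle set.

## Statistics

Linear indicators use Mann–Whitney (independent) or Wilcoxon matched-pairs
(paired) two-sided tests; circular indicators (CoA, timing) use the
Watson–Williams two-sample F test with the 1 + 3/(8κ) concentration
correction, κ estimated from the mean within-group resultant length by the
standard ML approximation. The F approximation assumes concentrated
samples; a resultant length < 0.45 attaches a warning. Benjamini–Hochberg
correction is applied per indicator family (modules, spinal maps) at
α = 0.05. A 1000-replicate null simulation in the test suite checks the
empirical size of the circular test stays within [0.03, 0.07] at α = 0.05.

## Synthetic data

The generator emulates exactly the structure the analysis assumes: Gaussian
bursts (FWHM 8–12% of cycle) at 5/30/60/85% of the cycle — weight
acceptance, push-off, early swing, late swing — mixed by a fixed
non-negative weight matrix with each module dominated by its functional
muscle group; per-cycle × muscle multiplicative gain noise (CV 0.10);
cycle durations 1.1 ± 0.05 s; carriers are white noise band-passed
30–400 Hz and scaled so rectification + 10 Hz low-pass recovers the
modulator (E|N(0,σ)| = σ√(2/π)); optional line-frequency contamination and
corrupted cycles (random unrelated bursts) exercise the notch and
outlier-detection stages. Default problem sizes — 10 cycles per trial, 10
subjects per cohort, 20 replicates for recovery checks — are desk-scale
choices that keep the whole suite fast while leaving the recovery
properties comfortably away from their thresholds. Realized gains and
envelopes are returned so tests can use exact oracles.

What the generator does *not* emulate: motion artifacts with realistic
spectra, electrode-contact nonstationarity, inter-muscle crosstalk,
within-cycle shape variability beyond a scalar gain, and condition-specific
coordination changes (for example exoskeleton unloading). Passing tests
therefore validate the estimators on data satisfying the model assumptions;
they do not certify performance on pathological or heavily contaminated
recordings.

## Numerical choices and limitations

Sampling-rate uniformity is enforced to 1 ppm at load; filter edges must
sit below Nyquist. The NMF restart loop can hit the iteration cap on hard
restarts; best-of-restarts makes this harmless and the diagnostic RMSE per
restart is kept. FWHM uses a strict > max/2 comparison, so a pattern
exactly at half maximum does not count. CoA/timing are undefined (and
reported as such) for uniform or all-zero waveforms. The heel-marker
touchdown detector requires minima prominent by ≥ 25% of the trace range
and separated by ≥ 0.3 s. Known limitations: only offline processing; no
signal restoration for corrupted channels; no time-shifted or alternative
(PCA/ICA) decompositions; chart slice-level innervation is uniform within a
segment.
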