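# Methods

This note documents the models, estimators and design choices behind
`clicktypes`, and what the synthetic tests do and do not demonstrate about
real passive-acoustic data.

## Click model

Each click type is described by a template: a set of spectral peaks
(centre frequency, −3 dB bandwidth, relative amplitude) and a Gaussian modal
inter-click-interval (ICI) model (mode, sd; optionally a two-Gaussian
mixture for the bimodal false-killer-whale ICI, default mixture weight 0.5
on the short mode). The ten built-in templates carry the descriptors of the
Hawaiian-Islands click types, with the 10th/90th percentile spread of each
peak retained for the variability model.

A synthetic click is a sum of damped sinusoids, one per spectral peak, with
a symmetric (rise-and-decay) exponential envelope `exp(-a|t|)`. The
component's power spectrum is then a squared Lorentzian whose −3 dB full
width is `C·a/π` with `C = 0.6436`, so bandwidth is controlled analytically;
component amplitudes are scaled by `a` so realized spectral peak heights
follow the template's relative amplitudes. The symmetric envelope was chosen
over a one-sided decay because its spectral tails fall twice as fast (in
dB), which keeps >95% of energy inside the 10–100 kHz analysis band and
suppresses coherent interaction with the Nyquist fold for the 93.5 kHz
*Kogia* peak. Clicks are Tukey-tapered (taper fraction 0.25) to the
requested 30–1200 µs duration and high-pass filtered at 10 kHz (the
recording band). The default duration per template is `8/a` of its
narrowest component, clipped to the admissible range — long enough that
windowing does not inflate the realized bandwidth by more than ~20%.

Near the band edge the *Kogia* peak is only marginally measurable at
fs = 200 kHz: single-click spectral maxima wobble by ±1.5 kHz with the
random component phase (the folded tail beats with the direct spectrum), so
fidelity checks use the median over phase realizations — the same statistic
the descriptor pipeline reports. This mirrors the physical situation: that
peak is itself an alias of higher-frequency content in real recordings.

ICI gaps are drawn from the template's Gaussian truncated below at 5 ms (no
animal clicks faster). Received levels are expressed as
`rl_dBpp = 20·log10(peak-to-peak pressure in µPa)` through a single flat
calibration constant (default 60 dB counts→µPa); frequency-dependent
transfer functions are out of scope.

## Within-class variability

Real click features vary at two scales: between encounters (different
animals, ranges, sites, recording chains) and click-to-click within an
encounter. The generator is hierarchical: each 5-minute bin draws one
encounter-level template perturbation with sd equal to **0.6** of the pooled
10–90 percentile band, then perturbs each click at **0.2** of that band,
adds 1.5 dB spectral noise per click, and blends an ambient-noise floor
25 dB below the spectral peak into every measured spectrum. The pooled
percentile bands include cross-site and equipment variation (the stenellid
type split in the source descriptors is attributed to a recording-chain
artifact), so a single synthetic deployment legitimately sees a narrower
encounter spread. Population-level descriptor-recovery tests draw per-click
perturbations at the full pooled spread instead.

The "junk" class emulates the detector's false triggers: ship-like spectra
decaying from 10 kHz (1–2.5 dB/kHz) with occasional narrowband echosounder
lines at 10–18 kHz, slowly decaying envelopes, and un-patterned gap
distributions.

## Detector

Two-stage energy logic: short-time band energy (1 ms window, 10–100 kHz
after an 8th-order zero-phase Butterworth bandpass) is compared against a
blockwise running-median noise floor (1 s blocks) with a 6 dB trigger
margin; each triggered region contributes one candidate impulse at its
rectified maximum. Duration is the span where the analytic envelope stays
within 10 dB of its peak, measured on a window 1.5× the maximum admissible
duration so over-long events cannot be clipped into the passing band.
Candidates closer than 100 µs merge, keeping the earliest onset and the
largest peak-to-peak amplitude. Retained clicks must be 30–1200 µs and
≥ 115 dB peak-to-peak. Spectra use a 400-point (200 kHz) or 640-point
(320 kHz) Hann-windowed FFT centred on the click peak — 0.5 kHz resolution
at both rates — cropped to the common 10–100 kHz grid (181 bins). The
envelope feature is the analytic-signal magnitude over a 1.5 ms window,
resampled to 100 points and max-normalized.

## Feature estimators

* **Spectrum normalization**: affine min→0, max→1 on the dB scale;
  constant spectra are rejected as degenerate.
* **ICI distribution**: histogram of successive gaps at 10 ms bins over
  [0, 0.6] s (the bin width resolves the narrowest modal ICI of 28.4 ms,
  which no coarser width would), truncated before normalization; < 2 times
  → all-zero histogram.
* **Modal ICI**: nonlinear least-squares Gaussian fit to the histogram,
  initialized at the argmax bin with the empirical spread, mode bounded to
  [0, 0.6] s. The first bin is censored by the 5 ms physical floor and is
  excluded from the fit; degenerate histograms fall back to the argmax bin
  centre. Because truncation removes histogram mass without distorting the
  in-support Gaussian shape, the fitted mode is essentially unbiased even
  for heavily truncated types.
* **Spectral peaks**: prominence-based local maxima (2 dB), with the global
  argmax always among the candidates so band-edge peaks are not lost;
  sub-bin peak location by parabolic interpolation; −3 dB bandwidth by
  linear interpolation at the crossings, bounded by adjacent valleys,
  floored at one grid step.

## Clustering

Both phases use Chinese Whispers: nodes start as singletons and, visited in
a fresh random order per iteration, adopt the label with the largest summed
edge weight among their neighbours (ties broken at random), for at most 15
iterations. The algorithm runs 5 times with different orders; each run is
scored by its mean NMI (geometric normalization) against the other runs and
the highest-scoring partition wins, ties broken toward fewer clusters.

Graphs connect node pairs whose correlation-based similarity
`(1 + Pearson r)/2` exceeds **0.85**, with edge weight equal to the *excess*
similarity above the threshold. The excess weighting matters: with raw
similarities as weights the within-type/cross-type contrast on realistic
synthetic data is only ~0.95 vs ~0.85, and once label propagation coalesces
two adjacent types it can never split them again (a merged label always
outweighs any emerging alternative). Excess weights turn the same data into
a ~3:1 contrast and were verified to recover k = 4 planted types at 100%
purity where raw weights merged 2–3 of them at every threshold tried.

Phase 1 (within a bin) uses spectral correlation distance on min-max
normalized spectra, a 120 dB<sub>pp</sub> received-level floor, a random cap
of 10,000 nodes, and discards clusters under 50 detections. Phase 2 (across
bins) fuses spectral and envelope correlation distances by an unweighted
mean, caps the network at 20,000 bins, prunes the 1% least-connected nodes
(lowest summed intra-cluster weight) inside each cluster of the winning
partition, and discards clusters under 25 bins. The 120 dB floor is applied
only in phase 1; phase-2 nodes are bin-cluster summaries, which already
passed it. Type clusters are assigned to templates by minimum correlation
distance between the cluster's mean spectrum and the template's idealized
normalized spectrum, with clusters beyond a 0.5 distance ceiling left
"unassigned" — a programmatic stand-in for the operator-mediated grouping
used on real data.

## Classifier

A numpy feed-forward network: input (341) → four 512-node fully-connected
ReLU layers with 50% inverted dropout between them → softmax. Training
minimizes cross-entropy with Adam (learning rate 1e-3, batch 128, default
50 epochs), records validation loss per epoch, stops early after 10
non-improving epochs and restores the best-validation weights. All
randomness (initialization, batch order, dropout masks) is seeded. Balanced
training sets hold `examples_per_class` examples per class (5000 at full
scale; the separable benchmark in the tests uses 500 to stay desk-sized)
split 70/20/10; classes short of the quota keep all real bins — test and
validation are filled with real examples first — and the training split is
topped up with augmented copies (Gaussian noise at 0.05 of the normalized
range on spectrum and envelope, re-normalized; ICI histograms blended with
multinomial resamples of the class's pooled empirical ICI distribution,
weight 0.2). Augmented examples never enter test or validation.

## Evaluation

Per-class one-vs-rest metrics from bin-count confusion matrices (cell (i, j)
= bins of true class i labelled j): accuracy, recall, precision,
specificity, misclassification rate. Ratios with zero denominators are
reported as not-available, never as 0. Site matrices with a shared class
order sum element-wise for combined metrics. Comparisons against published
percentages round half-up to one decimal. The published accuracy column is
not reproducible from bin-level matrices via the accuracy equation (its
denominator evidently differs from the printed bin counts), so accuracy is
computed for new data but not asserted against the published summary.
Relative acoustic presence is 100 × (days with ≥ 1 bin of a class) /
(recording days) per deployment, averaged without weighting across a site's
deployments. The evaluation filter keeps bins whose maximum received level
is strictly above 125 dB<sub>pp</sub>.

## Problem sizes

The shipped tests run the full logic at desk scale: parameter recovery uses
10,000 gaps and 500 clicks per template; planted clustering scenes use
28 bins × 60 clicks per type for k ∈ {2, 3, 4}; the classifier benchmark
uses 500 examples per class across all ten types plus junk; the end-to-end
pipeline demo renders two 30 s scenes at 200 kHz. These sizes were chosen
so the whole suite completes in a few minutes on one CPU while every
threshold and cap in the workflow is still exercised.

## Known limitations

* The damped-sinusoid click model reproduces peak locations, bandwidths and
  durations but not the frequency-modulated upsweep structure of real
  beaked-whale clicks; passing tests show the pipeline separates types that
  differ in spectral shape, not that it reaches any particular performance
  on sea data.
* Propagation, hydrophone directivity, duty cycles and frequency-dependent
  calibration are not modelled; the flat calibration constant makes
  received levels exact by construction.
* The detector's trigger statistic is a faithful stand-in for the two-stage
  "period then impulse" logic of operational systems, whose exact internals
  vary; its single tunable is the trigger margin above the noise floor.
* Phase-2 type separation depends on the similarity threshold sitting
  between the within-type and cross-type similarity distributions; types
  with nearly identical spectra and envelopes (e.g. two broad mid-frequency
  types) can merge, as they do for human analysts without auxiliary
  evidence.
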