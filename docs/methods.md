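# Methods

## Scope and model

`vsdquant` quantifies two kinds of brain-slice imaging data:

1. **Voltage-sensitive dye (VSD) movies** of photostimulation-evoked
   population activity. A trial is a stack of grayscale frames (default
   88 × 60 px at 2.2 ms/frame, 1000 frames, stimulation after a 50-frame
   baseline, 14.6 × 17.9 µm pixels). The readout chain is: Gaussian
   smoothing (3 × 3 px, σ = 1 px in space; 3 frames, σ = 1 frame in time) →
   per-pixel baseline mean/SD over the 50 pre-stimulus frames → amplitude
   maps in SD-above-baseline units (ΔI/I % as an alternative scale) →
   activated pixels at ≥ 1 SD (1.1 SD for display) → activation size as a
   percentage of the frame → a scalar evoked response per slice →
   treated/control pair normalization in percent, summarised as mean ± SE
   with a two-sided nonparametric or t comparison.
2. **Confocal/ISH micrographs**: z-stack projection → background
   subtraction → a per-image threshold eliminating ~15 % of the total
   signal as background → suprathreshold pixels per µm² in each ROI (summed
   and mean suprathreshold intensity reported alongside) → percent of the
   control-group mean. Dark-field ISH images are quantified as the mean
   pixel intensity over a fixed ROI.

## Key design choices

**Which movie supplies the baseline SD.** Quantification in SD units leaves
a choice: estimate the per-pixel baseline SD from the smoothed movie or from
the raw one. Normalising the smoothed movie by its *own* baseline SD leaves
pure noise at unit amplitude, so ~16 % of noise pixels always exceed a 1 SD
threshold and the activation-size statistic acquires a large noise floor.
The default here (`baseline_source='raw'`) expresses the smoothed movie in
units of the raw per-pixel baseline SD: smoothing then genuinely narrows the
noise band (the spatial + temporal kernel leaves residual noise at ≈ 0.21
raw SD, pushing the effective false-positive threshold to ≈ 4.7 noise SDs)
while evoked signal, being spatially and temporally extended, is barely
attenuated. This is what makes a 1 SD cut a usable detection rule.
`baseline_source='smoothed'` restores the all-smoothed reading.

**Evoked-response reduction.** The scalar "evoked response" of a slice is
not uniquely defined by the activation maps; three reductions are available
and recorded in every output:

* `peak_activation_size` (default): maximum over a 100-frame (~220 ms)
  post-stimulus window of the per-frame activation size. Natural companion
  of the activated-pixel statistic.
* `mean_activation_size`: window mean of the same trace.
* `peak_mean_amplitude`: maximum over the window of the frame-mean SD-unit
  amplitude. This reduction is *linear* in signal amplitude, whereas the
  activated area of a Gaussian footprint grows only logarithmically with
  its peak; when the quantity of interest is a treated/control **amplitude
  ratio**, the linear reduction is the right estimator and is the one the
  ratio-recovery experiments use.

**Artifact exclusion.** The focal laser-excitation artifact occupies the
first post-stimulus frame at the uncaging site. A disc of radius 3 px
around the stimulation site is excluded from activation counting for the
first 3 post-stimulus frames (covering the artifact's spread under the
smoothing kernels). Excluded pixels still count in the frame size, so
activation size remains a percentage of the full frame.

**Other conventions.** Frame indexing is 0-based and half-open; the
baseline window is `[stim − 50, stim)`. Baseline SD uses the sample
(ddof = 1) estimator. Convolution boundaries use nearest-edge replication so
border pixels are not dimmed into the activation count. Baseline SDs below
10⁻⁶ × the mean baseline intensity are floored (and flagged) to keep
synthetic noiseless pixels finite. Non-square pixels affect physical-area
reporting only, never pixel-fraction statistics. Repeated trials of one
site are averaged frame-wise before analysis; multi-site amplitude maps are
pooled pixel-wise (mean by default, max selectable).

**Thresholding "~15 % of the total signal".** Read as 15 % of *summed
intensity*: the threshold is the smallest observed pixel value `T` such
that the summed intensity of pixels `< T` reaches 15 % of the image total
(the discreteness of pixel values can overshoot; the achieved fraction is
reported). A pixel-count mode is available behind `mode='pixels'` since the
phrase admits either reading. Thresholds are always computed per image,
never per batch.

**Statistics.** Welch's t is the default t variant (no equal-variance
assumption is warranted); all tests are two-sided. The Mann-Whitney U uses
mid-ranks; its null is enumerated exactly over all group assignments for
pooled n ≤ 12 (ties included), with a tie- and continuity-corrected normal
approximation beyond. The exact test's discrete achievable level at
α = 0.05 for n = 6 + 6 is 0.0411. ANOVA post-hoc comparisons use
Holm-adjusted pairwise pooled t-tests — a repository choice, as no standard
is implied by the data.

## The synthetic-data generator

The simulators emulate the study conditions so that every stage has an
exactly checkable input:

* Baseline noise is independent Gaussian per pixel-frame (SD 8 intensity
  units on a resting level of 1000, i.e. ~0.8 % — a realistic optical-noise
  scale for fast CCD voltage imaging); a Student-t option provides heavier
  tails, and an exponential bleaching drift is available behind a flag but
  off by default.
* The evoked response is phenomenological and separable:
  `A · noise_sd · exp(−d²/2σ²) · r(t)` with a unit-peak
  difference-of-exponentials time course (rise 5 frames ≈ 11 ms, decay 30
  frames ≈ 66 ms). Amplitude `A` is parameterised in baseline-SD units so
  ground truth aligns with the SD-unit readout. The stored
  `true_active_fraction` is the exactly enumerated percentage of pixels
  whose noiseless peak signal reaches 1 baseline SD.
* The stimulation artifact is a disc offset confined to the first
  post-stimulus frame by default (duration configurable).
* Fluorescence images are unit-peak Gaussian puncta (default peak 100,
  σ = 1.5 px) at distinct uniform positions on a noisy diffuse background,
  with the total in-frame injected signal recorded. Intensities are real
  numbers; integer camera quantisation is not applied.
* Slice pairs share spec and noise statistics with independent noise
  realisations; the treated amplitude is exactly `ratio ×` the control
  amplitude. Slice-to-slice biological variability belongs to the
  *experiment* simulator, not the pair generator: simulated experiments
  draw each slice's amplitude from a lognormal with σ = 0.24, calibrated so
  that the standard error of the 6-pair mean normalized response is ≈ 22 %
  of control, the SE scale such slice-pair experiments report.

What the simulators do **not** emulate: optics and laser power, dye
spectra and concentration, bleaching (by default), motion, biophysical
membrane dynamics, and spatially correlated (shot/dye) noise. Passing
recovery tests therefore demonstrates correctness of the quantification
machinery under a clean phenomenological signal model, not fidelity to any
particular acquisition's noise statistics.

## Verification strategy and problem sizes

* Every numerical stage is tested against a naive loop implementation on
  small random inputs (≤ 16 × 16 × 20) to 1e-9, exactly for counting.
* Activation-fraction recovery runs at the full 88 × 60 frame with 250
  frames per trial (50-frame baseline + 100-frame analysis window, with
  margin), 20 seeds per target fraction {5, 15, 30} %, peak amplitude 8 SD.
  Mean recovery error stays within ±2 percentage points; the residual
  positive bias (~1.3 points at 30 %) comes from the max-over-window
  selection acting on borderline pixels.
* Pair-ratio recovery and the power study use compact 32 × 24 × 130-frame
  movies (the statistic is frame-size-free), 10 seeded pairs per ratio
  {0.5, 1.0, 1.65}, and 1000 replicated 6-pair experiments for power.
* Statistical calibration uses 10,000-replicate Gaussian-null simulations
  at n = 6 per group; the exact-U test is judged at its achievable level.
* `scripts/acceptance.py` recomputes all of these from scratch from a
  single seed.

## Known limitations

* The activated-pixel statistic saturates: activation size cannot exceed
  100 % and its ratio between conditions is not an amplitude ratio; use
  `peak_mean_amplitude` for ratio questions.
* The exact-U enumeration is combinatorial; beyond pooled n = 12 the
  normal approximation is used automatically.
* `percent_of_control` on summed suprathreshold intensity is diluted
  toward 100 % by residual background pixels; direction and ordering of
  effects are preserved (verified down to ratio 0.69 and up to 4.0), but
  absolute percentages underestimate strong effects.
* ROIs are masks or rectangles from config; there is no interactive
  drawing, no motion/bleaching correction, no colocalization and no
  deconvolution.
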