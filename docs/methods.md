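# Methods

This note documents the models, parameter choices and numerical conventions
behind `v1sparse`, and what the synthetic benchmarks do and do not show.

## The synthetic population model

The generator is the package's stand-in for recordings of ~1000 V1 neurons
responding to a large natural-image set.  It produces an S × N tuning
matrix (stimuli × neurons, ΔF/F0 units) with two components:

* **Strong responders.**  Each stimulus drives `k_strong` neurons with an
  amplitude drawn uniformly in [`amp_strong`, 1.1·`amp_strong`]
  (default `amp_strong` = 1.0 ΔF/F0).  Strong slots are dealt from a
  balanced pool in which every neuron appears as evenly as possible, so
  that when `k_strong·S ≥ N` every neuron is a strong responder to at
  least one stimulus.  This mirrors the empirical picture — almost every
  recorded cell responds strongly to some image — and makes the zero-noise
  closure exact: the half-max population sparseness of the noiseless
  tensor is `k_strong/N` for every stimulus, and per-neuron lifetime
  counts equal the planted assignment.  A fully independent uniform draw
  per stimulus would leave ~e⁻¹ of neurons with no strong stimulus, whose
  half-max thresholds would then sit in the weak-response noise and break
  that closure.
* **Weak background.**  All other entries are half-normal with scale
  `weak_scale` (default 0.05), keeping the matrix non-negative like ΔF/F0
  responses.  No quantitative distribution of weak responses is available
  for this preparation; the half-normal is a modelling choice, not an
  inference.

Trials add i.i.d. Gaussian noise (`noise_sd`, default 0.1 ΔF/F0) and are
floored at zero by default (disable `floor_at_zero` where unbiased trial
means matter, e.g. law-of-large-numbers checks).

**Desk scale.**  Defaults are S = 200 stimuli × N = 200 neurons × 3 trials
with `k_strong` = 1 — the same 0.5% strong fraction as the full-scale
setting (2250 × ~1000, `k_strong` ≈ 5), at a size where the entire test
suite runs in seconds.  The full scale is available by passing the sizes
explicitly.

**Movies.**  `generate_movie` renders disc ROIs (radius 3.5 px ≈ 37 px)
on a regular grid.  Background pixels carry a slowly varying neuropil
field n(t); ROI pixels carry `f0·(1 + ΔF/F0 target) + r·n(t)`, so
subtracting `r` times the annulus trace recovers the somatic signal
exactly — the planted contamination and the correction share the same
index `r` = 0.7 by construction.  Planted per-frame integer translations
are zero during an initial reference epoch (the frames averaged into the
registration template) and i.i.d. uniform afterwards; ROIs keep a margin
larger than the maximum shift plus the annulus extent so that noiseless
round trips are exact.  The generator does not model indicator kinetics
(rise/decay, saturation) or bleaching; movie-level results validate the
pipeline's arithmetic, not biophysics.

## Imaging front end

* **Registration** searches integer shifts within ±`max_shift` for the
  maximum normalized cross-correlation with the template (the mean of the
  first `template_frames` frames).  Vacated edge pixels are filled from
  the template so differential images stay unbiased at borders; a
  zero-variance frame registers as (0, 0) with a warning.  Registration is
  idempotent on noiseless data.
* **Differential images** are mean ON minus mean OFF frames per stimulus,
  pooled over trials.
* **Band-pass** is a difference of Gaussians, σ = `low_size` minus
  σ = `high_size`.  The canonical sizes are 5 and 50 px, read as Gaussian
  σ values (the conventional single-parameter specification); both are
  configuration.  For the synthetic movies the defaults scale down to
  1 and 20 px because the planted somata (~37 px) are an order of
  magnitude smaller than real cell bodies at recording resolution; filter
  scales should track the cell scale.
* **ROI detection** thresholds each band-passed differential image at its
  mean + 3·std (statistics over all pixels of that image) and keeps
  8-connected components larger than 25 pixels.  Components from
  different differential images are merged (union) when their overlap
  exceeds half the smaller component — the consolidation rule across
  stimuli is not uniquely determined by the functional-segmentation
  recipe, so this is a documented choice.  Remaining partial overlaps are
  resolved by assigning contested pixels to the larger ROI, keeping pixel
  sets disjoint.  The band-pass exists only for detection; every
  measurement downstream reads raw data.
* **Neuropil annuli** are 4 px wide, starting 2 px outside each ROI, and
  exclude all ROI pixels.

## Traces and ΔF/F0

Neuropil correction (`F − 0.7·F_np`) is applied to raw traces *before*
ΔF/F0, the standard order.  F0 is the mean corrected trace over the
trial's blank window; F is the mean over the full 1 s stimulus window
(8 frames at 8 fps; window offsets are configurable since the exact
sub-window is a free choice).  A non-positive baseline aborts with the
trial named rather than propagating NaNs into the counts.

## Sparseness

Counts use trial-mean responses and a strict `>` at `thresh_frac` × peak
(default 0.5): ties at exactly half-peak do not count.  Neurons with a
non-positive peak are excluded from numerators and denominators and
reported.  Both measures are invariant to rescaling any single neuron, and
the per-stimulus and per-neuron counts sum to the same number (they count
the same strong (stimulus, neuron) pairs).  The moment-based measure
`(1 − a)/(1 − 1/n)` with `a = (Σr/n)²/(Σr²/n)` is provided for
comparison only; responses are floored at 0 for it and all-zero vectors
are reported as missing.

## Reliability (shuffle ROC)

The ON class is `mean response > 0.5 × max mean response`; the AUC is the
rank-sum (Mann–Whitney) formulation with ties counting ½, invariant under
any increasing transform of the responses.  Each of the 1000 shuffles
permutes the pooled R·S single-trial responses jointly across
(trial, stimulus) slots and *recomputes* the per-stimulus means, the
maximum, the half-max threshold and the classes before its AUC — without
that recomputation the null would be too easy.  Shuffles with an empty OFF
class score AUC = 0.5.  Shuffle AUCs ≥ the observed AUC count against
significance (ties are conservative), and the default p-value is
`(1 + hits)/(1 + n_shuffles)`, which cannot be exactly zero; the plain
fraction is available via `plus_one=False`.  Calibration on exchangeable
null neurons puts the type-I rate at α = 0.01 at ~0.01 (the `+1/+1`
convention is slightly conservative).  No multiple-testing correction is
applied across neurons; the reported criterion is per-neuron p < 0.01.

## Decoding

Centroids are element-wise means of the held-in trials; prediction is the
Euclidean-nearest centroid row with ties broken toward the smallest
stimulus index (deterministic).  Accuracy is averaged over the R held-out
trials.  Thresholding pools all R·S·N entries (absolute mode) or
peak-normalized entries (relative mode; neurons with non-positive peaks
never rank into the top) and keeps/zeroes the top p%; the cut keeps
exactly round-to-nearest(p%·count) entries (ceiling when fractional),
with ties at the cut resolved by a stable order (neuron, then stimulus,
then trial), so `top_only(p)` and `top_excluded(p)` partition the entries
exactly and p = 100 / p = 0 reproduce the untouched tensor bit-for-bit.
Thresholding is applied before the cross-validation split, to train and
test alike.  The default evaluation grid is the 29-point percentage list
{0, 0.1, …, 0.9, 1, 2, …, 10, 20, …, 90, 99}.  A second reading of the
peak-relative variant — top p% *within* each neuron rather than pooled
peak-normalized ranking — is exposed as `mode="relative_per_neuron"`;
pooled ranking is the default because it is the only reading under which
"the top 0.5% of responses" is commensurable with the population-
sparseness fraction.

## Problem sizes used in the benchmarks

The acceptance script and acceptance tests use: the desk-scale tensor
(3 × 200 × 200) for sparseness, reliability and decoding; S = 2250 with 50
stimulus-independent neurons for the chance-level check; 2000 null neurons
(R = 3, S = 50) for type-I calibration and 200 tuned replicates (S = 200)
for power; and a 128 × 128, 200-trial noiseless movie with 16 planted ROIs
for the imaging round trip.  These sizes were chosen so the whole suite
completes in minutes on one CPU while each statistic retains enough
replication to be meaningful.

## What passing does and does not show

The synthetic generator matches the *structure* the analysis assumes, with
clean separations (strong ≫ weak responses, exact integer shifts, linear
fluorescence).  Passing closures therefore demonstrates correctness of the
implementation — registration, segmentation, extraction arithmetic,
counting and decoding — not robustness to real-data pathologies: non-rigid
motion, z-drift, overlapping somata, indicator nonlinearity, correlated
noise, or eye-movement artefacts are all outside the model.  Desk-scale
decoding accuracies (≈100% full-data) are higher than any real recording
because the synthetic tuning is noiseless across trials up to i.i.d.
Gaussian noise; the *shape* of the thresholded-decoding curves (steep rise
of top-only at small p; steep fall of top-excluded) is the reproducible
qualitative finding.
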