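# Methods

`neurofuse` implements an encoding-model pipeline for asking *where* in an
intracranial (SEEG) recording vision and language information are integrated.
The question is operationalised as a model-comparison problem: an electrode is
called a multimodal integration site when a multimodal vision-language network
predicts its activity better than every unimodal network, under a battery of
increasingly strict statistical tests.

## Event structures and alignments

The stimulus (a movie) is parsed into *event structures* — image-text pairs —
under two alignments:

* **language-aligned**: one event per word onset; the text is the word with
  its sentence context, the image is the movie frame nearest the onset
  (equidistant frames resolve to the earlier one);
* **vision-aligned**: one event per scene cut; the image is the cut frame, the
  text is the first sentence whose onset is at or after the cut (closed
  boundary; cuts with no following sentence are dropped and counted).

Scene-cut detection and audio alignment are upstream of this package: cut and
word tables are inputs.

## Epoching and binning

Around each event onset a window from −2000 ms to +2000 ms is extracted and
reduced to mean amplitudes in 200 ms sub-windows advanced in 25 ms steps.
Bin *start* offsets span [−2000, +2000] inclusive, giving exactly 161 bins;
each bin averages the 200 ms after its start, so epochs extend to +2200 ms.
(Splitting a 4000 ms window naively gives 153 bins; the inclusive-start
convention is the one consistent with the published figure count of 161 and is
declared here, not inferred.)  Events without full margin inside the recording
are dropped, never zero-padded — padding would bias bin means.  No
re-referencing, detrending or spectral processing is applied.

## Encoding model

Per electrode, per time bin, ridge regression predicts mean bin activity from
a network layer's feature vector over events.  Cross-validation uses 5
*contiguous* folds: fold *f* holds out the *f*-th fifth of the event sequence
(first half validation, second half test) and trains on the remainder, so
held-out events are temporally separated from training events — the defence
against the movie's autocorrelation.  Features are standardised per column
and targets centred with training-fold statistics only.  Performance is the
Pearson correlation between predicted and actual activity over held-out
events (not over time), averaged across folds.  Degenerate fits (constant
response in a fold) propagate as missing values, never as zeros.

The ridge penalty grid is {1e−2, 1e−1, 1, 10, 100, 1000} (configurable).

**Layer/penalty selection granularity.**  The (layer, λ) pair is selected on
validation scores, by default one pair per *electrode* per fold (maximising
the across-bin mean validation correlation).  Per-bin selection is available
(`selection="bin"`) but is anti-conservative at small validation-block sizes:
with 40 validation events the max over ~18 configurations inflates the
selected per-bin validation score by ≈0.13 under the null — the same order as
the bootstrap CI half-width — and the bin filter described below then passes
large numbers of pure-noise bins (measured: ~158/161 false survivors per
noise electrode at n=400).  Electrode-level selection decouples the
hyperparameter choice from any single bin's validation noise and restores
filter calibration; it is also what large-scale encoding practice does (one
penalty per voxel/electrode, not per time point).

## Event bootstrap

Confidence intervals per (electrode, model, bin, split) come from resampling
events with replacement B times (default 1000; the desk-scale test profile
uses 100) and re-running the *entire* procedure — standardisation, every
(layer, λ) fit, and the validation-based selection — on each resample.
Resampling is performed independently inside each train/validation/test
block, preserving split membership; whole-dataset resampling would move
events across splits and contaminate selection.  The same resampled indices
are used for every model and electrode so models can be compared
resample-by-resample.  CIs are empirical percentile intervals (95%, linear
interpolation) over resamples, requiring ≥0.8·B non-missing scores.

Freezing the original (layer, λ) selection and refitting only the weights is
available (`refit_selection=False`) but is *not* the default: the winner's-
curse bias of the original selection then sits at the centre of every
resample's distribution, and the null false-survival rate of the validation
filter rises about five-fold (measured on pure-noise banks).

## Bin filtering, default winners, model comparison

A bin survives for (electrode, model) when the lower 95% validation CI is
strictly above zero (a bound exactly at zero counts as overlapping).  Models
with no surviving bins are removed from that electrode.  If exactly one model
has ≥10 surviving bins it is the best model by default.  With more than two
models this literal rule rarely fires, so the decision logic generalises it
one-sidedly: if every model with ≥10 surviving bins belongs to the candidate
class (or every one to the competitor class), that side wins by default;
otherwise the top-ranked model — ranking by mean bootstrapped test score over
each model's own surviving bins, ties broken lexicographically — must be a
candidate and must beat the best-ranked competitor in a second-order
bootstrap: bins shared by both models are resampled with replacement (paired
across models), the statistic is the difference in mean test score, and the
two-sided sign-based p-value `2·min(#{d*≤0}, #{d*≥0})/B2` (clipped to
[1/B2, 1]) is corrected across electrodes with Benjamini–Hochberg at
α = 0.05, one family per (test, alignment).  Comparisons with fewer than 10
shared bins are skipped and logged.  Filtering uses validation scores;
every comparison uses held-out test scores.

## The multimodality battery

1. **weak** — any multimodal or linearly-integrated model beats all unimodal
   models in either alignment;
2. **weak SLIP** — the multimodally-trained vision tower beats its
   architecture- and data-matched unimodal control in either alignment (the
   only comparison that holds architecture, data and parameters fixed);
3. **strict** — test 1 in both alignments;
4. **strict SLIP** — test 2 in both alignments;
5. **non-linear integration** — among strict passers, the best multimodal
   model also beats both linear-integration baselines (MultiConcat: columnwise
   concatenation of unimodal features, layers paired by depth fraction;
   MultiLin: that concatenation through a fixed linear projection, supplied as
   an artifact — synthetic runs use a seeded random orthonormal map), in both
   alignments.

Untrained model variants keep or lose their multimodal status by mechanism:
dual-encoder contrastive models (marked with an encoder side) become unimodal
when randomly initialised — the cross-modal alignment lives in the trained
weights — while cross-attention architectures remain multimodal because both
modalities enter the computation regardless of training.  The trained-vs-
random analysis reuses the same decision machinery with trained models as
candidates and their random-init variants as competitors.

Per-electrode labels aggregate into Desikan–Killiany–Tourville region
percentages; region labels are inputs.

## The synthetic world

The generator states a world with known ground truth; its defaults are the
package's test conditions and are not tuned.

* 400 events per alignment; latents per event: vision v ~ N(0, I₁₆),
  language l ~ N(0, I₁₆), multimodal m_k = tanh(vᵀA_k l) with fixed seeded
  bilinear forms scaled to unit argument variance, and the concatenation
  c = [v; l].  By symmetry m is exactly linearly uncorrelated with v, l and
  c — an m-tuned electrode is invisible to unimodal and linear-integration
  features, which is precisely the contrast test 5 needs (least-squares of m
  on c leaves ≳90% residual variance at n=400).
* Electrode bank: 8 electrodes per tuning type (vision, language, multimodal,
  linear, noise); each signal electrode has unit-variance tuning signal
  wᵀz_type and a Gaussian temporal gain centred on the bin starting at the
  onset (width 8 bins = 200 ms).  snr (default 4) is the signal-to-noise sd
  ratio at the peak-gain bin.
* Noise is drawn on the 25 ms micro-bin grid and averaged over the 8
  micro-bins each 200 ms bin covers, so neighbouring bins share noise exactly
  as overlapping sliding windows do; i.i.d. per-bin noise would misstate the
  grid's 87.5% overlap and overstate the number of independent chances a
  noise electrode has to pass the filter.
* Providers: per modality a "trained" network of 3 layers, each a seeded
  random linear map of the matching latent plus layer-specific noise (layer
  noise levels 1.0/0.25/0.5, so layer selection is meaningful), and a
  "random-init" variant that is pure white noise of the same shape.  Real
  randomly initialised networks retain some input structure; the fully
  uninformative choice gives a clean separation for acceptance testing and is
  a documented divergence from realism.  The manifest mirrors the real model
  classes, including the untrained-dual-encoder modality rule.

What a green synthetic run does **not** establish: realistic SEEG spectral
content (1/f, line noise), subject-level hierarchy, realistic feature
geometry of actual networks, or anything about the real-data headline counts.

## Known calibration limits (measured, documented, not patched)

* The validation-CI **bin filter is a per-bin test at roughly the 2.5% level**
  under the null.  Refit churn and electrode-level selection push the
  measured per-bin false-survival rate down to ~0.1–0.6% per model at B=100,
  but across 161 bins × many models a pure-noise electrode still retains a
  handful of falsely surviving bins with high probability.  The pipeline's
  protection against false *detections* is therefore the ≥10-surviving-bin
  eligibility threshold plus the FDR stage — and with those in place, zero
  pure-noise electrodes pass any battery test across seeded null worlds.
* **Percentile bootstrap CIs for the test-split correlation under-cover the
  asymptotic true correlation** when the regression's finite-sample bias is
  non-negligible: the statistic estimates the fitted model's performance
  (downward-biased by weight-estimation error ~ d/2n_train and resample-refit
  noise), not the population correlation of the ideal predictor.  At n=200,
  d=8, snr=1 measured coverage is ≈0.82 (bias ≈ 1 sd); with d=2 it is ≈0.98.
  A bias-corrected interval (basic/BCa) would fix this but percentile
  intervals are the stated procedure.

## Numerical choices

* Ridge solves are closed-form; the bootstrap engine eigendecomposes each
  resampled Gram matrix once and treats every λ as a diagonal rescale,
  computing correlations from sufficient statistics in the eigenbasis
  (float32; the single-fit path is float64).
* Pearson r of a constant vector is missing (NaN), never 0; missing fold
  scores are excluded from fold means; CIs require ≥80% non-missing
  resamples.
* All randomness flows from `numpy.random.SeedSequence` children of one
  master seed; identical config + seed reproduces identical labels bit-for-
  bit.  Event resamples are drawn resample-major, so the first B draws are
  identical for any larger B with the same seed.
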