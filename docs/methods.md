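# Methods

This note documents the models and procedures implemented in `vidsleep`,
the parameter choices that matter, what the synthetic cohort does and does
not emulate, and the numerical conventions used throughout.

## Motion estimation

The activity trace is derived by block-matching motion estimation in the
recursive-search family. The image is tiled into `block_size` × `block_size`
blocks (default 16 px; edge blocks are cropped to the image and costs are
normalised per valid pixel). For each frame transition, each block receives
an integer displacement from a small candidate set:

- the zero vector;
- the vectors already assigned to the left and upper neighbours in the pass
  in progress (spatial predictors);
- the same block's vector — and its right/lower neighbours' vectors — from
  the previous pass, or on the first pass from the previous transition's
  converged grid (temporal predictors);
- the best of those perturbed by `n_random_updates` (default 4) seeded
  pseudo-random updates with components of magnitude ≤ 2 px.

The matching cost is the **mean-subtracted** sum of absolute differences per
pixel: each block's mean intensity is removed before differencing, which
makes the estimate exactly invariant to a uniform brightness change between
frames (the dominant illumination artefact in infrared recordings). Three
passes per transition (configurable) let a good vector found anywhere
propagate across the grid; this is what gives the recursive search its
effective range despite evaluating only a handful of candidates per block.
All randomness comes from one seeded generator, so the motion field is a
pure function of (frames, parameters, seed).

**Zero-vector preference.** A non-zero candidate is accepted only if it
improves on the zero-vector cost by more than `noise_threshold` intensity
units per pixel (default 1.0). Infant recordings are quiescent most of the
night; without this margin, sensor noise would make every block report
spurious motion. The per-frame activity count — the number of blocks with
non-zero displacement — is therefore exactly zero in a static scene.

Search parameters default to `search_bound` 8 px at 10 Hz; an exhaustive
full-search matcher with the same cost and zero-preference is included as a
slow baseline, and a thresholded frame-difference detector as a low-compute
back-stop (the latter is *not* illumination-invariant).

## Epoch features

Epochs are 30 s, aligned to the recording start, half-open, 0-based; a
trailing partial epoch is dropped. At 10 Hz an epoch spans 300 frame
transitions.

**mACT** is the epoch mean of the per-frame activity count (blocks/frame).
A binary variant — the fraction of frames with any motion — is available by
configuration and off by default; the two differ only by a monotone
within-recording transform on typical data.

**pSLP** is built in three steps: (1) an epoch is *high-activity* when its
mACT strictly exceeds the recording's 95th percentile of mACT (percentile by
linear interpolation between order statistics, so 1..100 → 95.05); (2) each
epoch gets `u = ln(1 + d)` with `d` the distance in whole epochs to the
nearest high-activity epoch (`d = 0`, hence `u = 0`, for high-activity
epochs themselves); (3) `u` is smoothed by a centred moving average of
half-width `round(10 min · 60 / (2 · 30 s)) = 10` epochs — a 21-epoch
(~10.5 min) window — truncated to the available epochs at the recording
edges rather than padded. The log is taken before smoothing. The `+1`
offset makes the log defined at `d = 0`; base and offset are conventions —
any monotone variant yields the same discriminant up to rescaling. If a
recording has no high-activity epoch (possible only for pathologically flat
traces), pSLP is the uninformative constant `ln(1 + n_epochs)` and the
recording is flagged degenerate.

Both features are Min–Max rescaled to [0, 1] **within each recording**,
removing between-infant amplitude differences (camera distance, infant
size). A constant feature maps to all zeros with a degenerate flag rather
than dividing by zero. Because normalisation never uses statistics from any
other recording, subject-wise cross-validation is leak-free by construction.

## Classifier

A two-class Gaussian discriminant with shared covariance: class means are
per-class averages, the pooled covariance is the bias-corrected within-class
average `[(n_w−1)S_w + (n_s−1)S_s]/(n_w+n_s−2)`, and priors are fixed at
(0.5, 0.5) regardless of class frequencies, so the decision at threshold 0.5
is the Mahalanobis-equidistant hyperplane between the class means and is not
biased toward the majority sleep class. Posteriors are computed in log space
through the closed logistic form of the two-density ratio.

If the pooled covariance is singular or has condition number above 1e8, a
ridge of `ridge_fraction · trace(Σ)/dim` (default fraction 1e-6, with an
absolute floor when the trace is zero) is added to the diagonal. This keeps
the model well-posed on degenerate inputs such as duplicated feature columns
or zero-variance classes; on well-conditioned data the ridge never engages.
Ties at exactly the decision threshold classify as wake — deterministic, and
conservative in the direction of sensitivity for the positive class.

Models serialise to a human-readable YAML file holding the means, covariance,
priors, feature names and the normalisation convention in force at training
time.

## Evaluation

Wake is the positive class. Precision, sensitivity, specificity and accuracy
come from the confusion cells; ratios with zero denominators are reported as
NaN with an explicit flag, never silently zero. Cohen's κ uses
`(p_o − p_e)/(1 − p_e)` with the κ = 0 convention when `p_e = 1`. ROC curves
sweep the observed score values (computed via scikit-learn without dropping
intermediate thresholds); the trapezoidal AUC equals the tie-corrected
pairwise concordance probability, which the test suite verifies against
O(n²) enumeration. The Mann–Whitney U test uses the exact permutation null
when the pooled sample is ≤ 20 without ties, and otherwise the normal
approximation with tie and continuity corrections (via SciPy).

Leave-one-subject-out cross-validation featurizes each recording
independently, pools the other subjects' scored epochs for training
(unable-to-score epochs are excluded from both training and scoring), and
evaluates the held-out subject at the fixed 0.5 posterior threshold. The
headline aggregation is the per-subject mean ± sample SD; per-subject
metrics that are undefined for a given fold (e.g. precision when no epoch is
predicted wake) are excluded from the aggregation with an exclusion count.
Pooled-epoch quantities — summed confusion cells and the ROC over all
subjects' concatenated test scores — are reported separately and never mixed
with the per-subject aggregation. Three feature-set configurations (mACT
alone, pSLP alone, both) are evaluated side by side.

## Synthetic cohort

The generator emulates the statistical shape of a small laboratory cohort:
10 subjects, recording length Normal(70, 26) min floored at 20 min, ~28%
wake, ~0.7% unable-to-score epochs placed uniformly at random.

- **Hypnogram.** Alternating wake/sleep bouts with lognormal durations.
  Sleep bouts average 18 min (SD 12); the wake-bout mean is derived from the
  wake-fraction target (18 · 0.28/0.72 = 7 min, SD 5), so the stationary
  wake share matches 28% without further tuning. Durations are rounded to
  whole epochs with a 1-epoch floor. Sleep epochs are sub-labelled by a
  two-state REM/NREM Markov chain with stationary REM share 0.4 and mean REM
  run 10 epochs (infants spend an unusually large share of sleep in REM);
  NREM runs draw a stage from N1/N2/N3 with probabilities 0.2/0.5/0.3.
- **Actigraphy.** Wake epochs emit a burst/quiet Markov-modulated Poisson
  process at frame resolution (burst intensity 6 blocks/frame; per-frame
  switching probabilities 0.02 into and 0.03 out of bursts, giving multi-
  second movement bouts). Per wake bout of ≥ 4 epochs, with probability
  0.35 an interior run of 2–6 epochs is forced to zero — *motionless wake*
  flanked by bursts, the case that defeats a pure-activity classifier and
  that pSLP is designed to recover. Sleep epochs emit Poisson-many short
  movement events (3–10 frames), at 0.6 events/epoch in REM versus 0.2 in
  NREM, reflecting the greater movement propensity of REM sleep. No
  quantitative movement statistics were available for calibration; the
  rates were chosen once to reproduce the qualitative structure (vigorous
  clustered wake movement, sparse sleep movement, REM > NREM) and are all
  configurable.
- **Rendering.** Optionally, frames realise a trace as a smoothly textured
  ellipse on a dark noisy background that translates by logged integer
  steps exactly when the activity count is positive. The default test
  geometry is 48×64 px (the full-scale recording geometry, 376×480 px at
  10 Hz, is configurable) so that cross-module round trips run in seconds.

What passing tests on this cohort show — and what they do not: the pipeline
recovers the planted wake/sleep structure, the feature directions, the
feature-set ordering and the false-negative rescue mechanism under
controlled conditions with a stationary camera, no occlusion and no external
motion sources. They do not certify performance on real infant video, where
parental interference, out-of-bed periods, camera placement and infant-to-
infant variability degrade classification; the synthetic cohort deliberately
excludes those confounders. Typical synthetic-cohort κ (~0.85) is
accordingly higher than what clinical recordings of this kind yield.

## Numerical conventions and problem sizes

- Frames and epochs are 0-based with half-open intervals; vectors are
  (dy, dx) in array order.
- All stochastic components take explicit seeds; cohort subjects draw from
  spawned, collision-free seed streams, and fixed seeds give bit-identical
  outputs end to end (the CLI writes no timestamps for this reason).
- Block-matching ties are broken toward the smaller displacement (L1), then
  candidate order; this plus the zero-preference makes the estimator fully
  deterministic given its seed.
- The validation script and the acceptance-style tests use 20 seeded
  replicates of the default 10-subject cohort (~140 epochs per subject),
  exhaustive-search oracles on 96×128-px frames, and n = 10,000/class for
  parameter recovery — sizes chosen so the full suite completes in well
  under a minute while keeping Monte-Carlo noise far from the asserted
  margins.

## Known limitations

- The recursive-search matcher is a documented re-design within the
  recursive-search family, not a bit-level reproduction of any published
  implementation; published variants differ in candidate sets and penalty
  terms.
- mACT is defined here as the mean count of moving blocks per frame; the
  alternative reading (fraction of frames with any motion) is provided but
  secondary.
- Whether smoothing should precede or follow the log in pSLP is a design
  choice; log-then-smooth is implemented.
- Per-subject metrics use the fixed 0.5 posterior threshold rather than
  per-subject ROC-optimal thresholds.
- The generator does not model parental interference, out-of-bed periods,
  camera motion or vital-sign signals; REM/NREM classification beyond the
  binary wake/sleep task is out of scope.
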