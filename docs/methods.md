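# Methods

This note documents the model, the synthetic study conditions, the
numerical choices and the limits of what the synthetic experiments can
show. Everything quantitative referenced here is computed by the test suite
or by `scripts/acceptance.py`; nothing is asserted from memory.

## The shallow-network response model

The encoding model has four stages.

1. **Oriented filtering.** Luminance (ITU-R 709 weights via
   `skimage.color.rgb2gray`) is convolved with a quadrature Gabor pair at
   each of four edge orientations (0°, 45°, 90°, 135°; channel angle labels
   the *edge*, so a vertical luminance edge drives the 90° channel). One
   spatial frequency (0.25 cycles/px), isotropic envelope σ = 1.8 px,
   support 11 px — sized for 200-px stimuli subtending 20° of visual angle,
   i.e. roughly V1-scale receptive fields. The even-phase kernel is made
   zero-mean so uniform luminance produces exactly no orientation energy.
   Orientation energy (root-sum-square of the quadrature pair) is divided
   by the bank's maximum attainable response to a unit-contrast step edge,
   computed numerically once per bank, so that a full-contrast edge maps to
   1.0 and orientation and color channels share a scale.
2. **Local max pooling.** Each channel is max-pooled with window = stride =
   10 px (border cells pool the valid intersection; output size is
   ⌈input/stride⌉). A 200×200 image becomes a 20×20×7 stack, on which the
   allowed fragment sizes 8–20 cover 40–100 % of a stimulus. Color channels
   are raw pooled R, G, B intensities in [0, 1].
3. **Template matching.** The α-weighted squared distance between a
   fragment and every stimulus sub-window is minimized over all offsets and
   over candidate rescalings b ∈ {0.8, 1.0, 1.25} (bilinear, per channel;
   the candidate, not the stimulus, is resampled). α defaults to 0.5 —
   orientation and color weighted equally; α = 1.0 reproduces the
   "no color" control. Distances are divided by the number of spatial
   cells so fragments of different sizes compete on one scale (a config
   switch disables this). Ties break deterministically: earliest scale in
   the list, then row-major first offset.
4. **Radial basis readout.** r = exp(−d²_min / 2σ²) ∈ (0, 1]. σ² is
   calibrated per candidate as the median of its minimum distances over the
   calibration (identification) stimulus set — a per-candidate refinement
   of per-size-class calibration that keeps every candidate's responses in
   a usable dynamic range. Rescaling to spikes/s uses the unique affine map
   matching the predicted face and non-face means to the neural ones; a
   degenerate map (equal predicted means) is an explicit error.

A BLAS-based batch path (`bank_min_distances`) computes the same quantity
for a whole bank at once via the ‖c‖² + ‖x‖² − 2c·x expansion, grouped by
scaled fragment shape; tests assert its equality with the naive per-pair
scan at 1e-9.

## Synthetic study conditions

The generator defines the conditions under which every claim is tested.

**Stimuli.** Faces are parametric-geometric (ellipses and polygons): head,
hair above an identity-specific hairline, two eyes, nose, mouth. Views
−90°…+90° in 30° steps are emulated by (a) horizontal feature displacement,
an odd smooth function of view; (b) foreshortening of mouth/nose/head
width; (c) occlusion of the far-side eye beyond ±60°; and (d) a lateral
self-shadow whose strength is odd in the view angle. The shading term
matters: a position-invariant matcher discards pure feature displacement,
so without an appearance change tied to view, fragments would carry almost
no view information. Identity is carried by geometry and by view-invariant
skin/hair/mouth colors. Rendering −v is the mirror of +v up to the seeded
1 %-sd pixel noise field. Non-face objects are textured blobs, gratings and
box silhouettes with no eye-above-mouth configuration. Default counts: 8
identities × 7 views, 40 view-uncontrolled faces (fresh identities at poses
sampled uniformly from the 7 views, unlabeled), 60 non-face objects, all
200×200 px; the full published counts (41 identities, 532, 690 → 1509) are
available via `StimulusSetConfig.paper_scale()`.

**Columns.** A ground-truth column is a planted fragment plus an affine
rate map and i.i.d. Gaussian trial noise (negative trial rates clipped at
0). Defaults: 10 trials, noise sd 3 spikes/s, rate = −18 + 38·r clipped at
zero — i.e. a thresholded response reaching 20 spikes/s at a perfect match
and near zero for most non-faces, which is how face columns actually look
(strong face rates, near-zero object rates). The threshold depth trades
face selectivity against recoverability: a very deep threshold maximizes
FSI but flattens all sub-threshold structure, making the planted fragment
statistically indistinguishable from its neighbors; −18 keeps ~90 % of
face-derived fragments above the FSI = 1/3 gate while preserving recovery.

**Experiment sizes.** The identification experiments (planted recovery,
view generalization, cross-validation) use 120 uncontrolled faces + 160
objects — the published 532/690 face/object proportion at desk scale —
because candidate fragments overlap heavily and a ~100-stimulus set cannot
disambiguate near-duplicates. The population-readout experiment uses 16
planted identities: with 8, a "10× chance" identification bar would exceed
100 % by arithmetic. All randomness flows from one master seed through
named substreams.

## Statistical procedures

- **Repeatability**: Pearson correlation across stimuli between odd-trial
  (1, 3, …) and even-trial means, Spearman–Brown corrected 2r/(1+r);
  r = −1 and constant vectors are explicit errors.
- **FSI**: (F − N)/(F + N) on trial-averaged responses with means clipped
  at 0 first; exactly 1/3 at a 2:1 ratio.
- **View/identity ANOVA**: scipy's one-way F test; views (identities) as
  groups with identities (views) as replicates; threshold p < 10⁻⁶ applied
  without multiplicity correction, as printed in the source analyses. Null
  simulations confirm uniform p-values (KS test).
- **Selection screen**: per-candidate Pearson r with the trial-averaged
  neural vector over all identification stimuli (global) and over faces
  only (local); two-sided t-approximation p on n−2 df (a permutation mode
  exists for verification). Joint significance at α = 0.05 additionally
  requires r > 0 on both subsets — an anti-correlated template is not a
  feature, and without the sign condition the null screen admits spurious
  features in a non-trivial fraction of noise runs. No correction across
  candidates, faithfully reproducing the per-candidate α. "No feature" is a
  first-class outcome, not an error.
- **View-tuning predictability**: both neural and predicted responses are
  z-scored within identity (population sd; symmetric treatment of the two
  sides) and correlated over all (identity, view) pairs, so n = 7 ×
  n_identities. Identities with zero variance on either side are dropped.
- **Identity tuning**: Spearman ρ on view-averaged responses; exact
  permutation p below n = 9, t-approximation otherwise.
- **Axis extraction**: with a univariate response, CCA degenerates, so the
  axis is the ridge-regularized regression direction (RidgeCV over λ ∈
  10⁻⁶…10³ by efficient leave-one-out), unit-normalized, sign-fixed so the
  largest-|loading| cell is positive. Sub-regions captured at non-unit
  scale are bilinearly resampled to the candidate grid first.
- **Readout**: features standardized (zero mean, unit variance) before the
  ±1-indicator OLS — predicted responses have heterogeneous scales — with
  the minimum-norm solution on rank-deficient designs (duplicated axes get
  equal weights). AUC is Mann–Whitney pair counting with ties at 0.5.
  Leave-one-view-out fits on the remaining six views of *all* identities
  (standardization from the training rows only) and scores a hit only on a
  strict maximum. Incremental curves rank axes by |w| (ties by axis order);
  view specificity is Var(target projections)/Var(all projections),
  normalized to 1 at the full feature count, with the all-zero curve
  returned unnormalized in the degenerate perfectly-view-invariant case.

## The ground-truth experiments

- **Planted recovery**: 20 seeded columns, each planting one of 500 bank
  candidates; success = selecting the planted fragment or one whose
  noiseless predicted-response vector correlates ≥ 0.95 with it.
- **View generalization**: planted candidates are drawn from the pool with
  a *well-defined* preferred view — ANOVA p < 10⁻⁶ across views **and** a
  top-view margin of ≥ 0.75 × the mean within-view sd. Without the margin
  the curve's argmax is ill-defined and the comparison tests a coin flip.
  Success = the selected feature's noiseless view curve peaks at the
  planted candidate's preferred view, with selection run only on
  identification stimuli.
- **Population readout**: one fragment per identity cut from that
  identity's front-view render; the feature space is the 112 × 16 matrix of
  predicted responses plus a 2 %-sd perturbation; mean AUC and
  leave-one-view-out rate are compared to 0.95 and 10 × the 1/16 chance
  level.

## What passing these tests does and does not show

The generator produces controllable, fully-labeled stimuli, but its faces
are schematic: no texture, hairstyle variation, illumination diversity or
photographic background clutter, and its "natural image" fragment source is
the synthetic image set itself. Consequently the synthetic experiments
validate the *machinery* — that the selection screen finds planted causes,
that view tuning genuinely generalizes from view-free identification
stimuli, that the readout analyses behave as designed — not the empirical
claim that real IT columns are fragment detectors. Published quantities
that depend on the actual recordings and copyrighted photograph sets (site
counts, r distributions, the 29-axis space, 65.9 % identification) are
context, not reproduction targets; the acceptance script reports this
package's own measured analogues instead.

## Known limitations

- The front end is single-scale; no Gabor pyramid, no opponent color.
- Scale search resamples the candidate only, at three fixed factors.
- Trial noise is i.i.d. Gaussian on the rate; no trial-to-trial
  correlations, latency structure or Poisson variance scaling.
- The exact-scan matcher is O(offsets × cells) per pair; the batch path
  makes 500-candidate × 280-stimulus banks interactive (~seconds), but
  million-fragment dictionaries would need chunking.
- `spearman_rho_p`'s exact mode enumerates permutations and is capped at
  n ≤ 8 by design.
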