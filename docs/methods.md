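# Methods

`browkit` quantifies eyebrow position in sign-language video from
pose-estimation keypoints and tests how it depends on emotion, sentence
type, and signer group. This note documents the measurement model, the
statistical model, the synthetic data the package is validated on, and the
numerical choices that a user changing defaults should understand.

## Measurement model

OpenPose's 70-point face layout places five landmarks on each eyebrow
(indices 17–21 and 22–26) and one at the top of the nose bridge (index 27).
Raw image y-coordinates confound brow movement with camera placement, body
height, and posture, so eyebrow position is measured as the Euclidean
distance from an eyebrow landmark to the nose-top landmark, in pixels —
a head-relative quantity. Two variables summarize each frame, following
facial anatomy (AU1/AU4 act on the inner brow, AU2 on the outer):

- **internal** — mean of the two inner-brow distances (landmarks 21, 22);
- **external** — mean of the two outer-brow distances (landmarks 18, 25).

Averaging the two brows absorbs ordinary facial asymmetry; the signed
left-minus-right asymmetry is exposed per frame as a diagnostic but is not
modelled.

Per video the pipeline is: **filter → trim → frame features → mean**.

1. *Confidence filter.* Keypoints with detector confidence strictly below
   0.7 are marked missing; equality keeps the point (the rule is "below
   threshold", and the boundary choice is documented so counts reproduce).
   Idempotent.
2. *Edge trim.* The first and last `floor(0.2·n)` frames are dropped by
   position. Signers raise their hands into signing space at the start of a
   recording and lower them at the end; those spans do not belong to the
   sentence. The fraction is a fixed configuration constant, not inferred
   per video — `hand_activity_profile` (mean wrist elevation above the
   video's resting wrist position) exists to *inspect* that choice, not to
   set it. `floor` per end guarantees never trimming more than 2×the
   fraction.
3. *Frame features.* A frame contributes an internal (external) value only
   if both constituent landmarks and the nose landmark survived filtering
   (`require_both_sides=True`); one-sided dropout would otherwise bias the
   mean whenever a face is asymmetric. A sensitivity flag allows one-sided
   fallback. An optional inter-ocular normalization (divide by
   pupil-to-pupil distance, landmarks 68/69) is off by default: with a
   fixed camera and seated signer, raw pixels are comparable within the
   design, and the downstream effect estimates are reported in pixels.
4. *Video summary.* The per-video mean over frames with valid values, one
   row per video. A video with no valid frame for either variable is
   dropped from modelling.

## Statistical model

Each outcome (mean internal or external position, pixels) is fitted
separately with the same right-hand side — a full
emotion × sentence-type × group factorial (18 columns) plus crossed random
effects: by-sentence intercepts and slopes for emotion, group, and
emotion:group; by-signer intercepts and slopes for emotion, sentence type,
and their interaction.

Factors enter through difference/Helmert-style contrasts chosen so each
coefficient is a named pixel-scale comparison:

| coefficient | comparison |
|---|---|
| `emotion_c1` | neutral − anger |
| `emotion_c2` | surprise − mean(neutral, anger) |
| `stype_c1`   | wh − statement |
| `stype_c2`   | polar − mean(statement, wh) |
| `group_c1`   | deaf − hearing (±½ coding) |

Positive values mean higher eyebrows for the first-named side; interaction
coefficients are products of these columns, so e.g. a negative
`stype_c2:group_c1` means the polar-question raise is smaller for deaf
signers.

**Estimation.** Restricted maximum likelihood over *independent* variance
components: each random-effect column (per grouping factor) carries its own
variance, with no covariances — the `||` structure of lme4. The full
unstructured alternative would add 21 + 45 covariance parameters to be
estimated from 10 sentences and 9 signers; with so few levels those
parameters are weakly identified and are precisely where boundary
(singular) estimates arise. The marginal covariance is
`σ²(I + Z G Zᵀ)` with diagonal `G`; the likelihood is profiled over `σ²`
and `β` and evaluated in the q-dimensional random-effect basis via the
Woodbury identity, so one evaluation costs O(q³) with q ≈ 141 at the
default design.

**Regularization.** With few grouping levels, REML frequently estimates
some variance as exactly zero (a singular fit). When
`regularize_covariance=True` (default), each relative variance gets a weak
Gamma(shape 1.5, rate 0.01) penalty: the log-barrier of the shape keeps
every variance strictly positive while the near-zero rate leaves
well-identified components essentially untouched. A fit is flagged
`singular` when any relative variance falls below 1e-4. If optimization
fails outright, random-slope groups are dropped in a fixed, logged order
(highest-order interactions first) down to intercept-only.

**Inference.** Wald chi-square per term on the fitted coefficient
covariance, df = number of contrast columns (2, 2, 1, 4, 2, 2, 4). Type II
(default) tests each term in a GLS refit — marginal covariance held fixed —
that omits every higher-order term containing it; Type III tests the
term's block in the full model. The two coincide for the three-way
interaction and whenever the design stays orthogonal under the GLS metric;
random slopes generally break that orthogonality, so lower-order terms can
differ. p-values use the χ² reference distribution with no small-sample
correction, so they are asymptotic: with 9 signers the emotion test is
expected to be slightly anticonservative, which the type-I-error simulation
bounds empirically.

## Agreement statistics

For the emotion-identification validation design (raters choose among
neutral / surprised / angry / other; the intended label is never "other"):
raw and stratified accuracy (all responses in the denominator, including
"other"); Cohen's kappa `(p_o − p_e)/(1 − p_e)` of each rater against the
intended labels, with `p_e` from marginal products and perfect agreement
defined as exactly 1; Light's kappa as the mean over unordered rater pairs,
aligned on videos with pairwise deletion; and the chance-corrected accuracy
`(p − 1/k)/(1 − 1/k)`, reported for both k = 3 and k = 4 because the
"other" category makes the effective number of choices ambiguous.
Printed proportions round half-up (0.415 → 0.42), via
`agreement.round_half_up`, since Python's built-in `round` ties to even.
Kappa significance tests and weighted/Fleiss variants are out of scope.

## Synthetic data

The generator emulates the study design this pipeline targets: 5 deaf + 4
hearing signers × 10 sentences × 3 emotions × 3 sentence types = 810
videos of 90 frames at 30 fps, with 5 videos voided (all confidences below
threshold) so the pipeline's droppage path is exercised (805 modelled
rows). Effects are injected *in contrast space* and mapped to condition
cells through the same coding the model uses, so every coefficient is an
exact recovery target. Eyebrow landmarks are placed at
`nose + unit_direction · distance`, which makes the measured distance equal
the injected value by construction; per-frame noise is one shared Gaussian
draw per variable, so the frame-level SD is interpretable directly.
Wrists ramp up/down over the first/last 20% of frames, and eyebrow
distances in those spans carry a fixed +6 px perturbation so edge trimming
has a measurable effect (with the default trim the perturbed span is
exactly excluded).

Defaults with no external anchor are free parameters, chosen once:
baselines 45 px (internal) and 75 px (external); random intercept SDs
2.0 px (signer) and 1.5 px (sentence); random slope SDs 1.2 / 0.8 px;
frame noise 3.0 px; low-confidence probability 0.08 per keypoint-frame.
These put contrast standard errors at the default design in the
0.3–0.5 px range, the order observed in studies of this scale. The
summary-level fast path (`simulate_summary_table`) draws per-video means
directly with residual SD `sd_frame/√54` (the 54 retained frames) and is
used for the replicate simulations; the full-file path writes genuine
OpenPose JSON and is used for end-to-end checks.

What the generator does **not** emulate: head rotation and translation,
temporal contours of eyebrow movement within a sentence, correlated
(burst-like) detector dropouts, inter-signer face-geometry differences,
and any dependence of detector confidence on expression. Passing tests
therefore validate the pipeline's arithmetic, its statistical calibration
under the assumed model, and its handling of missingness — not robustness
to those real-video phenomena.

## Numerical choices

- REML optimization: L-BFGS-B on log relative variances, bounds
  [−23, 8], finite-difference step 1e-5 (the objective carries ~1e-7
  linear-algebra noise; a smaller step stalls the line search), ftol 1e-12.
  An abnormal line-search exit returns the best point found with
  `converged=False` rather than an error.
- Zero-residual (noiseless) data floors the profiled RSS at 1e-12; GLS
  coefficient estimates are exact regardless, and t-values beyond 1e6 are
  flagged `exact` in the effect report.
- Flat-table round-trips keep 6 decimals (sub-pixel noise floor);
  frame-file JSON likewise.
- Trim and ramp spans use `floor`; positional, not frame-index based, so
  gaps in frame indices do not shift the trimmed window.

## Problem sizes used in the test suite

Replicate simulations run at the summary level: 20 replicates for
parameter recovery and 200 for the null-emotion type-I check, both at the
full 810-video design. The on-disk study (810 videos × 90 frames of JSON)
is generated once per test session for the end-to-end and droppage checks;
smaller grids (2–4 signers, 2–3 sentences, 12–30 frames) cover the
remaining file-level behavior.

## Known limitations

- Wald χ² p-values are asymptotic; no Satterthwaite/Kenward–Roger style
  correction is offered.
- Independent variance components cannot represent correlation between a
  signer's intercept and slopes; if such correlation matters, fixed-effect
  SEs may be mildly misstated.
- The asymmetry features are computed but not modelled.
- The agreement module reports point estimates only.
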