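# browkit

Quantifying eyebrow position in sign-language video from pose-estimation
keypoints.

In sign languages the eyebrows do double duty: they mark grammar (polar
questions are typically signed with raised brows) and they express emotion
(surprise raises them, anger lowers the inner brow). When a signer produces
an angry yes/no question, both systems compete for the same muscles.
`browkit` is a pipeline for studying that competition quantitatively: it
turns per-frame OpenPose keypoint files into per-video eyebrow-position
measurements, fits a factorial mixed-effects model of
emotion × sentence type × signer group, and computes the rater-agreement
statistics used to validate that recorded emotions were recognizable. A
synthetic study generator with exact ground truth lets the entire pipeline
run — and be verified — without any video data.

It is intended for sign-language linguists and speech-prosody researchers
working with landmark time series, and for anyone needing a tested
reference implementation of the underlying statistics.

## The measurements and the model

Eyebrow position is measured head-relatively, as the Euclidean distance
(pixels) from an eyebrow landmark to the nose-top landmark (index 27 of the
70-point face layout). Two variables summarize each video after confidence
filtering (drop keypoints with detector confidence < 0.7) and edge
trimming (drop the first and last 20% of frames, where signers raise and
lower their hands):

- **internal** eyebrow position — mean distance of the inner-brow
  landmarks 21 and 22 (the part AU1 raises and AU4 lowers),
- **external** eyebrow position — mean distance of the outer-brow
  landmarks 18 and 25 (raised by AU2).

Each outcome *y* (one value per video) is modelled as

```
y ~ emotion * sentence_type * group
    + (emotion * group || sentence)
    + (emotion * sentence_type || signer)
```

a full factorial with crossed by-sentence and by-signer random intercepts
and slopes (independent variance components), estimated by REML with a
weak Gamma penalty on each variance so that boundary ("singular")
covariance estimates cannot occur. Factors are coded so every coefficient
is a named pixel-scale comparison (e.g. *neutral − anger*,
*polar − mean(statement, wh)*, *deaf − hearing*), and each term gets a
Wald chi-square test. Rater agreement is summarized by accuracy, Cohen's
kappa per rater, Light's kappa across raters, and the chance-corrected
accuracy `(p − 1/k)/(1 − 1/k)`.

## Worked example

Simulate a study at the default design (9 signers × 10 sentences ×
3 emotions × 3 sentence types) and fit the internal-eyebrow model:

```python
from browkit import synthetic, mixed_model as mm

table, truth = synthetic.simulate_summary_table(seed=42)
fit = mm.fit_mixed_model(table, mm.ModelSpec(outcome="mean_internal"))
print(mm.report_effects(fit).head(5).round(3))
print(mm.anova_wald(fit).round(4))
```

```
                                  comparison  estimate_px     se       t  exact
contrast
emotion_c1                  neutral vs anger        3.729  0.420   8.886  False
emotion_c2  surprise vs mean(neutral, anger)        4.079  0.369  11.051  False
stype_c1                     wh vs statement        1.048  0.427   2.455  False
stype_c2        polar vs mean(statement, wh)        2.167  0.428   5.062  False
group_c1                     deaf vs hearing        0.637  1.001   0.637  False

                             chi_square  df       p
term
emotion                        200.3243   2  0.0000
sentence_type                   30.4726   2  0.0000
group                            0.4054   1  0.5243
emotion:sentence_type            5.0522   4  0.2820
emotion:group                    0.9440   2  0.6238
sentence_type:group              1.9012   2  0.3865
emotion:sentence_type:group      8.2360   4  0.0833
```

The generator injected a 3.7 px neutral-vs-anger effect, a 4.0 px
surprise-vs-rest effect, and a 2.3 px polar-question raise; the fitted
estimates (3.73, 4.08, 2.17 px) recover them within one standard error,
and the Anova table shows strong emotion and sentence-type contributions
with no spurious group effect.

The same run from the shell, end to end (keypoint files on disk → feature
table → model → agreement report):

```sh
$ browkit run-all --config run.yaml
pipeline complete; results in results
$ browkit validate --results-dir results --seed 42
overall accuracy: 0.630
Light's kappa:    0.237
chance-corrected accuracy (3 choices): 0.44
chance-corrected accuracy (4 choices): 0.51
```

Subcommands `simulate`, `extract`, `fit`, `validate` run the stages
individually; `--config` takes a YAML file with `feature_config`,
`synthetic_config`, paths, and the seed (see
`browkit.pipeline.RunConfig`). Every stage writes its artifacts atomically
and stamps a manifest with the configuration hash and seed.

## Layout

```
src/browkit/
  landmarks.py     face-layout constants (eyebrow/nose/pupil/wrist indices)
  keypoints_io.py  OpenPose per-frame JSON + combined CSV round-trip
  features.py      confidence filter, edge trim, eyebrow distances, summaries
  mixed_model.py   contrasts, penalized REML fit, Wald Anova, effect report
  agreement.py     accuracy, Cohen's/Light's kappa, chance correction
  synthetic.py     study generator (summary-level and full OpenPose files)
  pipeline.py      stage orchestration, config, atomic artifacts
  cli.py           the `browkit` command
docs/methods.md    model assumptions, defaults, and numerical choices
```
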