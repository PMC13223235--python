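# feargen

Analysis pipeline for quantifying how learned odor fear generalizes across
stimuli, combining widefield calcium-imaging response quantification in the
mouse olfactory bulb with open-field avoidance behavior and formal model
comparison of competing generalization hypotheses.

## The scientific problem

When a mouse learns that one odor (the CS+, methyl valerate, "MV") predicts
a threat, its fear typically generalizes to other odors in proportion to
their similarity — strongly to the similar ester butyl acetate ("BA"),
weakly to the dissimilar ketone 2-hexanone ("HEX"). Pharmacological
manipulation of GABA_B receptor signaling in the olfactory bulb can reshape
that gradient. This package implements the quantitative machinery such an
experiment needs:

- **Imaging** — per-ROI ΔF/F from 20-s trials (1000 frames at 50 Hz:
  225 pre-odor / 350 odor / 425 post-odor), odor-evoked peak responses, the
  pre-drug → post-drug percent change per glomerular ROI (the main
  dependent variable of drug experiments), temporal-bin profiles, and
  cumulative percentile distributions of effect sizes.
- **Spatial generalization** — classification of CS− ROIs as overlapping
  the CS+ representation (center within 70 µm of any CS+ ROI) and
  categorization by Euclidean distance to the maximally responsive CS+ ROI
  (within/beyond 400 µm).
- **Behavior** — dwell time in the 9 zones of a square open-field arena
  with odors in the corners (MV and BA adjacent), mean distance from each
  odor corner, freezing-test immobility percentages with the ≥5-point
  CS+-specificity exclusion rule, and habituation/dishabituation
  investigation-time summaries.
- **Model selection** — AIC comparison of four a priori occupancy models of
  the avoidance data: *no fear* (uniform occupancy, k=0), *CS-specific
  fear* (one avoidance weight on the MV corner, k=1), a *similarity
  gradient* (MV weight ≥ BA weight, HEX at baseline, k=2), and
  *overgeneralization* (one shared weight on all three odor corners, k=1).
- **Inference** — repeated-measures and mixed two-way ANOVA with classical
  η², Greenhouse–Geisser correction, Pearson correlation, Holm–Bonferroni
  adjustment.
- **Synthetic data** — a generator producing imaging sessions and arena
  trajectories with the statistical structure above plus exported ground
  truth, so the entire pipeline is testable end-to-end without raw data.

## The core model

Zone dwell times are thinned to one effective observation per 5 s and
scored with a multinomial counts kernel; for candidate model *m* with
maximized log-likelihood *L̂* and *k* free avoidance weights,

    AIC_m = 2k − 2 ln L̂_m

and the relative likelihood (evidence ratio) of model *a* over model *b* is

    exp((AIC_b − AIC_a) / 2).

A zone carrying avoidance weight *a* receives unnormalized mass e^(−a)
(other zones 1); the probability vector is the normalization, so the
no-fear model reduces exactly to the uniform 1/9 vector.

## Worked example

Fit the four occupancy models to a synthetic cohort of 10 mice generated
under the similarity-gradient hypothesis:

```python
import feargen as fg

trajs, truth = fg.generate_cohort("gradient", effect_size=1.5, n_mice=10, seed=42)
res = fg.OccupancyModelComparison.from_trajectories(trajs).fit()
print(res.summary())
```

```
Occupancy model comparison (multinomial kernel, ess interval 5 s, n = 600 effective observations, 10 mice)

model                 k        logL       AIC     dAIC   ev.ratio
gradient              2    -1281.98   2567.97     0.00          1
cs_specific           1    -1292.45   2586.90    18.93   1.29e+04
overgeneralization    1    -1297.94   2597.89    29.92   3.14e+06
no_fear               0    -1318.33   2636.67    68.70   8.29e+14
```

The generating model wins: the gradient model's AIC is lowest, and the
evidence ratios say the data are ~1.3×10⁴ times more likely under it than
under CS-specific fear. The fitted avoidance weights (MV ≈ 1.40,
BA ≈ 0.69) recover the generating values (1.5 and 0.75). The same
arithmetic applied to published AIC values — e.g.
`fg.evidence_ratio(14.2, 18.2)` — returns the familiar 7.4-fold figure.

A command-line surface chains the stages on file artifacts
(`feargen simulate | dff | drug-effect | spatial | behavior | model-select
| stats | report`); every command stamps its outputs with a provenance
record (stage, config hash, seed).

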