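# liftbiome

Longitudinal analysis of gut-microbiome remodeling under progressive
resistance training.

## The scientific problem

Endurance exercise reliably shifts the gut microbiome toward a
short-chain-fatty-acid-producing, anti-inflammatory profile; whether pure
resistance (strength) training does the same is much less clear.  The
design this package implements follows a sedentary adult cohort through an
8-week, machine-based resistance program with three stool sampling
timepoints (weeks 0, 4 and 8), digital session-level training logs, diet
surveys and a targeted stool metabolite panel.  The analysis asks three
questions:

1. Does the community change *within* a participant, and does the size of
   that change track the participant's strength improvement?
2. Which taxa (16S amplicon sequence variants, ASVs) shift over time in
   the participants who respond most strongly to training?
3. Are those taxon-level calls robust, or would random subsets of
   ordinary participants produce them too?

Because data of this kind are typically deposited under controlled access,
the package ships a first-class synthetic study generator
(`liftbiome.simulate`) that emulates the full design — enrollment funnel
(205 enrolled → 150 analyzed), 7 strength machines × 2 training programs,
~69,000 reads per stool sample, a 24 ± 16 % average strength gain, a
34-compound null metabolite panel, stable diets — with planted,
responder-coupled differential ASVs whose identities are written to a
ground-truth sidecar.  Every analysis stage is exercised and validated
end-to-end against that generator.

## The statistics at the core

* **Average strength gain** per participant: the mean over machines *m* of
  log₂(S<sub>m,W8</sub>/S<sub>m,W0</sub>), reported as a percent via
  2<sup>x</sup> − 1.  Responder classes are quantile-based: high
  responders (HR) sit strictly above the 80th percentile of a metric's
  change, low responders (LR) strictly below the 20th.
* **Within-subject community shift**: Bray–Curtis dissimilarity
  1 − 2Σmin(x,y)/(Σx+Σy) between a participant's rarefied timepoint
  samples, correlated (Pearson) with the strength gain.
* **Paired, bias-corrected differential abundance**: per participant and
  follow-up timepoint, the log₂ fold change of relative abundance versus
  baseline (pseudocount 0.5); a per-participant median shift across ASVs
  is removed as a compositional/sampling-fraction artifact; one-sample
  t-tests per ASV with Holm correction across the two baseline contrasts
  (a many-to-one, Dunnett-type family); an ASV is called at
  Holm-p ≤ 0.05 **and** |log₂FC| ≥ 1.
* **Permutation-subset robustness**: the identical analysis runs on 100
  random, size-matched subsets of the non-HR pool; the empirical p is the
  fraction of subsets with at least as many significant ASVs, and each
  HR-significant ASV gets a Benjamini–Hochberg q-value of its chance
  frequency across subsets.
* **Rank-based inference throughout**: Friedman (+ Conover post hoc),
  Kruskal–Wallis (+ Dunn), Wilcoxon rank-sum with continuity correction,
  two-sample KS, chi-square, and a seeded permutation surrogate for the
  group × time interaction of a two-group repeated-measures design.
* **Diet stability**: Euclidean distances on RMS-scaled survey variables,
  embedded with Sammon's nonlinear mapping (stress < 0.2 ≈ fair fit), and
  responder-stratified within-participant diet-distance tests.

## Worked example

Run the whole pipeline on a default-size synthetic study (the prediction
stage is disabled here; with its 1000-permutation random-forest benchmark
it dominates the runtime):

```python
from liftbiome.config import PipelineConfig
from liftbiome import pipeline as pl

cfg = PipelineConfig(seed=1)
cfg.stages = tuple(s for s in cfg.stages if s != "predict")
pl.run_all(cfg, "demo")
print(open("demo/report.md").read())
```

which prints (abridged):

```
## Cohort flow
- enrolled: 205
- dropouts: 43
- quality excluded: 6
- validation excluded: 6
- final cohort: 150 (conserved: True)

## Strength
- mean gain: 24.9% +/- 16.5%
- leg press W0 -> W8: 158 -> 194 kg
- mean compliance: 94.9%

## Community-shift / strength coupling
- Pearson r = 0.551 (p = 2.8e-13, n = 150)

## Differential abundance (HR subset)
- W4: 4 up, 4 down
- W8: 16 up, 11 down

## Permutation robustness
- observed significant ASVs: 27
- empirical p vs 100 non-HR subsets: 0

## Diet
- Sammon stress: 0.122
```

Reading the numbers: the funnel reproduces the enrollment design exactly;
the cohort-mean strength gain lands on the calibrated 24 %; within-subject
Bray–Curtis distances correlate positively with strength gain (the
generator couples the planted community shift to the gain percentile); the
high-responder subset recovers all 27 planted ASVs (16 enriched, 11
depleted) at week 8 while none of the 100 non-HR subsets reaches that
count (empirical p < 1/100); and the diet ordination's stress of 0.12
indicates a fair 2-D representation of stable diets.

The same pipeline is available from the shell:

```bash
liftbiome run-all --config cfg.yaml --out run/ --seed 1
liftbiome simulate --out run/ --seed 1        # or stage by stage
liftbiome daa --out run/ --seed 1
```

## Layout

| module | role |
| --- | --- |
| `liftbiome.simulate` | synthetic cohort, training logs, ASV counts, metabolites, diet |
| `liftbiome.strength` | strength metrics, BioAge surrogate, compliance |
| `liftbiome.diversity` | rarefaction, alpha diversity, Bray–Curtis trajectories |
| `liftbiome.stats` | rank-test toolkit and multiple-testing adjustments |
| `liftbiome.responders` | LR/MR/HR stratification, random-forest benchmark |
| `liftbiome.daa` | paired bias-corrected DAA + permutation robustness |
| `liftbiome.diet` | RMS-scaled diet distances, Sammon mapping |
| `liftbiome.pipeline` | stage orchestration, coupling analysis, report |

See `docs/methods.md` for the modeling assumptions, parameter defaults and
known limitations.
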