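# bmiconn

Multimodal brain-connectivity analysis and BMI prediction.

`bmiconn` is for researchers studying obesity-related differences in brain
networks who want a tested, reproducible implementation of a classic
multimodal pipeline: build per-subject **structural** (DTI fiber-density) and
**functional** (resting-state correlation) connectomes, find edges that
separate healthy-weight (BMI < 25 kg/m²) from non-healthy-weight subjects,
keep the edges whose anatomy couples to functional degree centrality, and
predict BMI from the fused features with partial least-squares regression.
Because real connectome cohorts sit behind data-access agreements, the
package ships a synthetic cohort generator with the same statistical
structure, so every stage is exercised end to end by the test suite.

## The analysis

1. **Structural networks.** Fibers (region pair + length) are filtered to
   20–500 mm; the edge weight is the fiber density
   `FD(u,v) = 2/(S_u+S_v) · Σ_f 1/l(f)`, an inverse-length-weighted count
   normalised by the endpoint surface areas. Absent edges are tracked in an
   explicit presence mask.
2. **Functional networks.** ROI time series are nuisance-regressed and
   band-passed (0.009–0.08 Hz, hard Fourier mask); edges are Pearson
   correlations, Fisher z-transformed. A region's mean functional
   connectivity (mean z to all other regions) is its scaled degree
   centrality.
3. **Group differences.** Each edge's densities (subjects carrying the edge;
   edges missing in ≥ 20% of subjects are skipped) are compared with a pooled
   two-sample t; family-wise error over all edges is controlled by the
   max-statistic permutation test (default 5000 label shuffles), and
   survivors are filtered to the reward system (thalamus, insula, putamen,
   orbitofrontal cortex).
4. **Cross-modal coupling.** A significant edge is retained if its density
   correlates (p < 0.05) with the mean functional connectivity of either
   endpoint; retained edges yield one structural feature each plus one
   functional feature per distinct significantly-coupled region.
5. **BMI prediction.** PLS1 (NIPALS) on the standardised features; the
   latent-variable count is chosen where leave-one-out PRESS stops
   improving, nested inside leave-one-subject-out cross-validation. Reported:
   RMS error, percent error, predicted-vs-actual r, and explained variance,
   for the combined, DTI-only and fMRI-only designs.

## Worked example

Generate a synthetic cohort at the study scale and run everything:

```sh
bmiconn simulate --seed 1 --out cohort/
bmiconn run-all --config pipeline.yaml
```

with `pipeline.yaml`:

```yaml
paths:
  atlas: cohort/atlas.tsv
  fibers: cohort/fibers.tsv
  timeseries_dir: cohort/timeseries
  subjects: cohort/subjects.csv
  out_dir: out
params:
  n_perm: 5000
seed: 1
```

or equivalently from Python:

```python
from bmiconn import (default_spec, generate_cohort, build_structural_matrix,
                     run_analysis, PipelineParams)

cohort = generate_cohort(default_spec(seed=1))
networks = {s.id: build_structural_matrix(s.fiber_set, cohort.atlas)
            for s in cohort.subjects}
series = {s.id: s.roi_timeseries for s in cohort.subjects}
result = run_analysis(cohort.atlas, networks, series, cohort.subject_table,
                      PipelineParams(), seed=1)
print(len(result.significant), "significant edges")
print(result.summaries["combined"])
```

which prints

```
9 significant edges
{'explained_variance': 0.7084193362777089, 'modal_n_lv': 2,
 'rms_error': 3.4144712362686684, 'percent_error': 9.956666125658335,
 'pearson_r': 0.7994090779099469, 'n_features': 15}
```

Nine edges separate the groups after family-wise correction (the generator
plants ten, with effect sizes 0.9–1.2); six survive the functional-coupling
screen, contributing 6 structural + 9 functional features. The combined
model explains ~71% of BMI variance in training at the modal 2-LV model, and
under leave-one-subject-out CV predicts held-out BMI with r ≈ 0.80, RMS
error 3.4 kg/m² and percent error ~10%. The DTI-only and fMRI-only designs
do worse (explained variance 0.64 and 0.36), illustrating the multimodal
synergy the pipeline is built to expose. Stage tables (`edges.tsv`,
`coupling.tsv`, `feature_r2.tsv`, `predictions.csv`, `summary.json`) and a
checksummed run manifest land in `out/`.

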