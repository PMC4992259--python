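# laborbasin

A dynamical-systems analysis of human parturition for computational
biologists studying the pregnancy myometrium.  The package models the
competition between PR-B-mediated progesterone action (which keeps the
uterus quiescent) and tissue-level inflammation (which drives labor) as a
planar ODE, turns the phase space into a per-patient *probability of labor*,
parameterizes that probability from surrogate-gene transcriptome data, and
evaluates the resulting classifier exhaustively against single- and two-gene
null classifiers.

## The model

PR-B transcriptional activity B̂ and inflammatory load Î follow coupled
logistic-competition equations

    dB̂/dt = b̂·B̂·(1 − B̂/B_c) − k₁·B̂·Î
    dÎ/dt = î·Î·(1 − Î/I_c) − k₂·B̂·Î

Rescaling by the critical levels B_c, I_c and time by k₁·I_c leaves three
dimensionless parameters b, i, k:

    dB/dτ = b·B·(1−B) − B·I
    dI/dτ = i·I·(1−I) − k·B·I

on the unit square.  The corners (1,0) and (0,1) are the stable *quiescent*
and *laboring* equilibria; an interior saddle's stable manifold (the
separatrix) divides their basins.  The **probability of labor** is the area
of the laboring basin under a uniform measure on initial states.  Per
patient, b and i are set from min–max-normalized surrogate transcripts
(PR-B-responsive: FOXO1A, FKBP5; inflammatory: IL1B, IL6, IL8) with k = 1,
so each (PR-B gene, inflammatory gene) *predictor* maps a patient onto the
probability surface.

Classifier assessment follows the exhaustive-partition design: for each of
the C(10,5)·C(8,4) = 17,640 half/half train/test splits of an 18-sample
(10 in-labor, 8 not-in-labor) cohort, nonparametric 95 % confidence
intervals about the group medians form the classifier; test samples are
called IL, NIL or no-call by interval membership, scored by
precision = correct/classified, recall = classified/total, and aggregated
into average F-scores and the classifier success rate (CSR).

## Worked example

```python
import laborbasin as lb

# phase-space analysis at one parameter point
p = lb.DimensionlessParams(b=0.4, i=0.7, k=1.0)
for r in lb.equilibria(p):
    print(r.label, r.location, r.stability)
print("p(labor) =", lb.basin_probability(p).value)
```

```
trivial (0.0, 0.0) source
quiescent (1.0, 0.0) sink
laboring (0.0, 1.0) sink
intermediate (0.5833333333333334, 0.1666666666666667) saddle
p(labor) = 0.8505977574812504
```

A patient with weak PR-B drive (b = 0.4) and strong inflammation (i = 0.7)
sits in a phase space where 85 % of initial states drain to the laboring
equilibrium.

```python
# full synthetic-cohort pipeline
cohort = lb.generate_cohort(lb.default_config(seed=42))   # 18 samples, 10 IL / 8 NIL
norm = lb.minmax_normalize(cohort)
result = lb.sweep(norm, lb.SweepConfig(master_seed=42, subsample=2000))
print(result.model_summary.round(3))
```

```
 kind   predictor  avg_f_score  csr
model IL1B-FOXO1A        0.865  1.0
model  IL6-FOXO1A        0.828  1.0
model  IL8-FOXO1A        0.885  1.0
model  IL1B-FKBP5        0.879  1.0
model   IL6-FKBP5        0.879  1.0
model   IL8-FKBP5        0.872  1.0
```

Every model predictor constructs a separating classifier on every sampled
training split (CSR = 1.0) and classifies held-out samples with average
F-scores near 0.88; `result.null_summary` holds the corresponding null
classifier table.  The same workflow is available from the shell:

    laborbasin synth --seed 42 --out cohort.csv
    laborbasin sweep --cohort cohort.csv --out-dir results
    laborbasin basin --b 0.4 --i 0.7 --k 1.0
    laborbasin stability --b 0.4 --i 0.7

## Layout

- `src/laborbasin/ode_model.py` — dimensional/dimensionless equations,
  nondimensionalization, trajectory integration
- `src/laborbasin/stability.py` — equilibria, Jacobian eigenvalues,
  bifurcation detection
- `src/laborbasin/labor_probability.py` — basin-of-attraction probability
  (grid and separatrix estimators), probability surface
- `src/laborbasin/expression.py` — cohort I/O, within-platform min–max
  normalization, predictor parameterization
- `src/laborbasin/classification.py` — partitions, confidence intervals,
  model/null classifiers, the exhaustive sweep
- `src/laborbasin/synthetic_data.py` — two-platform synthetic cohort
  generator with ground truth
- `src/laborbasin/pipeline.py`, `src/laborbasin/cli.py` — orchestration and
  the `laborbasin` command

See `docs/methods.md` for the modeling assumptions, numerical choices and
known limitations.
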