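# multlearn

Treatment-sensitivity prediction and counterfactual treatment simulation for
multiple-myeloma-style cohorts combining clinical markers, bulk gene
expression and first-line treatment.

## The problem

Newly diagnosed multiple-myeloma patients respond very unevenly to first-line
therapy, and good responders (stringent complete / complete response) are the
minority.  Given a cohort with clinical markers, a gene-expression matrix,
the treatment each patient received and their six-class treatment response
(PD < SD < PR < VGPR < CR < SCR), this package

1. derives a binary **treatment-sensitivity (TS)** outcome by choosing the
   response cutpoint that best stratifies days-to-disease-progression
   survival (log-rank / Cox score test) — on real cohorts this groups
   CR and SCR as the sensitive class;
2. trains a **multi-learning TS predictor**: Kolmogorov–Smirnov marker
   selection with correlation-redundancy pruning (keep the more significant
   member of any pair with |r| > β), then three gene-derived feature
   blocks — patient-to-centroid distances **L**, gene-cluster mean expression
   **E** (cluster counts chosen by a silhouette-based criterion
   SCM = (mean SC − sd SC)/(1 + sd cluster sizes)), and a denoising-autoencoder
   reconstruction **G**^d — feeding a three-member LightGBM ensemble whose
   hyperparameters are tuned by Gaussian-process Bayesian optimization of the
   log loss, with a training-data Youden-J decision threshold;
3. evaluates everything with treatment × TS stratified, class-equalized
   10-fold cross-validation against a simplified single-classifier baseline
   (SMLA: selection → BO → LightGBM/MLP/SVM); and
4. **simulates treatments**: for every patient the one-hot treatment input is
   swapped for each candidate and the treatment κ maximizing the predicted TS
   score is reported, along with the fraction of patients whose best
   simulated treatment differs from the one they received.

Because real myeloma registry data is access-restricted, the package ships a
synthetic cohort generator that plants every structure the pipeline exploits
(informative genes among nulls, redundant correlated duplicates, a minority
sensitive class, survival hazards split by TS, an optional treatment ×
biomarker interaction) together with the ground truth needed to score
recovery.

## Worked example

```python
import multlearn as ml

cfg = ml.SyntheticConfig(n_patients=400, n_genes=200, seed=7)
cohort, truth = ml.generate_cohort(cfg)
cohort, log = ml.filter_cohort(cohort)

definition = ml.select_ts_definition(cohort.response, cohort.ddp_days,
                                     cohort.ddp_event)
print("sensitive classes:", definition.sensitive_classes)

cohort = cohort.with_ts(ml.derive_ts(cohort.response, definition))
plan = ml.make_cv_plan(cohort, n_folds=10, seed=1)
result = ml.run_cv(cohort, plan, pipeline="mult", seed=1,
                   settings=ml.MultSettings.fast())
print(f"pooled AUC: {result.pooled['auc']:.3f}")
print(f"pooled accuracy: {result.pooled['accuracy']:.3f}")

kept = cohort.subset(list(plan.fold.index))
sim = ml.pooled_simulation(result.predictors, kept, plan)
print(f"switch fraction: {100 * sim.switch_fraction:.1f}%")
```

Output:

```
sensitive classes: ['CR', 'SCR']
pooled AUC: 0.968
pooled accuracy: 0.913
switch fraction: 53.8%
```

The survival-guided cutpoint search recovers the planted CR/SCR boundary;
cross-validated discrimination is high because this synthetic cohort plants a
clean 1-sd expression signal; and roughly half of the (equalized, scored)
patients get a different score-maximizing treatment — on this fixture the
planted outcome is mostly treatment-independent, so reassignments reflect
score noise among near-tied candidates rather than a true benefit (plant an
`InteractionSpec` to make κ recover a latent optimal treatment).

A command-line surface wraps the same stages:

```bash
multlearn synth --seed 3 --out cohort/
multlearn evaluate --cohort cohort/ --pipeline mult --folds 10 --seed 7 --out results/
multlearn simulate --cohort cohort/ --seed 7 --out sim.tsv
multlearn run --config run.yaml --out results/   # end-to-end with manifest
```

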