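# pfradiomics

Radiomics analysis of the patellofemoral (PF) joint on lateral knee
radiographs for knee-replacement (KR) risk prognosis.

Knee osteoarthritis prognosis has traditionally leaned on the
Kellgren–Lawrence grade (KLG) of the tibiofemoral joint. The PF joint —
visible on the widely acquired lateral view — carries complementary
prognostic information, but has no standard grading. This package
implements a complete, tested pipeline that quantifies the PF joint with
radiomic texture features and fuses them with KLG into a KR risk score and
a three-class progression-speed stratification:

1. **Preprocessing** — patella alignment (exhaustive rotation search
   maximising the bounding-box height/width ratio), isotropic 0.5 mm
   resampling, z-score normalisation over the patella bounding box
   (clipped at ±6 SD), 32-level gray discretization.
2. **ROIs** — three equal rectangles (ROI_sup / ROI_mid / ROI_inf) built
   from the posterior third of the patella bounding box with a double-width
   posterior extension toward the trochlea.
3. **Features** — 93 first-order/GLCM/GLRLM/GLSZM/GLDM/NGTDM features per
   image type over a 10-image filter bank (original, 4 undecimated
   Coiflet-1 wavelet sub-bands, Laplacian-of-Gaussian σ=1 mm, square,
   square-root, logarithm, exponential) = **930 features per ROI**,
   implemented natively against the standard (IBSI-style) definitions.
4. **RadScore** — per-ROI mRMR ranking (greedy, mutual-information
   relevance minus mean redundancy), top 5 features into an easy-ensemble
   of 500 class-balanced L2-logistic submodels fitted on 60-month KR
   occurrence; RadScore = mean predicted probability; the best-performing
   ROI (by training AUC) is kept.
5. **KR risk score** — multivariate Cox (Breslow ties, Newton–Raphson)
   over {RadScore, age, gender, BMI, KLG, PFOA} with p<0.05 covariate
   retention and refit; the risk score is the linear predictor.
6. **Stratification** — two Youden-index thresholds on the training
   cohort split subjects into low / medium / high risk, targeting
   non-progressors (no KR within 84 months), slow progressors (KR in
   30–84 months) and fast progressors (KR ≤ 30 months); evaluated by
   C-index (bootstrap CI, permutation comparisons), time-dependent
   ROC/AUC at 30/60/84 months, Kaplan–Meier curves, confusion matrices
   and positive predictive values.

Because the motivating cohort data (initial-visit weight-bearing lateral
radiographs with manual patella contours) are access-controlled, the
package ships a first-class synthetic cohort generator
(`pfradiomics.synthdata`) that renders lateral-knee phantoms — a bright
convex patella (rotated superellipse with a severity-scaled inferior-pole
protrusion), a femoral condyle, collimation border and side marker, and a
spatially correlated peri-trochlear texture field whose amplitude drives a
Weibull proportional-hazards KR model (~10.5 % events by 84 months,
realistic KLG mix, administrative plus dropout censoring). Every stage of
the analysis is exercised end-to-end on these cohorts with planted signal.

## Worked example

```python
from pfradiomics import pipeline, synthdata

cfg = pipeline.PipelineConfig(
    sim=synthdata.SimulationConfig(n_subjects=300, seed=7),
    n_submodels=100, seed=7)
res = pipeline.run_pipeline(cfg)
r = res.report
print(r["radscore"]["best_roi"], round(r["radscore"]["train_auc_60m"], 3))
print(r["risk_model"]["retained_covariates"])
print(round(r["metrics"]["combined"]["test"]["c_index"], 3),
      round(r["metrics"]["klg"]["test"]["c_index"], 3))
```

prints

```
roi_inf 0.875
['radscore', 'klg']
0.865 0.856
```

i.e. the inferior ROI wins the per-ROI comparison (training 60-month AUC
0.88), the RadScore survives multivariate Cox selection alongside KLG, and
the fused risk score reaches a test C-index of 0.87 versus 0.86 for KLG
alone on this synthetic cohort.

The same analysis is available as numbered drivers that persist their
artifacts under `results/`:

```bash
python analysis/01_simulate_cohort.py 300 7    # images+masks+table+manifest
python analysis/02_extract_features.py         # 2790-column feature matrix
python analysis/03_train_radscore.py           # mRMR + easy-ensemble + best ROI
python analysis/04_fit_risk_model.py           # Cox fusion + model comparison
python analysis/05_stratify_report.py          # thresholds, confusion, KM
```

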