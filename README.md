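# lvshape

Statistical shape analysis of left-ventricular (LV) surfaces for studying
cardiac remodelling — for example under aortic stenosis, where the
degenerating valve reshapes the ventricle itself. Traditional 2D
measurements (length, diameter) discard most of the 3D anatomy; `lvshape`
instead builds a *point-distribution model* over a population of segmented
LV surfaces and relates its shape modes to clinical function and outcomes.

The pipeline, given triangulated endocardial/epicardial surfaces (STL/PLY/
OBJ, mm) at end-diastole (ED) and end-systole (ES) plus a clinical cohort
table:

1. **Sample** each surface area-uniformly to a dense point cloud
   (default 15,000 points, validated by a resolution-convergence analysis).
2. **Align** all subjects to an iteratively re-estimated mean template —
   similarity registration (Umeyama closed form inside ICP) for matching,
   with only the rigid part applied so natural size variation is retained.
3. **Model**: PCA of the corresponded landmark matrix. Mode *k* has
   eigenvalue λₖ (variance, mm²), variance fraction λₖ/Σλ, and is
   visualised as mean ± kσ·vₖ with σₖ = √λₖ. Subjects project to mode
   scores (shape vectors).
4. **Analyse**: Pearson correlation of mode scores with functional
   parameters (EDV, ESV, SV, EF, CO, ...), and a logistic risk model on the
   concatenated ED+ES scores retained to 90% cumulative variance, compared
   against a demographic baseline (age, sex, stroke volume) by ROC/AUC
   (in-sample and leave-one-out).

Because clinical surface data is rarely shareable, the package ships a
first-class synthetic generator: capped-ellipsoid LV shells whose dominant
variation is cavity sphericity (with size, wall-thickness and basal-tilt
factors, nuisance pose, and a statistically linked cohort with analytic
ground-truth volumes), so the whole pipeline is testable end to end.

## Worked example

```sh
lvshape simulate --n 30 --seed 4 --outdir run/sim --resolution 24
lvshape build    --manifest run/sim/manifest.csv --outdir run/build \
                 --n-points 2000 --seed 0
lvshape analyze  --build-dir run/build --cohort run/sim/cohort.csv \
                 --outdir run/stats
```

The `build` step logs, per phase:

```
INFO phase ED: 30 subjects, 2000 sample points
INFO phase ED: 29 modes, mode-1 fraction 0.781
INFO phase ES: 29 modes, mode-1 fraction 0.826
```

i.e. the leading shape mode explains 78% (ED) and 83% (ES) of landmark
variance — it is the generator's sphericity factor, recovered through
sampling, alignment and PCA. `analyze` then reports

```
INFO AUC shape 1.000 vs baseline 0.713 (LOO 0.676 vs 0.519)
```

the in-sample and leave-one-out AUCs of the shape-mode risk model versus
the demographic baseline: events were simulated from shape, and the shape
model ranks them better. `run/stats/` contains the correlation scan
(`r`, raw and Benjamini–Hochberg-adjusted `p` per mode × variable), both
coefficient tables (β, SE, standardised coefficient, odds ratio with 95%
CI) and the ROC curves as CSV.

The same operations are available as a library
(`lvshape.sample_surface`, `fit_similarity`, `icp_align`,
`build_mean_template`, `fit_ssm`, `synthesize_mode`, `project_shape`,
`pearson`, `fit_logistic`, `roc_auc`, `compare_prediction_models`, ...);
see `docs/methods.md` for the model and every numerical convention.

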