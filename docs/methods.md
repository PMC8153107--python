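# Methods

`lvshape` implements a statistical shape analysis (SSA) pipeline for
left-ventricular (LV) surfaces: dense surface sampling, iterative
mean-template alignment, a PCA point-distribution model, mode–function
correlation, and a shape-mode logistic risk model compared against a
demographic baseline by ROC/AUC. This note records the model, its
assumptions, the numerical choices, and what the synthetic experiments do
and do not demonstrate.

## Pipeline model

**Sampling.** Each triangulated surface (coordinates in mm) is sampled
area-uniformly: faces are drawn with probability proportional to area and a
point is placed uniformly in the face by barycentric coordinates. The
default resolution is 15,000 points per surface, chosen by the
sampling-resolution convergence analysis (below). Sampling is
bit-reproducible given a seed.

**Registration.** The primitive is the closed-form least-squares similarity
fit (Umeyama's method): given corresponded point sets it returns the scale
`s`, proper rotation `R` (reflections excluded by sign-correcting the
smallest singular direction, so det R = +1) and translation `t` minimising
Σ‖sRxᵢ + t − yᵢ‖². Unmatched clouds are registered by iterative closest
point (ICP): alternate nearest-neighbour matching (source→target) with the
closed-form fit until the matched RMS stops changing. ICP is initialised by
centroid translation and radius-of-gyration scale; a cold identity start can
collapse the similarity fit (scale → 0) when the clouds are far apart. The
matched-RMS history is non-increasing, the standard ICP guarantee.

**Correspondence and template.** Point correspondence across subjects is
established against a template: for each template point, the nearest point
of the (similarity-aligned) subject cloud is taken; nearest-neighbour ties
resolve to the lowest point index for determinism. The template is built
iteratively: round 0 aligns all subjects to a reference shape and averages
the corresponded landmarks point-wise; each later round re-aligns everyone
to the current mean and re-averages, until the mean moves by less than
`tol = 1e-3 ×` the mean centroid size (default) or 20 rounds. The default
reference is the medoid shape — minimum summed pairwise post-rigid-alignment
RMS — computed on deterministically subsampled clouds (≤ 120 points per
subject) to keep the O(N²) scan tractable at N ≈ 100; an explicit reference
index can be supplied instead. Because discrete nearest-neighbour matching
re-jitters between rounds, the mean-shape change typically plateaus at a
small positive level rather than reaching an arbitrarily small tolerance;
the iteration stops once the change stops shrinking (change > 0.9 × the
previous round's change after round 3) and reports non-convergence with a
warning rather than spending the remaining rounds re-shuffling matches.

**Scale handling.** Registration during template building and
correspondence uses the full similarity transform, which maximises matching
quality, but the transform *applied* to produce each subject's stored
landmark set is the rigid part only (a rigid Procrustes fit of the
corresponded native-frame points to the template). Heart size is itself a
clinical indicator, so size variation is deliberately retained in the shape
matrix while pose is removed.

**Shape model.** Aligned landmarks are flattened to 3m-vectors and stacked
into an n × 3m matrix. The PCA uses the sample covariance (divisor n − 1),
computed via SVD of the centred matrix; eigenvalue_k is the variance of
mode k (mm²) and its share of the total landmark variance is the mode's
variance fraction. σ_k = √eigenvalue_k is the unit for mode synthesis
(mean ± kσ along eigenvector k). Numerical conventions: rows are put in a
canonical (lexicographic) order before centring so the fit is bit-identical
under subject permutation; eigenvector signs are fixed by forcing each
mode's largest-magnitude component positive; modes below 1e-10 × the
leading eigenvalue (or beyond rank n − 1) are truncated. ED and ES
populations are aligned and modelled independently; for risk prediction the
two score vectors are concatenated.

**Mode-score distribution.** Under the model's Gaussian assumption a mode
score beyond ±kσ has two-sided tail probability 2(1 − Φ(k)); at 3σ this is
≈ 0.27%, below 2%. (A commonly quoted 25.7% figure for ±1σ deformation has
no standard Gaussian derivation — 2(1 − Φ(1)) is 31.7% — and is not
implemented as a closed form.)

**Resolution convergence.** "Change of the first shape mode" is
operationalised as the relative change of the mode-1 variance fraction
between successive sampling resolutions; the chosen resolution is the first
whose change from the previous one falls below the 5% threshold. The
fraction rises monotonically with resolution because nearest-neighbour
correspondence noise — whose magnitude is set by the inter-point spacing —
dilutes the leading mode; this is precisely why a convergence analysis is
needed before interpreting variance fractions.

**Statistics.** Pearson correlation uses the t-distribution two-sided
p-value on n − 2 degrees of freedom. Logistic regression is fitted by IRLS
(Newton–Raphson), tolerance 1e-8 on the penalised log-likelihood and
gradient norm < 1e-6, max 100 iterations; standard errors come from the
inverse observed information, inference is Wald (matching the usual
coefficient/SE presentation), standardised coefficients are β_j·SD(x_j) and
odds ratios exp(β_j) with 95% CIs exp(β_j ± 1.96 SE_j). Perfect separation
(diverging |β|) triggers a ridge-penalised refit (λ = 1e-4, intercept
unpenalised) flagged `penalized`. ROC curves are empirical over all score
thresholds with AUC by the trapezoid rule; ties are grouped so AUC equals
the Mann–Whitney statistic. The risk comparison fits (a) the concatenated
ED+ES mode scores retained to 90% cumulative variance per phase and (b) a
demographic baseline (age, sex coded F=0/M=1, stroke volume). AUC is
reported in-sample (mirroring the usual single-cohort presentation) *and*
by leave-one-out refitting, clearly labelled, because in-sample AUC of a
many-predictor model is optimistic. No multiple-testing correction is
applied to the mode–function correlation scan, but a Benjamini–Hochberg
adjusted column is emitted alongside raw p for transparency. Note that in
the clinical literature printed odds-ratio tables do not always equal
exp(β) of the printed coefficients; this package always reports
OR = exp(β).

## Synthetic data generator

The LV is idealised as a capped prolate half-ellipsoid shell: endocardium
with semi-axes (a, a, c), truncated by a basal plane through the ellipsoid
centre (optionally tilted by up to 30°, emulating valve-plane orientation)
and capped flat so the mesh is closed; the epicardium is the same surface
with semi-axes enlarged by the wall thickness t. Because the basal plane
passes through the centre of a centrally symmetric ellipsoid, the cavity
volume is exactly (2/3)πa²c at any tilt — every subject has an analytic
ground-truth volume. Meshes are emitted with outward orientation (verified
by the signed-volume test at construction).

Population variation is drawn as independent truncated Gaussians on four
interpretable axes: cavity sphericity s = a/c (the designed dominant
factor), global size, wall thickness, and basal tilt, plus a nuisance rigid
pose (rotation up to 20°, translation up to ±10 mm) shared across a
subject's phases. Defaults: a = 25 mm, c = 58 mm (cavity ≈ 76 mL, matching
published end-diastolic volumes for this population), t = 10 mm,
sphericity SD 0.05, size SD 4%, thickness SD 1.2 mm, tilt SD 4°; the SDs
are calibration choices that make sphericity the leading mode, mirroring
the reported dominance of sphericity in LV remodelling under aortic
stenosis. Sphericity varies at constant long axis by default (a constant-
cavity-volume option exists), since size and sphericity are not separated
in the leading clinical mode. The ES geometry shrinks the short semi-axis
at constant long axis so the analytic ES cavity volume equals
EDV × (1 − EF/100) for the subject's drawn ejection fraction (mean 63.6%,
SD 8%); the ES wall is thinned when needed to keep the shell
parameterisation valid (t < a). Per-subject RNG streams make generation
bit-reproducible and independent of subject ordering.

The linked cohort draws EDV as the analytic cavity volume plus Gaussian
measurement noise (SD 3 mL), ESV through the ejection fraction,
demographics from published-range distributions (age 60.1 ± 10.1 y, BSA
2.0 ± 0.2 m², heart rate 73 ± 12 bpm, pressures 133/77 mmHg), and the
binary adverse-event label from a logistic model on standardised shape
parameters. LV mass uses the standard myocardial density 1.05 g/mL.

**What the generator does not emulate:** trabeculation, papillary muscles,
the aortic valve annulus (also excluded from the segmentations the method
targets), regional wall-motion abnormality, non-rigid inter-subject
deformation beyond the four parametric axes, imaging noise and segmentation
error. Passing tests therefore demonstrate that the pipeline recovers known
low-dimensional structure through sampling, alignment and PCA — not that it
resolves arbitrary anatomic variation in clinical images.

## Problem sizes used in tests and experiments

The packaged experiments run at desk scale: populations of 6–200 subjects,
sampling resolutions of 500–5,000 points (the 15,000-point default remains
the API default), mesh resolutions of 24–64 circumferential divisions.
These sizes were chosen so the full suite and the acceptance script run in
minutes while leaving each effect comfortably detectable; the recovered
quantities (variance fractions, correlations, AUC orderings) are stable
well below the default resolutions, as the convergence analysis shows.

## Known limitations

- Closest-point correspondence is a documented design choice; group-wise or
  parameterisation-based correspondence would reduce the resolution-
  dependent noise floor but is out of scope.
- ICP is a local optimiser; with near-symmetric shapes or sparse clouds it
  can settle 5–10° from the global pose. The LV's broken symmetry (apex,
  tilted base) and dense sampling keep this benign in the pipeline.
- In-sample AUC of the shape model is optimistic by construction; the
  leave-one-out AUC is the honest generalisation estimate and is always
  reported next to it.
- The epicardial surface is a parallel offset in semi-axes, not a true
  constant-normal-offset surface; wall thickness is uniform.
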