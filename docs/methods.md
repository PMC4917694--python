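# Methods

`kcmap` is a tested re-implementation of a corneal-OCT diagnostic-accuracy
analysis for keratoconus screening, together with a synthetic cohort
generator that stands in for the original (non-public) patient data.  This
note documents the models, the numerical choices, and what the synthetic
cohort does and does not establish.

## The clinical problem

Keratoconus is a progressive, noninflammatory corneal ectasia: the stroma
thins locally and the anterior surface steepens into a cone.  Established
topographic indices detect moderate disease, but the clinically urgent case
is the *topographically normal* eye that will nevertheless develop
keratoconus — e.g. before refractive surgery.  The natural model for that
state is the fellow eye of a patient with strongly asymmetric keratoconus:
clinically and topographically normal, yet very likely pre-keratoconic.
The analysis asks whether fourteen variables computed from OCT pachymetry
(total corneal thickness) and epithelial thickness maps over the central
5 mm separate three groups of eyes — normal (healthy subjects), keratoconic,
and fellow — and how well single variables and logistic combinations of
them discriminate, with AUCs that respect the pairing of two eyes within a
patient.

## Map representation and feature extraction (`kcmap.maps`, `kcmap.features`)

Maps are scalar fields on a polar grid over the central 6 mm (radius
0–3 mm), default 64 radial rings × 128 spokes, plus the vertex value.  In
the oriented frame 0° is temporal and 90° superior for both eyes; left-eye
maps are mirrored about the vertical axis before analysis so nasal/temporal
sectors coincide.  The default grid keeps thin-point localization error
below one ring spacing (47 µm in the map plane).

Zones follow the device convention: a central 2 mm disc (radius 1 mm), a
2–5 mm annulus (radii 1–2.5 mm) split into superior/inferior half-annuli
(strictly above/below the horizontal meridian) and eight 45° octants
centered on the principal semi-meridians (T, ST, S, SN, N, IN, I, IT).
"2 mm" and "5 mm" are read as diameters.  All zone statistics are
area-weighted (polar cell area ∝ radius); the median and SD are computed
over all grid points of the central 5 mm with those weights, since the
exact sampling pattern of the original instrument is not published.

The fourteen variables: from the pachymetry map, SN−IT (superonasal minus
inferotemporal octant mean), Min (global minimum, vertex included),
Min−Med (minimum minus weighted median), S−I (superior minus inferior
half-annulus mean), Y location (signed vertical map-plane offset of the
arg-min, in µm, positive superior; arg-min ties broken by smallest radius,
then smallest angle), Min−Max (minimum minus maximum; always ≤ 0) and CCT
(vertex value); from the epithelial map, Sup, Inf_ep (half-annulus means),
Min_ep, Max (global extremes), Min−Max_ep, SD (area-weighted population
standard deviation) and CET (vertex value).  The µm convention for
Y location follows the scale of the published group values (hundreds of
µm), not mm.

## Synthetic cohort (`kcmap.synthetic`)

No raw data are available, so the package generates cohorts whose
*extracted feature means* reproduce the published per-group summary table
(stored in `kcmap.reference`).  Each eye is a sum of interpretable parts,
in the oriented frame (mm, µm):

    pachy(x,y) = t0 + k2·r² + k4·r⁴ + gy·y + gx·x + noise
                 − depth·exp(−d²/(2·width²))
    epi(x,y)   = e0 + ey·y + noise − thin·exp(−d²/(2·w_e²))
                 + ann·exp(−(d−r_ann)²/(2·s_ann²))
    power(θ,d) = K + (AST/2)·cos 2(θ−axis) + noise
                 + c·depth·exp(−d²/(2·w_p²))

with `d` the distance to the cone apex.  The disease structure is the
canonical one: a localized stromal depression (the cone), epithelial
thinning over the cone surrounded by an annulus of epithelial thickening,
and anterior-surface steepening co-located with the depression.  `noise`
is a low-order random harmonic surface (radial powers 1–2, angular
harmonics 0–3, random coefficients normalized to a target RMS), not white
noise, so map extremes are stable under grid refinement.

Choices worth flagging:

* **Radial profile.**  A pure quadratic peripheral-thickening term cannot
  reproduce Min−Med and Min−Max simultaneously (it ties the median to
  3.125·k2 over the central 5 mm disc).  The model therefore carries a
  quartic correction; moment calibration gives each group its own
  (k2, k4) — near-quadratic for normals, an almost flat center with a
  quartic periphery for fellow eyes.
* **Fellow eyes** are attenuated, inferiorly decentered cones (mean depth
  ≈ 24 µm vs ≈ 62 µm for keratoconic, apex around 0.33 mm below the
  vertex), with a nearly silent anterior surface: their power-map
  steepening coefficient is ~10× smaller than the keratoconic one.  A
  shared coefficient would contradict the defining property of the group
  (no topographic signs despite measurable stromal thinning).
* **Keratoconic epithelium** combines a thinning pit at the cone, a
  +11 µm (mean) thickening annulus at ~1.9 mm from the apex, and a
  positive vertical gradient; together these reproduce the superior
  epithelium being *thicker* in keratoconus while the inferior is thinner.
* **Latent severity.**  Each eye has a standard-normal severity `z`,
  correlated within patient at `rho` (default 0.5; the source analysis
  reports no within-patient correlation, so it is a free, exposed
  parameter).  `z` loads on the thickness offsets and cone amplitudes, so
  two eyes of one subject are realistically similar.
* **Physical bounds.**  Pachymetry must stay in [300, 700] µm and
  epithelium in [20, 90] µm; a parameter draw violating them is rejected
  (`CalibrationError`) and redrawn at the same severity (rejection
  sampling; ≈ 1 in 2,000 draws at the default calibration).
* **Calibration.**  The per-group parameter distributions were
  moment-matched with a numerical sensitivity probe and a weighted
  ridge least-squares step, then frozen as `DEFAULT_CALIBRATION`.  At 500
  eyes per group every extracted feature mean is within 2%
  (thickness-valued features) or 15% (difference/dispersion/location
  features) of its reference value; only the feature *means* are
  calibrated.  Per-eye SDs are qualitatively reasonable but not matched —
  in particular the generated Y-location spread is kept below the
  published SD so that the mean of 500 eyes stays inside its (very tight)
  15% band.

`feature_sample` is the fast path: it draws the fourteen variables
directly from (optionally correlated) multivariate normals with the
published group means/SDs, bypassing map synthesis.  Map-level and
feature-level sampling answer different questions: the former exercises
the full extraction pipeline, the latter matches the published marginal
moments exactly.

## Topographic screening (`kcmap.topo`)

Four standard indices with inclusive thresholds: I-S ≥ 1.4 D (mean power
of 5 inferior minus 5 superior points at the 3 mm ring, 30° spacing,
bilinear interpolation on the polar grid); central power ≥ 47.2 D
(area-weighted mean over the central 3 mm diameter — the averaging zone is
not standardized and is a parameter); KISA% ≥ 100, assembled as
K·(I-S)·AST·SRAX/300·100 with AST the second-harmonic astigmatism
magnitude and SRAX the skew (degrees) between the steep semi-meridian axes
of the superior and inferior half-rings; and KPI ≥ 0.23, shipped disabled
because its discriminant coefficients are not published (user-suppliable).
SRAX uses least-squares second-harmonic axis fits per half-ring rather
than a raw arg-max over spokes: the arg-max variant is noise-dominated on
near-spherical maps and produces spurious large skews.  A negative I-S
contributes zero to KISA, keeping the index non-negative.

Group assignment mirrors the study construction: an eye is keratoconic if
slit-lamp positive or any index fires; a clean eye whose contralateral eye
is keratoconic is a fellow eye; otherwise normal.  At the default
calibration no generated fellow eye triggers any criterion (verified over
1,600 draws; an acceptance test re-checks 100 fellow eyes).

## Statistics (`kcmap.stats`)

Descriptive summaries report mean, sample (n−1) SD, median and range per
group and variable; a single-observation group gets SD 0 with a
`degenerate_sd` flag rather than an error.  Normality is screened with a
one-sample Kolmogorov–Smirnov test against a normal with estimated
mean/SD; estimating the parameters from the same sample makes the nominal
p conservative (Lilliefors effect), which is documented rather than
corrected because the replicated analysis used the test in this form.
Group differences use the tie-corrected Kruskal–Wallis H (χ², k−1 df;
all-equal data yields H=0, p=1 by convention) with pairwise two-sided
Mann–Whitney post hoc tests, unadjusted by default (the replicated
analysis reports raw pairwise p-values against 0.05) with an optional
Holm correction.

## Diagnostic accuracy (`kcmap.roc`, `kcmap.gam`)

The AUC is the Mann–Whitney pair-counting estimator with midrank ties,
auto-oriented so the reported value is ≥ 0.5 (direction retained).
Because both eyes of a patient enter the data, the SE comes from a
leave-one-cluster-out jackknife over patients — chosen over a
structural-components estimator for transparency and testability — and
the 95% CI is Wald, `auc ± 1.96·SE`, reported untruncated and truncated
to [0, 1] (the source analysis printed an upper bound above 1, i.e. an
untruncated Wald interval; truncation is the default here).  The
orientation is fixed on the full data before jackknifing.  Empirical
coverage at nominal 95% is 93–94% in the suite's two-eye designs with
within-pair correlations 0.5 and 0.9.

Markers whose relationship to disease is not monotone understate their
information in a ROC analysis.  The remedy is a logistic P-spline GAM:
a cubic B-spline basis (default 12 functions, clamped uniform knots over
the observed range) with a second-order difference penalty, fitted by
penalized IRLS (converged when the deviance change is below 1e-9
relative, 100-iteration budget), smoothing parameter chosen by GCV
`n·dev/(n−edf)²` over 20 log-spaced values in [1e-4, 1e4].  The fitted
probability is the transformed marker; outside the training range it is
clamped.  The penalty nullspace is linear, so the heavy-smoothing limit
is the plain logistic fit (checked against an independent IRLS
implementation).  Separation is detected by a near-zero deviance or
diverging coefficients and handled by a small ridge with a warning.  The
monotonicity check inspects the sign of the fitted slope on a 200-point
grid with a 1% tolerance band; the pipeline applies the transform
whenever the check fails (whether the original analysis transformed only
the thin-point location or every non-monotone marker is not stated; the
conditional rule covers both).

Multi-marker combination is an unpenalized logistic fit (same IRLS core,
standardized internally for conditioning), whose linear predictor is the
combined marker; models are fitted and evaluated in-sample, as in the
replicated analysis (a cross-validation toggle exists but is off by
default).  Constant or collinear columns are rejected by name.  In the
map-level pipeline the all-variable model uses 13 of the 14 variables:
the epithelial minimum-minus-maximum is exactly Min_ep − Max on extracted
maps and would make the design singular.

## Pipeline (`kcmap.pipeline`, `kcmap.cli`)

`run_study` chains simulate → extract → screen → stats → roc and writes a
CSV report bundle (roster, features, screening labels, per-group summary,
normality checks, hypothesis tests, per-variable AUC tables for the three
pairwise contrasts, combined-model AUCs, ROC curve points) plus a JSON
manifest with seed, config and config hash.  A run is a pure function of
its configuration: re-running with the same seed reproduces every CSV
byte for byte.  Everything is plain text so external tools can audit the
numbers.

## Problem sizes

The shipped test-suite and acceptance sizes are: 500 map eyes per group
for calibration checks, 2,000 feature-level eyes per group for
single-marker AUC targets, 500 per group for combined models, 500
replicates × 60 patients for CI coverage, and 100 replicates × 400
observations for the GAM gain check.  The full suite runs in about a
minute on one core.

## Known limitations

* Only feature means are calibrated; SDs, ranges and cross-feature
  correlations of the map generator are emergent, not fitted.  Map-derived
  features share latent factors (e.g. `t0` moves Min and CCT together), so
  multi-variable in-sample models separate synthetic groups more easily
  than real data — at study sizes the combined models saturate near
  AUC 1.0, whereas single-variable AUCs land close to the published
  values.  Conclusions about combined-model *magnitudes* should rest on
  the feature-level sampler, which the acceptance targets use.
* Tear-film thickness (3–5 µm, included in the measurements this mimics)
  is not modelled; thicknesses are "as measured".
* The KPI discriminant is pluggable but disabled: its coefficients are
  not public.
* The KS normality screen inherits the Lilliefors bias discussed above.
* No biomechanical or optical modelling, no raw A-scan simulation, no
  segmentation: maps are generated directly at the thickness level.
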