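# Methods

## Scope and model

`eritwin` quantifies the proximal seal of a deployed EVAR stent-graft
from surface geometry alone. The package deliberately starts *after*
deployment: segmentation of CT angiography and the finite-element
contact simulation that produces the deployed configuration are outside
its scope. Its inputs are two watertight triangulated surfaces — the
aortic lumen and the deployed graft — in a common frame, plus a
centerline; its outputs are a radius/gap field over the sealing region,
three normalized risk features, the composite Endoleak Risk Index
(ERI), geometric-fidelity metrics, and a cohort-level evaluation layer.

### Radial apposition sampling

The sealing region is a longitudinal window of length L (default 20 mm,
the extent of the first two covered stents) sampled every Δs = 0.5 mm
with slicing planes normal to the centerline tangent; slice 0 is
proximal. Each plane section of a watertight surface is a set of closed
polylines; the contour whose centroid is nearest the plane origin is
kept and oriented counter-clockwise about the normal. Both the aortic
and the graft contour are discretized into n = 200 radii at uniform
angles about a *shared* center, the aortic contour centroid, so that
rA(s, φ) and rG(s, φ) are comparable pointwise and g = rA − rG is the
local wall–graft gap. (A config switch measures the graft about its own
centroid instead; the shared center is the default because the gap is
then a true radial separation.) When a ray crosses the boundary more
than once — folded graft fabric — the first crossing outward from the
center is used, i.e. the lumen-facing surface. At the defaults this
yields 40 × 200 × 2 = 16,000 radius measurements per case, a count the
pipeline logs and asserts.

Small negative gaps occur where the two surfaces coincide (the two
triangulations interleave); they are slicing noise, clamped to zero for
feature computation and retained signed in the raw field.

### Risk features and the ERI

- **AC** — aortic conicity: |r̄A(first slice) − r̄A(last slice)| divided
  by the larger of the two. Symmetric under taper vs widening; zero for
  a cylinder. The region boundaries stand in for the supra-/infra-renal
  boundaries of the sealing zone.
- **SGS₂** — stent-graft shape: per-slice non-circularity
  (rG,max − rG,min)/rG,max, averaged over slices. Averaging (rather
  than a raw sum over 40 slices) keeps the score in [0, 1]; the raw sum
  is available as a diagnostic mode.
- **SGM₂** — malapposition extent: a sample is malapposed when
  g > ε; for each angle the longest contiguous run of malapposed slices
  is converted to millimetres and the maximum over angles is divided by
  L. "Extent" (longitudinal persistence) rather than gap depth is the
  scored quantity because persistence is what defeats a seal; the peak
  gap depth is carried in every report as a diagnostic, and a
  depth-normalized mode exists as a config switch.

ε defaults to 0.1 mm, the mesh-noise floor measured on synthetic
fixtures where the true gap is zero (observed |g| < 0.05 mm at the
default mesh resolutions); gaps below it cannot be distinguished from
discretization error.

The composite index is ERI = (AC + SGS₂ + SGM₂/2)/2.5. The divisor is
the maximum attainable raw score, so ERI ∈ [0, 1]; the decision cutoff
is 0.80, boundary-inclusive on the positive side. On synthetic deployed
geometries with realistic single-mechanism defects the normalized ERI
stays well below the cutoff (a severe case with AC = 0.4, SGS₂ = 0.2,
SGM₂ = 1 scores 0.44); the cutoff is therefore exercised through the
evaluation layer and the cohort generator's score distributions rather
than through mesh-derived scores.

### Wall mechanics

The directional elastic modulus of the orthotropic aortic wall,
1/E(θ) = cos⁴θ/E_L + sin⁴θ/E_C + ¼(1/G_LC − 2ν_LC/E_L)sin²2θ, is
provided as a standalone utility and recorded in case reports as
material metadata. No stress solver is included, so the constants only
annotate reports. The defaults (E_L = 3.0, E_C = 1.5, G_LC = 0.6 MPa,
ν = 0.27) are placeholders of the right order of magnitude for aortic
wall tissue and should be replaced by study-specific values in the case
config.

### Geometric validation

Two gates certify that a reconstructed surface is faithful to its
reference: volumetric Dice > 0.95 and symmetric Hausdorff
distance < 0.5 mm. Voxelization uses center-inside semantics on an
isotropic grid (default 0.25 mm, finer than the Hausdorff bound being
certified): each z-layer is filled from the exact plane section with
even-odd parity, which handles nested contours. The Hausdorff distance
uses all mesh vertices plus 2,000 seeded area-weighted surface samples
per direction, against *exact* point-to-triangle distances (a
vectorized region-based closest-point computation; KD-trees on vertices
and triangle centroids prune candidates, with oversized cap-fan
triangles handled exhaustively so the pruning radius stays tight). The
reported value is the exact symmetric maximum over the sampled points,
not a percentile variant.

The reconstruction stage under test (`reconstruct_tube`) is the
pipeline's internal representation made explicit: the surface is
reduced to one contour every 0.5 mm with 200 radii each and lofted back
into a watertight tube, with end contours carried out to the centerline
endpoints so the caps sit at the original ends.

## Synthetic data

The generator emulates *deployed* configurations directly, since no
deployed EVAR geometries are publicly deposited. An anatomy is a tube
along a smoothly bent centerline (total direction change =
`angulation_deg`, ramped by a smoothstep so the ends are straight): the
neck radius interpolates linearly (proximal → distal, taper = conicity),
bulges to the sac radius over a sin² profile and returns to a straight
tail. The graft surface starts from the wall radius (perfect
apposition) and is modified by (a) ovalization — an inward minor-axis
deviation with (r_max − r_min)/r_max equal to the stated amplitude; the
graft cannot exceed the lumen, so ovalization itself opens wall gaps —
and (b) declared gap defects, sin²-tapered radial depressions with a
stated peak depth, longitudinal extent and angular span. Meshes are
lofted with parallel-transported frames and capped, watertight by
construction, and byte-reproducible given the spec.

The cohort generator draws per-case specs and clinical covariates
(age 78.6 ± 8.7 y, 73% male, BMI 22.7 ± 4.7, comorbidity flags at
registry-typical rates, neck length/angle/diameter tied to the drawn
anatomy). The ground-truth label comes from a *declared* rule on the
geometry: leak iff a gap deeper than 1 mm persists ≥ 5 mm
longitudinally (declared defects, or an ovalization gap amp × r > 1 mm,
which persists over the whole graft) or neck conicity exceeds 0.25;
labels are then flipped at a 3% noise rate. A `leak_fraction` parameter
(default 0.3) sets the share of anatomies drawn from the leak-prone
regime; benign cases keep taper below 0.18, near-circular grafts
(ovalization < 0.008 — deployed grafts in adequate necks are close to
circular) and only shallow sub-threshold defects. Analytic expected
features (closed forms of AC, SGS₂, SGM₂ from the spec parameters, plus
1% measurement noise) are attached to each record so statistical tests
at cohort scale do not need to mesh and slice hundreds of cases; the
mesh pipeline and the analytic features are cross-checked against each
other on representative cases. A `confounding` parameter couples the
planning-group flag to age, smoking and hostile-neck anatomy for
propensity-matching tests; at 0 the group is randomized.

What the generator does *not* emulate: deployment mechanics (radial
force, friction, fabric wrinkling), wall calcification and thrombus,
non-circular native lumens, and imaging/segmentation noise. Passing
tests therefore demonstrate correctness of the measurement and
evaluation chain on smooth FEA-like geometry, not clinical performance.

## Evaluation layer

Confusion-matrix metrics are reported in percent with 95% CIs: exact
Clopper–Pearson for sensitivity, specificity and accuracy; standard
logit (Mercaldo) intervals for PPV/NPV — the form standard diagnostic
calculators print — falling back to Clopper–Pearson when the logit
variance is undefined at a boundary (e.g. NPV with sensitivity 100%);
Simel's log method for likelihood ratios; LR− is exactly 0 when FN = 0.
The binary-prediction AUC is (sens + spec)/2, equal to exhaustive
pairwise comparison, with a Hanley–McNeil interval. ROC cutoff
selection uses Youden's J with ties broken toward higher specificity.
Group comparison reports Welch's unequal-variance t-test (two-tailed)
with a Mann–Whitney U companion for small-n robustness; two identical
zero-variance groups give p = 1 rather than an error.

Propensity matching estimates the probability of digital-twin-arm
membership by logistic regression on the full baseline covariate list,
then greedily matches each treated unit (descending propensity order)
to its k = 3 nearest unused controls on the logit scale, within a
caliper of 0.2 SD of the logit propensity; treated units that cannot
receive a full set of in-caliper controls are dropped with a warning.
Standardized mean differences (continuous and binary forms) are
reported before and after matching; |SMD| < 0.1 is the balance
convention. Note that with ~15 covariates and a few hundred units per
arm the *pre*-match max |SMD| of a randomized cohort routinely exceeds
0.1 by sampling variation alone; the caliper-matched set reliably
satisfies the threshold, and that is what the tests assert.

The logistic risk model over (AC, SGS₂, SGM₂) is a maximum-likelihood
fit with a small ridge penalty (α = 0.01) so that separable simulated
cohorts remain estimable; fits are deterministic given data. Because
the generating rule is threshold-based, SGS₂'s effect on the label is
mediated through the gap it opens (SGM₂); recovery tests therefore
assert positive marginal associations for all three features and
positive multivariate coefficients for AC and SGM₂.

## Numerical choices

- Ray casting against contour polygons widens the edge-parameter window
  by 1e-9 so a ray through a shared polygon vertex is not lost to
  rounding on both adjacent edges; the minimum over crossings makes the
  overlap harmless.
- Mesh resolution defaults: 0.4-mm ring spacing, 128 circumferential
  vertices (chordal error ≲ 1e-3 mm at aortic radii), chosen so that
  slicing noise sits well below ε.
- Problem sizes in the test and acceptance runs — 10 reconstruction
  cases, cohorts of 500–1,000, 2,000 Hausdorff samples per direction —
  were chosen as the smallest sizes at which the statistical assertions
  are stable across seeds.
- Degenerate inputs raise typed errors: planes missing the mesh, open
  section polylines, centers outside contours, branching slices (two
  comparable lumens), non-watertight voxelization input, single-class
  cohorts, zero-variance SMDs with unequal means (flagged infinite).

## Limitations

- The ERI normalization (divide by the raw maximum 2.5) makes the 0.80
  cutoff very conservative on mesh-derived scores; clinical
  recalibration of the cutoff on real deployed geometries would be
  required before any applied use.
- Shared-center radii assume the graft lies within the aortic contour;
  grossly migrated grafts would need the separate-centers mode.
- The centroid-based fallback centerline is not a medial axis; it is
  adequate for near-tubular vessels only, and end caps bias its tangents
  within roughly one radius of the ends.
- Hausdorff distances are exact point-to-surface distances from a dense
  but finite sample; an adversarial spike between samples could be
  missed, which is acceptable against the 0.5-mm gate at the default
  densities.
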