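# Methods

This note documents the models, parameters and numerical choices behind
`carilow`, in the order the pipeline runs: faces → caricatures → low-vision
renderings → trial schedules → simulated raters → statistics.

## Landmark schemes

Two annotation schemes are modelled as fixed, ordered point layouts:

- **S147** (hand annotation, frontal): 147 points in named blocks —
  jaw/outline 21, forehead/hairline 16, two ears of 11, each brow as a
  12-point closed contour (6 top + 6 bottom, so brow *width* is covered),
  each eye 10, nose 20 (bridge 4, mid-width 4, base 7, nostrils 5), mouth 24
  (outer 14, inner 10).  **S136** is S147 with the occluded ear removed, used
  for all non-frontal views.
- **S68** (automatic detector): the widely used 68-point convention —
  jawline 17, brow top edges 5+5, nose bridge 4 + base 5, eyes 6+6, mouth
  12+8.  It carries no forehead, ear, brow-width or mid-nose-width points;
  that coverage gap is precisely what the 147-vs-68 comparison probes.

The original hand scheme was published only as a figure; the S147 layout
here is a canonical parametric reconstruction defined over the synthetic
face template, scheme-defining for this package.  It reproduces the region
coverage, not anyone's original pixel coordinates.

Coordinates are top-left-origin, x rightward, y downward, 0-based float
pixels.  Landmark files use shortest-round-trip float formatting, so
save→load is bit-exact.

## Caricaturing

A caricature at strength `s` pushes each landmark along the ray from its
category-average position `a` through its veridical position `v`:

    p' = v + s (v − a)

so `s = 0` is veridical and `s = 1` doubles every landmark's distance from
the average; the study regime is `s = 0.6`.  Two algebraic identities follow
and are enforced in tests: collinearity with ‖p′−a‖ = (1+s)‖v−a‖, and the
composition rule `s₁ then s₂ ≡ s₁+s₂+s₁s₂`.  Strengths above 1.0 are
refused by default (they leave the validated regime and produce warp
artefacts) but can be forced.

Only shape is exaggerated ("warp not fade").  The warp is piecewise-affine:
control points are the landmarks plus eight fixed frame anchors (corners and
edge midpoints), the Delaunay triangulation is computed once on the *source*
points and its simplices are reused on the destination points, and each
output pixel inside a destination triangle is mapped back through that
triangle's affine transform and sampled bilinearly.  Pixels outside every
triangle pass through unchanged, which keeps the background stable and
avoids holes.  A zero-area destination triangle is an error naming the
triangle; orientation flips (possible in sliver triangles between adjacent
contours, e.g. the inner/outer lip lines) are reported in a warning and
resolved last-writer-wins.  The identity warp short-circuits and is
bit-exact.

Category averages are landmark-wise means.  In the synthetic pipeline each
sex × viewpoint average is built from a 50-identity pool disjoint from the
26 test identities, mirroring averages taken over a large number of
individuals rather than over the test set itself.

## Low-vision simulators

**Blur** emulates peripheral viewing at eccentricity `E` degrees.  The
cutoff spatial frequency falls inverse-linearly,

    f_c(E) = f₀ E₂ / (E₂ + E),

with defaults `f₀ = 30` cyc/deg (foveal cutoff) and `E₂ = 2.5`° (the
eccentricity that halves acuity); both are configurable, and the defaults
are declared approximations to the original study's unpublished constants.
The image is low-passed with a spatially uniform Gaussian whose modulation
transfer equals 0.5 at `f_c`: since a Gaussian of spatial s.d. σ degrees has
MTF `exp(−2π²σ²f²)`, σ = √(ln 2 / 2)/(π f_c), converted to pixels via the
image's angular width (default: image width subtends 18.11°, a face at
54 cm).  Filtering uses reflective edge handling, which preserves the image
mean to well under 1e-3; the operator is linear by construction.  `E = 0`
returns the input unchanged.

**Phosphenisation** emulates a retinal implant.  A rows × cols electrode
grid (40×40 or 32×32) tiles the face bounding box (from landmarks when
available, else the frame) as a cell-centred lattice — corner sites sit half
a cell in from the box edges.  Whether the original grid was square on the
image or stretched to the face box is unstated in the source; here the
lattice follows the box per axis.  Dropout removes `round(d·N)` sites
uniformly without replacement under a seed (30% in the DO conditions); one
mask is drawn per condition/seed and held fixed, emulating a fixed set of
dead electrodes.  Each surviving site samples the luma of the
nearest-neighbour pixel, binned uniformly into L = 8 levels.  Rendering
composes, on black, one isotropic Gaussian per site with peak amplitude
ℓ/(L−1) and s.d. σ_p = Δ·(0.30 + 0.10·ℓ/(L−1)) where Δ is the grid spacing
— the published description couples brightness to both size and centre
intensity without giving the mapping, so this package couples radius
linearly to level and documents it.  Overlapping phosphenes are summed then
clipped to [0, 1] (additive light), making outputs bit-reproducible under a
fixed seed.

## Synthetic faces

Faces are schematic, not photorealistic: the pipeline's contracts are
geometric and photometric, and realism would add nothing testable.  A
sex-specific S147 template (male template has a wider jaw and thicker
brows) is perturbed per identity by a smooth displacement field: each region
group (jaw, forehead, each ear, each brow, each eye, nose, mouth) receives a
small random affine about its centroid — rotation s.d. 0.02 rad, per-axis
scale s.d. 0.05, translation s.d. 1.2% of image width — plus per-point
jitter of s.d. 0.35% of width.  Fields are mean-centred within each sex
cohort, so the cohort average coincides with the template.  Distinctiveness
scales the whole field.

Viewpoints apply horizontal foreshortening `x → x_c + (x−x_c)cos(yaw)`
about the vertical midline, with the occluded ear's 11 points removed at
any non-zero yaw (S147 → S136).  The S68 ground truth is derived from the
hand-scheme set by arc-length resampling of the covered contours only.

Rendering fills the outline, ears, brows, eyes, nose and mouth from the
landmark polygons with a radial shading gradient and a light 0.8-px
Gaussian smoothing.  Because every drawn element is a function of the
landmarks, re-rendering deformed landmarks approximates warping the
rendered original; the documented agreement is mean absolute pixel
difference below 0.02 at `s = 0.6` (feature edges can disagree locally by
about a pixel).  Passing tests on these faces exercise the geometry and
the photometric contracts; they say nothing about texture, hair, lighting
or other photographic structure that real faces carry.

Default problem sizes: 128 × 128 px images; 26 test identities
(13 M + 13 F) × 4 viewpoints; 50-identity average pools per sex.

## Experiment design

Each sex is split (seeded) into subsets of 7 and 6; pairs are enumerated
within subsets only: C(7,2)+C(6,2) = 36 pairs per sex, 72 over both, × 9
conditions = 648 trials per participant.  Both faces of a trial share the
same resolution, caricature level and (a design choice — the alternative of
mixing viewpoints within a trial would make the latent landmark distance
ill-defined) the same randomly drawn viewpoint.  Left/right placement is
randomised per trial.  Experiment 1 blocks by face sex with order
counterbalanced by participant parity and all 9 conditions intermixed;
Experiment 2 additionally blocks by resolution in the fixed order 40x40ND →
40x40DO → 32x32DO and emits a rescaling marker at each new resolution
block.  Schedules are exhaustively reconstructible from (experiment, seed,
participant).

## Simulated raters

A trial's latent dissimilarity `d` is the mean Euclidean distance between
the two identities' corresponding hand-scheme landmarks at the trial's
viewpoint.  The model multiplies `d` by a caricature-level gain (g_V = 1;
g_C68 and g_C147 are the true effect sizes; the default g_C147 = 1.6
matches the landmark geometry of a 60% caricature) and a per-resolution
attenuation.  Within each rescaling block the latent values are mapped
affinely so the block mean sits at the scale midpoint (5) and the extreme
pairs span ±2.25; Gaussian rater noise (σ_r = 1 rating unit, a free
simulation parameter — the source data give no noise estimate) is added,
and the result is rounded and clipped to 1–9.  This calibration keeps
condition means in the 4–6 band while trial-level ratings reach the scale
ends.

Because every rescaling block contains the same pairs at every caricature
level and the block map is affine, group condition means inherit the gain
structure and the recovered relative effectiveness equals
(g_C68−1)/(g_C147−1) up to rounding distortion and Monte-Carlo noise — the
basis of the parameter-recovery tests.  The same affine-absorption makes
multiplicative resolution attenuation vanish from the ratings when
rescaling is on, which is the simulated counterpart of "between-resolution
comparisons are not valid".

Known limitation: all participants share the same gains and latent
distances, so simulated effect sizes (t statistics) are far larger than
human data, where rater heterogeneity and perceptual noise dominate.  The
simulator targets estimator calibration, not effect-size realism.

## Statistics

- Cell means per participant × resolution × caricature (optionally × face
  sex for the preliminary 3×3×2 check).  Collapsing across sex is a simple
  mean because the design is balanced.
- Paired t-tests, two-tailed, df = N−1; the zero-variance case returns
  t = 0 (identical samples) rather than NaN.
- Repeated-measures ANOVAs run through statsmodels' `AnovaRM` with
  uncorrected degrees of freedom (no sphericity correction anywhere, and no
  multiple-testing correction: contrasts are a priori).  The 3×3
  interaction has df (4, 76) at N = 20.  Tests verify every ANOVA against
  an explicit sums-of-squares decomposition.
- Within-subject error bars are computed as √(MSE/N) from the one-way
  repeated-measures decomposition on caricature level at fixed resolution —
  the dimensionally consistent reading of "MSE divided by √N".
- Relative effectiveness: RE = 100·(C̄68 − V̄)/(C̄147 − V̄), i.e. the
  68-point gain as a percentage of the 147-point gain; RE = 100 when the
  levels tie, 0 when the 68-point caricature adds nothing, and an explicit
  error (not a number) when the reference gain is within tolerance of zero.
  The reciprocal orientation is available behind `literal_printed=True`.
  RE is invariant to uniform affine rescaling of the three means.
- Overall RE averages the per-resolution-plot REs (six plots across the
  two experiments).
- Workbook ingestion reads long-format XLSX through a schema-mapping
  config; unrecognised layouts raise a named error rather than guessing.

## Reproducibility and problem sizes

All stochastic stages (identity sampling, schedules, dropout masks, rater
noise) run off explicit seeds.  The test suite and the acceptance script
use 128-px faces, 512-px gratings for MTF measurement, and 200 replicates
for the Monte-Carlo check of the relative-effectiveness estimator; these
sizes were chosen as the smallest at which the measured quantities are
stable to well inside their test tolerances.
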