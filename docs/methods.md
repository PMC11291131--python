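# Methods

`chambervol` reconstructs and quantifies the aqueous-humor-filled chambers of
the mouse eye from multi-view anterior-segment OCT, and propagates the
resulting anterior-chamber volume through the standard aqueous-humor-dynamics
(AHD) relations. This note records the models, the numerical choices, and
what the synthetic validation does and does not establish.

## The measurement problem

Fluorophotometric estimates of aqueous inflow scale with the assumed
anterior-chamber (AC) volume, Va. Mouse studies have historically assumed
the AC holds essentially all aqueous humor, as in humans (~80 %). Because
the mouse lens is proportionally much larger, the posterior chamber (PC) in
fact holds a comparable share, so direct in-vivo volumetry of both chambers
matters: with Q = d(ln Cc)/dt · (Va + (Cc/Ca)·Vc), a two-fold error in Va is
close to a two-fold error in Q, and through Goldmann's balance
Q − Qu = C·(IOP − EVP) it distorts the inferred unconventional outflow
fraction.

The imaging obstacle is that the PC is only visible with the OCT beam
roughly normal to the limbus, where a single acquisition cannot cover the
whole anterior segment, and that the anterior hyaloid membrane — the PC's
posterior limit — cannot be resolved at all. The pipeline therefore has
four stages: multi-view montaging, seeded chamber segmentation, a geometric
correction of the PC's posterior boundary, and voxel volumetry; a fifth
module evaluates the AHD chain.

## Synthetic eye and acquisition model

The generator builds an axisymmetric parametric eye (optical axis = +z,
posterior; corneal outer apex at z = 0; lengths in mm):

* spherical corneal shell — outer radius of curvature 2.1, thickness 0.1;
* axis-aligned ellipsoidal lens — semi-axes (1.217, 1.217, 0.894), center
  z = 1.253;
* planar annular iris at z = 0.70688 (pupil radius 0.45, outer radius 1.52,
  slab thickness 0.05 drawn posterior to the plane);
* spherical globe — chamber-limiting radius 1.6 centered at the eye equator
  (z = 1.253), with a 0.1 scleral shell;
* a ciliary/pars-plana wedge sealing the chamber's outer wall: the wall
  follows the globe sphere down to 0.22 below the iris, then drops straight
  (cylindrically) to the equator.

The AC is the region inside the inner cornea, outside the lens, and
anterior to the iris plane (or to the lens cap inside the pupil); the PC is
the region between the iris slab, the lens, the outer wall and the
equatorial plane. Every rendered bright structure lies strictly *outside*
these analytic regions (capsule drawn inside the lens surface, iris below
its plane), so the dark voxels a segmenter can recover coincide with the
analytic truth — without this consistency the generator itself would impose
a ~15 % bias on any segmentation.

True chamber volumes are computed at model construction by midpoint
quadrature of the axisymmetric regions in cylindrical (r, z) coordinates,
refined until two successive grids agree to < 0.2 % (typical agreement
~0.1 %). The defaults above were tuned once so the analytic volumes sit at
the reported in-vivo means for albino mice: AC 1.533 µL, PC 1.719 µL,
AC fraction 0.471 (target 47 ± 8 %), angle-apex separation 2.870 mm.

A faint-but-solid "vitreal interface" is rendered from the anterior lens to
the ciliary body, *anterior* to the true equator. It reproduces the real
failure mode: the anterior hyaloid is invisible, segmentation stops at this
spurious interface instead, and the raw PC underestimates truth (by ~45 %
with the default placement). The interface intensity (0.7) and thickness
(70 µm) are chosen so speckle cannot punch flood-fill holes through it at
desk-scale sampling.

The acquisition model rasterizes eight views at 45° azimuthal steps, each
tilted so the beam axis is normal to the limbus (~75° from the optical
axis), with a per-view field of 2.04 × 2.04 × 1.56 mm (the full protocol's
512×512 A-line raster; desk-scale grids keep the field and coarsen the
sampling — 160³ by default, i.e. ~13 µm lateral). Adjacent views overlap by
~50 % of voxels. A ninth, axis-aligned apex view is added by default,
mirroring the single whole-AC acquisition of the underlying protocol; it
covers the small blind spot the limbus-normal ring leaves over the corneal
apex. Fifteen corresponding vessel-branch landmarks per adjacent pair are
sampled on the outer surface inside both fields of view; they are exact
under the true view poses.

Noise: unit-mean lognormal multiplicative speckle (σ = 0.15) plus additive
Gaussian (σ = 0.02 of the unit dynamic range). Landmark picks get isotropic
Gaussian jitter with σ = 4 µm — one voxel at the *acquisition's* full
sampling — rather than one desk-grid voxel: vessel branch points are
identified on acquisition-resolution angiography images regardless of the
raster the volume is stored at, and voxel-proportional jitter would make
desk-scale registration several times noisier than the instrument's actual
operating point. An optional outlier fraction replaces picks with uniform
mispicks to exercise robust estimation.

The validation phantom is a 3 mm hemisphere containing an ellipsoidal
cavity whose axial semi-axis is solved so the analytic cavity volume is
exactly 2.99 µL.

## Volume fusion

Each view's outer surface is extracted as the first supra-threshold voxel
per A-line of the largest 26-connected bright component. Pairwise rigid
transforms come from the landmark correspondences via MSAC (3-point minimal
samples solved by orthogonal Procrustes; per-point cost capped at the
squared inlier tolerance, default 3 voxels; 2000 iterations, fixed seed).
After the best hypothesis, the consensus set is re-estimated once at a 2×
distance gate before the final inlier refit: with jitter comparable to the
tolerance, a strict gate truncates true correspondences and biases the
refit. Absolute poses are chained with view 0 as the reference and mapped
into the eye-aligned common frame through the reference view's pose (known
by construction in synthetic mode; real-data mode would take an axis
override in config).

Point-to-point ICP (KD-tree pairing, 90th-percentile trimming, Procrustes
updates, monotone mean matched distance) is available as a refinement, but
the eye's outer surface is close to a surface of revolution, which makes
surface ICP azimuthally degenerate — unguarded, it slid by tens of degrees.
The pipeline therefore accepts an ICP refinement only when it does not
worsen the landmark residual (×1.25 gate); in practice landmark MSAC alone
sets the registration accuracy (exact in the noiseless setting; ~0.3–1° per
pair at 4 µm jitter).

Fusion averages trilinearly interpolated intensities of all covering views
on a common grid (montage spacing = 1.25 × view spacing by default) and
returns a coverage count. Arithmetic mean is used for overlaps: unbiased
under symmetric noise.

## Chamber segmentation

The guide-point protocol is emulated: inlier/outlier points every
`stride` B-scans (stride = 50/512 of the stack, scaled to the raster),
densified per tracked point by least-squares cubic polynomials x(b), z(b)
in the B-scan index. Short tracks (the iris periphery, the lens interior,
per-view PC tracks) are picked at a finer stride, since a cubic needs four
supports and these structures cross few B-scans. Interpolated points are
snapped to the nearest in-band voxel within a 3-voxel window, as an
operator would nudge a drifted marker.

The segmentation backend is deterministic seeded region growing: each
B-scan is thresholded to the dark chamber band (0–0.45 of the dynamic
range; the upper edge sits near the half-way point of boundary ramps so
thresholding is nearly unbiased), partitioned into 4-connected components,
and components holding an inlier seed are kept while any component holding
an outlier seed is removed (exclusion wins). The backend is a plain
function of (volume, seeds) and can be swapped for any other promptable
segmenter with the same signature.

Two pathways mirror the acquisition: the AC is segmented on montage
cross-sections (voxels covered by no view are treated as boundary so the
flood cannot leak through unimaged gaps); the PC is segmented per tilted
view and the per-view masks are union-merged (nearest-neighbour resampling,
preserving binarity) into the common grid. The merged PC mask is closed
(2 iterations), hole-filled and lightly opened before boundary extraction:
the union of slightly misaligned view masks is ragged, and raw raggedness
poisons the downstream lens-surface extraction. Guide points for the PC
are only placed in the *visibly bounded* part of the chamber (anterior to
the spurious interface) — an operator cannot click inside a region whose
boundary they cannot see — with the lens interior and the pre-ocular
background marked as outliers.

## Hyaloid correction

The anterior lens surface is sampled from two sources: AC posterior-exit
voxels anterior to the iris plane (the modal boundary depth identifies the
iris; a 50 µm margin excludes it; a half-voxel posterior offset moves voxel
centers onto the interface), and the PC mask's innermost voxel per meridian
and depth (72 meridian bins; the innermost-of-several statistic needs no
half-voxel offset). An axis-aligned ellipsoid is fitted to these points:
the homogeneous quadric form is solved scale-invariantly by SVD, stray
points are trimmed at 3 × the MAD-based robust residual scale (three
rounds), and the result is polished by a geometric (first-order orthogonal
distance) Gauss–Newton step. The geometric polish matters: the algebraic
form exhibits curvature-dependent shrinkage under half-voxel quantization
noise that biased the fitted lens center by ~20–50 µm and the corrected PC
volume by 3–10 %. Axis-aligned (6-parameter) rather than freely rotated
(9-parameter) fitting is used because the optical axis is fixed by the
montage frame and cap-only data makes the rotated quadric unstable.

The anterior hyaloid membrane is approximated by the equatorial plane
through the fitted lens center, normal to the optical axis. The corrected
mask is (original ∪ fill) ∩ {anterior side of the plane}, where the fill
comprises voxels anterior to the plane, outside the fitted lens, radially
inside the chamber's outer wall, within the original mask's per-meridian
angular support, and posterior to the mask's per-meridian anterior limit.
The outer wall is taken as the per-meridian maximal boundary radius of the
mask (circular-median smoothed over 5 meridians, plus a half-voxel outward
offset): below the ciliary body the chamber wall runs essentially parallel
to the axis (pars plana), so the deepest observed radius is the right
extrapolant, whereas fitting a sphere to the short visible wall band proved
ill-conditioned.

Accuracy at desk scale (10 noisy single-volume rasters at 128³): raw PC
−47.8 % (all seeds low), corrected PC −2.0 %; the noiseless 9-view montage
at the default 160³ grid gives AC −0.9 % and corrected PC +2.0 %. With full
noise the montage-path PC lands between +2 % and +9 % across seeds,
dominated by sub-degree registration errors amplified across the globe —
an honest portrait of what landmark-driven montaging can deliver, which is
why the correction-accuracy claim is established on the single-volume path
where registration is not in the loop.

## Volumetry and statistics

Volumes are voxel counts × voxel volume (µL = mm³). The angle-apex
separation averages the distance between diametrically opposite
most-peripheral AC voxels over 36 meridian pairs, erroring on an open
periphery. Solids of revolution from half-profiles are evaluated exactly
for the polygonal profile with Pappus's theorem (2π·A·r̄, shapely area and
centroid), after closing open profiles along the axis and rejecting
axis-crossing or self-intersecting input. Cohort summaries use the n−1 SD,
Student-t 95 % CIs and Welch's unequal-variance t-test for two-group
comparisons (the source protocols state "mean ± SD", "95 % CI" and
"unpaired t-test" without further specification).

## AHD chain

All Discussion-level relations are closed-form: the fluorophotometric
inflow equation, the correction factor Q*/Q, Goldmann partitioning (a
negative unconventional rate is preserved as a diagnostic but clamps the
reported fraction at 0, since pressure-independent outflow cannot run
backward), compliance volume change, and isotropic growth scaling
((1+f)³−1). Defaults carry the published mouse values: Q = 90 nl/min,
Va = 5.9 µL, Vc = 0.5 µL, Cc/Ca = 4.0, C = 5.89 nl/min/mmHg at an 8 mmHg
pressure drop, Va* ∈ [1.55, 2.8] µL, φ ∈ [43, 49] nl/mmHg. The "0–15 %"
unconventional bound is treated as an upper bound (whether it was computed
from rounded or unrounded intermediates is ambiguous; unrounded gives
13.8 %). Internal arithmetic is full precision; rounding is display-only.

## Reproducibility and problem sizes

Every random draw derives from one seeded generator; reruns with the same
config are bit-for-bit identical in noiseless mode (and for fixed seeds in
noisy mode). Artifacts carry JSON provenance sidecars (stage, parameters,
seed, input hashes); the run directory is deliberately excluded from the
recorded parameters so runs into different directories remain comparable.

Desk-scale sizes used throughout the tests: 160³ default views (the full
512³ protocol is config-selectable), 128³ single-volume rasters for the
correction study, 96³ for reproducibility runs, 48³ for registration-only
checks. These were chosen as the coarsest grids at which each stage's
discretization error is comfortably inside its validation tolerance.

## What the synthetic validation does not show

The phantom eye is axisymmetric with sharp, fully opaque boundaries; real
vis-OCT data have refraction at the cornea (not modelled — spacing is
taken as given), angle-dependent backscattering, iris pigment shadowing
(the reason the PC is only measurable in albino animals), motion between
views, and a point-spread function that blurs boundaries asymmetrically.
Passing tests establish that the *algorithms* recover known geometry under
speckle and landmark noise at the stated accuracy — not that a specific
scanner achieves it in vivo. The hyaloid correction in particular assumes
the anterior hyaloid truly lies at the lens-center plane; that anatomical
premise is taken from micro-CT evidence and is not re-derivable from the
OCT data itself.
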