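# Methods

`footmech` quantifies internal foot mechanics from serial CT acquisitions
of a loaded foot.  One acquisition (the unloaded reference) is segmented
bone by bone; every other acquisition is only thresholded, producing a
single *skeleton* mask in which the bones are not separated.  The package
recovers each bone's rigid motion into every loaded configuration, maps a
generic ligament model onto the patient's bones, and derives bone motion
amplitudes, projected joint angles and ligament strains, with a paired
nonparametric comparison between footwear conditions.

## Rigid registration onto the skeleton

Each bone is a rigid body.  For a bone with reference-pose surface points
$\{p_i\}_{i=1}^{N_p}$ and a skeleton point cloud, the transform is the
minimizer of the iterative-closest-point style cost

$$ C(R, T) = \frac{1}{N_p} \sum_{i=1}^{N_p} \lVert x_i - (R\,p_i + T)\rVert^2 , $$

where $x_i$ is the skeleton point nearest to the transformed bone point —
recomputed at every cost evaluation, since the correspondence depends on
the candidate transform.  The six parameters (intrinsic Z-Y-X Euler angles
in radians, translation in mm; rotation taken about the cloud centroid so
the two blocks are well-scaled) are optimized directly with SLSQP and
numerical gradients rather than with the closed-form SVD update of
classical ICP: the direct minimization tolerates the partial overlaps and
interconnected joints of a thresholded skeleton better.

Joints make the cost heavily multimodal: adjacent bones' voxels are
interleaved and similar small bones can capture each other's minimization.
Three devices address this, all deterministic:

1. **Coarse-to-fine segment hierarchy** (15 levels).  The whole foot (all
   bones except tibia and fibula) is registered first as one rigid body,
   then anatomical groups (lower leg, hindfoot, midfoot, the five rays,
   the metatarsus, the phalanx rows), finally each bone alone, proximal to
   distal.  Each level's optimum initializes the members at the next
   level, so every optimization starts at (current transform ∘ identity)
   and the returned cost never exceeds its starting cost.
2. **Skeleton point subtraction** in the bone-by-bone pass.  Before a bone
   is registered, skeleton points whose nearest current bone placement is
   some *other* bone are removed (plus a capture radius of one voxel
   diagonal, ≈1.37 mm, for unclaimed points), so neighbouring bones'
   voxels cannot attract the fit.  Distance columns are refreshed as bones
   are refined.
3. **Nudged restarts.**  A voxelized skeleton aliases the cost at sub-voxel
   scale; the bone-level search is therefore repeated from small
   deterministic offsets (±0.5 / ±1.0 mm along the cloud's principal axes,
   ±1.25° / ±2.5° about the long axis), keeping the lowest-cost result, for
   up to three improvement rounds.

For speed, each rigid-body optimization uses an even-stride subsample of
at most 1500 points; reported residuals are always evaluated on the full
clouds.  Skeleton and bone clouds default to interface voxels only
(voxels with at least one empty 6-neighbour) — the nearest-point cost only
ever probes the interface when the surfaces are close.

**Quality metrics.**  Two residuals are reported.  The *cloud residual* is
the mean non-squared nearest-point distance of the registered bone cloud
to the skeleton cloud — the direct by-product of the optimized cost, but
it carries an irreducible offset of roughly half a voxel (~0.4 mm at
0.66 × 0.66 × 1.0 mm) because two voxel-centre samplings of the same
surface at different poses cannot coincide.  The *surface distance*
(`registration_quality`) extracts both the bone and the skeleton surface
by marching cubes, which interpolates the interface to sub-voxel accuracy,
and reports the mean distance from the registered bone surface to the
skeleton surface; this is the registration quality figure (≈0.18 mm on
the synthetic foot, against the 0.28 mm benchmark).

## Generic-to-patient mesh morphing

Ligament attachment points live on a generic source model (one closed
mesh per bone plus attachment coordinates).  Each source bone is deformed
onto the patient's target bone in three stages; the Hausdorff
root-mean-square distance (HRMSd — the RMS of vertex-to-opposite-surface
distances pooled over both directions) tracks progress.

1. **Align & scale.**  Centroids are matched, principal axes aligned
   (signs chosen right-handed with the smallest rotation; near-spherical
   sources fall back to centroid + scale), and one isotropic scale — the
   ratio of mean centroid-to-vertex distances — applied.
2. **Normal projection.**  Every vertex moves along its unit normal
   (flipped to point toward the nearest target point) by $w(t)\,d_i$,
   where $d_i$ is its distance to the target surface and the weight ramps
   linearly, $w(t) = \min(a(1+t), w_1)$ with $a = 0.025$, $w_1 = 1$.
   After each step the mesh is smoothed (below).  Iterations stop when the
   HRMSd drops under 0.2 mm (500-step cap).
3. **RBF morphing**, five iterations.  Correspondences come from normal
   distance measurement: each target vertex casts its normal line onto the
   source; the intersection is the landmark source position $p_j$, the
   target vertex its destination $p_j^\star$ (nearest surface point when
   the line misses within 5× the mean edge length).  Pairs are ranked by
   displacement magnitude, deduplicated at 2× the source mean edge length,
   and an increasing fraction (0.10, 0.25, 0.45, 0.70, 1.00) is used per
   iteration.  Weights solve $K_{\text{land}} W = D_{\text{land}}$ with the
   inverse-multiquadric kernel

   $$ k(d) = \left(d^2 + d\,c\right)^{-\beta}, \qquad
      \beta = \min(b\,d, k_1),\; b = 10,\; k_1 = 0.1, $$

   $k(0) = 1$ by continuity, and every vertex is displaced by its
   kernel-interpolated landmark displacement.  Interpolation is exact at
   the landmarks (to 1e-4 mm before smoothing).

**Numerical choices that matter.**  The kernel scale $c$ is the mean
nearest-landmark separation, floored at 1e-6 mm.  With the exponent capped
at $\beta = 0.1$ the kernel is extremely flat, and a too-small $c$ leaves
the landmark system near-singular: the solve stays exact at the landmarks
while the weights grow by orders of magnitude and the surface oscillates
wildly between them.  Tying $c$ to the landmark spacing keeps the system
conditioned; as a guard, the kernel scale is doubled (up to three times)
whenever the solved weight magnitudes exceed 100× the largest landmark
displacement.  A ridge of 1e-9 is added when the condition number passes
1e12.

**Windowed-sinc smoothing.**  Mesh quality would degrade if projection and
RBF displacements accumulated unchecked, so the mesh is low-pass filtered
after every projection step and every RBF step except the last (the final
iteration's result is not re-projected, so it keeps full interpolation
accuracy).  The filter is one application of a degree-$n$ Chebyshev
approximation of the ideal low-pass in the umbrella-Laplacian eigenbasis
with a Hamming window (passband 0.1 of the [0, 2] spectrum, degree 20,
coefficients normalized to unit DC gain).  Raising the degree *sharpens*
the cutoff rather than smoothing more — essential here, because the filter
is applied dozens of times and a compounding shrink would erase exactly
the landmark-scale corrections the RBF stage adds.  Enclosed volume
changes stay well under 1%.

**Attachment transfer.**  Attachment points are carried through the
alignment similarity, then displaced by barycentric interpolation of the
total per-vertex displacement field (morphed minus aligned source) on the
nearest source triangle.  Points farther than 5 mm from the source surface
raise an error naming the offending fibre.  Note an identifiability
limit: a surface-matching morph can only observe the component of a
deformation that moves the surface; on a featureless shape (a sphere) the
tangential part of an affine map is invisible and the realized
correspondence is radial.  Transfer accuracy should therefore be judged on
shapes with surface relief, where the phantom's known generic-to-patient
map is recovered to better than 2%.

## Biomechanical measures

Per-configuration, each bone carries a rigid transform from the reference
pose.  Relative motion with respect to a frame bone (tibia, to include
whole-foot motion; calcaneus, to remove it) is
$T_{\text{rel}} = T_{\text{frame}}^{-1} \circ T_{\text{bone}}$; the
translation amplitude is the displacement of the bone's volume-weighted
centre of mass under $T_{\text{rel}}$, the rotation amplitude the geodesic
angle $\arccos\!\big((\operatorname{tr} R_{\text{rel}} - 1)/2\big)$.

Two joint angles are tracked between bone centres of mass — tibia–talus–
calcaneus (sagittal: plantar/dorsal flexion; coronal: varus/valgus) and
calcaneus–talus–medial sesamoid (sagittal: arch sagging; transverse:
abduction/adduction).  The anatomical frame is built from the reference
pose: superior = tibia long principal axis, anterior = calcaneus→second
metatarsal orthogonalized against superior, medial = their cross product
with a side-dependent sign.  Angles are signed (two-argument arctangent in
the plane, reported in (−180°, 180°]); the statistics layer consumes
amplitudes, i.e. differences from the unloaded reference configuration.

Ligament fibres are straight lines between bone-fixed attachment points;
strain is engineering strain in percent, $100\,(L - L_{\text{ref}})/L_{\text{ref}}$,
with the reference length taken in the bare unloaded configuration.
Multi-fibre complexes report per-fibre strain.

## Statistics

Bare and shod measures are compared entity by entity (bone, angle, or
fibre) with the two-sided Wilcoxon signed-rank test at α = 0.05, pairing
on configuration.  Zero differences are dropped, tied magnitudes receive
average ranks, the exact null distribution is used up to n = 25 (without
ties) and the continuity-corrected normal approximation above.  No
multiple-testing correction is applied; p-values are raw, and the summary
fraction of significant entities is reported alongside.

## The synthetic foot phantom

No imaging data ships with the package; every claim is exercised on a
synthetic foot with known ground truth.

* **Bones.**  Thirty bones (28 foot bones plus tibia and fibula) shaped as
  superellipsoids with a smooth pseudo-random radial perturbation, meshed
  by radially mapping an icosphere (closed, genus 0).  Sizes are
  anatomical (calcaneus ≈ 80 mm down to sesamoids ≈ 8 mm); the layout
  follows the anatomical chains with 2–4 mm joint gaps and an overlap
  check.  The perturbation amplitude is min(1.2 mm, 0.12 × geometric-mean
  radius): real bones carry tubercle- and facet-scale relief, and a
  near-surface-of-revolution would make rotation about the long axis
  unobservable to any surface-distance cost — an ill-posed recovery
  problem rather than a hard one.
* **Volumes.**  Reference masks (one per bone) and loaded skeleton masks
  (union of all bones after their truth transforms) are voxelized at
  0.66 × 0.66 × 1.0 mm by z-column parity counting; an optional one-voxel
  dilation reproduces the joint interconnections that motivate the
  hierarchy.
* **Load cases.**  Truth transforms compose one whole-foot motion
  (2.5°, 2.5 mm about the foot centroid) with per-bone perturbations
  (0.5–3°, up to 1.5 mm), keeping every bone within a 15°/10 mm envelope;
  a shod counterpart scales the per-bone component by 0.5 with identical
  random draws, modelling stiffer relative bone motion in a shoe.
* **Generic model.**  Each patient bone is resampled at rotated icosphere
  directions and carried through a known smooth map (isotropic 1.05 scale
  plus three sinusoidal displacement modes of ~1 mm amplitude and 39–63 mm
  wavelength), so morphing and attachment transfer are checkable against
  the analytic truth.  Morphing benchmark pairs use icosphere subdivision
  5 (~1.3 mm edges at calcaneus scale, comparable to CT voxel pitch):
  landmark-spacing corrections must lie inside the smoother's passband,
  which requires mesh edges finer than the landmark spacing, as with real
  segmented meshes.

Everything is a pure function of the seed; identical runs are bitwise
identical.

The demo study (`footmech run`) registers six load cases (neutral at
0.1/1.0/1.5 body weights, plantar flexion, dorsal flexion and eversion at
1.0) in both footwear conditions and compares them.  Its shod effect —
per-bone motion halved — is deliberately sub-millimetre: comparisons on
the ground-truth transforms flag essentially every bone, while the same
comparisons on the registered transforms flag only a minority, because
the ~0.4 mm transform-recovery noise masks effects of its own size.  The
gap quantifies the workflow's noise floor and illustrates why
small-structure strain comparisons warrant caution on real data as well.

**What the phantom does and does not show.**  Passing tests demonstrate
that the algorithms recover known rigid motions, known deformation maps,
known attachment positions and planned angles/strains at CT resolution,
and that the statistical layer is exactly calibrated.  The phantom does
not model CT physics (beam hardening, partial-volume intensities, noise),
true articular geometry, cortical/trabecular contrast, or soft tissue;
thresholds, registration robustness to segmentation errors, and anatomical
fidelity of the generic model are not validated by these tests.

## Default problem sizes

The shipped defaults — a 30-bone foot on a ~360 × 130 × 150 voxel grid,
1500-point optimization subsamples, subdivision-5 morphing pairs, ten
pairs for the morphing benchmark — run the registration benchmark in
about two minutes and the morphing benchmark in about five on one CPU.

## Known limitations

* Bones are rigid; no deformable registration.
* Volumes must be axis-aligned (identity direction matrix); no DICOM.
* The CT threshold is a required input on real data; the package never
  guesses Hounsfield calibration.
* The anatomical frame construction is the package's own (the angle
  definitions require one); angle values are comparable only within one
  frame convention.
* The Euler convention (intrinsic Z-Y-X) is a documented choice; only the
  action on points is convention-free, and recovered angle triples should
  not be compared across conventions.
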