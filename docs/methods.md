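# Methods

## Shape model

Every synthetic cell is a solid of revolution built from two spheres (the
future daughter "lobes", radii r₁ ≥ r₂, centers a distance d apart) plus a
bridging neck: a surface of revolution whose meridian is a circular arc
externally tangent to both sphere cross-sections, with waist radius a
(`neck_radius`). One parameter therefore controls furrow ingression:

* at the waist radius where the arc degenerates into the common external
  tangent line, the shape equals the convex hull of the two spheres (a
  spherocylinder for equal lobes) — CHVR is exactly 1;
* as a → 0 with externally tangent spheres, the shape approaches two
  spheres touching at a point — CHVR = 1.25 for equal lobes.

Volume and lateral surface area are closed-form piecewise integrals of the
meridian profile (sphere segments: polynomials; arc segment: polynomial
plus arcsin terms). The convex hull of two spheres is two spherical caps
joined by the tangent conical frustum; the neck never protrudes past the
tangent line, so this is the hull of the whole shape. An independent
voxel-counting oracle (`numeric_volume`, default grid r₂/40) agrees with
the closed forms to well under 0.5% and is exercised in the tests.

The arc circle is solved by bracketing and bisection on its radius R;
near the tangent-sphere limit the waist scales as √R, so the bracket
spans R ∈ [10⁻¹⁸, 10⁹]·r₁ and the waist expression is evaluated in a
cancellation-free form.

## Time courses

Shapes are parameterized by a normalized separation ŝ = d/2r ∈ [0, 1]
(0 = sphere, 1 = externally tangent) and a normalized neck n̂ ∈ [0, 1]
interpolating the waist between the sphere-union crease and the convex
fill. For each frame the common lobe radius is solved by bisection so the
analytic volume equals the target exactly — volume conservation is
enforced by construction, not approximated.

* **wildtype**: sphere until the elongation-onset frame (default 10);
  ŝ rises along a smoothstep over 15 frames; n̂ falls 1 → 0 starting
  `cytokinesis_lag_frames` (default 7) after onset, over 14 frames. The
  7-min lag sits inside the experimentally observed 6.6 ± 1.1 min
  elongation-to-furrowing interval. The end state is two tangent spheres
  of half volume: surface area +2^(1/3)−1 ≈ +26%, CHVR 1.25, aspect
  ratio 2.
* **mutant_arrest**: ŝ rises to 0.5 (aspect ratio peak 1.5, matching the
  1.4–1.5 peaks reported for exocyst-mutant cells) then relaxes; n̂ stays
  at the convex fill, so CHVR is identically 1 — furrowing never starts.

Defaults (lobe radius 6 µm, 40 frames at 60 s, voxels 0.166 µm XY / 1 µm
Z) reflect the target acquisition; cells in the source system are large
(≈12 µm diameter) primary spermatocytes.

## Rendering

Intensity = background + shell + internal rod, PSF-blurred, plus clipped
Gaussian read noise. The membrane shell is the set of voxels within
`shell_thickness`/2 (default 0.4 µm) of the analytic surface **union the
voxels adjacent to the mask boundary on either side**. The second term
models what coarse axial sampling does physically: at the cell poles the
1 µm slab integrates a large tangent patch of membrane and is bright even
though no voxel center lies within the thin band. Without it the
watershed ridge has polar holes and the flood leaks (volume errors over
100%); because the band is symmetric about the surface it does not bias
the boundary inward or outward. The spindle stand-in is a bright capsule
between the lobe centers. Identical `RenderSpec` + seed gives
bit-identical movies, and noise never touches the ground-truth labels or
trace.

What the generator does **not** emulate: photobleaching, Poisson shot
noise (read noise only), mechanical deformation by neighboring cells,
sub-voxel partial-volume intensity, and real PSF side lobes. Passing
tests therefore demonstrate correctness of the measurement pipeline on
idealized optics, not robustness to every artifact of real acquisitions.

## Segmentation

Gaussian pre-filter sigmas are specified in µm and converted per axis to
voxels (defaults 0.166 µm XY, 0.2 µm Z — i.e. 1.0 and 0.2 voxels at the
default spacing). The watershed floods the filtered intensity from all
seeds simultaneously with 6-connectivity and no explicit ridge lines, so
every voxel is assigned and each region is connected — the label volume
partitions the grid, which the voxel-sum geometry requires.

Seed propagation erodes the previous frame's labels with an ellipsoidal
structuring element (default radii 3 voxels XY, 1 Z: roughly isotropic in
µm at the default anisotropy). Fallbacks guarantee a nonempty seed: halved
radii, then the label's deepest voxel (distance-transform maximum). Seeds
exclude voxels above the 99th intensity percentile of the cell interior,
so bright internal structures (spindles) never seed the flood. Once the
furrow pinches, erosion splits the cell core in two; both cores keep the
parent label so the cell is tracked as one object through division —
matching how dividing cells are followed in practice (daughters remain in
contact). Initial seeds are still validated strictly (one connected
component per label, background touching the border).

Measured behavior on synthetic wild-type movies (ground-truth frame-0
seeds, moderate noise): per-frame volume error ≤ 3% at the default
0.166/1.0 µm anisotropy and ≤ 1% at 0.25/0.5 µm, with ≥ 97% voxel-level
identity overlap across the movie. The error does not shrink
monotonically with resolution: the ridge sits on a membrane band of fixed
physical thickness, so boundary placement wobbles within about a voxel at
any grid. Test scenes use 3–4 µm lobes and 16-frame movies to keep the
suite fast; nothing in the pipeline depends on that scale.

## Descriptors

* **Volume**: foreground count × voxel volume.
* **Surface area**: exposed voxel faces, each weighted by its physical
  face area. This estimator is *not* consistent for smooth surfaces (it
  converges to the ℓ¹-projected area, 3/2 of the true area for a sphere),
  but the factor is stable across similar smooth shapes, so percent
  changes and ratios — the quantities the statistics use — are preserved.
  This is a deliberate, stated convention, not an approximation error.
* **Aspect ratio**: major axis = maximum pairwise distance between
  surface-voxel centers, searched over convex-hull vertices (the maximum
  over a point set is attained there); minor axis = twice the maximum of
  the anisotropy-aware Euclidean distance transform (the largest inscribed
  sphere, which sits in the larger lobe of a two-lobe shape). The minor
  axis carries a sub-voxel negative bias (≈0.8 voxel), so calibration
  checks use ≥ 40 voxels per radius where the ratio error is ≈ 2%. The
  ratio is reported unclamped; oblate cells can score below 1.
* **Hull volume / CHVR**: the hull of surface-voxel centers is built in
  index space (the diagonal index-to-physical scaling preserves convexity)
  and rasterized exactly — per (z, y) column, the facet half-spaces cut
  one x-interval. CHVR divides the rasterized hull volume by the voxel
  volume so numerator and denominator share the same half-voxel
  discretization bias: convex voxelized shapes score exactly 1 without
  any correction. The polyhedral center-point hull volume (smaller by a
  half-voxel rind) is available as an alternative convention.
* **Furrow diameter**: cross-sections are binned along the principal
  (PCA) axis of the foreground — not the max-caliper pair, which runs
  corner-to-corner on flat-ended shapes — with bin edges aligned to the
  voxel-layer spacing (unaligned bins alias and can double a bin's
  apparent area). The furrow is the global minimum of the
  equivalent-circle diameter; if that minimum falls outside the middle
  60% of the axis (convex cells taper at the end caps) the mid-axis width
  is reported, so pre-ingression cells return their mid-cell width.

## Alignment and statistics

Window slopes are ordinary least squares over the forward or backward
10-min window, both including the candidate sample (11 samples at 60 s).
The shoulder criterion — forward slope ≥ (1 + threshold) × backward slope
— is ill-posed on flat baselines: any index whose forward window merely
touches the later rise passes trivially, which would place the call up to
a full window early. Detection therefore adds two guards: the backward
slope is floored at 10⁻⁶ of the signal's dynamic range per minute, and
the forward slope must reach 90% of the trace's maximum forward slope.
On a flat-then-linear trace this pins the call to the junction within one
frame; on smooth synthetic cell traces onsets are recovered with median
error ≤ 1 frame at 1% descriptor noise; strictly linear traces yield an
explicit no-call. The 90% fraction is exposed in `AlignmentSpec`
(`peak_fraction`). Cytokinesis onset applies the same rule to the CHVR
series with the same default threshold (0.20), exposed in config; the
maximum forward slope is taken over every index whose forward window
fits, even where no backward window exists.

Aligned groups report mean and SEM per descriptor at every aligned time
covered by at least two traces. `peak_rate` smooths the group mean with a
5-point moving average before central differencing — 60 s sampling is
noisy, and the window is logged and configurable; a derivative peak
narrower than the window is attenuated, so programmed-rate recovery is
tested with a ramp wide relative to the smoothing. Group comparison is
the pooled-variance two-sample Student t-test (as named, not Welch),
two-sided, on per-cell percent changes over 0–25 min; two zero-variance
samples with equal means give p = 1 by convention. Its type-I error at
α = 0.05 is verified to sit in [0.03, 0.07] over 1000 null replicates.

The mutant-vs-wild-type threshold (0.60 vs 0.20) is a per-cohort
configuration field, not auto-detected.

## Known limitations

* The published cohort numbers from real movies (26.1% area gain,
  63 µm²/min peak rate, per-genotype curve shapes) are not reproducible
  here because the raw data are not deposited; the pipeline instead
  verifies the analytic calibration values and generator-programmed
  properties at matching cell scale. Peak rates scale with cell size —
  the 6 µm-lobe default gives ≈ 14 µm²/min.
* The exposed-face area estimator must not be compared against
  mesh-based (marching-cubes) areas; it is a different, internally
  consistent convention.
* Seed-point CSVs replace the interactive seeding a GUI would provide;
  there is no unseeded cell detection.
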