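# Methods

## Model

Observed fixes are modelled as true locations plus independent Gaussian
observation error per axis (variances σ²_obs,xy per horizontal axis,
σ²_obs,z vertically; supplied by the user from manufacturer data or field
trials). Movement within a usable step is a Brownian bridge conditioned on
the noisy endpoints, approximated by linear interpolation of the mean path.
At within-step time fraction α the axis-wise kernel variance is

    σ²(t) = Δt·α(1−α)·σ²_move + ((1−α)² + α²)·σ²_obs,

which equals the observation-error variance at the endpoints and is maximal
mid-step. The three axes are independent, with x and y sharing one
diffusion coefficient η² and z having its own γ² (m²/min; time is kept in
minutes so the coefficients stay numerically small). The 3D kernel is the
product of the univariate normals, which is what makes voxel integration a
product of per-axis CDF differences.

## Move-step screening

A step is used iff its duration is ≤ t_max, the movement test passes, and
(3D only) both endpoint z values are within the admissible range. The
movement null treats each coordinate difference as the difference of two
independent error draws, Normal(0, 2σ²_obs,dim); the step is a movement if
Φ(|Δ|/√(2σ²_obs,dim)) strictly exceeds the quantile (default 0.975) in any
of the three dimensions (the conditions are disjunctive). By default the
z-range check is strict; `z_slack` tolerates violations up to one error SD
in z, for receivers that occasionally place a fix below ground.

## Diffusion-coefficient estimation

Within each maximal run of consecutive usable steps, fixes at odd positions
are treated as held out; each contributes a Gaussian likelihood term around
the chord between its flanking fixes with predictive variance
T·α(1−α)·σ²_move + ((1−α)²+α²)·σ²_obs + σ²_obs. We include the held-out
fix's own observation error once — the natural predictive form — and treat
runs independently, so triples never span a rejected step. The NLL is
minimized on log(σ²_move + 1e−9) with a bounded derivative-free scalar
method (default bounds [1e−9, 1e9] m²/min), separately for the horizontal
(x and y share one term sum) and vertical dimensions.

The movement-test screen censors small displacements and inflates η̂²
upward by roughly 10% at the default simulation settings (η² = 100,
10-minute fixes, σ²_obs,xy = 25); with the screen effectively disabled the
estimator is nearly unbiased. This is a property of the screening protocol,
not of the likelihood, and is why the recovery tests accept a ±20% band.

## Grids and integration

Grids are regular lattices with lower-corner origin; rows index y, columns
x, levels z; voxels are half-open (closed on lower faces) and linearized as
v = i + jI + kIJ. Automatic extents buffer the usable fixes by 4.265 kernel
SDs per dimension (per-axis tail mass ~1e−5), using the largest mid-step
kernel SD. Time integration is the midpoint rule at a user step `dt_int`
(the case-study scales use 0.5–2.5 min); halving `dt_int` moves voxel
probabilities by < 1e−4 at those scales, which the tests enforce. At each
evaluation time only voxels within 4.265 SDs of the kernel mean are
touched; the truncated tail plus any boundary leakage is absorbed by
renormalizing each step's masses to its duration, which realizes the
modified per-step normalization a bounded domain requires. The UD is the
step sum divided by the total used duration — the proportion of time per
voxel. The 2D estimator is identical with the z factor omitted, so an
unbounded 3D UD marginalizes to the 2D UD exactly (tested to 1e−6).

## Vertical bounds and reflection

Bounds a(x, y) (floor) and b(x, y) (ceiling) may be constants or rasters;
they are sampled at column centers and snapped outward to voxel level
boundaries so every voxel is entirely in or out. Kernel mass beyond a bound
is reflected back (z → 2a − z, z → 2b − z), one reflection per active
boundary rather than the infinite image series: the neglected images are
O(exp(−2(b−a)²/σ²_z)) and the per-step renormalization absorbs the
remainder. For very shallow domains (b − a comparable to σ_z) the single
reflection is a known approximation; conservation still holds by
renormalization, but the within-column shape may flatten slightly.

## Terrain surface areas (2.5D)

Each DEM cell is tessellated into eight 3D triangles: the four corners and
four side midpoints (elevations by bilinear interpolation among the four
surrounding cell centers) fan around the cell center at its DEM elevation;
areas come from 3D side lengths via Heron's formula. On a plane the facets
lie in the plane, so a flat 30 m cell gives exactly 900 m² and a 45° ramp
900√2 m²; a dense 100×100 sub-triangulation of the same bilinear surface
agrees within 1% on curved terrain. The boundary ring has no full
neighborhood; by default its areas are left as nodata (a `replicate` edge
policy pads elevations instead). The 2.5D UD reweights cell probabilities
by surface area and renormalizes; contour areas sum surface areas over
member cells of the *adjusted* field (cells without a computed area fall
back to planimetric, i.e. receive no correction). Contours here are taken
on the adjusted probabilities, since the correction precedes draping.

## Interaction statistic

For two animals with temporally matched usable steps (endpoint times within
a tolerance; matched pairs are re-timed to the average schedule), the local
similarity integrates √(f_A·f_B) over each voxel and over matched time.
Per axis, √(N_A·N_B) is a scaled Gaussian with coefficient
√(2σ_Aσ_B/(σ²_A+σ²_B))·exp(−(μ_A−μ_B)²/(4(σ²_A+σ²_B))), so voxel values are
closed-form CDF differences rather than pointwise center evaluations; a
Monte-Carlo oracle guards the derivation in the tests. The global score is
the sum over voxels, normalized by the matched duration only (unmatched
time carries no information about joint use; both durations are reported).
It is 1 for identical kernels, ≤ 1 by Cauchy–Schwarz, and decays as
exp(−d²/(8σ²)) for equal-variance kernels a constant distance d apart.
With vertical bounds, reflection is applied to the combined Gaussian — an
approximation, exact when both kernels share their z geometry.

## Contours and summaries

The p-contour threshold sorts voxel probabilities ascending and excludes
the largest prefix whose cumulative sum is ≤ (1−p) of the field total; the
threshold is the first retained value and ties at it are all included.
Taking the prefix relative to the field's total makes the threshold
scale-equivariant and applicable to interaction fields that sum below 1.
This rule guarantees achieved mass ≥ p with minimal membership; a
nearest-match rule could undershoot p on coarse fields. Contour volume is
member count × voxel volume. Depth-bin probabilities assign each voxel
level to the half-open bin containing its center's depth below a reference
surface (default: the UD's constant upper bound) and error out if bins
leave probability uncovered; the detection-zone summary is the cumulative
mass within a cutoff depth. Structure-encounter probabilities sum the
lowest `n_levels` admissible voxels in a site's column (ground = snapped
lower bound there), and the 2D/3D risk ratio divides the 2D cell
probability by that sum.

## Synthetic data

The generator simulates exactly the assumed process: independent Brownian
increments per axis at the fix schedule (variance rate·Δt), mirror-reflected
in z at the terrain floor and optional constant ceiling, observed with
additive Gaussian error (observations are deliberately not re-bounded,
mimicking fixes below ground). Defaults are a 10-minute schedule, 500
fixes, η² = 100 m²/min, σ²_obs,xy = 25 m² — a mid-sized GPS deployment.
It does not emulate autocorrelated (e.g. Ornstein–Uhlenbeck) movement,
behavioral states, or heavy-tailed error, so passing tests demonstrate
correctness of the estimator under its own model, not robustness to model
misspecification. Analytic DEMs (flat, ramp, Gaussian hill, sinusoidal
bathymetry) have closed-form slopes for the surface-area oracles.

## Numerical choices and problem sizes

Normal CDFs use `scipy.special.ndtr`; the optimizer is
`scipy.optimize.minimize_scalar(method="bounded")` with xatol 1e−8 on the
log scale. Writers emit scientific notation with nine significant digits in
fixed order, so identical inputs give byte-identical files. Test and
acceptance runs use deliberately small problem sizes — tracks of 60–500
fixes, grids of order 10⁴ voxels, Monte-Carlo oracles of 10⁵–10⁶ draws —
chosen so the full suite completes in well under a minute while keeping MC
standard errors far below the tolerances being checked.

## Known limitations

- Single-reflection boundary correction (see above) for very shallow
  z-domains.
- Raster bounds are sampled at voxel-column centers (nearest cell), not
  area-averaged; use a bound raster at least as fine as the grid.
- Steps are assigned whole to one analysis (e.g. one tidal class by their
  first fix); steps crossing class boundaries are not split.
- No reprojection: all inputs must share one projected metric CRS.
- The GeoTIFF reader handles plain single-band rasters with
  ModelPixelScale/ModelTiepoint georeferencing and square cells; anything
  richer should be converted to ESRI ASCII.
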