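# Methods

`laametrics` characterizes the left atrial appendage (LAA) — the
blind-ended pouch of the left atrium where almost all thrombi form in
nonvalvular atrial fibrillation — jointly by its shape and by in silico
haemodynamic indices derived from wall shear stress, and runs the
case/control statistics used to ask which of those features separate
patients with a TIA/CVA history from controls. Because no imaging or CFD
data ship with the package, a calibrated synthetic cohort generator
stands in for both, with exact ground truth stored per subject so every
measurement stage can be validated end to end.

## Reference frame and morphological indices

All morphometrics are computed in a canonical frame: the least-squares
plane of the ostium rim (the orifice loop between atrium and appendage)
is rotated onto the zx-plane with the appendage body toward +y, the rim
centroid at the origin, and the rim's major principal axis along x. The
principal axis rather than the literal maximum-diameter chord fixes the
in-plane rotation because the max-diameter pair is near-degenerate on
elliptical rims and would make the frame (and everything voxelized in
it) numerically unstable; for an ellipse the two coincide. Because the
pose is canonicalized before any discretization, the entire feature
vector is invariant under rigid motion of the input to ~1e-15 relative.

Ostium metrics on the projected rim polygon: `D_max` is the maximum
pairwise point distance; `D_min` the minimal rotating-caliper width
(minimum over hull-edge normal directions, which is exact); `D_mean`
their average; `r_min` the minimal centroid-to-rim distance — note that
`r_min` is *not* `D_min/2`: a caliper width is attained between two
parallel support lines, a centroid distance at a single point, and real
rims make the former larger. Eccentricity is `1 − D_min/D_max`. Area and
perimeter come from the planar polygon (shapely validates simplicity).

Volume uses the signed-tetrahedra formula on the watertight surface
obtained by fan-capping the ostium from the rim centroid; wall area
excludes the cap. Extents: `p_mass` is the volume centroid of the capped
body; `d_A`/`d_P` are the +x/−x extents of the wall from `p_mass`
(anterior/posterior; the +x sign is fixed by placing `p_mass` on the +x
side), `h_LAA` the perpendicular extent above the ostium plane, and
`h_theta` the maximal wall distance from the ostium centre `O_LAA`
(taken as the rim centroid; the construction of these two heights is an
interpretation, as is common for figure-defined quantities).

## Centreline

The centreline runs from `O_LAA` to the anatomical tip. The lumen of the
capped mesh is voxelized (default pitch 1 mm, chosen to resolve distal
tubes of ≥ 3 mm radius) and flood-filled; a small irrational sub-voxel
offset of the grid prevents aligned meshes whose coordinates fall
exactly on rounding boundaries from discretizing differently. The tip is
the wall vertex farthest from the ostium centre measured geodesically
*through the lumen* (26-connected voxel graph); near-ties within one
voxel are resolved toward the radially farthest vertex. A through-lumen
rather than along-wall geodesic is used because the wall geodesic lands
on the outer bend wall of curved pouches instead of the apex.

The path itself is a Dijkstra shortest path under a medial cost — step
length divided by the squared distance-to-wall — which pins it to the
lumen axis rather than the geometrically shortest (corner-cutting)
route. It is then smoothed (moving average, window 5), recentred once
per point on the local cross-section centroid (voxels within a thin slab
perpendicular to the path, within three local wall-distances, and at a
similar through-lumen geodesic level — the level gate excludes voxels of
other limbs of hooked shapes), smoothed again (window 3, twice) and
resampled at 0.5 mm. Tortuosity is chord/arc (1 = straight; the
convention that yields values in (0, 1]); the bending angle is 180°
minus the angle between the chord of the proximal third and the chord of
the distal third, so a straight tube scores 180° and a right-angle elbow
90°.

Accuracy, assessed against the generator's exact curves: arc length and
tortuosity are unbiased at cohort level (|mean error| < 2%, median
|error| ≈ 2%), with heavier per-subject tails (up to ~9% arc length on
the most strongly hooked, near-fold-limit shapes). Oracle tubes: a
straight cylinder of total extent 40 mm measures 40.1 mm at tortuosity
0.996; a quarter-torus tube (ring radius 20 mm, tube radius 4 mm)
measures within 1% in arc and 0.04 in tortuosity of the analytic values.

## Regional partition

The centreline is split at 1/3 and 2/3 of its arc length; every wall
vertex inherits the third containing its nearest centreline point:
inferior (adjoining the ostium), middle, superior (toward the tip).

## Haemodynamic indices

From the wall shear stress vector history τ(t) per node, with trapezoid
integration over the averaging window (beats 2–3 by default; beat 1 of
any simulation is a stabilisation transient):

- TAWSS = (1/T) ∫‖τ‖ dt  (Pa)
- OSI = ½ (1 − ‖∫τ dt‖ / ∫‖τ‖ dt), 0 for unidirectional shear, ½ for
  fully reversing shear
- ECAP = OSI / TAWSS  (1/Pa)
- RRT = [(1 − 2 OSI) · TAWSS]⁻¹  (s), capped at a configurable 10³ s
  where the denominator underflows (fully oscillatory nodes); capped
  nodes are counted and logged

Zero-shear nodes get TAWSS = 0, OSI = 0 and missing ECAP/RRT. Cohort
summaries discard values outside the 10th–90th percentile band
(linear-interpolation percentiles) and average the rest, per region and
for the whole appendage; aggregation is unweighted over nodes by
default, with an area-weighted variant behind a flag. Intra-LAA velocity
is summarized as the volume-weighted mean speed over samples and window
divided by the appendage volume (`Vel/LAAv`, (m/s)/ml — the size
normalization applied before group comparisons). Flow stagnation
converts the per-beat ostium outflow volume `V_out = ∫ max(q,0) dt` into
a retained-blood percentage: `100·exp(−V_out/V)` under perfect mixing
(default) or `100·max(0, 1 − V_out/V)` under piston (plug-flow) washout.
Min–max normalization of cohort columns is provided with the inverse
transform and the scaling record retained.

## Synthetic cohort generator

The generator draws per-subject parameters from per-group calibration
targets: normal marginals (truncated at ±3 SD) where a mean ± SD is
published, log-normal matched to median and range for volumes and areas,
logit-normal for tortuosity. Range-based σ uses the expected extreme
z-score Φ⁻¹(n/(n+1)) at the published group sizes (38 controls, 33
cases), independent of the generated n. A Gaussian copula imposes ρ=0.7
among ostium size metrics and ρ=0.4 between ostium size and LAA volume
(a modelling choice — the source tables report no correlations);
everything else is independent. Hard-infeasible rows (D_min ≥ D_max,
nonpositive extents) are resampled; volumes outside what the swept
geometry can realize for the drawn ostium and length are redrawn from
the conditional truncated law of the volume coordinate, which leaves all
other marginals exactly intact.

Each subject's surface is an elliptical cross-section (semi-axes
D_max/2 along x, D_min/2 along z) swept along a 3-D curve whose heading
starts perpendicular to the ostium plane, turns in-plane over the
proximal half (yaw), and sweeps out of plane over the distal half as an
S-hook (a pitch phase that may partially swing back). The S-hook is what
decouples chord/arc ratio from the third-chord bending angle — a single
smooth bend cannot produce tortuosity 0.79 together with a 114° bending
angle. (yaw, pitch, back-swing) are solved by weighted least squares to
the drawn tortuosity and bending angle, prioritizing tortuosity.
Sections scale along the curve as an ostium→neck transition (distal
relative width 0.42), a proximal body bulge whose amplitude is solved in
closed form so the swept volume ∫A(s)ds matches the drawn volume (real
appendage bodies, not their tails, carry the volume), and a rounded tip.

Two geometric guards keep every realized shape measurable: curvature ×
local half-width is held below 0.72 in each bending plane (beyond ~1 the
inner wall folds; the margin leaves the tightest admissible bend with
clear inner-wall separation), and genuinely separate tube limbs must
keep a wall-to-wall gap above the voxel scale or the voxelized lumen
would merge. Draws whose tortuosity cannot be realized under these
constraints are clamped toward feasibility and flagged; this raises the
realized tortuosity of the extreme low tail, and shifts the realized
control-group median up by roughly 0.00–0.05 depending on the seed —
the main known distortion of the generator relative to its calibration,
documented rather than hidden. The exact realized curve, arc length,
tortuosity, bending angle, analytic swept volume and rim are stored as
per-subject ground truth.

Wall fields are synthesized to hit the subject's haemodynamic draws
exactly: axial speed decays from ostium to tip as exp(−s/λ) with
λ = L/2; wall shear magnitude follows the Poiseuille form 4μv/r
(μ = 0.0035 Pa·s) clipped to a running minimum along the tube (shear in
a blind pouch cannot exceed its upstream neck value — without the clip
the body bulge would invert the inferior > middle > superior ordering);
the overall scale is set so the trimmed-mean TAWSS equals the draw. The
shear direction reverses over a grid-aligned sub-interval of each beat
whose extent, together with a closed-form amplitude factor
γ = A·OSI/(B·(1−OSI)) for the reversed lobe, makes the trapezoid-rule
OSI exact. The ostium flow is a half-sine pulse whose per-beat outflow
volume inverts the mixing washout model at the subject's stagnation
draw, and velocity samples at the sweep stations (volume weights =
analytic slice volumes) are scaled to the drawn Vel/LAAv. Beat 1 ramps
from zero amplitude so that windows including it are measurably biased —
a deliberate test that the beat-2–3 window logic matters. Recovery on
the default cohort: per-node TAWSS to ~1e-5 relative, OSI to ~1e-15,
velocity index exactly, stagnation to < 0.1 percentage points.

What the generator does not emulate: multi-lobed morphology (single
swept tube), pectinate-muscle wall texture, patient-specific pressure or
Doppler waveforms, mitral annulus motion, or any actual flow physics —
the fields are constructed to have prescribed summary indices, not
solved. Passing tests therefore demonstrate that the measurement
pipeline is correct and well-conditioned, not that the indices of real
appendages would be recovered from real CFD exports with the same
accuracy.

## Statistical stage

Continuous features are tested with a pooled-variance two-sided Student
t-test when both groups pass Shapiro–Wilk at 0.05 (Welch behind a flag),
otherwise a two-sided Mann–Whitney U (normal approximation with tie
correction above n = 20, exact for small untied samples, no continuity
correction); categorical features use chi-squared without continuity
correction (Yates behind a flag). Summary styles follow the normality
outcome (mean ± SD vs median (min–max); count (%) for categorical). α =
0.05 per test, no multiplicity correction by default (Benjamini–Hochberg
behind a flag), matching common clinical-table practice. A
summary-statistics t-test (`t_test_from_summary`) reproduces printed
group-table p-values from mean ± SD and n alone.

Stepwise logistic regression (GLM binomial/logit) starts from the full
candidate model and applies the best single add/drop move until AIC
(−2 logLik + 2k, intercept counted) stops improving. Perfect separation
is flagged and the coefficients of a separated model are not to be
interpreted. The joint comparison fits morphology-only and
morphology+haemodynamics stepwise models on the identical subject set
and reports both AICs; on the default synthetic cohort restricted to 15
subjects per group the joint model's AIC is substantially lower,
reproducing at desk scale the qualitative advantage of adding
haemodynamic indices. The random forest uses 500 trees, 4 variables per
split and at most 90 terminal nodes, with mean-decrease-Gini importances
and out-of-bag accuracy (scikit-learn's normalized impurity importances;
rankings match R's unnormalized MeanDecreaseGini).

## Numerical choices and degenerate inputs

Units are fixed package-wide (mm, s, Pa, ml/s, ml). Rims must be simple
closed loops of ≥ 16 vertices; self-intersecting rims, collinear rims,
faces referencing missing vertices, zero-area triangles, non-watertight
capped meshes, inconsistent node counts between timesteps, constant
columns under min–max scaling, and regions with fewer than 10 values all
raise errors rather than being repaired silently. RRT capping defaults
to 10³ s. Every pipeline stage logs input hashes, parameters and seeds.

## Problem sizes used in the test suite

The acceptance checks build the full default cohort (38 + 33 subjects,
0.5 mm mesh edge, 1 mm voxel pitch, 80 timesteps per beat, ≤ 2000 field
nodes per subject) and run in a few minutes on one CPU. Simulation-based
statistical checks use 2000 replicates for error-rate calibration and
10–30 replicates for model-selection behaviour; these sizes are the
package's own choice of a well-conditioned experiment.
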