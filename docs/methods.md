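# Methods

This note records the models implemented, the numerical choices behind
them, what the synthetic generators do and do not emulate, and the known
limitations. Everything quantitative stated here is computed by the test
suite or `scripts/acceptance.py`.

## FvCB model and A–Ci fitting

Net assimilation is the hard minimum of the Rubisco-limited,
RuBP-regeneration-limited and TPU-limited rates (no hyperbolic blending),
matching the default behaviour of the standard fitting tools:

- A_c = Vcmax (Cc − Γ*)/(Cc + Km) − R_d
- A_j = Jmax (Cc − Γ*)/(4 Cc + 8 Γ*) − R_d
- A_p = 3·TPU − R_d

All constants are fixed at 30 °C (Γ* = 54.9 µmol mol⁻¹,
Km = 1093.6 µmol mol⁻¹); no Arrhenius scaling is applied because the
measurement protocol holds one chamber temperature. R_d is stored as a
positive respiration magnitude everywhere; the Laisk intersection also
reports the signed intercept.

`fit_aci` uses Cc = Ci − A_n/g_m with the *observed* A_n (the standard
correction; it makes the noiseless round trip exact and keeps the problem
an ordinary NLS). Fitting is trust-region least squares (`scipy`,
bounds Vcmax, Jmax ∈ (0, 10³], TPU ∈ (0, 10²], R_d ∈ [0, 10], tolerances
1e-12) with a deterministic three-point multistart on scaled initial
values; initials come from inverting the Rubisco branch on the low-Ci
points and the RuBP branch on the top points.

Identifiability is structural, not assumed: a parameter whose limitation
never binds on the observed curve cannot be estimated from a hard-minimum
model. When fewer than two points lie beyond Ci = 600 µmol mol⁻¹ the
RuBP branch is dropped from the model entirely (otherwise the optimizer
can trade Vcmax against Jmax) and `jmax` is reported unidentifiable; the
same flag is derived post hoc from the per-point limitation assignment.
The round-trip tests therefore use parameter sets in which all three
limitations bind at two or more of the 13 protocol setpoints
(Jmax = 1.5·Vcmax, 3·TPU = 0.215·Jmax); with those, recovery on noiseless
curves is at machine precision, and under Gaussian An noise of
0.5 µmol m⁻² s⁻¹ the median relative error of Vcmax and Jmax over 100
replicates is a few percent.

### TPU plateau detection

The TPU term is included only when the high-Ci tail shows a plateau
*distinct* from the natural flattening of A_j (whose slope at high Ci is
itself below any practical threshold, so a slope test alone would
misfire). Detection requires all of:

1. slope of the line through the k = 2 highest-Ci points
   ≤ 0.005 µmol m⁻² s⁻¹ per µmol mol⁻¹ (configurable);
2. those points not exceeding the TPU-free fit's A_j by more than its
   rmse;
3. a candidate refit with the TPU term placing A_p strictly below both
   other limitations at ≥ 2 setpoints without worsening the fit.

Amax is the highest observed A_n on the curve (with the plateau flag
carried through for reporting), normalized by leaf thickness (µm) and by
LMA (mg cm⁻²) on request.

## Laisk intersection

One straight line is fit per curve to the points with
Ci ≤ 150 µmol mol⁻¹; the common intersection (x*, y*) minimizes the
summed squared vertical offsets over all lines, Ci* = x*, R_d = −y*.
Standard errors are leave-one-curve-out jackknife. On exact lines through
a common point the recovery is machine-precision with zero jackknife SE.
A `grouped` mode first averages line coefficients within species —
mirroring analyses run on averaged curves — before intersecting.

The estimator's conditioning depends entirely on the spread of line
slopes: var(Ci*) ≈ σ_b²/Σ(m_i − m̄)². Within one habit the slopes differ
only through between-species Vcmax spread (~15 %), so with An noise of
0.5 µmol m⁻² s⁻¹ on three low-Ci points per curve the intersection can
wander by tens of µmol mol⁻¹ and even land above the axis (negative
apparent respiration). The pipeline therefore checks physicality
(R_d ≥ 0, 0 < Ci* < 150), falls back to the all-curves estimate (both
habits, much wider slope spread) when the per-habit one is non-physical,
and clamps the Eq.-2 respiration input at zero as a last resort, recording
which source was used. Field campaigns with lower low-Ci noise will not
hit these fallbacks.

## Variable-J mesophyll conductance

g_m = A_n / (Ci − Γ*(J_flu + 8x)/(J_flu − 4x)), x = A_n + R_d, with
J_flu = Φ_PSII·PPFD·α·β, β = 0.5 and leaf absorbance α of 0.863
(deciduous) and 0.844 (evergreen) by default. Inputs with
J_flu ≤ 4x or a non-positive bracket raise rather than return invalid
estimates; estimates above 2 mol m⁻² s⁻¹ are treated as invalid by the
per-curve profile helper (the method's usual sanity filter). The closed
form agrees with brute-force numeric inversion to better than 1e-9
relative over 1000 random valid inputs.

The bracket is a small difference of large terms, so single-point
estimates are extremely sensitive to An error — and the sensitivity is
asymmetric, biasing estimates low for low-assimilation leaves. In the
pipeline the per-leaf traits g_m(400) and the per-curve median are
reported as measured, but the value fed into the FvCB fit is the median
over *all* valid per-point estimates in the leaf's habit-and-year group,
the most stable aggregation the design affords. With noiseless input the
whole chain (simulated Φ_PSII → J_flu → g_m) returns the generating g_m
exactly; under the default noise the fitted capacities inherit a g_m
bias of tens of percent while group rankings and the noise-robust traits
(Amax, TPU, anatomy) are unaffected. This is a property of the
single-point variable-J method at this noise level, not of the
implementation.

## Anatomy from labeled volumes

Volumes are integer class grids indexed (slice, row, column), row axis
adaxial → abaxial, isotropic voxel edge 0.65 µm by default. The mesophyll
volume is V_P + V_S + V_IAS; vein and bundle-sheath-extension voxels are
excluded. θ_IAS, P:M, S:M sum to exactly 1 by voxel-count arithmetic.

SA_mes is implemented as the cell–IAS *exposure* surface (the classical
S_m), not total cell-wall area; a `boundary="all"` option measures the
total cell boundary for comparison. Two estimators are provided:

- **face** (reference): shared voxel faces × edge², exactly reproducible
  and invariant under grid symmetries, but it measures the staircase, not
  the smooth surface — on spheres it overestimates by a factor ≈ 1.5.
- **mesh**: marching cubes on the mask after a Gaussian pre-smoothing of
  σ = 0.8 voxels (raw 0/1 marching cubes still tracks the staircase,
  ~8 % high on spheres; σ = 0.8 recovers voxelized spheres of r ≥ 8
  voxels to ~1 %, while σ ≥ 1.5 begins to shrink them). Cell–IAS
  restriction uses the identity
  A(cell|ias) = [A(cell|rest) + A(ias|rest) − A(cell∪ias|rest)]/2,
  exact for face counting and a good approximation for meshes.

Leaf thickness mirrors the line-tool protocol: five sampled columns on
each of six sampled slices (seeded), thickness = inclusive row span from
outermost adaxial to outermost abaxial epidermis voxel; an exhaustive
all-column mode is the oracle for the sampled one. Columns missing an
epidermis are resampled; slices with none are an error.

Per-class segmentation F1 is 2TP/(2TP+FP+FN) over voxels, omitting
classes absent from both volumes.

## Leaf phantoms

The phantom fills the grid with epidermis/palisade/spongy/epidermis slabs
and carves the airspace as analytic primitives, so every volume and
interface area has a closed form: vertical cylindrical channels through
the palisade (integer-centred, radius 6 voxels — a radius at which the
voxelized disk area matches πr² to 0.1 %) and non-touching spheres
(radii 8–12 voxels, random sub-voxel centres, whose voxelization errors
average out) placed by rejection sampling in the spongy layer until the
whole-mesophyll porosity reaches its target. Channels contribute lateral
area to the palisade interface and one end-cap disk to the spongy
interface; spheres contribute their full surface. Spheres keep ≥ 1 voxel
of cell between shells so no analytic area is lost to IAS–IAS contact;
that exclusion caps the achievable spongy fill at ≈ 0.20–0.22, and an
unreachable target raises rather than silently undershooting.

Habit-typical geometries: deciduous — palisade 120 / spongy 81 voxels,
channel lattice 19, porosity 0.23; evergreen — 104/97, lattice 14,
porosity 0.32. Both give ~150 µm leaves; the deciduous phantom is
palisade-dominant (S:P < 1), the evergreen spongier and more porous, the
contrast the comparative analysis is meant to detect. Measured θ_IAS lands
within 0.02 of target and volume ratios within 1 % of the closed form.

What the phantoms do *not* emulate: real cell-shape irregularity,
cell-wall curvature distributions, anisotropic airspace networks, scan
noise or segmentation error. Passing the geometry tests shows the
estimators are correct on known geometry, not that they are unbiased on
real leaves.

## A–Ci simulation

For each chamber setpoint Ca the generator solves the coupled system
A_n = g_s (Ca − Ci), Cc = Ci − A_n/g_m, A_n = FvCB(Cc) by bracketed root
finding in Ci (the equilibrium always satisfies A_n ≤ g_m·Ci, so Cc ≥ 0).
Gaussian noise (default sd 0.5 µmol m⁻² s⁻¹) is added to A_n only — Ci is
treated as measured without error — and g_s is constant per curve (no
stomatal dynamics); both are deliberate simplifications. Φ_PSII is
emitted consistent with the true g_m by inverting the variable-J
relation (NaN where Cc ≤ Γ*), so the fluorescence chain is exactly
invertible on noiseless data. Setpoints default to the 9-value protocol
(50…1600 µmol mol⁻¹) with a 13-value extended protocol available.

The study campaign uses six species (three deciduous/evergreen sister
pairs on a synthetic ultrametric tree of depth 35, labelled synthetic),
three trees each, two seasons. Habit-level base parameters were set so
the simulated Amax (≈ 3·TPU − R_d) matches the magnitudes reported for
deciduous (~23) and evergreen (~12 µmol m⁻² s⁻¹) oaks, with Jmax/Vcmax =
1.49 and TPU chosen so the plateau binds within the protocol; species
factors are lognormal (sd 10 %) shared across capacities (they co-vary
biologically), tree factors lognormal (sd 3–8 %).

## Phylogenetic ANOVA

The Brownian covariance C has C[i,j] = depth of the MRCA of tips i, j.
Response and design are whitened by C^(−1/2) (symmetric
eigendecomposition, eigenvalue floor 1e-12);
F = (SSE_reduced − SSE_full)/(SSE_full/(n−2)). The null distribution
permutes reduced-model residuals in the whitened space (RRPP); the
observed statistic counts as one of the n_perm draws, ties counted
inclusively, so p ≥ 1/n_perm. An exact mode enumerates all n!
permutations and is the test oracle for the sampled mode.

On a star tree the statistic equals classical one-way ANOVA F to 1e-10
relative, and p is invariant under affine trait transforms. Calibration:
over 500 Brownian null simulations at n = 6 and 1000 permutations the
rejection rate at α = 0.05 is ≈ 0.05. Two small-n caveats: whitened
residual permutations have symmetry ties, so the smallest attainable p
is a few tied arrangements out of n_perm rather than 1/n_perm; and with
six species power is modest — large observed F can still yield p near
0.05–0.10. No multiplicity correction is applied across traits, matching
per-trait reporting conventions.

Brownian motion is assumed throughout (no Pagel's λ or OU transforms);
BM trait simulation walks the tree with Gaussian increments of variance
σ²·branch length and adds the habit effect at deciduous tips, and its
tip variance/covariance match σ²·C in Monte-Carlo tests.

## Problem sizes

The default test run uses the 27-point recovery grid, 100 noisy
replicate fits, 1000-input oracle checks, one ~2-million-voxel phantom
per geometry test, and 500×1000-permutation null calibration; the
acceptance script adds the full 18-tree campaign (two seasons, one
phantom per 2022 tree). These sizes were chosen so the whole suite runs
in a few minutes on one core while keeping Monte-Carlo errors well below
the tolerances tested.

## Known limitations

- Single chamber temperature only; no temperature response of the
  kinetic constants.
- The hard-minimum FvCB model makes parameters whose regime never binds
  structurally unidentifiable; the fit flags rather than regularizes.
- Variable-J g_m is noise-fragile pointwise (see above); treat per-leaf
  g_m under noisy input as order-of-magnitude.
- The Laisk intersection is ill-conditioned when all curves share similar
  slopes; its jackknife SE understates the error in that regime.
- Face-count surface area is a staircase measure; use the mesh estimator
  when absolute areas matter.
- Phantom spongy porosity above ≈ 0.35 of the layer is not reachable with
  non-touching spheres; the generator errors instead of approximating.
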