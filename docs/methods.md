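# Methods

hemoshear reconstructs, at desk scale and on synthetic geometry, the chain
of computations behind image-based wall-shear-stress (WSS) studies of the
middle cerebral artery: parametric lumen → tetrahedral mesh → steady
laminar Navier–Stokes solve with measurement-derived boundary conditions →
Cauchy-stress WSS extraction → anatomical wall labeling → projection onto
a vessel-wall-MRI voxel grid → regional WSS ratios and agreement
statistics.

## Flow model

Blood is an incompressible Newtonian fluid with constant density
ρ = 1.06×10³ kg/m³ and dynamic viscosity μ = 3.5×10⁻³ kg·m⁻¹·s⁻¹:

    ρ ∂v/∂t + ρ (v·∇)v = −∇p + μ∇²v + ρf,      ∇·v = 0,

with f = 0 (stored explicitly so a body force can be switched on).  The
characteristic Reynolds number ρ·v·D/μ with D = 6 mm and v = 0.4 m/s is
≈ 727, far below the ≈ 2300 transition, so no turbulence model is used.
The solver computes this formula exactly as written and attaches a laminar
flag rather than asserting a hard-coded regime.

Boundary conditions follow ultrasound/pressure measurements:

* Mean inflow velocity `V_in = w_sys·V_systole + w_dia·V_diastole` with
  default weights (1/3, 2/3).  A (1/2, 2/3) variant is selectable; since
  those weights sum past one, the 1/3–2/3 reading (a standard
  systole/diastole duty-cycle average) is the default.
* Inlet area defaults to the circular cross-section A = πr²; a doubled
  2πr² convention is available as a config option for compatibility, but a
  cross-sectional area of a single circular lumen is πr².
* `R_total = P_brachial/Q_in`.  For multiple outlets the flow split is
  area-cubed proportional (a Murray-law-style rule), with per-outlet
  resistances `R_k = R_total/φ_k` so the parallel combination reproduces
  `R_total` exactly.  The split rule is a modeling choice and is
  configurable in the API.
* Each outlet carries the resistance condition `P_out = R_out·Q_out`,
  applied as the instantaneous algebraic relation (a time integral of
  R·Q would grow without bound under steady flow).  `Q_out` is lagged one
  nonlinear iterate; with a single outlet the lag converges immediately
  because a uniform outlet-pressure shift does not alter an incompressible
  velocity field.
* The vessel wall is no-slip; the inlet carries a fully developed
  parabolic profile rescaled so that its *discrete* boundary flux equals
  the prescribed `Q_in` exactly (this makes the mass-conservation check
  meaningful to solver precision).

## Discretization and solver

Equal-order P1/P1 tetrahedral elements with SUPG/PSPG stabilization.  The
stabilization parameter is the standard combined advective–diffusive form
τ = (‖2ā/h‖² + (4ν/h²)²)^{−1/2} per element, evaluated with the centroid
advection velocity; the 1/Δt contribution is deliberately omitted so the
discrete steady state does not depend on the time step (verified by a
dt-independence test).  Element integrals of the convective term use the
exact P1 product rule; stabilization terms use one-point quadrature.

Time integration is implicit backward Euler from a zero initial state
(default Δt = 0.01 s).  Because the default inflow is steady (the
prescribed velocity is already a cycle mean), the default solver mode
solves the stationary equations directly: a Stokes solve provides the
initial iterate, then Newton iterations (exact residual, analytic
convective Jacobian, backtracking line search) run until the relative
nonlinear residual falls below 10⁻⁶.  When a Newton step fails to reduce
the residual the iteration falls back to Picard (fixed-point) updates,
which are globally much more forgiving; if the whole loop stalls, the
solve restarts with flow-rate continuation (25% → 100% of Q_in).  This
combination converges for the bulk Reynolds range exercised here
(Re ≈ 25–800).  A transient mode runs honest backward Euler with the same
nonlinear machinery and stops at the horizon or when
‖v^{n+1}−v^n‖/(‖v^n‖·Δt) < 10⁻⁶.  An optional sinusoidal pulsatile inflow
exists for the transient mode; it is not the validation path.

Linear systems are solved by sparse direct LU (SuperLU) by default —
exact to machine precision, so the linear tolerance of 10⁻⁴ applies to
the optional GMRES+ILU path.  A Stokes (convection-off) mode exists for
linearity tests: there the solution scales exactly with Q_in.

Discrete mass conservation: constant functions lie in the P1 pressure
space and the PSPG perturbation vanishes on them, so the discrete solution
satisfies ∮v·n dA = 0 identically; measured inlet/outlet flux imbalance is
at round-off (≪ 10⁻³).

## Meshing

Tube lumens are meshed by sweeping a graded polar disk template along the
centerline and splitting each triangular prism into three tetrahedra with
the minimum-global-index diagonal rule, which keeps shared quad faces
conforming.  This is deterministic and dependency-light; it trades
generality (tube topologies only) for exact control of the near-wall
layer.  The wall-adjacent radial layer is `near_wall_factor` (default 0.3)
times the nominal edge; subsequent layers grow by 1.5× up to the nominal
edge.  Boundary faces are extracted from the tet complex, oriented outward
against the owning tet, and labeled inlet/outlet by end-plane tests.
Normals and closure are validated by the divergence identity
∮x·n dA = 3V (relative residual < 10⁻⁶).

Default problem sizes are desk-scale by design: ~10⁴–10⁵ cells (the
minimum-cell-volume guard of 10⁻¹⁴ m³ = 10⁻⁸ cm³ is kept as a quality
flag).  Validation solves use ~5×10⁴ cells for the straight-tube oracle
and ~2×10⁴ for the curved bend.

With linear elements the wall-gradient recovery underestimates the true
wall shear by ≈ t/(2R) where t is the first-layer thickness — the main
reason the near-wall layer is thin.  At the default settings the straight
tube reproduces the analytic Poiseuille wall shear 4μQ/(πr³) to ~4% and
the centerline velocity 2Q/(πr²) to ~1.5%; the inscribed-polygon
cross-section contributes O((2π/n_θ)²) of the remaining bias.

## WSS extraction

σ = −p̄I + μ(∇v + ∇vᵀ) per wall face, with ∇v taken from the owning
element's finite-element basis (constant per P1 tet) and p̄ the mean of
the face's nodal pressures; the WSS vector is the tangential part of σn.
Nodal gradient averaging was rejected because it smears the field near the
end caps.  Wall faces within a configurable band (default twice the median
wall edge length) of the inlet/outlet are excluded from regional means —
the cap boundary conditions contaminate the local stress there.  Regional
means are area-weighted by default (uniform weighting is available).

## Anatomy labels

* Segments: the origin→branch span is trisected by arclength; wall faces
  inherit the segment of their nearest centerline point.
* Quadrants (ventral/dorsal/superior/inferior): the declared anatomical
  axes (anterior, superior — stored with every dataset, LPS-style) are
  projected into the plane normal to the local tangent; faces are assigned
  by the dominant angular component (45° sectors).  Sector assignment
  keeps the two half-plane splits consistent on oblique vessels.
* Curve side: a face is *inner* when its radial offset points along the
  local curvature vector dT/ds (toward the bend center); curvature below
  5 m⁻¹ leaves the side undefined, so straight segments are never labeled
  inner/outer.
* Plaque annotations (2–5 points) are assigned the labels of the wall face
  nearest their arithmetic centroid; centroids farther than one local
  diameter from the wall are rejected.

The tube sweep uses a rotation-minimizing frame (double-reflection
method), not the Frenet frame, so the angular coordinate never flips at
inflection points of s-shaped vessels.

## Registration

The model and image share one world frame; mapping is purely metric with
fixed conventions: 0-based indices, voxel-center alignment,
nearest-neighbor rounding (index = ⌊(x−origin)/spacing + ½⌋), axis order
(in-plane x, in-plane y, slice z), orientation signs carried in the
transform.  The voxel grid defaults to 0.4×0.4 mm in-plane and 0.8 mm
slices, the working resolution of high-resolution vessel-wall MRI.
Round-trip error is bounded by half a voxel by construction.  WSS
deposition: each wall face lands in the voxel containing its centroid;
voxels hit by several faces take the area-weighted mean, and a validity
mask separates empty voxels from true zeros.

## Statistics

`rwss_vi_ds` (ventral+inferior over dorsal+superior mean WSS) and
`rwss_inner_outer` (inner over outer curve wall) are ratios of
area-weighted regional means and are invariant under global scaling of
the field.  The inferential battery uses established implementations
behind the module surface: scipy for t tests (Welch by default for
two-sample comparisons), ANOVA F and Fisher's exact test (two-sided, by
summation of hypergeometric probabilities ≤ observed); scikit-learn for
Cohen's κ; pingouin for the ICC.  The ICC variant is fixed to two-way
random effects, absolute agreement, single measurement — ICC(2,1) — and
recorded in the result's metadata.  Pairwise post-hoc p-values are
Bonferroni-corrected and capped at exactly 1.000.  Agreement above 0.75
is flagged "excellent"; α = 0.05 throughout.  The test suite cross-checks
each test against brute-force oracles (exhaustive hypergeometric
enumeration, hand sum-of-squares ANOVA, hand κ, variance-component ICC
recovery), keeping implementation and oracle on separate routes.

## Synthetic data: what it does and does not emulate

The generator supplies straight/curved/s-shaped tube lumens with optional
eccentric plaque, a binary lumen phantom at vessel-wall-MRI resolution,
and ultrasound panels (systolic velocity 0.6–1.2 m/s, diastolic 0.2–0.6
m/s, radii 1.5–3.5 mm, brachial pressure 80–120 mmHg — plausible cervical
artery ranges, uniform for transparency).  Plaque is modeled as inward
lumen narrowing on one named wall with a smooth angular window under 180°,
so the thinnest wall thickening is always below 50% of the thickest (the
eccentric-plaque identification rule holds by construction); the CFD
domain is the lumen, so only lumen shape matters to WSS.  Seeds are
mandatory arguments; identical seeds reproduce geometries, phantoms and
panels bit-for-bit.

Not emulated: real MR signal (the phantom is a geometry mask, not a T1
image), segmentation error, bifurcating arterial networks, vessel-wall
compliance, non-Newtonian rheology, and cardiac-cycle waveform shapes.
Passing tests therefore demonstrate that the machinery is correct on
idealized tubes — convergence to analytic oracles, correct direction of
the curvature effect (inner-wall shear below outer-wall shear, the
secondary-flow prediction for curved pipes), exact conservation and
circuit identities — not that patient-specific values are reproduced.
Cohort-level results require the cohort's images and are out of scope.

## Numerical choices and degenerate inputs

* Ties in quadrant assignment (|anterior| = |superior| component) go to
  the ventral/dorsal branch; nearest-face ties in point localization go to
  the lowest face index.
* A zero-inflow configuration is solved exactly by the zero state; the
  pipeline completes, writes an all-zero WSS field, flags the summary as
  degenerate, and the CLI exits with a distinct code (4).
* Zero difference variance (paired t), single rating category (κ) and
  zero between-subject variance (ICC) are reported as errors/undefined
  rather than fabricated numbers.
* Non-unit wall normals are normalized with a warning; non-finite solver
  fields abort the run.

## Known limitations

Tube-topology meshing only (no bifurcation trees); steady validation path
(the pulsatile mode is exercised only qualitatively); first-order wall
gradient recovery bounds WSS accuracy at a few percent on desk-scale
meshes; the anatomical quadrant convention must be supplied for oblique
vessels — image-plane conventions alone do not determine it.
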