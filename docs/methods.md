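# Methods

## The two-step activation model

Transcutaneous electrical stimulation drives current between two skin
patches; a motor or sensory axon fires when the induced extracellular
field depolarizes enough membrane to launch a propagating action
potential.  `fesim` computes that threshold in the standard two steps:

1. **Volume conduction.**  The tissue block is a passive conductor obeying
   the quasistatic equation ∇·σ∇V_e = 0 with an insulating outer boundary.
   Each tissue has a single real conductivity (its 2 kHz value) — the
   quasistatic approximation discards dispersion and capacitive effects,
   which is the usual trade for a square stimulation pulse.  Muscle is
   anisotropic (82.38 mS/m across fibres, 329.53 mS/m along the limb
   axis); skin, fat, cortical bone, bone marrow, blood and nerve are
   isotropic.  Because the equation is linear, the field is solved once
   per geometry for ±1 A (the *lead field*); any stimulus amplitude scales
   it exactly.

2. **Fibre response.**  A straight myelinated fibre parallel to the limb
   axis is discretized at its Ranvier nodes (McNeal's compartment cable;
   myelin a perfect insulator by default).  The sampled extracellular
   potentials drive the cable through their second spatial difference.
   Nodal membrane follows the CRRSS description (fast sodium m²h plus
   leak, 37 °C).  An action potential counts as elicited when the
   transmembrane deviation from rest exceeds +80 mV at a node at least
   five internodes away from the end-of-pulse depolarization peak — the
   distance guard distinguishes propagation from the local response under
   the cathode.  The activation threshold is found by bisection on the
   amplitude until the bracket is 10 μA wide; the midpoint is reported.

## Geometric representations

* **CM** — concentric finite cylinders: bone marrow, cortical bone,
  muscle, subcutaneous fat, skin (thicknesses from the standard
  two-subject table; e.g. stack 1: 0.87/0.63/4.32/1.24/0.20 cm).
* **PM** — the same thicknesses as parallel slabs, skin on top.  The
  lateral slab width is half the equivalent-cylinder circumference so the
  skin surface area is comparable and edge truncation stays small; no
  width is standard in the literature, so it is config-exposed.
* **PSEUDO_AM** — a cylinder stack with smooth low-harmonic (≤ 4) radial
  perturbation of the fat–muscle and skin–fat boundaries, an off-centre
  bone, and embedded blood-vessel (medial) and nerve-trunk (posterior)
  inclusions.  It emulates the structural features an MRI-derived
  anatomical model adds over a cylinder — boundary irregularity and
  discrete inhomogeneities — without claiming any subject's anatomy.
  Inclusion cross-sections default to 16 % (vessel) and 6 % (nerve trunk)
  of the bone cross-section disk; with the stack-1 bone radius of 15 mm
  that gives radii of 6.0 mm and 3.67 mm.  The bone "disk" (marrow
  included) rather than the cortical annulus is used for the ratio — the
  resulting radii are the anatomically sensible reading.  Inclusion
  surfaces sit 20.17 mm (vessel) and 30.07 mm (nerve) below the
  fat–muscle boundary along their site rays.  All randomness (harmonic
  amplitudes and phases) comes from one seeded generator; a spec embeds
  its seed and parameter digest, and the inclusion-ablated "(VN)′"
  variant keeps identical boundaries and meshing hints so omission
  studies compare like with like.

Axial length defaults to 40 cm (6.3 cm fibre + electrodes + ≥ 10 cm
margin each side) so insulated-end artefacts stay below solver tolerance.
Coordinates: z along the limb axis, origin at mid-length; x medial→lateral,
y posterior→anterior; sites at 90° intervals (lateral 0°, anterior 90°,
medial 180°, posterior 270°).

## Discretization and solver

The solver is a cell-centred finite-volume method on non-uniform
tensor-product grids — Cartesian for the PM, cylindrical (r, θ, z) for CM
and PSEUDO_AM.  Grid axes are built from mandatory breakpoints (layer
interfaces, electrode patch edges, inclusion extents) so those features
coincide with cell faces at every refinement level; perturbed boundaries
and inclusion circles are resolved by cell-centre classification.  Face
conductances use harmonic averaging, which handles the three-decade
conductivity jumps (skin 0.79 mS/m to blood 700 mS/m) at interfaces.
Each refinement level doubles the cell count exactly by halving the cells
of *one* axis, cycling z → θ (x) → r (y).  Nested per-axis refinement has
a useful property for convergence studies: the threshold change between
two successive levels isolates the error contribution of the axis just
refined and contracts it fourfold, so the refinement ladder decreases
cleanly instead of wobbling with the rounding of an isotropic 2^(1/3)
scheme.  The default per-direction balance is deliberately uneven — the
radial direction, refined last in the cycle, starts finest.

Default spacings concentrate cells under and around the electrode patches
(2.1 mm azimuthal arc under the patch, 2.8 mm axially in the core,
graded transition bands beyond the patch edges) and in the outer muscle
where fibres lie (1.1 mm radially); the level-0 CM grid is ≈ 3.3×10⁵
cells.  Sweep drivers
accept a uniform coarsening factor when many configurations are needed;
orderings and correlations reported by the comparison pipeline are stable
under that coarsening, absolute thresholds shift at the few-percent level.

**Electrode models.**  Two realizations of the patch boundary condition
are provided.  The default *equipotential* patch couples the surface
cells under the patch to a floating super-node through the half-cell skin
conductance and constrains the node's total current to ±1 A — a
well-conducting electrode.  The *uniform-current* variant imposes the
current density directly (Neumann).  Physically they bracket real
electrodes; numerically the equipotential patch has the classic
current-density edge singularity, which measurably slows the convergence
of activation thresholds under grid refinement.  The mesh-convergence
protocol therefore defaults to the uniform-current realization, under
which the threshold error contracts about 3× per cell-count doubling.

**Linear solve.**  One degree of freedom is pinned to make the insulated
(Neumann) system symmetric positive definite; afterwards the potential is
re-gauged to zero volume-weighted mean (no physical ground exists — both
patches carry current).  The system is solved by conjugate gradients to a
relative residual of 1e-8, preconditioned by a recursive two-level scheme:
Jacobi smoothing plus a Galerkin coarse-grid correction on 3³-cell
aggregates of the structured index space (applied recursively until the
coarsest level, ≲ 12 000 unknowns, is factorized directly).  Assembly
works directly with int32 COO triplets and eliminates the pinned row and
column before the CSR matrix is formed, which keeps the 2.4-million-cell
convergence level within a few GB of memory.

**Sampling.**  General point sampling uses cubic (C¹) interpolation on
the rectilinear cell-centre lattice.  This matters: the cable drive is
the second difference of the profile at 0.8–1.6 mm node spacing, and the
derivative kinks of trilinear interpolation on 2–4 mm cells corrupt it.
Fibre profiles additionally use a dedicated sampler
(`sample_fiber_profile`): across the layered direction the interpolation
stencil is a one-sided Lagrange stencil restricted to the fibre's own
tissue run, because the potential has a derivative kink at each
conductivity interface and a symmetric cubic stencil spanning the
fat–muscle boundary (only a few millimetres above a superficial fibre)
rings at reduced order — measurably stalling the grid convergence of
thresholds.  The two smooth directions (θ/x and z) stay cubic.  Interior
point sources (used by the analytic verification studies) are deposited
with trilinear cloud-in-cell weights, which preserves the source's first
moment.

**Mesh-convergence protocol.**  Thresholds are declared grid-converged by
refining from the coarsest grid with ≥ 2×10⁵ degrees of freedom, at least
doubling the count per step, for at least four evaluations, until
successive thresholds differ by < 0.1 %.

## Membrane constants

The nodal constants are the canonical 37 °C CRRSS set (Sweeney's fit):
maximal sodium conductance 1445 mS/cm², leak 128 mS/cm², sodium reversal
+115.5 mV above rest, nodal capacitance 2.5 μF/cm², axoplasmic
resistivity 54.7 Ω·cm, resting potential −80 mV, node length 1.5 μm.
Fibre geometry uses the standard myelinated ratios: internode = 100 ×
outer diameter, axon = 0.7 × outer diameter; the node count is the
largest odd integer whose span fits the 63 mm fibre, so one node sits
exactly under the cathode centre (e.g. 79/53/39 nodes at 8/12/16 μm).
The leak reversal is calibrated so V = 0 is an exact equilibrium of the
implemented rate functions — resting stability then holds by construction
rather than by rounding luck.  All potentials are deviations from rest;
the +80 mV detection level is likewise read as deviation from rest (with
rest at −80 mV this equals a 0 mV absolute crossing).

Integration is semi-implicit with 2 μs steps over 2 ms (for a 0.5 ms
pulse): gates advance by exact exponential update at the current
potential, then the linear-in-V system is solved implicitly (banded),
which is stable against the stiff sodium kinetics without step-size
hunting.  Halving the step moves thresholds by well under 0.5 %.  A
passive-internode variant (10 compartments per internode, 0.01 mS/cm²
myelin conductance, 0.005 μF/cm² myelin capacitance — the lamellated
myelin sheath passes far less current per area than nodal membrane) is
available behind a flag; the default is McNeal's perfectly insulating myelin.

## Comparison pipeline

Sweeps iterate models × sites × electrode areas × gaps × fibre diameters
× depths, with exactly one field solve per (model, site, area, gap)
geometry — amplitude scaling inside the bisection is exact by linearity,
which a solve counter asserts.  Failed configurations are recorded with a
reason, never silently dropped or clamped.  The *activation error* of a
model against the flagged reference is 100·|I − I_ref|/I_ref (unsigned
primary; the signed variant is kept for over/under-estimation analysis).
Threshold curves over a shared parameter grid are compared by zero-lag
Pearson correlation — the curves share an abscissa, so lagged
cross-correlation would be meaningless.

Projection metrics mirror the geometry-matching study: the average fat
thickness and bone-surface-to-muscle-boundary distance are measured along
each site's projection ray, averaged over the z-window covered by the
electrode variations (default ±5 cm, config-overridable — no numeric
window is standard).  `adjust_geometry` then matches targets by a uniform
fat-thickness change compensated in muscle (outer radius preserved) or by
translating the bone along the site ray; re-measurement recovers targets
to < 0.05 mm.

## What the synthetic data can and cannot show

The PSEUDO_AM plays the reference-model role that an MRI-derived anatomy
plays in imaging-based studies.  It reproduces the *mechanisms* — boundary
irregularity, off-centre bone, high-conductivity blood and low-conductivity
nerve inclusions near particular sites — so qualitative findings
(representation orderings, tendency correlations, the growth of omission
error as fibres approach an omitted inclusion, the locality of that
effect) are meaningful.  It does not reproduce any subject's morphology,
so quantitative error magnitudes reported against it are properties of
the synthetic phantom, not predictions for human thighs.  Muscle is a
single homogeneous anisotropic compartment (no fascicles or fascia), the
fibre is straight, and electrode–skin interface impedance is not
modelled.

## Numerical choices and degenerate inputs

* Bisection bracket 5–500 mA; activation below 5 mA triggers one downward
  extension to 0.1 mA before an out-of-range flag; nothing is clamped.
* Thresholds are reported as the final bracket midpoint (minimax error
  within the 10 μA bracket).
* Constant threshold curves have undefined correlation → NaN, reported as
  missing rather than 0 or 1.
* A zero-length z-window degrades the projection metrics to a single
  cross-section; an empty parameter list fails sweep validation.
* Electrode areas/gaps outside the studied ranges (1–25 cm², 0–6 cm) are
  accepted with a warning — they are physically meaningful, just not part
  of the standard study grid.
* Grids refuse inclusions thinner than two local cells and report the
  refinement level that would resolve them.

## Problem sizes used by the shipped tests and the acceptance script

Unit and acceptance tests run the solver at a uniformly coarsened spacing
(factor 1.7–2.6, i.e. tens of thousands of cells) for sweep-style checks,
the analytic oracles at ≈ 0.5 M cells, and the convergence protocol at
its contractual ladder (3.3×10⁵ → 2.6×10⁶ cells over four evaluations).
`scripts/acceptance.py` reports single-configuration thresholds at the
default level-0 resolution and sweep/omission quantities at the factor-2
coarsening; each JSON entry records the size actually used.
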