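# Methods

`vasctx` simulates solute transport in skeletonized microvascular networks
as a chain of three coupled problems on a graph: steady laminar blood flow,
advection–dispersion of solutes through cell-sized volume elements, and
carrier-mediated exchange with perivascular tissue units running a minimal
glucose→lactate metabolism. This note records the model, its assumptions,
the numerical choices, and what the synthetic test geometries do and do not
establish about real vasculature.

## Flow model

Each vessel segment is an axisymmetric cylinder carrying fully developed
laminar (Poiseuille) flow, so its volumetric flow is linear in the pressure
drop with conductance

    G = π r⁴ / (8 µ l),

with r and l the segment radius and length and µ the dynamic viscosity of
blood, treated as Newtonian with µ = 0.004 Pa·s. Shear-dependent rheology,
vessel compliance and pulsatility are out of scope; the linear model is
valid while Re = ρ|u|d/µ < 1 in every segment, which `reynolds_numbers`
verifies a posteriori (typical capillary values here are 10⁻⁴–10⁻³).

With the signed incidence matrix M (M[e, tail] = +1, M[e, head] = −1) the
edge flows are Q = G·M·P and mass conservation at interior nodes closes
the symmetric positive semi-definite system MᵀGM·P = b. Boundary
conditions are nodal: each terminal node prescribes either a pressure (Pa)
or a flow (nl/min in files). Pressure-anchored rows are eliminated — their
columns, scaled by the known pressures, move to the right-hand side, and
their rows are dropped because their boundary flow is the unknown
reaction. At least one pressure anchor is required (and enforced by
validation) or the pressure level is undetermined. The reduced system is
solved by SVD-based least squares; on networks small enough to solve
densely by independent loop-assembled elimination, the two agree to 1e−10
relative.

Sign conventions are fixed once and used consistently everywhere: Q_e > 0
means flow along the stored edge orientation, and the discrete
accumulation at a node is −MᵀQ (negative at inlets, positive at outlets,
zero in the interior).

Mean velocity u = Q/(πr²) is used downstream. For Poiseuille flow the
centerline velocity is exactly twice the mean; because published usage
varies, the convention is a config switch (`velocity_convention:
mean|centerline`, default `mean`, which is the standard form of the
Aris–Taylor relation).

## Discretization

Segments are split into tank-in-series volume elements whose length h
targets the diameter of a biological cell, c_l = 11.5 µm, within a band
±δ = 2.5 µm. The splitting rule is k = round(l/c_l) equal elements
(k ≥ 1). Two classes of parent length cannot satisfy the open bound
(c_l−δ, c_l+δ) with any integer split: stubs shorter than c_l−δ (kept as
one element of their full length — real skeletons contain them) and
lengths in the gap (c_l+δ, 2(c_l−δ)), for which k is chosen to bring h
closest to c_l. Both classes are flagged `h_exempt`.

Every refined node owns the half-cylinder volumes of its adjacent
elements, V_i = ½ Σ A·h; at junction nodes the merged half-cylinders form
the (spherical) junction element, of which only the volume is used. The
nodal volumes therefore sum to the total luminal volume exactly, a
property asserted at 1e−12 relative.

Each non-junction node is paired with an annular tissue unit — a
Krogh-type hollow cylinder of outer diameter d_bv + d_t over the node's
axial share of length, d_t = 12.4 µm by default (derived from a
1020 µm³ beta-cell volume). When adjacent elements differ in diameter the
node's shell is the sum of the per-element half-shells, which reduces to
(π/4)[(d+d_t)²−d²]·h_i for uniform diameter. Junction nodes carry no
tissue unit (V^cell = 0, no exchange). The shell volume, not a fixed
per-cell volume, is used; the tissue is a single well-mixed compartment
with no radial resolution and no interstitial space (assumed in rapid
equilibrium with plasma).

## Transport

The nodal mole balance on the refined graph is

    V dC/dt = L_Q C − L_D C,

with L_Q = MᵀQM° the flow-weighted advection Laplacian and
L_D = MᵀD_Q M the dispersion Laplacian, D_Q = diag(D·A/h). M° selects the
upwind node of each element (elements are reoriented along the local flow
before assembly, so the scheme is first-order upwind / tank-in-series).
The effective axial dispersion per element follows Aris–Taylor,

    D = D̃ + u²r²/(48·D̃),

which accounts for radial shear in laminar pipe flow and reduces to the
molecular diffusivity D̃ at u = 0. Defaults: glucose D̃ = 5.46e−4, lactate
7.71e−4 cm²/min. Both operators have zero column sums, so interior mass is
conserved exactly by construction.

Boundaries: inlet nodes are Dirichlet-forced, by state elimination rather
than penalty rows (keeps the Jacobian pattern clean); the inlet value may
be ramped by the cubic smoothstep s(x) = 3x²−2x³ over t_ramp (default
0.1 s; 0 disables it) to avoid forcing a discontinuity into the stiff
solver. Outlet nodes carry a pure advective sink −Q·C with no added
dispersive boundary flux (free outflow). With this bookkeeping the rate
of change of free-node moles equals boundary influx (advective plus the
dispersive flux through the inlet element) minus advective outflux as an
algebraic identity, which tests verify to machine precision along
trajectories.

Integration uses SciPy's BDF with the operator sparsity pattern supplied,
rtol = 1e−3 and atol = 1e−6 by default. Conservation-sensitive checks in
the test suite tighten these to 1e−8/1e−10; this measures integrator
accuracy, not a different model.

Known numerical limitation: first-order upwinding adds numerical
dispersion of order u·h/2 per element. At the default h ≈ 11.5 µm and
capillary velocities this is a few percent of the Aris–Taylor coefficient;
validation against the closed-form Ogata–Banks breakthrough curve is
therefore done in dispersion-dominated regimes (element Péclet < 2, 5%
tolerance on the midpoint breakthrough time), and exact-trajectory
validation uses an independently coded dense oracle of the same
discretization (agreement ≤ 1e−8 mM).

## Exchange and metabolism

Transmural exchange is carrier-mediated facilitated diffusion, saturable
in both compartments:

    j = V_m (C_bv − C_cell) / (K_m + C_bv + C_cell),

antisymmetric in its arguments and exactly zero at C_bv = C_cell. (The
equivalent form with the denominator 1 + C/K_m + C/K_m differs only by
scaling through K_m; the symmetric form above is implemented.) The amount
flux is V^cell·j — maximal rates are reported per unit cell volume — and
is divided by V^bv on the vessel side while the cell side evolves
intensively, dC^cell/dt = N·v. This bookkeeping makes cross-compartment
mole conservation exact, verified in closed systems at solver accuracy.

The demonstration metabolism is a minimal beta-cell glucose model with
three reactions over cell species A (glucose) and B (lactate):

| tag | reaction            | rate law                                  | V_m (M/min) | K_m (mM) |
|-----|---------------------|-------------------------------------------|-------------|----------|
| T1  | A^bv ⇌ A^cell       | V_m(A^bv−A^cell)/(K_m+A^bv+A^cell)        | 10          | 1.0      |
| E   | A^cell → 2 B^cell   | V_m·A/(A+K_m)                             | 0.01        | 4.5      |
| T2  | B^cell ⇌ B^bv       | V_m(B^cell−B^bv)/(K_m+B^cell+B^bv)        | 10          | 0.5      |

with stoichiometric matrix N = [[+1, −1, 0], [0, +2, −1]]. The V_m values
are working defaults chosen so transport and reaction fluxes are of
comparable magnitude; they are not calibrated to data and every constant
is config-overridable. Carbon bookkeeping (one glucose = two lactates)
makes Σ V·(C_A + C_B/2) a conserved quantity in closed systems, a
property test of the coupled integrator.

Fed-state defaults: inlet glucose 5 mM, inlet lactate 1.2 mM (basal),
cell species start at 0. Whether basal lactate also initializes the
vessel interior is scenario-dependent; inlet-only is the default with a
`uniform_lactate_init` option.

## Analysis metrics

- **Rise time**: time for a nodal series to go from 10% to 90% of its
  steady-state value, crossings located by linear interpolation; the
  steady state is the final sample, accepted only if the tail (last 5% of
  the span) varies by < 1e−4 relative. Undefined (missing, not an error)
  for unsettled or non-rising series. The closed-form check: an
  exponential approach with time constant τ has rise time τ·ln 9.
- **Transit time**: mean residence time, total luminal volume over total
  inlet inflow. It is invariant under mesh refinement and inversely
  proportional to the applied pressure drop in the Stokes regime — the
  20 Pa : 200 Pa ratio of 10.00 is asserted to ±0.01.
- **Péclet** u·l/D̃ per branch, **Schmidt** ν/D̃ per species (≈ 4.4e3 for
  glucose in blood plasma — momentum transport three orders of magnitude
  faster than mass transport, which is why junction accumulation is
  neglected for flow but not for transport), **Reynolds** ρ|u|d/µ per
  segment.
- **Net exchange totals**: trapezoid time-integral of Σ V^cell·v over the
  output grid for the import (T1) and export (T2) carriers.

## Synthetic geometries

No real skeleton ships with the package; a fixtures module generates the
study geometries: a single capillary (oracle geometry for analytic
checks), symmetric binary trees, a diamond loop sized from requested edge
conductances so the circuit has a closed-form hand solution (terminal
stubs of 100× the maximum requested conductance satisfy the degree-1
boundary rule; the returned expected solution accounts for them exactly),
and seed-reproducible random trees with diameters in [5, 20] µm and
lengths in [10, 200] µm — ranges typical of capillary beds — drawn
uniformly because published distributions give ranges rather than shapes.
Default driving conditions mirror islet-scale measurements: inlet
velocity 160 µm/s or 3.76 nl/min, inlet pressure 60 Pa, and a 52-segment
network size for the laminar-regime check.

These fixtures establish operator correctness, conservation, scaling laws
and qualitative coupled behavior. They do not reproduce the spatial
statistics, loop structure, or diameter–length correlations of any real
vascular bed, so quantitative predictions for a particular tissue require
importing its skeleton (CSV or GraphML) and, for the metabolism, rate
constants calibrated to measurements.

## Problem sizes and runtimes

The shipped tests and examples run on networks of 1–63 segments (up to a
few hundred refined elements) and horizons of 2–60 s of simulated time;
a full coupled run on the 20-element capillary takes well under a second,
and the entire suite a few seconds. The formulation is sparse throughout
and scales to thousands of segments; only the dense SVD solve in the flow
step would warrant replacement (by a sparse Cholesky) for very large
networks.
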