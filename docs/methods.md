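# Methods

## Geometry and labeling

The chamber is an 8 cm-diameter cylinder filled with 110 mL of medium
(fill height ≈ 21.9 mm). Exploiting the four-fold symmetry of the port
and scaffold layout, the default domain is one quadrant with symmetry
planes at x = 0 and y = 0. The domain is a labeled isotropic voxel grid
(default 2 mm spacing at chamber scale): each voxel is exactly one of
fluid, wall, scaffold solid, air interface, inlet, outlet, or symmetry,
and boundary labels always form a closed shell around the fluid so that
every boundary condition is a face between a fluid voxel and a labeled
voxel.

The set of fluid columns is chosen as the cells nearest the cylinder axis
whose count best matches the requested fill volume; this keeps the
voxelized volume within a fraction of a percent of 110/4 mL at 2 mm
resolution instead of relying on where cell centers happen to fall
relative to the ideal circle.

Ports are voxel patches on the base: the outlet at the center (where the
device's inner outlet channel sits) and the inlet near the periphery
(default 0.9 R at 45° azimuth). The base's internal channels are not
dimensioned in the device description, so both positions are arguments of
`build_chamber_domain`. At 2 mm resolution a 1.6 mm port maps to a single
voxel; the imposed plug velocity is scaled so the volumetric rate is
exact, which preserves every transport-relevant quantity at chamber scale
while underestimating the local jet speed (the real port speed,
Q/A = 0.663 m/s, is recovered on the fine-grid pipe fixture).

The air–liquid interface is a flat horizontal plane at the fill height,
held at equilibrium; free-surface dynamics are not modeled.

### Scaffolds

* **Sphere subtraction** (emulating fabricated bone-mimicking blocks):
  700 µm spheres with uniformly random centers are subtracted from a
  10×10×3 mm solid at ≤ 0.175 mm voxels. Porosity is monotone in the
  sphere count, so the generator records, per voxel, the first sphere
  covering it and then picks the count whose void fraction is closest to
  the target (52.5 % by default, tolerance ±0.5 pp); the same seed always
  reproduces the same block. This is an exact search along the nested
  family of sphere unions — equivalent to, but cheaper and more robust
  than, bisecting on the count.
* **Strut lattice** (the simplified geometry used in chamber runs):
  vertical walls along x and along y intersect in a periodic grid;
  porosity is (1 − aₓ)(1 − a_y) for per-direction solid fractions aₓ,
  a_y. Integer column counts are chosen to hit the target porosity within
  ±0.5 pp while keeping the two directions as symmetric as possible
  (a ≈ 1 − √porosity ≈ 0.29 at 50 %); the default pitch is 2.5 mm. The
  remainder columns are spread across struts deterministically.

For embedding in the chamber, fine blocks are resampled by solid
fraction (a coarse voxel is solid at ≥ 50 % fill). At 2 mm the 50 %
lattice collapses to a mostly solid obstacle with a few through
channels — the intended representation of a porous block whose pores the
chamber grid cannot resolve; its surface is then the envelope the areal
reaction acts on. Twelve scaffolds sit on one ring (0.6 R) at a 6 mm
stand height, three per quadrant; the stand itself is reduced to these
positions since only scaffold placement affects transport.

## Flow solver

Finite volumes on a staggered (MAC) grid: velocity components on faces,
pressure in cells. The steady state is obtained by solving the coupled
velocity–pressure saddle-point system with a sparse direct factorization;
advection is added by Picard (Oseen) iterations with first-order
upwinding, starting from the Stokes solution (typically < 10 sweeps to a
10⁻³ relative change at chamber scale). A pseudo-time march to steady
state was rejected: the viscous equilibration time of the chamber
(L²/ν ≈ hours) makes explicit marching impractical at any resolution,
while the direct solve is exact in the Stokes limit and reduces the
steady Navier–Stokes problem to a short fixed-point iteration.

Boundary conditions: no-slip on walls and scaffold solid (ghost-cell
reflection), free slip on symmetry planes and the interface, plug inflow
at inlet faces, uniform outflow at outlet faces with the outflow value
computed so discrete mass balance is exact. One pressure is pinned per
connected fluid component; a component whose prescribed fluxes do not
balance (inlet and outlet hydraulically disconnected) is rejected with an
error. Discrete continuity holds to direct-solver precision (max |∇·u|
≈ 10⁻¹¹ s⁻¹ on chamber runs).

Wall shear stress is sampled one-sidedly on solid-adjacent fluid faces,
τ = μ|u_t − u_wall|/(h/2). On voxelized curved surfaces the staircase
overcounts area by the Manhattan/Euclidean perimeter ratio (≈ 4/π on a
cylinder), so a corrected stress is also reported: each face is assigned
the obliquity |n̂·ê| of the true surface normal (estimated from a
Gaussian-smoothed solid indicator, σ = 1 voxel), the stress is divided by
it and the projected area used as the averaging weight. The area-weighted
corrected mean is force-consistent and reproduces the Poiseuille wall
stress within a few percent at 12 voxels per diameter.

The pipe oracle is solved in the creeping-flow limit. In fully developed
parallel flow the convective term vanishes identically, so the developed
Poiseuille profile is the exact solution there at any Reynolds number;
at the physical port Reynolds number (≈ 10³) the entrance region itself
would span ~10² diameters, which no fixture-sized pipe contains. The
shear-driven ("Couette") fixture is a closed cavity with a moving lid
rather than a periodic channel — the solver has no periodic boundaries —
and is checked against the exact zero-net-flux lubrication profile
u(z) = U(3z²/H² − 2z/H), with τ = 4μU/H at the moving and 2μU/H at the
fixed plate.

## Oxygen transport

Upwind advection on the staggered fluxes, central diffusion, and MM
uptake Picard-linearized as [V_max/(c_prev+K_m)]·c, assembled into one
sparse system per sweep. The interface Dirichlet value enters through a
half-cell flux 2D(C₀ − c)/h². Surface uptake is a flux on fluid faces
adjacent to scaffold solid with a face-count area estimate. The
recirculation condition c_in = ⟨c⟩_outlet (flux-weighted) is linear in c
and is imposed inside the matrix; iterating it as an outer fixed point
contracts by only ~1 − (consumed/recirculated) ≈ 0.99 per sweep and was
abandoned. Steady solves converge in < 15 Picard sweeps; the steady
oxygen budget (interface influx + inlet − outlet − consumption) closes to
~10⁻⁹ relative.

The transient mode (used by the well-mixed oracle) is backward-Euler in
time with the same spatial operators and an advective CFL guard that
reports the admissible Δt. Both discretizations are M-matrices, so the
discrete maximum principle holds: with consuming sinks and boundary
values ≤ C₀ the solution stays in [0, C₀], and increasing V_max can only
lower the steady field.

Degenerate case: a closed domain with no Dirichlet surface, no outflow
and no sink has a singular (pure-Neumann) steady operator; the conserved
uniform initial state is returned directly.

## Parameters

| Parameter | Default | Units | Meaning |
|---|---|---|---|
| ρ, μ | 1000, 10⁻³ | kg·m⁻³, Pa·s | medium density/viscosity (water-like) |
| D | 3×10⁻⁹ | m²·s⁻¹ | O₂ diffusivity in medium |
| C₀ | 0.214 | mol·m⁻³ | interface equilibrium concentration |
| K_O₂ | 932.4 | atm·L·mol⁻¹ | Henry constant |
| K_m | 5.6 | mmHg | MM half-saturation (→ 7.90×10⁻³ mol·m⁻³) |
| per-cell rate | 2 | nmol·min⁻¹/10⁶ cells | O₂ uptake of SAOS-2 cells |
| Q | 80 | mL·min⁻¹ | recirculation flow rate |
| chamber | 8 cm ⌀, 110 mL | — | vessel and fill volume |
| resolution | 2 (chamber), ≤ 0.175 (scaffold) | mm | voxel spacing |

C₀ is taken as given rather than recomputed from an assumed atmospheric
pO₂ (through K_O₂ it corresponds to ≈ 152 mmHg, consistent with a
humidified-incubator headspace rather than dry air). "2 nmol·min⁻¹ 10⁻⁶
cells" is read as per 10⁶ cells, the standard physiology convention. The
areal V_max uses the nominal 0.01 m² per scaffold; the voxel model's own
(resolution-dependent) surface area is what the flux then acts on and is
reported alongside in the reaction provenance. The bulk scenario applies
its volumetric sink uniformly over the fluid volume, matching the way
V_max is normalized by the vessel volume; `ReactionSpec.region` allows
restricting a sink to a sub-region (e.g. settled cells) if wanted.

## What the scenarios do and do not emulate

`paper_scenario` configures the three standard cases (bulk 11×10⁶ cells;
12 scaffolds at 4×10⁵ or 4×10⁶ cells each with surface uptake). These are
models of oxygen supply and demand, not of biology: cell numbers are
fixed (no proliferation), uptake parameters are literature constants, and
CO₂/pH/glucose are outside scope. The analytic fixtures (slab with
zeroth- and first-order sinks, Poiseuille pipe, shear cavity, well-mixed
MM depletion, closed box) exercise every discretized term against closed
forms or an independent ODE integration; passing them shows the solver
reproduces the model's mathematics, not that the model captures any
particular experiment.

A physical consequence worth stating explicitly: at 80 mL/min the loop
mixes the 110 mL vessel on a ~80 s timescale while consumption acts on a
~18 h timescale, so converged steady fields are close to spatially
uniform — a ~190 µM plateau for the bulk scenario — rather than strongly
stratified. Persistent large gradients require mixing-isolated regions
(closed recirculation cells, dead zones) that a 2 mm upwind grid cannot
maintain against numerical diffusion; finer grids and higher-order
advection would sharpen boundary layers near the interface and walls.

## Numerical choices at a glance

* Chamber grid 2 mm (≈ 3.4k fluid cells/quadrant): chamber runs complete
  in ~20 s each; scaffold blocks are generated at ≤ 0.175 mm.
* Flow: direct sparse solve; Picard tolerance 10⁻³ (relative velocity
  change), cap 10 sweeps; first-order upwind advection.
* Transport: steady Picard to ‖Δc‖∞ < 10⁻⁹ mol·m⁻³, cap 200; transient
  backward Euler with CFL ≤ 0.9.
* Porosity tolerance ±0.5 pp for both generators; sphere-count search is
  exact along the seeded sphere sequence.
* Ties/degeneracies: one pressure pinned per fluid component; strut
  remainder columns distributed deterministically; porosity ties resolved
  toward symmetric strut widths.

## Limitations

* First-order upwinding is diffusive; localized jets and scalar boundary
  layers are under-resolved at 2 mm, biasing chamber fields toward
  uniformity (see above).
* The staircase geometry perturbs near-wall quantities; the corrected WSS
  fixes the mean, not per-face extrema.
* The free surface is rigid and flat; port internals, tubing transit time
  and tubing gas exchange are not modeled (the loop closes
  instantaneously).
* Scaffold pores are unresolved at chamber resolution — internal pore
  transport is only represented on fine scaffold-scale grids.
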