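# Methods

`stentflow` is a desk-scale in-silico workflow for flow-diverter (FD)
treatment of intracranial aneurysms. It chains four models — synthetic
vessel geometry, braided-stent deployment, a measurement-driven porous FD
representation, and a lattice-Boltzmann (LBM) flow solver — and evaluates
treatments by the aneurysmal mean velocity reduction

AMVR = (STAV_pre − STAV_FD) / STAV_pre,

where STAV is the space- and time-averaged velocity magnitude in the sac.
This note documents the models, their assumptions, the numerical choices,
and what the synthetic setting can and cannot show.

## Synthetic geometry

Patient anatomies are replaced by a parametric sidewall idealization: a
straight (optionally curved) parent tube of diameter `D_p` carrying a
spherical sac of diameter `D_s` over a circular neck of diameter `D_n`.
The sphere centre is placed at height `sqrt((D_s/2)² − (D_n/2)²)` above
the plane tangent to the parent lumen, so that plane cuts the sphere in a
circle of exactly the neck diameter; it is stored as the analytic ostium
plane (normal pointing into the sac). Defaults (`D_p` = 4 mm, `D_s` = 8 mm,
`D_n` = 4 mm, parent length 20 mm) are representative supraclinoid-ICA
values for a wide-neck sidewall aneurysm, not reconstructions of any
patient. Openings are extruded by five local diameters before simulation
to push boundary effects away from the region of interest.

Voxelization is analytic (exact inside tests against the primitive list)
for parametric shapes and ray-parity based for imported watertight STL.
Voxels are isotropic, 0-based, with cell centres at `origin + (i+½)h`;
opening caps occupy the outermost voxel layer and carry boundary labels.
The fluid region is restricted to the 6-connected component containing
the inlet; a disconnected opening is an error, not a warning.

## Braided-stent deployment

The FD is an interconnected spring network on a diamond braid: `N/2`
crossings per ring, two helical wire families, each interior node with
four surface-spring neighbours. Two linear spring types act:

* **surface springs** along wire segments (stiffness `k_s`, N/mm), rest
  lengths equal to the as-built segment lengths, so the free equilibrium
  is exactly the nominal device;
* **radial springs** (stiffness `k_r`, N/mm) pulling each node toward the
  nominal radius, modelling the self-expansion of the heat-set braid.

Defaults: braid angle 75° from the device axis (typical for dense
clinical braids), wire diameter 30 µm, `k_s` = 0.05, `k_r` = 0.01 N/mm.
Stiffnesses can be calibrated against tensile force-elongation data: the
simulated tensile response scales linearly in an overall stiffness factor
at fixed `k_r/k_s`, so the fit is a bounded 1-D search over the ratio
with the scale solved in closed form. On noiseless model-generated data
the calibration is an exact inverse (within optimizer tolerance). The
force magnitude alone, however, is nearly scale-degenerate in the ratio
(the force *shape* barely depends on it), so noisy force-only data cannot
pin both stiffnesses; when the bench also records the braid's mid-length
necking diameter (an optional third sample column), the ratio is
identified by the scale-invariant deformed shape and the calibration
becomes robust to measurement noise.

Deployment mimics sheath withdrawal: the braid starts radially compressed
in a virtual 1-mm sheath, and rings are released distal-to-proximal, one
braid cell per band. Wire still inside the catheter is mechanically
decoupled from the deployed part (the catheter wall carries the load), and
the sheath mouth travels with the release front. Each released ring enters
at the axial station predicted by wire-inextensible braid kinematics
(`dz(r) = sqrt(ℓ0² − chord(r)²)`), which makes the release numerically
gentle without changing the equilibrium. Wall contact is a hard
projection onto the lumen. Relaxation is semi-implicit Euler with viscous
damping; the working phase uses near-critical damping scaled to the
softest whole-braid mode (≈ 1/n_rings per step), and a terminal
strictly-monotone energy-descent phase records the elastic-energy history
(velocities are zeroed whenever a step would raise the energy). The
equilibrium tolerance is a maximum nodal displacement of 1e-4 mm per step.
Push-pull compression, wire friction and plasticity are not modelled.

Metal coverage (MSA) follows from local braid geometry: one wire family
covers `c = N·d_w / (2πD·cosα)` of the lateral surface (α the local angle
from the axis), two crossing families cover `2c − c²`; the value is
area-weighted along the device and capped at 1. Oversizing opens the
braid (smaller α ⇒ larger cosα ⇒ smaller coverage), reproducing the
nominal > oversized coverage ordering.

## Porous flow-diverter model

The deployed braid is far below feasible flow-solver resolution, so its
flow effect is a homogeneous, isotropic thin porous layer obeying the
Darcy-Forchheimer law `Δp = l_c·v + q_c·v²`, with the linear (`l_c`,
kg/m²s) and quadratic (`q_c`, kg/m³) coefficients taken from bench
pressure-drop measurements of really deployed devices. The packaged
16-scenario table covers two devices (48-wire and 64-wire braids) in
nominal (device = vessel diameter) and oversized (device 1 mm larger)
deployment, with repeated insertions capturing deployment variability.

In the solver the areal law becomes a body-force density
`f = −l_c·k(x)·u − q_c·k(x)·|u|·u`, where `k(x)` is a triangular kernel
of the distance to the stent surface, `k(d) = (1 − |d|/t)/t` for
`|d| < t`, whose line integral across the layer is 1. Integrating the
force along any crossing path therefore recovers `Δp` exactly,
independent of how the curved surface cuts the voxel grid. A binary
(staircase) voxel layer was found to concentrate the transmural seepage
into spurious jets at locally thin spots, breaking the monotonicity of
AMVR in `l_c`; the diffuse kernel removes this artifact. Default kernel
half-width: 1.5 voxels (0.45 mm in fast mode). The drag velocity is the
local interstitial velocity; a flat uniform slab (`k = 1/t`) is used for
the plug-validation geometry, where superficial and interstitial
velocities coincide.

## Lattice-Boltzmann solver

D3Q19, BGK collision, halfway bounce-back walls (rigid), Guo forcing for
the porous drag with the velocity solved implicitly from the quadratic
drag balance (unconditionally stable in the drag strength). Blood is
Newtonian with ρ = 1055 kg/m³ and μ = 3.4 mPa·s. Planar validation cases
run as thin slabs with periodic transverse axes on the same kernel.

Boundary conditions: equilibrium velocity cells on the inlet cap
(parabolic profile, scaled by the inflow waveform), velocity-flux outlet
cells imposing Murray cube-law fractions (with a small feedback
correction after convergence so the realized split matches the target
within a fraction of a percent), and an equilibrium pressure outlet
(0 Pa reference) on the smallest-diameter outlet. Mean inlet velocity
follows a flow-area power law `Q = a·A^b` with `b` = 1.84 and `a` chosen
so a 4-mm inlet carries ≈ 0.25 m/s — a documented stand-in for the usual
area-based inflow scaling, configurable per run. The packaged inflow
waveform is a truncated 3-harmonic Fourier series with unit cycle mean,
systolic peak 1.8× mean and diastolic minimum 0.7× mean, ICA-like in
shape and fully swappable.

Unit conversion picks the time step so the peak lattice Mach number
(|u|/c_s) stays at 0.1 and caps the relaxation time at τ = 1.2; τ below
0.55 triggers a warning and below 0.505 an error. Pulsatile runs compute
whole cycles after a warm-up phase that repeats cycles until the
cycle-mean velocity magnitude changes by < 1% (at most 4 cycles), then
export 50 equally spaced instants for cycle averages. Steady runs
converge on a per-step relative velocity residual of 1e-6, measured every
250 steps. Instantaneous opening fluxes in pulsatile runs differ by the
weakly-compressible acoustic storage of the domain (a few percent at the
desk-scale Mach budget); mass conservation is therefore checked
instantaneously for steady runs and as a cycle mean for pulsatile runs.

## Neck metrics

Parametric geometries carry their exact ostium plane. For voxel grids
without one, the fallback locates the sac centre as the deepest point of
the lumen distance transform off the parent axis, takes the axis→centre
direction as the plane normal, and slides the plane to the minimal fluid
cross-section between parent wall and sac centre. On the sphere-on-tube
family this lands within one voxel and a few degrees of the analytic
plane. STAV averages the velocity *magnitude* over sac voxels and export
instants (the magnitude convention of the AMVR literature; averaging
components first would cancel recirculation).

## Study conditions and desk-scale similarity

The study crosses 16 measured scenarios with a set of geometries: one
pretreatment run per geometry plus one treated run per (geometry,
scenario) pair — 5 geometries give 80 treated + 5 pretreatment runs. Per
geometry one deployment per (wire count, sizing) combination is computed
and rasterized once; scenarios reuse the layer with their measured
coefficients. Treated runs warm-start from the previous flow state in
ascending-`l_c` order (the steady solution is unique at these Reynolds
numbers; this is purely a speedup).

**Fast mode** (the default study scale): voxel spacing 0.3 mm, steady
solver at the cycle-mean inflow, mean inlet velocity 0.018 m/s — the
largest value satisfying τ ≥ 0.55 and Mach ≤ 0.1 at this spacing with a
parabolic profile. Because the coarse-lattice velocity is far below the
physiological 0.25 m/s, a literal application of the measured `l_c`
would drive the layer deep into its sealed-neck limit (the relevant
dimensionless group is Λ = l_c/(ρ·v̄), and Γ = q_c/ρ for the quadratic
term). Fast mode therefore preserves the *physiological* similarity
numbers: the effective linear coefficient in the solver is
`l_c · v̄/v_ref` with `v_ref` = 0.25 m/s, while Γ is velocity-invariant
and needs no scaling. All reporting and fitting use the original
measured `l_c` values (a power law is form-invariant under this linear
rescaling: the exponent and R² are unaffected). **Full mode** keeps the
0.1-mm spacing and pulsatile inflow and applies no scaling; it is
implemented and tested at reduced scale but not exercised end-to-end in
the test suite for runtime reasons.

Typical fast-mode sizes: ≈ 38 000 active voxels, 4 000–12 000 lattice
steps per run, ≈ 2.5 minutes for the 17-run single-geometry study on one
CPU core.

## What the synthetic setting shows — and does not

Passing tests demonstrate: the solver reproduces analytic channel flows
and the areal resistance law; deployment reproduces braid kinematics
(nominal apposition, oversize foreshortening, coverage ordering);
calibration and coefficient fitting are faithful inverses; and on the
synthetic geometry the AMVR endpoint responds to the measured resistance
spectrum as a strong power law in `l_c`, with nominal deployments
reducing flow more than oversized ones and the 64-wire device winning in
nominal sizing. These are the study's qualitative and structural claims.

They do not certify patient-specific accuracy: the synthetic sac is
spherical and sidewall, the parent is straight, inflow is steady at
reduced Reynolds number in fast mode, the porous layer is homogeneous,
and per-patient AMVR magnitudes depend on anatomy that the idealization
deliberately omits. Group significance levels from a single geometry use
far smaller samples than the five-anatomy cohort statistics recomputed
from published cohort summaries.

## Known limitations

* BGK collision at τ near 0.55 on ~13 voxels per diameter is first-order
  accurate at walls; the Poiseuille oracle is run at 30 voxels per radius.
* Equilibrium boundary cells transmit flux with an O(3%) bias; flux
  outlets correct for it by feedback, the inlet bias is common to all
  runs of a geometry and cancels in AMVR.
* The spring network has a soft scissor (twist) mode; convergence relies
  on near-critical damping and the kinematic release placement.
* No fluid-structure interaction, non-Newtonian rheology, thrombosis
  biology, or push-pull deployment technique.
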