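# Methods

`vesihybrid` couples two descriptions of a cell volume discretized as a
tetrahedral mesh:

* **point molecules** (ions, cytosolic proteins, membrane proteins) are
  well-mixed counts per tetrahedron or surface triangle, evolved by an
  exact stochastic simulation algorithm (Gillespie direct method) in
  which diffusion is a set of first-order inter-voxel events;
* **vesicles** are hard spheres with continuous positions, exact
  per-tetrahedron overlap volumes, surface molecules with exact 3D
  positions, and well-mixed luminal contents; **membrane rafts** are
  exclusive fixed-radius disks anchored on surface triangles with
  well-mixed surface counts.

The two layers interact through reduced voxel volumes, through kinetic
processes that move material between them (surface reactions, binding,
exo- and endocytosis, raft lifecycle events), and through a shared
event loop: the SSA runs exactly between ticks of a fixed vesicle clock
(default Δt = 1 ms) on which vesicles and rafts move and all propensity
caches are refreshed.

## Vesicle motion

A free vesicle proposes one Brownian step per clock tick with
independent normal components of standard deviation √(2DΔt).  The step
is accepted only if the sphere at the new center is fully covered by
mesh tetrahedra (coverage fraction 1 within 1e-6 relative) and does not
intersect any other vesicle; otherwise the vesicle stays in place (no
resampling), a Metropolis-style rule that preserves detailed balance for
hard spheres.  Update order is shuffled every tick to avoid systematic
bias.  Docked/tethered vesicles (`dock_count > 0`) and vesicles bound to
a transport path do not take Brownian steps.

Finding the overlapped tetrahedra uses two regimes: if the step is
shorter than the vesicle diameter, the previous overlap set seeds a
breadth-first search (overlap is guaranteed in that set); otherwise a
best-first walking search first locates the destination tetrahedron,
exploring face neighbors closest-to-target first and giving up once all
tetrahedra within 3‖p_s − p_e‖ of the target are exhausted (at least 10
explored), which prevents jumps across gaps in the mesh.  The BFS then
expands layer by layer, stopping when a layer contributes no overlap or
the accumulated overlap reaches the sphere volume.

## Sphere–tetrahedron overlap

The overlap volume is computed exactly by the divergence theorem with
the sphere center as origin: each face contributes (d_f/3)·A_f, where
A_f is the closed-form area of the face triangle clipped by the disk in
which the sphere cuts the face plane, and the spherical boundary piece
contributes (r/3)·A_s, where A_s is the area of the sphere surface
inside the tetrahedron.  A_s is evaluated by Gauss–Bonnet over the
arrangement of the four small circles in which the face planes cut the
sphere: arcs contribute ∫k_g ds = cos α · Δφ, vertices contribute
turning angles, and the Euler characteristic is 2 − (number of boundary
loops).  When the sphere–tetrahedron intersection is disconnected this
characteristic is wrong by an even multiple, i.e. the area by a multiple
of 4π; since the true area lies in [0, 4π] it is recovered by reduction
modulo 4π.  Genuinely degenerate arrangements (tangent or coincident
circles, non-simple vertices) and any result outside the volume bounds
fall back to a deterministic sliced Simpson quadrature of the exact
disk–polygon cross-section (relative error ≤ 1e-4), which also serves as
an independent check in the test suite, next to a Monte-Carlo hit-count
oracle.

The kernel's inner loops are scalar Python by design: they act on single
3-vectors, where numpy's per-call overhead exceeds the arithmetic cost
by an order of magnitude.  Per-tetrahedron face planes are cached on the
mesh so repeated queries only shift offsets.

## Occupancy-corrected reaction–diffusion

Vesicle overlap reduces each voxel's free volume to V\*_k = V_k − (sum
of vesicle overlap volumes).  Inter-voxel diffusion rates become
d\*_{k,l} = D·A_{k,l}/(V\*_k·δx_{k,l}) (A the shared face area, δx the
barycenter distance); diffusion into a fully overlapped voxel is
forbidden, and as V\*_k → 0 the outbound rate is capped at its value for
V\*_k = 1e-3·V_k so event times stay finite (the limit is a modelling
fiction anyway: molecules evacuate before full overlap).  Second-order
reaction rate constants become c\* = K/(N_A·V\*_j); first-order rates
are unaffected.  The stationary distribution of a diffusing species is
then multinomial with p_k ∝ V\*_k, which the binomial-occupancy
validation measures directly.

Two equivalent execution paths exist for pure diffusion: the event-loop
engine (which tracks occupied (voxel, species) sites so its propensity
vectors stay O(molecule count) even on fine meshes), and a vectorized
propagator of the embedded jump chain of the same CTMC, with
exponential-dwell time weighting, used where large effective sample
sizes are needed (molecules do not interact under pure diffusion, so the
product chain factorizes).  The two are cross-checked against each other
in the test suite.

## Vesicle surface molecules

Surface molecules store body-frame positions (relative to the center),
so vesicle translation transports them rigidly; lateral diffusion is a
separate process.  One lateral step samples the polar displacement angle
from the spherical heat kernel at τ = DΔt/r²: the Legendre series
Σ (2l+1) e^{−l(l+1)τ} P_l(cos θ)·sin θ/2 is truncated when terms fall
below 1e-14 (l_max capped at 6000), integrated on a 2048-point grid and
inverted by interpolation; the azimuth is uniform.  Small-τ behaviour
reproduces the planar Rayleigh limit, large τ the uniform distribution
on the sphere.  Samplers are cached per τ.

For SSA coupling, each surface molecule is attributed to the overlapped
tetrahedron containing it; a vesicle-surface reaction with a cytosolic
partner then uses c\* of that tetrahedron, so surface reactions feel
local depletion and the reduced-volume correction exactly as volume
reactions do.

## Active transport

Paths are polylines with a speed v and stepsize s.  A free vesicle whose
surface comes within the capture radius (default: its own radius) binds
with probability 1 per tick (configurable).  A bound vesicle waits a
dwelltime sampled with mean s/v, then jumps s along the path, with
hard-sphere validity still enforced (a blocked jump is skipped and a new
dwelltime drawn); it is released at the path end.  Total distance over
total dwelltime therefore realizes v.  Dwelltime laws: single
exponential (default), a two-stage hypoexponential ("double_exp",
interpreting a double-exponential as two sequential rate-limiting
steps), or an explicit two-component mixture; law parameters set the
shape and are rescaled so the mean stays s/v.

## Links and binding

A binding rule turns a surface molecule on each of two vesicles into a
link species pair with length bounds [l_min, l_max]; the event is only
possible while the candidate end-to-end length is within bounds, and the
rate is a stochastic per-eligible-pair rate (s⁻¹).  Linked vesicles stay
mobile as long as every attached link stays within its bounds — both for
Brownian steps (the whole body moves, carrying its endpoints) and for
endpoint surface diffusion (an endpoint move violating a bound is
rejected).  Unbinding restores the two surface species at the endpoint
positions.

## Exo- and endocytosis, rafts

Exocytosis and endocytosis are SSA channels with species dependencies
and anti-dependencies: a process has zero propensity while a dependency
is unmet or an anti-dependency is present (threshold 1 by default).
Full-collapse fusion removes the vesicle, deposits each surface molecule
on the nearest overlapped patch triangle (or into a newly created raft),
and releases luminal contents into the declared outer compartment or —
when the extracellular space is not meshed — into a cumulative released
ledger.  Preserved fusion (kiss-and-run / open–closed) keeps the vesicle
and releases a binomial fraction of each luminal species.

Endocytosis reserves the spherical space just inside its zone (a set of
patch triangles); if another vesicle blocks it the attempt is rejected
without state change.  All species on the zone triangles move onto the
new vesicle's surface, positioned by radial projection.  The propensity
is the rate times the number of complete dependency sets on the zone, so
one dependency set is internalized per event.

Rafts occupy an exclusive set of surface triangles grown geodesically
from an anchor triangle to the raft radius.  Mobile rafts hop between
adjacent triangles at the 2D finite-volume rate D·L/(A·δx); hops that
would violate exclusivity are rejected.  Raft molecules have no exact
position; for positional SSA coupling they are sampled into overlap
triangles.  Raft surface reactions pool the owner-tetrahedron volumes of
the overlap triangles for their second-order c\* (an approximation noted
below).  Raft generation converts a triangle whose species counts meet a
signature into a new raft (consuming the signature into the raft),
dissolution disperses a raft's counts uniformly over its overlap
triangles, and raft endocytosis converts a raft into a vesicle carrying
its counts.

## Model-error diagnostics

Run before a simulation, with structured warning codes:

* **Step-length check.**  The fraction of Brownian steps longer than d
  is 1 − F(3d²/(6DΔt); 3) with F the χ² CDF; if more than 5% of steps
  exceed the vesicle's own diameter plus the smallest other diameter,
  crowding is underestimated (vesicles can tunnel through each other)
  and a Δt solving the 5% quantile is suggested.
* **Vesicle-timestep threshold.**  Δt_θ = r_tet²/(15D), the mean exit
  time of a uniformly started Brownian particle from the sphere with the
  mean tetrahedron volume (verified against a Monte-Carlo walker oracle
  with a Gobet boundary-shift correction).  Above it, vesicle-surface
  molecules dwell too long per voxel and bimolecular rates are
  underestimated.
* **Mesh-size check.**  Warn if more than 10% (strict) of tetrahedra
  have mean edge length below 20 nm — small voxels inflate bimolecular
  rate errors, and this also catches unit-scaling mistakes (the loaders
  take an explicit meters-per-unit factor for the same reason).
  "Size" of a tetrahedron is the mean of its 6 edge lengths throughout.
* **Static checks.**  Produce-only species; vesicles/rafts larger than
  the mesh; surface diffusion so fast that one tick randomizes the
  position (RMS angular step √(2DΔt)/r > π — our operationalization of
  "a random position on the surface"); reaction rates more than 3
  decades from the median of same-order rules (info only).

## Synthetic meshes

`make_sphere_mesh` places surface nodes on a Fibonacci lattice and
interior nodes on a seeded jittered grid, Delaunay-tetrahedralizes the
union (the ball is convex, so the triangulation fills it), drops sliver
artifacts, and rescales vertices so the meshed volume equals the
analytic ball volume (coarse meshes would otherwise undershoot by the
chord-sagitta deficit; the radius error at the Fig-2a-like resolution is
~2%).  Boxes use a jittered grid with exact faces.  Generated meshes
match target statistics (mean edge within 30%), not any particular
element count.  What these fixtures do not emulate: anisotropic or
graded resolution, curved biological boundaries, and the element-quality
profile of a professional mesher — validations on them say nothing about
mesh-generation robustness, only about the solver.

## Validation-suite conditions (and deliberate rescalings)

All suite defaults are desk-scale: a few hundred to a few thousand
tetrahedra and seconds-to-minutes runtimes, with replicate counts stated
per suite.  Reference values are analytic (integrated rate laws,
exponential decays, 6Dt/4Dt laws) or independent oracles (Monte-Carlo
hit counts, a finite-volume random walk on an icosphere for surface
diffusion, graph reachability for the walking search).  Comparisons are
at 3σ of the combined sampling error unless stated.

Two fixtures are deliberately rescaled from their source conditions, in
both cases because hard walls exclude sphere centers from a boundary
layer of one radius, capping the occupancy reachable in a small box:

* the crowding fixture reaches 0/20/40/60% occupancy in a 0.8 µm box
  with immobile crowders on a jittered FCC lattice (interior crowders
  are freed as tracers);
* the obstructed-diffusion fixture uses 12% mitochondria + 15% immobile
  + 8% mobile vesicles (instead of 28/25/17%); the caging signature — an
  apparent diffusion coefficient falling with lag time — survives the
  rescaling.

The bimolecular mesh-resolution study shrinks the domain to a 0.16 µm
sphere so that meshes spanning 28 → 13 nm edges stay desk-sized, keeps
the cytosolic reactant slow enough that voxel-scale depletion around
vesicle-surface molecules is the dominant error source, and runs on a
50 µs vesicle clock (a few times the fine mesh's Δt_θ): large vesicle
steps carry their own positive-bias artifact — freshly overlapped
voxels get an inflated c\* before the cytosolic reactant has evacuated
— which at the default 1 ms clock is large enough to confound the
mobility comparison.  The absolute error percentages are therefore not
comparable to the full-scale study; the qualitative structure (error
rising on sub-15 nm meshes, immobile vesicles worse than diffusing
ones) is.

The binomial-occupancy validation uses a coarse 0.5 µm sphere (~150
tets), 10% occupancy by immobile 40 nm vesicles and 10⁴ tracer
molecules, time-averaged over 6×10⁴ (test) / 1.5×10⁵ (acceptance
script) jump rounds; the max relative deviation metric is dominated by
the smallest-volume tetrahedra, which sets those round counts.

## Numerical choices

* Coverage completeness tolerance: 1e-6 relative on the summed overlap.
* Full-overlap threshold for forbidding diffusion into a voxel: V\* ≤
  1e-9·V; rate cap for outbound diffusion: V\* floored at 1e-3·V.
* Overlap kernel fallback quadrature: composite Simpson, 24 subintervals
  per smooth piece (pieces split at vertex z-planes), ≤ 1e-4 relative.
* RNG: a single `numpy.random.Generator` per run, seeded explicitly;
  every stochastic API takes the generator (or a seed) as an argument,
  and fixed seeds reproduce runs bit-exactly.
* Tie-breaks: surface molecules on the boundary between two overlapped
  tets are attributed to the first containing tet (tolerance 1e-7), or
  to the nearest overlapped tet if roundoff leaves none containing.

## Known limitations

* Serial only; no MPI partitioning, no membrane-potential solver.
* Hydrodynamic interactions between vesicles are not modeled (only
  steric exclusion), vesicles do not deform, and meshes do not adapt
  during endo-/exocytosis.
* Reaction order ≤ 2 everywhere.
* Raft second-order volume coupling pools the owner tetrahedra of the
  raft's overlap triangles rather than resolving per-triangle geometry;
  at raft scales well below the voxel size this is the same
  approximation the well-mixed validations test.
* Link species participate in surface diffusion and binding/unbinding
  but not in further chemistry (e.g. phosphorylation of a link complex
  would need it to be modeled as unbind-react-rebind).
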