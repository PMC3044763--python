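# Methods

`myoarch` simulates how a cardiac myocyte confined to a micropatterned
adhesive (ECM) island self-organizes its contractile cytoskeleton.  The
model is a coarse-grained reaction-kinetics description: instead of
individual molecules it tracks three density fields on a 2D lattice — free
integrin `rho_f`, bound integrin connected to premyofibrils `rho_p`, and
bound integrin connected to nascent myofibrils `rho_n` — together with an
all-pairs contractile fiber network that connects every focal adhesion
(FA) to every other one it can "see" inside the island.

## Model

**Domain.**  The island Omega is discretized on a regular square lattice
(points at cell centers, origin at the centroid).  The lattice spacing is
rescaled so the occupied area is exactly 1; with unit cell area the same
fitted constants apply to every shape.  Built-in islands: square,
equilateral triangle, circle, and a "stair" — a square with a staircase of
`stair_steps` steps (default 2) cut from one corner, whose surviving
corner-to-corner diagonal is the island's major axis.  The step
proportions are exposed as a parameter because only pictorial evidence
constrains them.  For concave islands a fiber may only connect two points
whose straight segment stays inside the island; this visibility set is
precomputed by sub-lattice segment sampling against the closed occupancy
(a segment that merely grazes a notch corner counts as contained).  Convex
islands are marked visible-everywhere analytically.

**Fiber network and forces.**  The tension carried between visible points
r and r' is the product of the Langmuir-attenuated fiber connections at
the two endpoints,

    w(r, r') = f_p(r) f_p(r') + G f_n(r) f_n(r'),
    f_c = rho_c / (rho_c + epsilon),

optionally multiplied by the separation |r - r'| (the fiber length-force
hypothesis, toggle `L`).  `G > 1` expresses that nascent myofibrils pull
harder than premyofibrils.  The net force on the bound integrins at r is
the delta-A-weighted vector sum of all pair tensions; pairwise
action-reaction makes the island-wide force balance exact to rounding.
The substrate traction is the reaction `T = -F`.  The force magnitude
|F(r)| (a rotation-invariant scalar) drives the kinetics.

**Kinetics.**  One forward-Euler step per dt:

    d rho_p/dt = (k_b + k_F |F|) rho_f  - k_u rho_p - k_m |F| rho_p + k_r rho_n
    d rho_n/dt =  k_m |F| rho_p - k_r rho_n

with basal binding `k_b`, force-promoted binding `k_F`, unbinding `k_u`,
force-promoted maturation `k_m` and nascent reversion `k_r`.  Mass
exchanged with the free pool is ledgered, and the step refuses to run if
`dt x (max outflow rate)` reaches 1, which guarantees positivity.

**Fast diffusion.**  Membrane diffusion of free integrin is much faster
than any binding process, so `rho_f` is replaced each step by its
quasi-steady profile.  Under the mutual-alignment biasing potential chi
this is the drift-diffusion equilibrium `rho_f ∝ exp(-sigma chi)`, scaled
to the conserved free pool (total integrin `phi0 * A` is conserved to
machine precision by construction); with alignment off or `sigma = 0` the
profile is uniform.

**Mutual alignment (biasing potential).**  Every nascent fiber carves an
attraction well along its segment:

    chi(r) = - sum_pairs f_n f_n dA^2 * integral_segment (zeta/pi) exp(-zeta d^2) dl,

so chi is deepest alongside thick nascent bundles and zero far away, with
support area inversely proportional to zeta.  It is evaluated by
rasterizing the nascent fiber mass onto the lattice (exact per-cell chord
lengths, see below) and convolving with the Gaussian kernel.  Free
integrin redistributed in this potential accumulates next to existing
bundles — the lateral-coupling ("torque") mechanism by which adjacent
myofibrils recruit each other.

**Rasterization.**  Fiber segments are clipped exactly against the grid
lines, so each crossed cell receives precisely its in-cell chord length.
Exact clipping conserves total fiber length, is independent of the number
of angular bins, and keeps every operator equivariant under lattice
symmetries — a symmetric initial condition on the square island stays
4-fold symmetric to rounding error, which the test suite asserts.

**Read-outs.**  The directional fiber-length field L(r, n) (per class, K =
36 bins on [0, pi)) yields: fiber density p(r) (share of cell-wide fiber
length, sums to 1); the local director and orientational order parameter
(OOP) from the first nontrivial Fourier mode of the direction distribution
on the rod period pi (OOP = 0 isotropic, 1 aligned; points with no fiber
length report OOP 0 and an undefined-director flag); and the parallel
coupling psi(r) = (nascent density normalized to its per-frame cell-wide
maximum) x (nascent OOP), averaged over the island as the bundling summary
psi_mean(t).  A global nascent OOP over the pooled direction distribution
serves as the axis-formation metric for the circular island.

## Parameters

Defaults (simulation time in arbitrary units, au):

| parameter | symbol | default | meaning |
|---|---|---|---|
| `phi0` | Phi0 | 1.0 | total average integrin density (conserved) |
| `binding_rate` | k_b | 0.5 | basal free->bound rate |
| `force_binding_rate` | k_F | 6.0 | extra binding rate per unit force |
| `unbinding_rate` | k_u | 2.0 | bound->free rate (unloaded FAs dissolve) |
| `maturation_rate` | k_m | 3.0 | pre->nascent rate per unit force |
| `reversion_rate` | k_r | 0.05 | nascent->pre rate (slowest process) |
| `nascent_force_ratio` | G | 3.0 | nascent/premyofibril force ratio |
| `epsilon` | eps | 0.3 | Langmuir half-saturation density |
| `sigma` | sigma | 15.0 | biased/plain diffusion ratio |
| `zeta` | zeta | 100.0 | inverse area of the alignment well |
| `dt` | dt | 0.1 | Euler step |
| `t_total` | — | 600 (circle 1800) | run length |

The original fitted constants for this model are not recoverable, so the
defaults were re-fitted with the same protocol the model was designed
around: choose rates obeying the biological time-scale ordering (FA
binding within ~1 au, premyofibril assembly a few au, nascent realignment
tens of au) and match the stair island's steady architecture — fibers
bundled along the major diagonal with FA accumulation at the diagonal's
corners.  `epsilon = 0.3` keeps the Langmuir fractions in their sensitive
range at typical bound densities; `k_F/k_u = 3` makes force-stabilized
adhesions win the competition for the conserved integrin pool;
`sigma = 15` gives an order-one redistribution contrast without collapsing
the free pool into the deepest wells.  The circle is given a 4x longer run
because, lacking boundary cues, it reorganizes far more slowly.

Default lattice resolutions give 300-400 interior points per island
(square 18, triangle 28, circle 21, stair 20 cells across).  With N ~ 350
an all-pairs step costs a few milliseconds, so a full stair run (6000
steps) takes ~30 s and the long circle run ~90 s on one CPU; these sizes
were chosen as the smallest at which the architecture read-outs are
resolution-stable (doubling the resolution moves directors by less than a
bin).

## Scenarios and detectors

Initial conditions: `uniform_random_free` (random free-integrin density,
no fibers — the canonical start), `clustered_free` (random blobs),
`seeded_bound` (a few soft premyofibril-bound seeds so fibers exist at the
first step), `custom`.  All are rescaled to the conserved total and are
reproducible for a fixed seed.

`detect_steady_state` reports the earliest time from which every forward
window (default 5% of the run) keeps the relative range of psi_mean below
1e-3; `director_stabilization_time` does the analogue on the high-density
nascent director map (max angular change below 5 degrees); and
`axis_formation_time` reports the first time the global nascent OOP
exceeds 0.5 and stays above it.

The in-silico hypothesis battery reruns the stair with the length-force
toggle `L` and alignment toggle `tau` on/off, plus the circle with and
without alignment, mirroring the organizing-mechanism comparison the model
was built to make.

## What the simulations do and do not reproduce

Reproduced robustly (asserted by the test suite): exact integrin
conservation and force balance; stair architecture unimodal along the
major diagonal with `L` on, and substantially de-concentrated with `L`
off; FA density and traction maxima at the corners of square and triangle
islands; initial-condition independence of the stair steady state; fast
director stabilization for boundary-cued shapes (about 10 au) versus
nearly two orders of magnitude slower on the circle;
a small positive steady-state psi_mean advantage of alignment-on over
alignment-off on the stair.

Not reproduced: spontaneous global symmetry breaking of the circular
island.  In this reconstruction the circle's isotropic and multipole
states are linearly stable — the chord-length force weighting damps
bipolar perturbations on a ring, the alignment potential is deepest at the
island center (every chord crosses it) so strong bias pools free integrin
centrally, and Langmuir saturation caps the achievable contrast.  Across a
wide parameter exploration the global nascent OOP never sustains 0.5 from
random initial conditions; seeded finite axes decay.  The acceptance
machinery reports the measured (non-)formation honestly rather than
special-casing it.  Consequently the circle-to-other-shapes
time-to-equilibrium ratio measured by the psi_mean detector comes out
near 1.5x, well short of the several-fold separation expected of a
purely alignment-driven equilibration.  The sarcomere-spacing estimator is
validated on synthetic profiles only; reproducing measured spacings would
require the original micrographs.

## Numerical choices

Forward Euler with a per-step positivity bound (error raised, never
silently clipped beyond floating-point dust); fixed per-step operator
ordering force -> kinetics -> potential -> redistribution -> analytics;
exact-clipping rasterization; Gaussian alignment kernel normalized to unit
integral so `sigma` alone sets the bias strength; psi density
normalization per frame (a global-over-run option is exposed by computing
psi from stored snapshots); directors reported in [0, pi); zero-fiber
points flagged rather than given spurious directors.  The sarcomere FFT
estimator detrends linearly (constant detrend switchable), applies a
Hamming window, searches spacings of 1-5 um and refines the peak by
quadratic interpolation; profiles whose detrended energy vanishes or whose
peak prominence is below 4x the in-band median are rejected as aperiodic.
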