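# Methods

## Model

A fibrin protofibril is a double-stranded polymer of fibrin monomers built
from 22.5 nm half-staggered fibrinogen units. `fibrinbd` represents each
protofibril as a chain of 22 beads ("nodes") with 22.5 nm rest spacing
(contour 472.5 nm), moving in a periodic box filled with implicit plasma.
Each node obeys the overdamped Langevin equation

    c dr_i/dt = -dW/dr_i + F_i^rand,

with Stokes friction `c = 6 pi mu a` (`mu = 1.2 mPa s`, fibrinogen radius
`a = 8 nm`) and white thermal noise of magnitude `sigma = sqrt(2 c kb T)` at
`T = 300 K`. Inertia, hydrodynamic coupling between beads and background
flow are absent by construction.

The potential energy is a sum of five harmonic terms:

| term | form | default constant | role |
|------|------|-----------------|------|
| stretch W^S | ½ k^S (\|r_ij\| − r0^S)², r0^S = 22.5 nm | k^S = 0.01 N/m | bond elasticity |
| bend W^B | ½ k^B (θ_ijk − π)² | k^B = 1e-18 J/rad² (swept 0.1–10e-18) | filament stiffness |
| torsion W^T | ½ k^T φ², signed dihedral of 4 consecutive nodes | k^T = 1e-23 J/rad² | twist resistance |
| aggregation W^A | ½ k^A (\|r_ij\| − 2a)² for inter-fibre pairs inside a_th = 45 nm | k^A = 2e-3 N/m (swept 0.2–20e-3) | αC-mediated lateral binding |
| repulsion W^R | ½ k^R (\|r_ij\| − 2a)² only inside 2a = 16 nm | k^R = 1e-3 N/m | linear excluded volume |

Angular forces are obtained by differentiating the arccos-form angles with
the chain rule; every gradient is certified against a central
finite-difference oracle (h = 1e-12 m, relative tolerance 1e-5) in the test
suite. At the bending minimum (collinear triple) the angular gradient is
singular but the force limit is zero, which the implementation reaches
smoothly through the cos-angle gradient; the same construction handles the
dihedral at φ = 0, and the measure-zero cusp at φ = π gets zero force.
Because φ0 = 0 and the energy is even in φ, the dihedral's sign convention
(`sgn{r_jk · (m × n)}`) never enters the force; it is kept for the reported
signed angles.

## Aggregation rule

The binding of protofibrils is distance-triggered: nodes of different
fibres interact when closer than one fibrinogen length (a_th = 2 r0^S =
45 nm). Two variants are implemented (`ModelParameters.aggregation_mode`):

- `"all"` — every inter-fibre pair inside a_th carries the harmonic
  attraction, recomputed statelessly each step.
- `"nearest"` (production default) — persistent bonds with bounded
  multiplicity. Each node offers `max_bonds_per_node` binding slots
  (default 2, one per αC arm of the fibrinogen-scale unit it represents).
  Free nodes bind their mutual nearest eligible foreign neighbour; a bond
  persists while its minimum-image distance stays below a_th and
  dissociates exactly when the pair leaves the a_th shell — the same
  distance criterion that defines dissociation in the survival statistic.

The default was chosen after the unbounded rule proved unphysical in
simulation: with ~20 attractions per node inside a bundle, the net
aggregation stiffness exceeds the bending stiffness k^B/r0^S² by an order
of magnitude and networks collapse into compact blobs (median tortuosity
~10, static bond stretch ~10 nm), destroying the near-straight fibre
conformations the model is meant to produce. Bounded persistent bonds keep
fibres straight (tortuosity ~1.05), produce zipped bundles joined by
multi-bond contacts that transmit tension, and make the survival ratio
n_agg/n_agg⁰ well defined. Repulsion always acts on all pairs inside 2a:
it is excluded volume, not binding. One further consequence worth knowing:
with two slots per node, ladder rungs and diagonal braces coexist in a
zipped pair, so the equilibrium inter-fibre spacing sits slightly below 2a.

## Time integration

The update is an operator split per time step Δt: (1) forward Euler for the
bend, torsion, aggregation and repulsion forces; (2) a Box–Muller thermal
displacement of per-axis standard deviation sqrt(2 kb T Δt / c); (3) the
stiff stretch term advanced by one classical RK4 step of dr/dt = f^S(r)/c
with the other contributions frozen (switchable to pure Euler for
ablation). Uniform deviates come from a seeded xorshift128+ generator
(initialized through splitmix64), giving bit-identical trajectories per
seed on a fixed platform.

Stability is governed by the stiffest Euler-integrated rate, dominated by
the discrete bending operator (λ ≤ 16 k^B / (r0^S² c)) and the pair
springs; RK4 extends the stretch-term bound to λΔt ≲ 2.8. Parameter
construction rejects λ_euler Δt > 1 and warns above 0.75. The default
Δt = 2 ns keeps λΔt ≤ 0.35 for all default constants; production runs at
the baseline constants use Δt = 4 ns (λΔt ≤ 0.7), and `stable_timestep`
shrinks the step for the stiffest swept k^B (10e-18 J/rad² needs
Δt ≈ 0.4 ns). The Euler treatment of noise inflates the variance of a mode
with rate λ by ≈ 1/(1 − λΔt/2); equilibrium-statistics checks therefore run
at Δt = 0.25 ns where the bias is ~2%, while the production step trades a
~15% inflation of the stiffest-mode fluctuations for a 16× longer reach in
simulated time.

Inter-fibre pairs come from a Verlet candidate list (cutoff a_th + 9 nm
skin) rebuilt whenever any node has moved more than half the skin, using a
periodic cell list that is tested to match exhaustive O(N²) enumeration
exactly. Coordinates are stored unwrapped so contour lengths and tortuosity
are exact; pair distances always use the minimum image, and imaging wraps
on demand.

## Protocols

**Aggregation phase.** Straight 22-node rods are placed with uniform random
centres and uniform-on-sphere orientations at 0.5 mg/ml (the fibre count is
calibrated so a 3 μm cube holds 1215 fibres, i.e. 1.11e-20 kg per fibre,
consistent with a ~6.7 MDa 21-segment protofibril; overlaps are allowed and
resolved by the repulsion). The system is integrated until the total energy
plateaus; the plateau detector compares consecutive windowed means of
W_total (window default 10 ms full-scale, 2 ms desk-scale) and fires below
1% relative change. At the configured steady-state time the per-fibre
reference contour lengths l0 and the reference bond set n_agg⁰ are frozen;
study runs freeze at the start of the tensile test.

At 0.5 mg/ml the initial rod gas is below static percolation: the network
only becomes a gel after fibres diffuse into contact and aggregate. The
steady state a tensile test presumes is that gel, and `percolation_axes`
detects it exactly (offset-consistent graph walk over chain plus
aggregation bonds; a cycle with inconsistent periodic-image offset along an
axis means the cluster connects to its own image, i.e. percolates). The
study protocol therefore equilibrates at least a minimum time and then
extends in 0.2 ms blocks until the network percolates along z, under a
hard cap.

**Virtual tensile test.** Affine z-scaling: every z coordinate and the box
length L_z are multiplied by ξ = 1 + c_s Δτ / L_z per increment
(c_s = 2.5 mm/s, Δτ = 2 μs of Brownian relaxation between increments), so
each increment adds the same length and the engineering-strain grid is
uniform. x and y are never scaled; the cross-section A = Lx·Ly stays
fixed. Engineering stress is σ_z = (1/A) dW/dL_z with W_total
moving-averaged over a strain window of 0.08 before central differencing;
the elastic modulus E and residual stress σ0 come from an ordinary
least-squares line over ε_z ∈ [0.05, 0.15]. Replica-mean energy curves are
averaged before differencing, since a single desk-scale replica's thermal
fluctuations exceed its elastic energy rise.

**Observables.** Segment orientation θ = arccos(|e_z·l̂|) ∈ [0, π/2]
(direction-agnostic folding); per-fibre ⟨θ_i⟩ is the segment-length-weighted
mean and band probabilities are normalized by the spherical band area
cosΘ₁ − cosΘ₂ (1 − cos(π/12) for the first π/12 band). Tortuosity is
contour length over end-to-end distance on unwrapped chains. The
stretched-fibre fraction counts fibres with ε = l/l0 − 1 ≥ 0.05; bond
survival is the fraction of *reference* bonds still inside a_th, so bonds
formed during extension cannot mask dissociation.

**Imaging.** Wrapped nodes are rasterized onto the x–y plane at 10 nm per
pixel; luminosity encodes the 0.3 μm z bin (10 levels in the 3 μm box,
higher = nearer the top), overlaps keep the maximum. A Sobel gradient pass
(3×3) extracts outlines and a Gaussian blur (default σ = 2 px) smooths
them; both filter parameters are free choices, as is the optional
segment-interpolation drawing mode (off by default: nodes only).

## Desk-scale study conditions

The full-scale experiment — 1215 fibres in a 3 μm box, 200 ms of
aggregation, 10 replicas per condition and a 3×3 (k^A, k^B) grid — costs
several orders of magnitude more than a single-CPU session. The bundled
study protocol (`fibrinbd.study`) therefore runs a volume-scaled system
that preserves the concentration and every intensive parameter:

- box 0.6 μm (10 fibres, 220 nodes) at 0.5 mg/ml, Δt = 4 ns;
- gel-adaptive aggregation: at least 6 ms, extended until the bond network
  percolates along z, capped at 18 ms; reference state frozen at the
  stretch start; plateau window 2 ms;
- stretch to ε_z = 0.5 at c_s = 2.5 mm/s, Δτ = 2 μs;
- 2 baseline replicas (k^A = 2e-3) and 2 weak-aggregation replicas
  (k^A = 0.2e-3) per ensemble; stretch observables average over the gelled
  replicas (a tensile test on a never-percolated cluster gas measures the
  voids between clusters, not clot mechanics — the full-scale protocol
  always stretches a gelled steady state); the bending sweep for the
  tortuosity ordering runs 1.2 ms per k^B at the stability-limited step.

The box edge was set as small as the physics allows rather than as large
as the budget allows, deliberately: at 0.5 mg/ml the initial rod gas is
below static percolation, and the bonded network only percolates after
fibres diffuse and aggregate. With the fibre contour (472.5 nm) comparable
to the box edge, gelation completes through the periodic boundary within
~10 ms; in larger desk-scale boxes (0.75–1 μm) it does not complete within
an affordable window and the unpercolated network transmits no tension at
all.

What the scaled system preserves: the thermal physics of single fibres
(diffusion, equipartition), bond mechanics and dissociation thresholds,
the energy-plateau kinetics, the orientation statistics at rest, and the
qualitative orderings in k^A and k^B. What it does not: with ~10 fibres
every fibre belongs to the single percolating cluster, whereas the
full-scale network keeps a large population of dangling or
weakly-anchored fibres; fraction-type observables under strain
(n_(ε≥0.05)/N, alignment fractions) are therefore systematically sharper
at desk scale, and stress curves are far noisier. Passing desk-scale tests
demonstrates the mechanisms, not the full-scale magnitudes.

## Numerical choices and degenerate inputs

- cos-angles clamped to [−1, 1]; collinear bending triples get zero force;
  degenerate dihedral normals (relative threshold 1e-6) skip the quadruple.
- Minimum image maps displacements into [−L/2, L/2) with explicit boundary
  folding so the map is idempotent.
- Cell counts are capped near N so enormous dilute boxes do not allocate
  empty grids; cells never shrink below the cutoff.
- Pair search rejects cutoffs beyond half the smallest box edge; bonded
  neighbours on the same fibre are excluded from all inter-fibre terms.
- Zero bond length or zero pair separation raises instead of producing an
  undefined force direction; non-finite energies abort integration with a
  state dump.
- The acceptance script derives all replica seeds from `--seed` and keeps
  them below 2^31.

## Known limitations

- The torsion constant (1e-23 J/rad²) is ~400× below kb T per joint: the
  term is retained for completeness but is thermally irrelevant.
- Nearest-partner bond formation is greedy mutual matching per step;
  ordering effects are possible in dense transients but vanish within a few
  steps as remaining free slots bind.
- Euler noise at the production step inflates stiff-mode variances by up to
  ~15% (quantified above); energies sampled during production runs carry
  that bias.
- Desk-scale fraction observables overshoot full-scale values once the
  network percolates (see above); the survival and ordering observables are
  robust to this.
- No hydrodynamic interactions, background flow, cells or plasma proteins;
  branching of fibres and network topology metrics are out of scope.
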