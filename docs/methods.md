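# Methods

## Model overview

`synapse_abm` simulates the first ten minutes of immunological synapse (IS)
formation at a T cell–bilayer contact as a kinetic Monte Carlo process on
paired 2D lattices. Two square lattices share one coordinate system: the
T-cell membrane carries TCR and LFA-1, the apposed bilayer (or APC membrane)
carries pMHC and ICAM-1. A circular active domain of radius R (the nascent
contact) is inscribed in the square; nodes outside the disk are permanently
blocked, and moves that would leave the disk are rejected (reflecting
boundary). Each node of a molecular lattice holds at most one agent
(excluded volume at the scale of a single protein footprint).

Per timestep τ the update order is fixed and documented as part of the
contract: **movement → unbinding → binding → foci update**. A molecule
freed by unbinding may therefore rebind within the same step. Units are
updated sequentially in a fresh random permutation each step.

### Diffusion

A mobile unit (free molecule, or bound pair moving as one unit on both
lattices) attempts a move with probability `p_move = 4·D·τ/a²` to a
uniformly chosen 4-neighbor (von Neumann); the move is rejected if any
target node is occupied or outside the domain. On an empty lattice this
reproduces the 2D law MSD(t) = 4·D·t exactly, which the test suite verifies
against the closed form. The stability bound `4·D·τ/a² ≤ 1` is enforced at
configuration time.

### Binding and unbinding

Binding occurs only between a free receptor and a free ligand occupying the
identical node index on the two lattices. The molar on-rate is converted to
a per-step probability through the characteristic association time

    τ_on = V·N_A / kon,      p_on = B_eff · τ / τ_on,

where V = a²·h is the per-node inter-membrane reaction volume (h the
membrane gap height) and B_eff collects the global binding scale and the
foci feedback coefficient at that node. p_on is clamped to 1 with a logged
warning (a clamp means τ is too coarse for the chosen kon/V). Unbinding
uses the exact exponential form `p_off = 1 − exp(−koff·τ)`, which reduces
to koff·τ for small τ and is correct for any τ. Dissociated partners remain
colocalized at their node until diffusion separates them — rebinding is an
emergent, not a modeled, process. koff is strictly constant: no catch/slip
bonds, no force dependence.

### Forces

Both deterministic biases act by reweighting the candidate moves
(stay + four neighbors) of bound complexes; they never displace an agent
directly, so exclusion and the Monte Carlo structure are preserved. For a
bias unit vector **f̂** and strength s ∈ [0, 1], the weight of direction
**ê** is multiplied by `max(0, 1 + s·(ê·f̂))`; factors from several forces
multiply, and the final distribution is the renormalized product with the
unbiased random-walk weights.

* **Size-based segregation (SBS).** Complexes of different size classes
  (short TCR–pMHC vs long LFA-1–ICAM-1) repel within radius `R_force`. The
  repulsion direction is the sum of unit vectors pointing away from every
  opposite-class complex within range (constant kernel by default; a 1/r
  kernel is config-selectable). The field is accumulated on the lattice by
  scattering each complex's kernel and is refreshed every
  `sbs_update_interval` steps (default 10, i.e. every 0.1 s) — complexes
  move at most a fraction of a node in that window, so the staleness is
  negligible; the interval is a pure performance knob.
* **Centripetal transport.** Complexes couple to the contracting F-actin
  arcs and drift toward the domain center. `coupling_enabled = False`
  reproduces the actin-arrest experiment: the centripetal factor is dropped
  entirely. The short TCR–pMHC complex couples more strongly than the long
  adhesion complex (`centripetal_strength` vs `centripetal_strength_long`),
  which is what lets TCR–pMHC claim the center of the bullseye while
  LFA-1–ICAM-1 forms the surrounding ring; with a single shared strength
  the competition for the center would be decided only by noise.

Forces act on bound complexes only; free molecules diffuse without bias.

### F-actin foci

A third lattice carries a per-node automaton with states
empty → nucleation → nucleation-polymerized → polymerization:

* empty → nucleation with `p_nucleate` where a TCR–pMHC complex sits;
* nucleation → nucleation-polymerized with `p_nuc_polymerize` when an
  LFA-1–ICAM-1 complex occupies the same node;
* nucleation or nucleation-polymerized → polymerization with
  `p_polymerize` when an LFA-1–ICAM-1 complex lies within
  `R_neighborhood`;
* every non-empty state self-inhibits (reverts to empty) with `p_decay`.

Transitions read a snapshot of the automaton taken at the start of the foci
phase, so the update is synchronous; at most one transition fires per node
per step, with self-inhibition tried first and the colocalization branch
taking precedence over the neighborhood branch for nucleation nodes.
4-connected clusters of polymerization nodes are the model's F-actin foci.

Formed foci (polymerization nodes; optionally all non-empty states) multiply
the TCR–pMHC `p_on` at their node by the binding coefficient **B** — the
feedback is applied to the TCR–pMHC rule only, before clamping. B > 1 is
positive, B < 1 negative feedback; B = 1 is the control. The automaton
draws from its own RNG substream, so a B = 1 run is bit-identical in every
molecular observable to a foci-disabled run under the same seed — this is
an exact design property, used as a regression check, not an approximation.
A focus persists after its seeding complex leaves until self-inhibition
removes it.

### Readout

The in situ dissociation constant is

    cellKD = [TCR_free]·[pMHC_free] / [TCR–pMHC]   (molecules/µm²),

computed over the whole active disk. cellKD is undefined (NaN, missing
data) when no complex exists. Because a single snapshot of a desk-scale
contact carries substantial shot noise, the per-replicate cellKD reported
by the experiment driver is the mean of instantaneous cellKD sampled every
2 s over the trailing 20 s window ending at the measurement time; replicate
aggregation is then mean ± SD across replicates (never a pooled-count
ratio). pMHC densities ≤ 1/µm² are reported but flagged high-variance
(ligand too scarce for receptors to find) and excluded from
minimum-finding.

An interior minimum of a mean-cellKD curve is declared when the argmin over
usable grid points is not an endpoint and both the first and last usable
points exceed the minimum by more than one pooled SD (root mean square of
the per-point replicate SDs). The one-SD depth threshold is a package
decision — it guards against declaring minima inside replicate noise.

## Default parameters

| parameter | default | units | rationale |
|---|---|---|---|
| node spacing a | 0.08 | µm | one protein-complex footprint per node; puts the bilayer near steric saturation at the top of the 0.07–100 /µm² pMHC titration range (pMHC 100 + ICAM-1 50 ⇒ ~96% occupancy), where transport jams |
| timestep τ | 0.01 | s | resolves the fastest per-step probabilities (p_move ≤ 0.9, p_on ≈ 0.04) |
| membrane gap h | 0.015 | µm | inter-membrane distance scale; enters only through V = a²·h |
| synapse radius | 3.5 | µm | library/CLI default contact size |
| D (TCR, LFA-1) | 0.05 | µm²/s | membrane-protein mobility on a cell surface |
| D (pMHC, ICAM-1) | 0.1 | µm²/s | bilayer lipids/proteins diffuse faster than cell-surface proteins |
| D (bound complex) | 0.005 | µm²/s | a two-membrane-spanning complex under cytoskeletal drag is far less mobile than either partner; this slow mobility is also what makes central accumulation take minutes rather than seconds |
| TCR–pMHC kon | 2.4·10⁵ | M⁻¹s⁻¹ | weak-agonist range; gives p_on ≈ 0.04 per colocalized step |
| TCR–pMHC koff | 0.4 | s⁻¹ | dwell time 2.5 s, in the single-molecule range for agonist pMHC |
| LFA-1–ICAM-1 kon / koff | 2·10⁵ / 0.03 | M⁻¹s⁻¹, s⁻¹ | long-lived adhesion bond; ~85% of adhesion molecules bound at 50/µm² |
| densities TCR / LFA-1 / ICAM-1 | 18 / 50 / 50 | µm⁻² | TCR 18/µm² is the reference density of the titration experiments; adhesion held fixed across sweeps |
| R_force | 0.5 | µm | SBS interaction range |
| sbs_strength | 0.15 | – | enough to segregate the two complex classes without freezing them |
| centripetal_strength (short/long) | 0.5 / 0.1 | – | with the slow complex D this yields a bound-state drift ≈ 0.06 µm/s, matching measured F-actin arc flow; a complex needs several bind–drift cycles to reach the center, so the central cluster matures over minutes |
| foci p_nucleate / p_nuc_polymerize / p_polymerize / p_decay | 0.02 / 0.1 / 0.2 / 0.05 | per step | sparse, short-lived foci: discrete puncta at a subset of complex sites, persisting only while refreshed by a resident complex |
| R_neighborhood | 0.24 | µm | three lattice nodes; keeps polymerization tied to the local adhesion neighborhood |
| B | 1.0 | – | control (no feedback) |

The paper-scale mechanism this parameterization realizes: at low pMHC the
observed cellKD sits at or above the intrinsic lattice KD
(= p_off/(a²·p_on) ≈ 15/µm²) because complexes are few and snapshot
statistics are poor; at intermediate pMHC, centripetal transport collects
complexes into a dense central cluster where a dissociated pair is caged by
its packed neighborhood and rebinds before it can escape, lowering the
observed cellKD (positive cooperativity); at the top of the titration range
the bilayer lattice is sterically saturated, complexes cannot be
transported, no trap forms, and cellKD returns toward the well-mixed value
(negative cooperativity). Arresting the coupling removes the trap at every
density, leaving a flat or slowly decreasing curve. All of this is
emergent — kon and koff are never changed during a run.

## RNG and determinism

Each simulation state owns two xorshift64\* streams seeded by splitmix64
from the user seed: one for molecular kinetics, one for the foci automaton.
Identical (config, seed) pairs give bit-identical trajectories, regardless
of process history; the step-wise API and the fused multi-step driver
execute the same compiled phase functions and consume the same draws, so
they produce identical trajectories too. Replicate seeds in experiment
plans are derived as `(base_seed + crc32(tcr|pmhc|replicate)) mod 2³¹` —
deliberately independent of the coupling flag and of B, so intervention
arms run with paired seeds.

## What the simulations emulate — and what they do not

The generator places molecules uniformly at random at t = 0; it does not
model pre-formed TCR nanoclusters, molecule shape or orientation,
sub-node positions, 3D T cell–APC topology, costimulatory molecules, or any
explicit downstream signaling (PLCγ1, calcium, NFAT). Passing tests
therefore demonstrate that the *mechanisms as modeled* produce the
qualitative phenotypes; they do not calibrate absolute cellKD values to any
particular experimental system, and the pMHC density at which cooperativity
changes sign in silico need not match cell-based measurements.

## Problem sizes used by the test and acceptance runs

Desk-scale study conditions were chosen once so that every phenotype is
measured on the smallest contact that still exhibits it:

* reference pMHC titration (coupling on; also provides the time-resolved
  readouts and the B = 1 control): radius 2.25 µm, 8 log-spaced pMHC
  densities in 1–100/µm², N = 10 replicates, 10-min runs, readouts at
  1/2/5/10 min;
* actin-arrest arm: radius 1.5 µm, same grid, N = 10;
* TCR titration (4.5, 18, 55.5/µm²): radius 1.5 µm, 5-point pMHC grid,
  N = 6;
* B sweep (0.1, 0.5, 1, 2, 10, paired seeds): radius 1.5 µm, 4-point pMHC
  grid in 3–100/µm², N = 8;
* kinetic-law checks: ≥ 1000 walkers / ≥ 1200 complexes; the well-mixed
  equivalence uses a 1.2-µm disk with fast diffusion and slow binding, with
  an exact Gillespie simulation (matched per-pair rates) as the
  independent oracle.

`scripts/acceptance.py` re-runs the same designs at a further reduced scale
(titrations on a 1.5-µm disk with a 6-point grid and N = 6; the B sweep on
its paired 4-point design with N = 8; patterning at the 2.25-µm reference
scale over 3 replicates) and writes every headline quantity it computes to
JSON.

## Numerical choices and degenerate inputs

* All-zero combined move weights (possible only when both force factors
  vanish in every direction) fall back to "stay" with a logged warning.
* A unit exactly at the domain center receives uniform centripetal weights.
* cellKD with zero bound complexes propagates as NaN and is dropped from
  replicate means; a grid point with no defined replicate value is flagged,
  not summarized.
* `detect_interior_minimum` requires ≥ 4 usable points and returns an
  insufficient-data marker (present = None) otherwise.
* Densities are converted to agent counts as round(density · π·R²); the
  build refuses configurations whose counts exceed the active node count of
  either lattice.

## Known limitations

* The bound-complex diffusion coefficient and the two centripetal strengths
  are free parameters of the coupled actin model; only their ratio scale is
  constrained by arc-flow speed, and other combinations reproducing the
  same drift would behave similarly.
* At desk scale (R ≤ 2.25 µm) the central cluster contains only tens to
  hundreds of complexes, so low-pMHC grid points remain noisy even with
  windowed sampling; the high-variance flagging below 1 pMHC/µm² is a hard
  cutoff, not an adaptive criterion.
* The foci automaton is a phenomenological caricature tuned for sparseness
  and refresh-dependence; its transition probabilities are not derived from
  actin biochemistry.
* Complexes of the same class do not repel each other; SBS acts only
  between classes, and whether SBS should also act between complexes and
  free molecules is left config-extensible (off by default).
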