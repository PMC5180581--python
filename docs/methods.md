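# Methods

`grnswarm` simulates a swarm of digital organisms ("robots") on a toroidal
90×90 grid, competing for regrowing, typed food under seasonal forcing.
Selection is purely energetic — there is no explicit fitness function. Each
robot is steered either by an agent-based gene regulatory network (GRN) read
from an evolvable artificial genome, or by a reference feed-forward neural
network (ANN) with per-edge reinforcement learning. The headline experiment
compares the two controller architectures on how far the swarm can run the
food supply down before the population collapses.

## The artificial genome

A genome is 10 chromosomes of 10,000 characters over the digit alphabet
`0123`. Genes are located by the fixed promoter motif `0101`; each gene is
promoter | 2-character type field | 5-character binding site | 9-character
payload. The type field selects signalling, regulatory or structural
(residue mod 3). The payload carries the gene product's 5-character
signature, two wiring characters (actuator index for structural genes;
activator/repressor flag for regulatory genes — wiring value ≡ 0 (mod 4)
marks a repressor, i.e. one quarter of regulators), and two characters
encoding a structural output value: a sign and a magnitude on [0.5, 1], so
products push actuators decisively rather than hovering near neutral.

Binding is complementary (`c → 3−c`, so 0↔3, 1↔2) with a mismatch tolerance
of 2 over the 5-character site; match quality is graded,
`(5 − mismatches)/5`. This width was chosen deliberately: with a shorter
site and tolerance 1 every site collects ~6–13 binders, the
concentration-weighted actuator means collapse toward zero and no gate ever
fires, while exact matching leaves most genomes without any functioning
pathway. Five characters at tolerance 2 give sparse, decisive pathways; in a
single-robot survival assay the fraction of random genomes that can forage
rises from ≈0 % to ≈8 %.

Replication applies point mutations (probability 5·10⁻⁵ per character; a hit
always changes the character) and segment duplications (probability 0.02 per
chromosome; geometric length, mean 50; uniform source and insertion point).
Deletions are off by default. Genomes round-trip bit-exactly through a plain
text format (header plus one chromosome per line).

## The agent-based controller

Only the environment-activated slice of the genome is instantiated at run
time, as *agents* (gene products) carrying a concentration ("dosage"):

1. **Sensing.** Nine bounded channels: neighbouring robots, food in the
   robot's own cell, food elsewhere in the Moore neighbourhood, energy
   level, four recent-action counters (attacks, defences, replications,
   feedings; exponentially decayed), and an internal ultradian rhythm — a
   triangle wave over the robot's age (period 24 steps). The rhythm channel
   lets genomes express time-alternating behaviour such as move/feed cycles;
   it reads 0 at age zero so a fresh robot with empty surroundings has an
   all-zero sensor vector. Each channel owns a fixed signature (an injective
   affine code over the alphabet).
2. **Signalling expression.** An active channel expresses every signalling
   gene whose binding site complements its signature within tolerance, at
   level channel value × match quality, floored at `c_init = 0.8`.
3. **Transduction.** Live signalling and activating-regulatory agents
   express the regulatory genes they bind; activating regulators also
   express structural genes. The expression level saturates with the summed
   binder drive, `S/(1+S)` with `S = Σ concentration × quality` — dosage
   tracks regulatory occupancy rather than integrating it, keeping
   concentrations on [0, 1] and sensitive to the sensor context (additive
   accumulation pins every agent at the cap and produces a behaviourally
   inert controller). Expression *refreshes* a live agent: concentration
   rises to the drive level, never above `c_max`. A gene bound by any live
   repressor is blocked that step regardless of co-binding activators.
   Transduction runs 3 rounds per behavioural step so a fresh signal can
   traverse signalling → regulatory → structural within one step (with a
   one-round cascade a robot walks past food before the eat response forms).
4. **Actuation.** Each of the seven actuators (heading, move, eat, attack,
   defend, replicate, aggregate) outputs the concentration-weighted mean of
   the structural agents targeting it; no contributor means neutral 0.
5. **Dosage update.** `c ← c·(1−d)·(1+β·sign(Δe)·min(|Δe|/F, 1))` with decay
   d = 0.2, feedback gain β = 0.1, scale F = 1 energy unit, and Δe the
   robot's net energy change last step. Agents below `c_min = 0.1` are
   deleted the same step. The short memory (≈10 steps) keeps behavioural
   phases crisp against the rhythm; with slow decay the phases smear into
   50–100-step blocks that de-correlate from foraging opportunity.

The controller never modifies the genome; deactivated genes remain encoded
and re-express when their context returns. The compiled network is cached
per genome and pruned to the channel-reachable subnetwork (semantically
invisible: unreachable genes can never be expressed). A numba kernel
implements the per-step update; the numpy reference path is kept and tests
assert both paths agree.

## Action selection

Gates fire when their output exceeds a threshold (default 0.25). Only mutually exclusive pairs are resolved by the
fixed priority eat > attack > defend > replicate > aggregate > move: eating
and attacking exclude each other, movement excludes every in-place action,
but replication is compatible with eating, defending and moving, and
defending is compatible with eating. Two gates carry negative default
thresholds (−0.5): *move* — robots with any live movement drive keep moving
(basal motility; a lineage stops moving, e.g. to save energy in winter, by
evolving suppression), and *replicate* — reproduction is near-automatic once
the energy precondition holds. An exactly neutral channel (no structural
contributor) never fires, so an empty controller idles.

Movement resolves the heading output in a food-anchored frame: octant offset
0 points at the richest cell of the Moore ring (gradient climb), the climb
stops when the robot's own cell is the local food maximum and the heading
output is neutral, and with no food in sight the frame falls back to a
per-robot idiosyncratic straight-line heading. This is a sensorimotor
encoding choice, not a behaviour: whether, when and with what rotation a
robot moves remains under genomic control.

## World, energy economy and seasons

Defaults (all configurable):

| parameter | value | notes |
|---|---|---|
| grid | 90×90, torus | |
| food types (threshold / energy / initial) | 0/100/1200, 30/200/500, 60/400/300 | threshold = min. energy to access |
| food regrowth | r₀ = 0.003, K = 5 | per source, `r₀·max(0, 1−k/K)` |
| seed-bank influx | 1.6 sources/step (Poisson) | uniform scatter, initial type mix |
| basic / move cost | 0.25 / 0.5 per step | |
| attack / defend cost | 10 / 3 | defence bonus 25, prey transfer φ = 0.5 |
| replication | threshold 600, cost 50, endowment 150 | offspring in parent's cell |
| initial population | 600 robots at energy 650 | founders replicate once immediately |
| extinction threshold | population < 100 | |
| seasons | 100-step blocks, 28-season climate cycle | see below |

The season table spans a seven-"year" climate cycle: two mild establishment
years, four moderate years, and an escalating final year whose catastrophic
winter (survival +4.0, movement +8.0 per step) falls at steps 2700–2799.
Food is abundant at the start; populations boom, overshoot and graze the
stock down, then persist as scavengers on the seed-bank influx until
scarcity and a deep winter intersect. Runs therefore end with the
food-at-extinction count measuring how thoroughly the terminal population
could find scarce, scattered food — the quantity the headline comparison is
about. A run is a pure function of `(config, seed)`: one `SeedSequence`
splits into independent child streams for initialization, action order,
world growth, and reproduction.

Energy is conserved exactly: robot energy + food energy + cumulative
dissipated costs − cumulative injected food energy is invariant (audited
step-by-step in tests; this audit caught a real bug where a robot recruited
into two aggregates had its energy counted twice).

## The ANN reference controller

Same sensors, actuators, action mapping, energy schedule and world; only the
controller differs. Topology 9 → 12 (tanh) → 7 with no biases; weights are
the heritable genome (uniform [−1, 1] at founding, Gaussian σ = 0.05 at
replication). Within a lifetime, per-edge reward-modulated eligibility
traces (η = 0.01, trace decay 0.9) nudge weights, and structural rewiring is
restricted to *zeroing*: an edge whose signal contribution stays below 10⁻³
for 60 consecutive steps is set to zero for the rest of the robot's life
(replication re-randomizes zeroed edges). During long famines the
food-channel columns inevitably go idle and are pruned, so ANN robots
progressively lose food reactivity precisely when food becomes rare — the
mechanism behind their higher food-at-extinction counts.

## Calibration

The exact parameter tables of the original study design are not public, so
every numeric default above is a declared choice, and the printed group
means of the headline comparison (≈78 food sources left for GRN swarms,
≈120 for ANN swarms) were used as calibration anchors for the declared
defaults — primarily the food table, seed-bank influx, energy schedule,
season cycle, binding-site width and concentration dynamics. Calibration
was done on the population/food trajectories and a solo-robot survival
assay; the anchors' *direction* (GRN swarms strip food further before
collapse) emerges from the architecture difference, not from any parameter
that references the controllers asymmetrically.

## What the simulations do and do not show

The generator *is* the study: all data are self-generated. Passing tests
show that the implemented mechanisms (genome → expressed network →
behaviour → energy-mediated selection) reproduce the qualitative phenomena
— emergent preying that intensifies with food scarcity, survival to lower
food levels under the GRN architecture, recovery after scheduled food
restoration — at desk scale (10 replicates per arm, ~2,700-step horizons)
under this package's declared ecology. They do not show anything about real
robot hardware, other ecologies, or the exact numeric behaviour of the
original system whose parameter tables are unavailable.

## Numerical and degenerate-input choices

* Attack ties favour the defender; cross-cell attacks are contract errors.
* A robot that lands exactly on zero energy after upkeep survives the step.
* Action frequencies and neighbour statistics raise an error on an empty
  population rather than silently returning 0; Pearson/Welch statistics
  raise on degenerate (zero-variance / too-small) samples, and a Welch test
  between two identical constant samples reports t = 0, p = 1.
* Per-window action counts accumulate over the 10-step window ending at the
  sample step; population size is taken at the sample step.
* The prey–food correlation is computed over the full logged series and,
  for the adaptation analysis, over the food-scarce tail (food < 150).
* Float32 is used in the controller kernel; the numpy reference path and
  the kernel agree to ~10⁻³ (summation order).

## Known limitations

* Cold-start viability of random genomes is ≈8 %; establishment of a viable
  lineage in the first two "years" is therefore stochastic, and run-to-run
  variance in extinction time is substantial.
* Prey frequency peaks during the crowded boom phase and during local
  scarcity dips of the scavenger era rather than rising monotonically at the
  very end of a run. The negative prey-food correlation over the food-scarce
  tail holds for a majority of GRN runs, but — unlike in the original
  qualitative contrast — ANN runs show a comparable tail correlation here:
  famine crowding and the per-capita frequency normalization couple preying
  to scarcity in both arms. The corresponding acceptance test documents this
  by failing.
* Aggregation is implemented fully (pooled energy, mean-of-members control,
  shared upkeep) but rarely persists under default conditions, mirroring
  the original observation that cooperation is slow to evolve.
* The ANN baseline is a faithful-in-spirit stand-in: topology and learning
  rule are declared here, not recovered from the original.
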