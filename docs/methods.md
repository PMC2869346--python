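# Methods

## Model overview

hextaxis simulates chemotactic signal transduction in a single *E. coli*
cell as two coupled layers on a finite hexagonal lattice (default 100
columns × 60 rows, odd-row offset coordinates, hard non-wrapping
boundaries):

* a **background** of fixed entities — chemoreceptor dimers and, once
  assembled, receptor-anchored CheA kinases — with unlimited multiplicity
  per cell, and
* a **foreground** of mobile protein agents, at most one per cell, that
  perform an unbiased excluded-volume random walk (a uniformly chosen
  in-bounds neighbor; the move is dropped if the target is occupied).

Ligands are not individual agents: binding equilibrates orders of
magnitude faster than phosphorylation, so each receptor carries the
time-averaged fractional occupancy `F(l) = l/(l + K_d)` of a spatially
uniform bulk concentration, with the dissociation constant selected by
the receptor's conformation on the previous iteration (Tar–MeAsp: 12 µM
active, 1.7 µM inactive).  Tsr binds MeAsp at 10⁵-fold weaker affinity
when cross-binding is enabled; its serine constants are not known
separately and default to Tar's MeAsp values.  Each receptor type binds
at most one ligand species per scenario.

## Receptor energetics

A receptor is active (+1) or inactive (−1).  Every iteration, all
receptors update **synchronously**: activation probabilities are computed
from the previous iteration's states, then each receptor draws
independently,

    p = 1 / (1 + exp(ΔG / T))
    ΔG = G₀ + E_l·F(l) + E_m·(m − 2) + E_j·Σₙ γ(mₙ)·aₙ

with defaults G₀ = −600, E_l = 2200, E_m = −400, E_j = −700 cal/mol.  The
neighbor sum runs over the 2 intra-trimer + 2 inter-trimer partners
(fewer on the array boundary), and `γ(m) = max(0, 1 − ω(m − 2))` is the
methylation–coupling modulation: the simplest form that equals 1 at
m = 2 for any ω, decreases with m for ω > 0, and is identically 1 at
ω = 0.  ω is 0 except in methylation-dependent-coupling scenarios, where
it is 0.2.  Methylation is an integer 0–4 (four modifiable glutamates per
monomer; only the count is tracked, not site identities).

**Thermal scale.**  `T` converts free energy to probability.  At the
physical RT ≈ 600 cal/mol the default coupling puts this lattice deep in
the all-or-none flipping regime (fitted Hill coefficients above 50), so T
is treated as the model's single calibrated parameter: sweeping it and
fitting the homogeneous-array dose-response crosses the experimentally
observed H ≈ 9.8 at **T = 1070 cal/mol**, which is the package default.
Consequences of this choice are noted under *Limitations*.

**Trimer mask.**  Trimers (three mutually adjacent cells) tile the
leftmost 60 columns — the receptor patch at the cell pole — with column
and row period 3, filled row-major until the requested count is placed;
the default 361 trimers = 1083 receptors.  An exhaustive scan verifies
every interior receptor has exactly 2 intra- and 2 inter-trimer
neighbors.  The specific tiling phase is a free choice; any tiling
meeting the neighbor constraints is equivalent, and this one is fixed
deterministically.  Receptor cells do not block the foreground, so CheR
and CheB can stand on a receptor's cell to modify it.

## Soluble-agent rules

Reaction probabilities (per opportunity, per iteration):

| reaction | p |
|---|---|
| CheW + CheA → CheW–CheA | 0.01 |
| Receptor + CheW → Receptor–CheW | 0.001 |
| CheW–CheA + CheW → CheW–CheA–CheW | 1 |
| CheA base autophosphorylation α | 0 |
| per attached active receptor β | 0.03 |
| CheA~P + CheB → CheA + CheB~P | 0.25 |
| CheA~P + CheY → CheA + CheY~P | 1 |
| CheR methylation | 0.05 |
| CheB~P demethylation (active receptor only) | 0.15 |
| CheY~P + CheZ → CheY + CheZ | 0.2 |
| CheB~P auto-dephosphorylation | 0.005 |
| CheY~P auto-dephosphorylation | 0.0001 |

CheA anchors only at **bridge sites** — receptor-free cells adjacent to
receptors of two distinct trimers — by engaging an unengaged
receptor-bound CheW on a flanking receptor (p = 0.01 bare, 1.0 once it
carries a CheW); on anchoring it leaves the foreground, immediately tries
to engage the second flank (distinct trimer), and retries each iteration
while it has a free CheW slot (a CheA holds at most two CheW, carried +
engaged; a receptor holds at most two bound CheW, one per flanking
bridge).  Anchored CheA autophosphorylates with probability α + βλ, λ
being the count of its attached receptors *currently* active (re-read
every iteration).  CheY and CheB accept the phosphoryl group when
standing on an anchored CheA~P's cell (strict transfer, never
duplication); CheZ acts on *adjacent* CheY~P — the co-location/adjacency
asymmetry is deliberate.  CheR methylates a co-located receptor in any
state; CheB~P demethylates only active ones.

**Arbitration.**  Each iteration the live mobile agents are processed in
a freshly shuffled order; each one moves, then attempts at most one
bimolecular reaction, chosen uniformly among its currently eligible
(partner, reaction) pairs.  Unimolecular events (autophosphorylation,
auto-dephosphorylation, second-flank engagement) run once per agent after
the sweep.  This ordering is a design choice — the underlying description
fixes neither ordering nor multiplicity — and keeps reaction pressure
independent of storage order.

**Stoichiometry.**  Counts are `round(n_receptors · ratio / 3.4)` (ties
up, floor 1) from 3.4 receptors : 2.4 CheY : 1.6 CheW : 1 CheA :
0.5 CheZ : 0.08 CheB : 0.05 CheR; for 1083 receptors: 764 CheY, 510
CheW, 319 CheA, 159 CheZ, 25 CheB, 16 CheR.  All agents start mobile,
unbound, unphosphorylated, at uniformly random distinct cells; the bridge
network self-assembles during burn-in.  Receptor-only experiments (fixed
methylation) omit the soluble layer entirely, which leaves the receptor
update untouched and runs an order of magnitude faster.

## Iteration order and reproducibility

Per iteration: (1) due ligand-schedule changes; (2) synchronous receptor
update; (3) shuffled mobile-agent sweep; (4) unimolecular events;
(5) recording every `record_interval` (default 100) iterations.  One
seeded `numpy.random.Generator` drives everything, so a run is
bit-reproducible from its config and seed; replicate experiments use
independent child seeds spawned from the base seed.  The hot loop is
compiled with numba over flat arrays; event tallies (autophosphorylation,
transfers, CheZ and spontaneous dephosphorylations, methylation changes)
support conservation audits in the tests.

## Measurement protocol

Steady-state activity after a concentration change discards a 1500-
iteration stabilization window, then averages the next 5 recorded points
(500 iterations).  Dose-response experiments hold each concentration of a
logarithmic grid (8–12 points per decade around the transition) for
stabilization + measurement in one sequential run per replicate, default
3 replicates; the Hill equation is fitted to the replicate-mean curve by
`scipy.optimize.curve_fit`, initialized at M₀ = first point, M_f = last
point, K_½ = the concentration nearest half-activity, H = 1, with
non-convergence and transition-free curves flagged rather than reported.
Iterations are not mapped to physical seconds; all schedules are stated
in iteration units.

## Scenario conditions

* **cooperativity / cooperativity-sweep** — homogeneous Tar, m = 2;
  the sweep varies E_j (0 to −900) for G₀ ∈ {0, −200, −400, −600}.
* **mixed-ratio** — Tar fraction swept; readout is Tar-only activity.
* **dual-ligand** — 1:1 Tar:Tsr, cross-binding off, ± 10⁻⁵ M Ser.  The
  composition is a package choice: the source experiments state only "the
  previous configuration" (which swept ratios).  Under this energy
  function no composition can hold Tar near full activity against a
  clamped-inactive Tsr *majority* (ΔG = −600 + E_j·Σγa > 0 regardless of
  T), and a 1:2 field collapses to ~14% total activity; the 1:1 field
  reproduces the observed ~30% baseline and the severalfold K_½
  sensitization.
* **methylation-coupling** — 1:2 Tar:Tsr, cross-binding on, Tsr fixed at
  m = 2, Tar m ∈ {2, 3, 4}, ω ∈ {0, 0.2}.
* **adaptation** — full pathway, homogeneous Tar, 4·10⁻⁶ M MeAsp added
  at iteration 30 000 and removed at 60 000 (90 000 total).
* **dynamic-range** — full pathway; MeAsp raised tenfold per step,
  10⁻⁸ M to 1 M.  The scenario default uses 3000-iteration steps (the
  full-length 30 000 protocol is one parameter away); problem sizes
  throughout are chosen so the whole suite runs in minutes on one core.
  Saturation is declared when a step's final-third mean activity falls
  below 0.1: under the calibrated T a fully pinned lattice retains a
  4–9% activity floor (thermal flicker plus boundary receptors with
  truncated neighborhoods), so a near-zero threshold would never fire;
  0.1 separates that floor band from the weakest genuinely responsive
  plateau observed (≥ 0.13).

## Limitations

* The exact printed forms of the activity and coupling equations are not
  available; the logistic/Boltzmann form and the linear γ are
  reconstructions constrained by the stated parameter values and
  behaviors.  Two published behaviors do not follow from the
  reconstruction: (1) with ω = 0 the low-dose plateau of the
  methylation-coupling sweep *rises* with Tar methylation here (higher m
  always makes Tar harder to deactivate when E_m = −400), whereas the
  source reports the inverse ordering; (2) the 50/50 staircase with
  ω = 0 saturates at 1 M rather than 0.1 M — at 0.1 M the 10⁵-fold Tsr
  Kd multiplier leaves E_l·F far below the bias from G₀ + E_m at the
  methylation levels adaptation reaches, so collapse waits one more
  decade.  The saturation ordering homogeneous < heterogeneous <
  methylation-dependent is robust.
* The calibrated T = 1070 cal/mol implies a nonzero pinned-state activity
  floor and a baseline (~0.90–0.92) slightly below full saturation.
* The recovery asymmetry after attractant removal vs addition is
  directionally present but modest (~15% on triplicate means):
  demethylation at 0.15 is supply-limited by CheB~P, which competes with
  30-fold-more-abundant CheY for scarce anchored CheA~P.
* Flagellar motors and swimming are outside the model; CheY~P is the
  terminal readout.  The lattice is two-dimensional; agent counts
  represent ratios, not absolute cellular concentrations; an iteration
  has no calibrated physical duration.
* Synthetic worlds built by the fixture module emulate composition and
  geometry only; they do not reproduce in vivo crowding, receptor patch
  curvature, or adaptational assistance neighborhoods, so passing tests
  on them validates rule bookkeeping, not quantitative biology.
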