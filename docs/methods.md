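# Methods

## Model overview

`t6sim` simulates contact-dependent combat between rod-shaped bacteria.
Cells are spherocylinders (capsules) of fixed radius R that elongate
exponentially, divide by binary fission, and push on one another; T6SS+
"attacker" cells fire short, toxin-tipped needles from random surface
sites.  A susceptible cell struck by `N_hits` needles of any single
non-kin genotype becomes an intoxicated victim: it stops growing, remains
a solid obstacle, and is removed (lysed) after a delay `1/k_lysis`.
Unlysed victims accumulate at interstrain boundaries and absorb incoming
needles — the corpse-barrier effect the metrics suite quantifies.

One timestep `dt` performs, in order: (1) combat — Poisson firing, needle
construction and hit resolution against the static configuration,
intoxication bookkeeping, lysis removal; (2) growth with weapon costs and
crowding restriction; (3) division; (4) mechanical relaxation;
(5) arena removal rules (sloughing, chamber exit); (6) clock advance.
Combat precedes growth because firing is fast compared with cell movement,
so needles see an essentially static configuration.  A single seed drives
three deterministically derived substreams (combat, growth, placement);
a (config, seed) pair reproduces a trajectory bitwise.

## Parameters, units, defaults

| parameter | meaning | default | rationale |
|---|---|---|---|
| R | cell radius (um) | 0.5 | typical rod-shaped bacterium |
| V0 | nominal birth volume (um^3) | 1.309 | 2-um-long, 0.5-um-radius capsule |
| k_grow | specific growth rate (1/h) | 0.7 | calibrated so a 100-cell inoculum fills the 100-um disc (coordination plateau) at ~5 h; ~1-h doubling |
| dt | timestep (h) | 0.025 | k_fire*dt stays small at the firing rates studied; rates are per-hour so results are dt-robust |
| eta_division | division-threshold noise, uniform on [0, s] (um^3) | s = 0.05 V0 | desynchronizes divisions without shifting mean size |
| eta_orientations | daughter-axis rotation s.d. (rad) | 0.05 | small spatial imperfection at division |
| k_fire | firing rate (firings/cell/h) | protocol variable | 50 matches the measured firing rate of an aggressive attacker |
| c | growth cost per unit firing rate | 0.001 | at this cost the optimal firing rate is near 50/h |
| N_hits | lethal hit threshold | 1 | single-hit lethality |
| k_lysis | victim lysis rate (1/h) | presets 0.8 ("slow-lysis") / 8.0 ("rapid-lysis") | the two regimes compared throughout |
| L_needle | needle length | R | contracted-sheath geometry: extended sheaths span a cell diameter and contraction halves them |
| contact threshold | touching distance (um) | 0.01 | surfaces within this distance interact mechanically and count as touching for all metrics |
| alpha | movement-cost regularization | 1.0 (0.05 in the chamber) | see mechanics |
| M_iter,max | relax repetitions per step | 10 (30 in the chamber) | see mechanics |
| eps_CG | conjugate-gradient tolerance (um) | 1e-3 | well below the contact threshold |
| 1/gamma | growth-restriction strength | 0 (0.1 in the chamber) | crowding slows growth only in the confined geometry |

Division threshold: a cell divides when its volume reaches
`2*V0 + eta`, with `eta` drawn once at birth; `V0` here is the *nominal*
genotype birth volume, not the cell's realized birth volume, so thresholds
do not drift across generations.  Daughters take half the parent volume
each, sit end-to-end along the parent axis with a shallow (0.05 um) axial
overlap that relaxation opens — placing them exactly tip-to-tip would make
the segment-segment contact normal degenerate — and start with empty hit
tallies (sub-lethal intoxication is not inherited).

## Mechanics

Contacts are detected with a uniform-grid broad phase (bin size at least
one maximal cell extent plus the interaction range, so candidate lists are
complete) and an exact clamped segment-segment narrow phase; a brute-force
all-pairs path is retained for testing.  Overlapping pairs enter a
regularized least-squares impulse solve `(J^T J + alpha*M) p = J^T d`,
where rows of `J` map per-cell impulses (2 translations + 1 rotation in
2D; 3 + 2 in 3D) to gap opening at each contact, `d` holds penetration
depths, and `M` is the identity scaled by cell total length (longer cells
cost more to move).  Arena walls contribute unilateral endpoint-sphere
contacts.  The system is solved by conjugate gradients to absolute
tolerance `eps_CG`; the detect/solve/apply cycle repeats until no
penetration exceeds the contact threshold or `M_iter,max` is reached
(warning).  For two symmetric overlapping bodies the iterated solution
converges to the analytic split: each body moves out by half the depth.

Two numerical choices matter in confined geometries.  First, the
"pressure" signal that drives growth restriction is the per-cell *residual
contact load* (summed unresolved penetration, in um) rather than the
summed impulse magnitude: a jammed cell cannot move, so a
displacement-based signal would read zero exactly where crowding is
strongest and the restriction would receive no feedback.  Accumulated
impulse magnitudes remain available (`relax(..., return_impulses=True)`).
The growth multiplier is `1/(1 + (1/gamma) * P / P0)` with normalization
`P0 = 0.01 um` (one contact threshold); it is 1 for unloaded cells and
decreases monotonically with load.  Second, the chamber protocol overrides
the solver defaults (`alpha = 0.05`, `M_iter,max = 30`): expelling cells
through the open ends requires long-range, collective displacement of the
whole column each step, which strong regularization suppresses — with the
disc defaults the column compresses without bound instead of flowing out.
In dense colony cores the regularized solver leaves some standing
compression (tens of nanometres to ~0.1 um between neighbors); this is a
known limitation discussed below.

## Combat

Each attacker draws `N ~ Poisson(k_fire * dt)` firings per step.  The
per-step growth-cost multiplier is `1 - c*(N/dt)`, floored at 0; averaged
over steps this gives the mean attacker growth rate
`k_grow * (1 - c*k_fire)`, which is the consistency condition fixing the
Poisson mean as `k_fire*dt` (a per-step mean independent of dt would make
both cost and kill rates timestep-dependent).  Needle origins are sampled
uniformly by area over the capsule surface (cylindrical wall vs the two
hemispherical caps in proportion to their areas); the direction is the
outward surface normal, the length equals the firer's radius.  A needle
strikes the first cell along its segment whose axis comes within that
cell's own radius (heterogeneous radii supported); ties are broken by
distance, then cell id; the firer is never a target; victims are
legitimate targets and absorb needles.  Hits are tallied per attacking
genotype; a cell ignores its own genotype's tally (self-immunity).  When a
non-kin tally reaches the target's `N_hits`, the target becomes a victim
and its lysis delay is `1/k_lysis` of the genotype that delivered the
crossing hit — deterministic by default, with an exponentially distributed
option (`deterministic_lysis: false`) for sensitivity analysis.

## Arenas

* **disc2d** — 100 cells (1:1 attacker:susceptible) scattered uniformly
  with random in-plane orientations in a 100-um-diameter circle
  (rejection sampling forbids deep overlaps; relaxation settles the rest
  before t = 0).  Motion is confined to the plane.  The run stops once
  living + victim count exceeds the population cap (10,000 by default;
  the confluent monolayer is then ~180 um across).
* **biofilm3d** — one cell of each strain on the floor of a walled
  40 x 40 um box, free 3D motion; cells whose center rises above 20 um
  are sloughed; 13-h duration.
* **chamber** — a walled 10 x 100 um channel, open at the short ends
  (cells forced past an end are removed as EXIT events).  Seeding places
  one susceptible cell at the center flanked symmetrically by two
  width-spanning rows of five attackers; a 3-h growth-only burn-in then
  defines t = 0, after which weapons engage for the configured duration
  (13 h).  The protocol enables growth restriction (1/gamma = 0.1) and
  gives the susceptible strain `k_grow = 1.5 /h` against the attacker's
  0.7: the prey species is the faster grower in this competition — that
  asymmetry is what makes the growth restriction necessary in the first
  place — and a 3-h burn-in from one cell can only produce the broad
  central prey band this protocol starts from at that rate.

## Metrics

Boundary attackers are attacker cells touching (contact threshold) at
least one susceptible-strain cell, living or dead.  Boundary saturation is
the fraction of boundary-attacker-to-susceptible *contacts* whose
susceptible partner is a victim.  Confluency is detected as the plateau of
the per-snapshot median coordination number (first time the median reaches
5 and stays within +-1 over a 1-h window).  The kill-rate series is the
central-difference gradient of the cumulative susceptible death count on
the snapshot grid, smoothed with a 0.25-h moving average.  The normalized
peak kill rate takes the argmax of the *smoothed absolute* rate restricted
to post-confluency times and divides by the boundary-cell count at that
time — deliberately not the max of the pointwise-normalized series, which
is dominated by noisy pre-confluent killing.  The Monte-Carlo hit
probability freezes a configuration, lets each boundary attacker fire N
(default 100) virtual needles, and reports the fraction striking non-kin
(living or victim) cells, averaged unweighted over configurations.  The
kill-rate prediction is `k_kill = (1 - f_boundary) * k_fire * p_hit`.
Relative fitness is the ratio of the strains' log2 volume fold-changes,
counting living cells only (victims cannot grow and are doomed; counting
their volume would mask killing).

## Phylogenetic signal

Effectors are classified by molecular target: peptidoglycan amidases and
glucosidases and phospholipases are fast-lysing (they destroy the
structures that maintain cell integrity); DNases, pore-formers and
NAD(P)+ glycohydrolases are slow-lysing.  Unknown labels raise — there is
no silent default.  For a clade of `N_c` species the similarity of an
effector is the mean agreement over all *ordered* species pairs including
self-pairs, `(k^2 + (N_c-k)^2)/N_c^2` for `k` possessors; it lies in
[0.5, 1], reaching 0.5 exactly at an even split with even `N_c` and 1 iff
presence is uniform.  Ratios `S_ce / S_Tree,e` are reported per rank level
1..9 (subspecies .. kingdom); the level-9 ratio is 1 by construction.
Missing intermediate ranks collapse to the nearest present ancestor;
clade labels are nested under their ancestors so same-named taxa in
different branches never merge; singleton clades are retained (S = 1).
One strain represents each species.

## Synthetic data and fixtures

The fixture generators produce hand-placed capsule configurations (duels,
single-file chains, checkerboards, hexagonal discs with known coordination
numbers), synthetic event logs with prescribed cumulative-death shapes
(linear, step, peaked — enabling closed-form checks of every kill-rate
metric), and balanced toy taxonomies with three planted effector
archetypes (clade-confined, Bernoulli-random, singleton).  They emulate
the geometry and bookkeeping of real simulations, not their physics: no
mechanics, no growth, and (for synthetic trajectories) no cell geometry at
all, so metric tests that need a boundary-cell series supply it
explicitly.  Passing tests on these fixtures validates the estimators and
bookkeeping, not the emergent biology; the emergent contracts (saturation
trends, kill-rate collapse, clearance vs persistence) are tested on real
reduced-scale simulations.

## Desk-scale test conditions

The full-scale protocols (10,000-cell disc runs; 13-h chambers) are
reachable through the CLI, but the test suite and the acceptance script
run reduced problem sizes chosen once:

* saturation / coordination runs: the full 100-um disc protocol with the
  population cap at 3,000 (the colony is confluent shortly before the cap)
  across 5 seeds;
* parameter grids (optimum firing rate, kill-rate prediction, saturation
  monotonicity, N_hits collapse): a 60-um disc with a 36-cell inoculum —
  the same inoculum density as the full protocol — capped at 1,100 cells,
  2 seeds per condition;
* chamber contrast runs: the full 10 x 100 um chamber for 5 h of
  competition, 2 seeds per lysis rate (the rapid-lysis arm clears within
  ~2 h, so the contrast is established well before 5 h);
* colony-geometry check: the analytic area consistency of the confluent
  monolayer (summed cell area vs pi*(D/2)^2) evaluated on ~2,000-cell
  snapshots, extrapolated to the full 10,000-cell diameter via the mean
  cell area.

## Known limitations

* The regularized impulse solver under-resolves long-range stress in
  dense cores: neighbors can interpenetrate by up to ~0.1 um at the
  centre of a 3,000-cell colony.  Coordination numbers and boundary
  classification are robust to this; absolute packing-derived quantities
  (colony area) carry a few-percent bias.
* At the highest firing rates with slow lysis the boundary saturates
  almost completely; at intermediate rates the exact plateau depends on
  parameters not fixed by the study conditions (division-noise range,
  baseline growth restriction), so saturation values at k_fire = 150
  carry a 2-3 point systematic uncertainty.
* The 3D biofilm arena has no gravity, adhesion or nutrient field; growth
  is space-limited only through mechanics and the slougher.
* In the chamber, the slow-lysis prey band survives the rapid-lysis arm
  by several hours but is fully consumed by ~7-8 h of competition:
  interface corpse turnover plus slow drift of the band toward an open
  end eventually removes it.  The clearance-vs-persistence contrast is
  therefore asserted at a 5-h horizon.
* Needles are fired isotropically in 3D even in monolayer simulations, so
  a fraction of shots harmlessly leave the plane; hit probabilities are
  correspondingly interpreted per fired needle, not per in-plane needle.
* Effector classification covers the catalogued toxin families only;
  effectors outside the catalog must be classified by the caller.
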