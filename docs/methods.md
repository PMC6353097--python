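# Methods

## Problem

Two protein structures can share extensive local geometry while the
shared segments appear in a different order along the two chains
(swapped domains, circular permutations) or even in the opposite
direction (reverse alignment).  Sequential alignment methods, which
require aligned pairs to preserve chain order, cannot express such
correspondences.  `nsalign` treats a pairwise structure alignment as
an unordered one-to-one set of Cα index pairs and searches that space
directly, using the Cα trace only.

## Alignment model

An alignment decomposes uniquely into *blocks* — maximal runs of pairs
consecutive in both chains.  Forward blocks satisfy `(i+1, j+1)`
succession, reverse blocks `(i+1, j−1)`.  Decomposition grows runs
greedily in increasing `i`, trying forward continuation before
reverse; a singleton has no direction and is forward by convention.
This tie rule makes the decomposition deterministic; any other
consistent rule would change only which of two touching runs claims a
shared corner pair.

Two constraints shape the search space: `min_block_size` (blocks
smaller than the threshold are forbidden — heavily fragmented
alignments are hard to interpret biologically, and a minimum of 4 is
the conventional choice) and `allow_reverse`.

`enforce_constraints` projects an arbitrary pair set onto the
constraint-satisfying set.  When removing offending blocks would empty
the alignment, two fallbacks apply: after removing forbidden reverse
blocks, one pair per original block is retained at the block center
(index `size // 2` of the run — the C-terminal of the two middle pairs
for even sizes); after removing undersized blocks, every block of the
largest size present is extended to the minimum size, alternating
sides starting C-terminal (so odd remainders favor it); a side blocked
by a chain end or a one-to-one conflict redirects growth to the other
side, and extension stops when both sides are blocked.  The
extension direction and the even-size center choice are free choices
of this implementation; both are deterministic and idempotent.

## Scoring functions

Four scoring functions are implemented (constants are the standard
literature values):

* **DALI** (`d0 = 20 Å`) — compares internal distance matrices only;
  pair term `(0.2 − |dᴬ−dᴮ|/d̄)·w` off-diagonal, `0.2` on the
  diagonal.  Two envelope variants are provided: `deviation`
  (`w = exp(−|dᴬ−dᴮ|²/d0²)`, the default) and `mean_distance`
  (`w = exp(−d̄²/d0²)`, the classic elastic weight).  The default
  follows the printed form of the score as this package defines it;
  the variant switch exists because published DALI values may have
  used either convention, and the variant is recorded in every score
  report.  DALI sees no coordinates, so it is exactly invariant under
  mirror reflection of either chain — a property the test suite
  asserts rather than "fixes", together with the diagnostic below.
* **SP** (`d0 = 4 Å`, `α = 0.3`) — superposition-based, normalized by
  `3·L^(1−α)` where `L` counts core residues (aligned pairs with
  post-fit deviation `≤ 2d0`) plus the average over the two chains of
  the neighboring-residue counts (non-core residues within `3d0` of
  any core Cα, measured in each chain's own coordinates).  The
  summation bound is strict (`d < 2d0`) while core membership is
  inclusive (`d ≤ 2d0`) — the printed inequalities taken literally.
  Counting neighbors per chain and averaging is one reading of "the
  average number of neighboring residues"; it is symmetric in the two
  chains and deterministic.
* **SO** (`d0 = 3.5 Å`) — fraction of aligned pairs within `d0` after
  superposition, normalized by `min(L_A, L_B)`.  Because the count is
  piecewise constant, optimization uses the logistic surrogate
  `SO_L` (`k = 10 Å⁻¹`); final reports re-evaluate the original SO.
* **TM** — `d0 = 1.24·(L_N−15)^⅓ − 1.8`, clamped below at 0.5 Å so
  the score stays defined on chains of ≤ 21 residues (the formula
  goes non-positive there); normalization by chain A, chain B, or the
  average of both normalized values (the default optimization
  objective).

All superposition-based scores use the least-RMSD proper rotation
(Kabsch, determinant sign-corrected) over the currently aligned pairs
— not a score-maximizing rotation search.  Degenerate point sets (1–2
points, collinear) take the deterministic transform the SVD yields.

## Refinement

Greedy best-first local search over a move list:

* `delete_pair` / `add_pair` — single-pair edits that keep every block
  at or above the minimum size (for `min_block_size > 1` additions are
  block extensions; candidates are the diagonal/antidiagonal neighbors
  of existing pairs);
* `delete_block` — remove an entire block;
* `add_block` — seed a complete minimum-size block at any
  non-conflicting placement (only when `min_block_size > 1`).  Without
  this move no single-pair edit could ever create a new aligned
  region under a block-size constraint; it is the minimal completion
  that lets constrained refinement grow new regions, and block seeds
  are ranked by score delta like every other move.

All score-improving moves enter the list with their residues and
deltas.  The best move is popped, its delta re-computed against the
current alignment (deltas of stored moves go stale as the
superposition shifts), and accepted only if it still improves by more
than `1e-9` (absolute; refits oscillate at machine precision).  On
acceptance, list entries sharing a residue with the move are removed,
and fresh candidates are enumerated among moves touching the affected
residues *and their immediate chain neighbors* — the ±1 window is
needed because the admissibility and profitability of extending a run
changes at positions adjacent to, not identical with, the accepted
pair.  The loop ends when the list is empty.  Every candidate delta is
computed with a full Kabsch refit; candidate evaluation is vectorized
(stacked 3×3 SVDs), which is the identical computation batched, not an
approximation.  Ties among equal-delta moves break lexicographically
(kind order: delete_pair, add_pair, delete_block, add_block; then
`(i, j)`), so refinement is deterministic.

Each accepted move strictly increases a bounded score over a finite
move set, so termination is guaranteed, and the final alignment is a
fixed point satisfying the constraints.

## Global search (CSA)

Conformational space annealing maintains a *bank* of locally refined
solutions and controls its diversity with an annealed distance cutoff
`D_cut` over the solution-space metric.  The metric used is the
normalized overlap `1 − |a∩b| / max(|a|, |b|)`; any metric that is
zero exactly on identical pair sets and symmetric would serve — the
annealing trajectory, not the optimum, depends on the choice.

* **Seeding** pools two kinds of starting points: fragment-pair
  superpositions (windows of length 6, shrunk to half the shorter
  chain for tiny inputs, never below the minimum block size; harvested
  greedily at a `2·d0_SO` deviation cutoff) and bare minimum-size
  block placements, which nucleate alignments in basins the fragment
  harvest cannot reach.  When the pool exceeds `seed_budget` (default
  240), every candidate is first screened by its local fragment-fit
  RMSD (batched Kabsch over all windows, milliseconds); half the
  budget goes to the best local matches — which finds structurally
  matching offsets deterministically instead of by sampling luck — and
  half to random candidates for diversity.  Every start is
  constraint-projected, refined, and the highest-scoring distinct
  results fill the bank.
* **Daughters**: seeds are picked least-recently-used (deterministic
  coverage of the bank); each seed alternates crossover — transplant a
  random subset of the partner's blocks, deleting conflicting pairs —
  with perturbation (delete / diagonal-or-axis shift / truncate a
  block, or seed a fresh random block).  Every daughter is refined
  before competing for a bank slot.
* **Update rule**: a trial within `D_cut` of its nearest bank member
  replaces that member iff strictly better; otherwise it replaces the
  worst member iff better.  `D_cut` starts at half the average
  pairwise bank distance and shrinks by 0.97 per round, floored at
  0.05.
* **Stopping**: after `n_collect` refined trials (seeding included).

One RNG stream seeded once drives every stochastic choice, so runs are
bit-reproducible; the best bank score never decreases.

## Synthetic structures

The generator provides the controlled conditions for every test:

* *ideal α-helix* — 1.5 Å rise, 100° turn, 2.3 Å radius (≈ 3.8 Å Cα
  steps);
* *self-avoiding walk* — 3.8 Å steps, ≥ 3.5 Å non-bonded separation,
  a compact irregular fold with no internal symmetry (important: a
  helix's translational self-similarity would make ground-truth
  recovery ambiguous);
* *permuted/reversed copies* — disjoint source segments concatenated
  in a new order, optionally reversed, with i.i.d. Gaussian coordinate
  noise; the ground-truth alignment is returned alongside.

Since a permuted copy reorders residues without moving coordinates, a
noise-free pair superposes exactly (RMSD 0) under its ground truth,
making the full truth the unique global optimum of TM — this is what
the recovery tests and the acceptance script exploit.  What these
fixtures do *not* emulate: real secondary-structure regularity,
domain-level rigid-body motions, missing residues, or the partial
similarity of genuinely homologous pairs — so passing recovery tests
demonstrates correctness of the machinery, not benchmark-level
accuracy on real proteins.

## Problem sizes and defaults

Defaults (`CSAConfig`): bank 30, 20 seeds/round, 10 trials/seed,
`n_collect` 100, `D_cut` schedule as above.  The test suite and the
acceptance script run desk-scale versions of every contract: recovery
on 60-residue walks (bank 10, 60 collects), exhaustive-oracle equality
on 5–6-residue chains with minimum block size 2 (where every
constraint-satisfying alignment can be enumerated and scored), 100
random refinement starts on 10–16-residue pairs, and 6-point Kabsch
instances against a quaternion-grid minimizer.  These sizes were
chosen so the full suite re-runs in minutes on one CPU while still
exercising each code path at meaningful depth.

## Known limitations

* The refiner re-checks a popped move against the current alignment
  but never re-adds moves discarded as non-improving unless a later
  accepted move touches their neighborhood; distant moves whose deltas
  turn positive purely through superposition drift can be missed.
  This is inherent to the move-list design; CSA's
  perturbation/crossover layer compensates in practice.
* DALI-objective refinement is deterministic here; the score's
  discreteness can in principle favor stochastic quenching.
* No flexible/hinge superposition, no sequence or secondary-structure
  terms, no many-to-many pairing, and no all-vs-all database mode —
  the global search costs minutes per pair at these sizes and far more
  at protein scale.
* `Eq`-level agreement with published benchmark tables is not a
  contract of this package: reference PDB chains, their parsing
  conventions (altLoc, missing residues), and multi-day search budgets
  all enter those numbers.
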