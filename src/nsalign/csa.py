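"""Global alignment search by conformational space annealing (CSA).

CSA is a population-based global optimizer, best thought of as a
genetic algorithm whose pool diversity is controlled explicitly.  A
*bank* of locally refined candidate alignments is maintained together
with a distance cutoff ``D_cut`` over the solution-space metric
(:func:`~nsalign.alignment.alignment_distance`).  ``D_cut`` plays the
role of temperature in simulated annealing: a trial solution that
lands within ``D_cut`` of an existing bank member competes with that
member (keeping the bank spread out early in the run, when ``D_cut``
is large), while a trial far from every member competes with the
worst member.  ``D_cut`` shrinks geometrically each round, letting the
bank condense into distinct local optima and share information through
crossover as it does so.

Three ingredients specialize CSA to the alignment problem:

1. the normalized-overlap distance between pair sets (the metric),
2. the greedy move-list refiner (the local optimizer — every trial is
   refined before it competes for a bank slot),
3. crossover (transplanting blocks between parents) and perturbation
   (block deletion / rigid shift / truncation) to generate daughters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .alignment import (
    Alignment,
    Constraints,
    ConstraintError,
    alignment_distance,
    blocks_of,
    enforce_constraints,
)
from .refine import refine
from .scoring import ScoreContext, ScoreSpec
from .structures import ProteinChain

__all__ = ["CSAConfig", "CSABank", "seed_bank", "crossover", "perturb", "bank_update", "csa_search"]


@dataclass(frozen=True)
class CSAConfig:
    """CSA hyper-parameters.

    ``n_collect`` counts every refined trial (including the seeding
    stage) and is the stopping criterion; runs of a few hundred
    refinements suffice for chains of ~100 residues.  All stochastic
    choices are driven by one RNG stream seeded with ``rng_seed``, so
    runs are bit-reproducible.
    """

    bank_size: int = 30
    n_seeds_per_round: int = 20
    n_trials_per_seed: int = 10
    dcut_start_factor: float = 0.5  # fraction of the average pairwise bank distance
    dcut_ratio: float = 0.97  # geometric reduction per round
    dcut_min: float = 0.05
    n_collect: int = 100
    seed_budget: int = 240  # fragment pairs sampled during seeding
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.dcut_ratio < 1):
            raise ValueError("dcut_ratio must lie in (0, 1)")
        if self.dcut_min <= 0:
            raise ValueError("dcut_min must be positive")
        if self.bank_size < 2:
            raise ValueError("bank_size must be >= 2")


@dataclass
class CSABank:
    """The population of candidate alignments with their objective scores."""

    members: list[tuple[Alignment, float]]
    dcut: float
    n_generated: int = 0
    last_used: list[int] = field(default_factory=list)

    @property
    def best(self) -> tuple[Alignment, float]:
        return max(self.members, key=lambda m: m[1])

    @property
    def best_score(self) -> float:
        return self.best[1]


def _fragment_window(c: Constraints, LA: int, LB: int) -> int:
    # nominal window 6, shrunk for tiny chains so several distinct
    # fragment placements exist; never below the minimum block size
    w = max(c.min_block_size, min(6, min(LA, LB) // 2), 2)
    return min(w, LA, LB)


def _screen_fragment_rmsd(
    ctx: ScoreContext, candidates: list[tuple], w: int, bsize: int
) -> np.ndarray:
    """Fragment-fit RMSD of every seed candidate, by batched Kabsch.

    A candidate (fragment window pair or bare block placement) whose
    two local segments superpose tightly is a promising nucleation
    site; ranking by this local RMSD finds the structurally matching
    offsets without any search.
    """
    rmsds = np.empty(len(candidates))
    by_len: dict[int, list[int]] = {}
    for k, (kind, _, _, _) in enumerate(candidates):
        by_len.setdefault(w if kind == "frag" else bsize, []).append(k)
    for length, idxs in by_len.items():
        PA = np.empty((len(idxs), length, 3))
        PB = np.empty((len(idxs), length, 3))
        for m, k in enumerate(idxs):
            _, i0, j0, dj = candidates[k]
            PA[m] = ctx.ca[i0 : i0 + length]
            PB[m] = ctx.cb[j0 + dj * np.arange(length)]
        from .scoring import _batch_deviations

        dev = _batch_deviations(PA, PB)
        rmsds[idxs] = np.sqrt((dev**2).mean(axis=1))
    return rmsds


def _harvest(
    ctx: ScoreContext,
    ia0: int,
    jb0: int,
    dj: int,
    w: int,
    cutoff: float,
) -> list[tuple[int, int]]:
    """Superpose one fragment pair and greedily harvest close residue pairs."""
    from .superposition import kabsch

    fi = np.arange(ia0, ia0 + w)
    fj = jb0 + dj * np.arange(w)
    sup = kabsch(ctx.ca[fi], ctx.cb[fj])
    moved = sup.apply(ctx.cb)
    dev = np.linalg.norm(ctx.ca[:, None, :] - moved[None, :, :], axis=2)
    close = np.argwhere(dev < cutoff)
    if len(close) == 0:
        return []
    order = np.argsort(dev[close[:, 0], close[:, 1]], kind="stable")
    used_i: set[int] = set()
    used_j: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for k in order:
        i, j = int(close[k, 0]), int(close[k, 1])
        if i in used_i or j in used_j:
            continue
        used_i.add(i)
        used_j.add(j)
        pairs.append((i, j))
    return pairs


def seed_bank(
    A: ProteinChain,
    B: ProteinChain,
    spec: ScoreSpec,
    c: Constraints,
    config: CSAConfig,
    ctx: ScoreContext | None = None,
    rng: np.random.Generator | None = None,
) -> CSABank:
    """Build the initial bank from superposed fragment pairs.

    Two kinds of starting points are pooled and subsampled to
    ``config.seed_budget`` by the seeded RNG:

    * *fragment-superposition* seeds — every window of A against every
      window of B (both orientations when reverse alignment is
      allowed); the fragment pair is superposed and residue pairs
      within ``2·d0_SO`` are harvested greedily into a one-to-one
      alignment;
    * *block-placement* seeds — bare minimum-size blocks at every
      legal placement, which nucleate alignments in basins the
      fragment harvest cannot reach.

    Each start is projected onto the constraint set and refined; the
    bank keeps the highest-scoring distinct results.
    """
    if ctx is None:
        ctx = ScoreContext(A, B, spec)
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    LA, LB = len(A), len(B)
    w = _fragment_window(c, LA, LB)
    orients = [1, -1] if c.allow_reverse else [1]
    candidates: list[tuple] = [
        ("frag", i0, j0 if dj == 1 else j0 + w - 1, dj)
        for dj in orients
        for i0 in range(LA - w + 1)
        for j0 in range(LB - w + 1)
    ]
    bsize = max(c.min_block_size, 2)
    if min(LA, LB) >= bsize:
        for dj in orients:
            for i0 in range(LA - bsize + 1):
                j_range = (
                    range(LB - bsize + 1) if dj == 1 else range(bsize - 1, LB)
                )
                candidates += [("block", i0, j0, dj) for j0 in j_range]
    if len(candidates) > config.seed_budget:
        # screen all candidates by their fragment-fit RMSD (batched),
        # spend half the budget on the best local matches and half on
        # random candidates for diversity
        rmsds = _screen_fragment_rmsd(ctx, candidates, w, bsize)
        order = np.argsort(rmsds, kind="stable")
        n_best = config.seed_budget // 2
        best_idx = list(order[:n_best])
        rest = order[n_best:]
        n_rand = config.seed_budget - n_best
        rand_idx = list(rest[rng.choice(len(rest), size=n_rand, replace=False)])
        chosen = [candidates[k] for k in sorted(best_idx + rand_idx)]
    else:
        chosen = candidates

    cutoff = 2.0 * spec.d0_so
    results: list[tuple[Alignment, float]] = []
    n_generated = 0
    for kind, i0, j0, dj in chosen:
        if kind == "frag":
            raw = _harvest(ctx, i0, j0, dj, w, cutoff)
        else:
            raw = [(i0 + k, j0 + k * dj) for k in range(bsize)]
        if not raw:
            continue
        try:
            start = enforce_constraints(Alignment(raw), c, LA, LB)
        except ConstraintError:
            continue
        res = refine(start, A, B, spec, c, ctx=ctx)
        n_generated += 1
        results.append((res.alignment, res.score))

    if not results:
        raise ConstraintError("no valid seed alignment could be generated")

    # highest-scoring distinct pair sets
    results.sort(key=lambda m: (-m[1], m[0].pairs))
    members: list[tuple[Alignment, float]] = []
    seen: set[tuple] = set()
    for aln, sc in results:
        if aln.pairs in seen:
            continue
        seen.add(aln.pairs)
        members.append((aln, sc))
        if len(members) >= config.bank_size:
            break

    bank = CSABank(members=members, dcut=0.0, n_generated=n_generated)
    bank.last_used = [-1] * len(members)
    bank.dcut = max(
        config.dcut_start_factor * _avg_pairwise_distance(bank), config.dcut_min
    )
    return bank


def _avg_pairwise_distance(bank: CSABank) -> float:
    ms = bank.members
    if len(ms) < 2:
        return 0.0
    total = 0.0
    count = 0
    for x in range(len(ms)):
        for y in range(x + 1, len(ms)):
            total += alignment_distance(ms[x][0], ms[y][0])
            count += 1
    return total / count


def crossover(
    p1: Alignment,
    p2: Alignment,
    c: Constraints,
    rng: np.random.Generator,
    len_a: int | None = None,
    len_b: int | None = None,
) -> Alignment:
    """Transplant a random nonempty subset of p2's blocks into a copy of p1.

    Pairs of p1 conflicting (one-to-one) with transplanted residues are
    deleted first; the result is projected back onto the constraint set.
    """
    if p2.n == 0:
        return enforce_constraints(p1, c, len_a, len_b) if p1.n else p1
    donor_blocks = p2.blocks()
    take = [b for b in donor_blocks if rng.random() < 0.5]
    if not take:
        take = [donor_blocks[int(rng.integers(len(donor_blocks)))]]
    new_i = {i for b in take for i, _ in b.pairs}
    new_j = {j for b in take for _, j in b.pairs}
    kept = [p for p in p1.pairs if p[0] not in new_i and p[1] not in new_j]
    merged = Alignment(kept + [p for b in take for p in b.pairs])
    return enforce_constraints(merged, c, len_a, len_b)


def perturb(
    p: Alignment,
    c: Constraints,
    rng: np.random.Generator,
    len_a: int | None = None,
    len_b: int | None = None,
) -> Alignment:
    """Random structural kick on one block.

    One of: delete the block; rigidly shift it by ±1 along i, j, or
    both (sliding it along its diagonal), dropping colliding pairs;
    truncate one end by one pair (respecting the minimum size); or
    seed a fresh minimum-size block at a random non-conflicting
    placement.  The result is projected back onto the constraint set.
    """
    if p.n == 0:
        return p
    blocks = p.blocks()
    op = ("delete", "shift", "truncate", "seed")[int(rng.integers(4))]
    b = blocks[int(rng.integers(len(blocks)))]
    others = [q for blk in blocks if blk is not b for q in blk.pairs]
    if op == "delete":
        result = Alignment(others)
    elif op == "shift":
        di, dj = ((1, 0), (0, 1), (1, 1), (1, -1))[int(rng.integers(4))]
        step = int(rng.choice([-1, 1]))
        di, dj = di * step, dj * step
        used_i = {i for i, _ in others}
        used_j = {j for _, j in others}
        moved = []
        for i, j in b.pairs:
            q = (i + di, j + dj)
            if q[0] < 0 or q[1] < 0 or q[0] in used_i or q[1] in used_j:
                continue
            if (len_a is not None and q[0] >= len_a) or (
                len_b is not None and q[1] >= len_b
            ):
                continue
            used_i.add(q[0])
            used_j.add(q[1])
            moved.append(q)
        result = Alignment(others + moved)
    elif op == "truncate":  # drop one end pair, respecting the minimum size
        if b.size > max(c.min_block_size, 1):
            end = int(rng.integers(2))
            kept = b.pairs[1:] if end == 0 else b.pairs[:-1]
        else:
            kept = b.pairs
        result = Alignment(others + list(kept))
    else:  # seed a fresh min-size block at a random free placement
        size = max(c.min_block_size, 1)
        all_pairs = list(p.pairs)
        used_i = {i for i, _ in all_pairs}
        used_j = {j for _, j in all_pairs}
        la = len_a if len_a is not None else max(used_i) + size + 1
        lb = len_b if len_b is not None else max(used_j) + size + 1
        result = p
        for _ in range(20):  # rejection-sample a non-conflicting placement
            i0 = int(rng.integers(max(la - size + 1, 1)))
            dj = int(rng.choice([1, -1])) if c.allow_reverse else 1
            if dj == 1:
                j0 = int(rng.integers(max(lb - size + 1, 1)))
            else:
                j0 = int(rng.integers(size - 1, lb))
            run = [(i0 + k, j0 + k * dj) for k in range(size)]
            if any(i >= la or j >= lb or j < 0 for i, j in run):
                continue
            if any(i in used_i or j in used_j for i, j in run):
                continue
            result = Alignment(all_pairs + run)
            break
    try:
        return enforce_constraints(result, c, len_a, len_b)
    except ConstraintError:
        return enforce_constraints(p, c, len_a, len_b)


def bank_update(bank: CSABank, trial: Alignment, trial_score: float) -> CSABank:
    """First-update rule of CSA.

    The trial competes with its closest bank member when that member is
    within ``D_cut`` (replace iff strictly better), otherwise with the
    current worst member.
    """
    dists = [alignment_distance(m[0], trial) for m in bank.members]
    closest = int(np.argmin(dists))
    if dists[closest] < bank.dcut:
        if trial_score > bank.members[closest][1]:
            bank.members[closest] = (trial, trial_score)
        return bank
    worst = min(range(len(bank.members)), key=lambda k: bank.members[k][1])
    if trial_score > bank.members[worst][1]:
        bank.members[worst] = (trial, trial_score)
    return bank


def csa_search(
    A: ProteinChain,
    B: ProteinChain,
    spec: ScoreSpec,
    c: Constraints = Constraints(),
    config: CSAConfig = CSAConfig(),
) -> CSABank:
    """Run the full CSA loop and return the final bank sorted by score.

    Seeds are chosen round-robin over the least-recently-used bank
    members; each seed spawns trials alternately by crossover with a
    random other member and by perturbation, every trial is locally
    refined before competing for a bank slot, and ``D_cut`` shrinks by
    ``dcut_ratio`` at the end of each round (floored at ``dcut_min``).
    The run stops once ``n_collect`` refined alignments have been
    generated.
    """
    rng = np.random.default_rng(config.rng_seed)
    ctx = ScoreContext(A, B, spec)
    bank = seed_bank(A, B, spec, c, config, ctx=ctx, rng=rng)

    round_no = 0
    while bank.n_generated < config.n_collect:
        round_no += 1
        n_seeds = min(config.n_seeds_per_round, len(bank.members))
        order = sorted(
            range(len(bank.members)), key=lambda k: (bank.last_used[k], k)
        )
        seeds = order[:n_seeds]
        for s in seeds:
            bank.last_used[s] = round_no
            for t in range(config.n_trials_per_seed):
                parent = bank.members[s][0]
                if t % 2 == 0 and len(bank.members) >= 2:
                    others = [k for k in range(len(bank.members)) if k != s]
                    mate = bank.members[others[int(rng.integers(len(others)))]][0]
                    try:
                        child = crossover(parent, mate, c, rng, len(A), len(B))
                    except ConstraintError:
                        child = parent
                else:
                    child = perturb(parent, c, rng, len(A), len(B))
                res = refine(child, A, B, spec, c, ctx=ctx)
                bank.n_generated += 1
                bank_update(bank, res.alignment, res.score)
                if bank.n_generated >= config.n_collect:
                    break
            if bank.n_generated >= config.n_collect:
                break
        bank.dcut = max(bank.dcut * config.dcut_ratio, config.dcut_min)

    idx = sorted(
        range(len(bank.members)),
        key=lambda k: (-bank.members[k][1], bank.members[k][0].pairs),
    )
    bank.members = [bank.members[k] for k in idx]
    bank.last_used = [bank.last_used[k] for k in idx]
    return bank
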