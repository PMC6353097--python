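"""Greedy move-list refinement of a non-sequential alignment.

Best-first local search: build the list of all score-improving moves
(single-pair additions/deletions, whole-block deletions, and — when a
minimum block size is enforced — seed additions of whole
minimum-size blocks), repeatedly take the best one, re-check that it
still improves against the current alignment, accept it, prune list
entries that share a residue with the accepted move, and enumerate
fresh candidates among moves touching the affected residues.  The loop
ends when the list is empty; every accepted move strictly increases
the score, so termination is guaranteed.

Block-seed additions are included because with ``min_block_size > 1``
no single-pair addition can ever create a new aligned region; seeding
whole minimum-size blocks is the minimal completion that lets the
refiner grow new regions, and the seeds are ranked by score delta like
any other move.

Score deltas are computed with a full superposition refit per
candidate move (vectorized over candidates, never approximated).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment import (
    Alignment,
    Constraints,
    blocks_of,
    enforce_constraints,
    validate,
)
from .scoring import ScoreContext, ScoreSpec
from .structures import ProteinChain

__all__ = ["Move", "RefinementResult", "admissible_moves", "refine"]

#: Absolute score-delta threshold below which a move does not count as
#: improving; floating-point refits can oscillate at machine precision.
IMPROVEMENT_TOL = 1e-9

_KIND_ORDER = {"delete_pair": 0, "add_pair": 1, "delete_block": 2, "add_block": 3}


@dataclass(frozen=True)
class Move:
    """One candidate edit of the alignment and its score delta at evaluation time."""

    kind: str  # add_pair | delete_pair | add_block | delete_block
    pairs: tuple[tuple[int, int], ...]
    delta: float

    def sort_key(self):
        # best-first, deterministic: larger delta first, then kind
        # order (delete_pair, add_pair, delete_block, add_block), then
        # lowest (i, j)
        return (-self.delta, _KIND_ORDER[self.kind], self.pairs[0])


@dataclass
class RefinementResult:
    alignment: Alignment
    score: float
    score_trace: list[float] = field(default_factory=list)
    n_accepted: int = 0
    n_evaluated: int = 0


def _apply(pairs: tuple, move_kind: str, move_pairs: tuple) -> tuple:
    if move_kind in ("add_pair", "add_block"):
        return tuple(sorted(pairs + move_pairs))
    removed = set(move_pairs)
    return tuple(p for p in pairs if p not in removed)


def _candidate_edits(
    a: Alignment,
    c: Constraints,
    LA: int,
    LB: int,
    touched: tuple[set, set] | None = None,
) -> list[tuple[str, tuple]]:
    """Enumerate admissible (kind, affected-pairs) edits, pre-validated.

    When ``touched`` (a pair of residue-index sets for chains A and B)
    is given, only edits sharing at least one residue with it are
    produced.
    """
    pairs = a.pairs
    pairset = set(pairs)
    used_i = {i for i, _ in pairs}
    used_j = {j for _, j in pairs}
    blocks = a.blocks()
    mbs = c.min_block_size

    def touches(mv_pairs) -> bool:
        if touched is None:
            return True
        ti, tj = touched
        return any(i in ti or j in tj for i, j in mv_pairs)

    def is_valid(new_pairs) -> bool:
        return not validate(Alignment(new_pairs), c)

    edits: list[tuple[str, tuple]] = []

    # delete_pair: any pair whose removal keeps the decomposition valid
    for p in pairs:
        if not touches((p,)):
            continue
        new = tuple(q for q in pairs if q != p)
        if is_valid(new):
            edits.append(("delete_pair", (p,)))

    # add_pair candidates
    if mbs == 1:
        cand = (
            (i, j)
            for i in range(LA)
            if i not in used_i
            for j in range(LB)
            if j not in used_j
        )
    else:
        # only diagonal/antidiagonal neighbors of existing pairs can
        # extend a block without creating an undersized one
        seen: set[tuple[int, int]] = set()
        cands: list[tuple[int, int]] = []
        for i, j in pairs:
            for di, dj in ((1, 1), (-1, -1), (1, -1), (-1, 1)):
                q = (i + di, j + dj)
                if q in seen:
                    continue
                seen.add(q)
                if 0 <= q[0] < LA and 0 <= q[1] < LB:
                    if q[0] not in used_i and q[1] not in used_j:
                        cands.append(q)
        cand = iter(sorted(cands))
    for q in cand:
        if q[0] in used_i or q[1] in used_j or not touches((q,)):
            continue
        new = tuple(sorted(pairs + (q,)))
        if is_valid(new):
            edits.append(("add_pair", (q,)))

    # delete_block: removing an entire block never shrinks another one
    for b in blocks:
        if touches(b.pairs):
            removed = set(b.pairs)
            new = tuple(p for p in pairs if p not in removed)
            if is_valid(new):
                edits.append(("delete_block", b.pairs))

    # add_block: seed a full run of exactly min_block_size pairs
    if mbs > 1:
        orients = [1, -1] if c.allow_reverse else [1]
        for dj in orients:
            for i0 in range(0, LA - mbs + 1):
                j_range = (
                    range(0, LB - mbs + 1) if dj == 1 else range(mbs - 1, LB)
                )
                for j0 in j_range:
                    run = tuple((i0 + k, j0 + k * dj) for k in range(mbs))
                    if any(i in used_i or j in used_j for i, j in run):
                        continue
                    if not touches(run):
                        continue
                    new = tuple(sorted(pairs + run))
                    if is_valid(new):
                        edits.append(("add_block", run))

    return edits


def _evaluate_edits(
    edits: list[tuple[str, tuple]],
    base_pairs: tuple,
    base_score: float,
    ctx: ScoreContext,
) -> list[Move]:
    """Compute the delta of every edit with a full refit, batched by size."""
    if not edits:
        return []
    groups: dict[int, list[int]] = {}
    new_sets = []
    for idx, (kind, mv_pairs) in enumerate(edits):
        new = _apply(base_pairs, kind, mv_pairs)
        new_sets.append(new)
        groups.setdefault(len(new), []).append(idx)
    deltas = np.empty(len(edits))
    for n, idxs in groups.items():
        if n == 0:
            for idx in idxs:
                deltas[idx] = 0.0 - base_score
            ctx.n_evaluated += len(idxs)
            continue
        ia = np.array([[i for i, _ in new_sets[idx]] for idx in idxs], dtype=np.intp)
        jb = np.array([[j for _, j in new_sets[idx]] for idx in idxs], dtype=np.intp)
        vals = ctx.objective_batch(ia, jb)
        deltas[idxs] = vals - base_score
    return [
        Move(kind, mv_pairs, float(deltas[idx]))
        for idx, (kind, mv_pairs) in enumerate(edits)
    ]


def admissible_moves(
    a: Alignment,
    A: ProteinChain,
    B: ProteinChain,
    spec: ScoreSpec,
    c: Constraints,
    touched: tuple[set, set] | None = None,
) -> list[Move]:
    """All admissible moves from ``a`` with their score deltas, sorted best-first."""
    ctx = ScoreContext(A, B, spec)
    base = ctx.objective(a.pairs)
    edits = _candidate_edits(a, c, len(A), len(B), touched)
    moves = _evaluate_edits(edits, a.pairs, base, ctx)
    return sorted(moves, key=Move.sort_key)


def refine(
    a0: Alignment,
    A: ProteinChain,
    B: ProteinChain,
    spec: ScoreSpec,
    c: Constraints = Constraints(),
    ctx: ScoreContext | None = None,
) -> RefinementResult:
    """Best-first greedy refinement until no score-improving move remains.

    The input is first projected onto the constraint set
    (:func:`enforce_constraints`).  The accepted-move score trace is
    strictly increasing and the final alignment both satisfies the
    constraints and is a fixed point of this procedure.
    """
    a = enforce_constraints(a0, c, len_a=len(A), len_b=len(B))
    if ctx is None:
        ctx = ScoreContext(A, B, spec)
    n_eval_start = ctx.n_evaluated
    cur = ctx.objective(a.pairs)
    trace: list[float] = []
    n_accepted = 0

    edits = _candidate_edits(a, c, ctx.LA, ctx.LB)
    moves = [
        m
        for m in _evaluate_edits(edits, a.pairs, cur, ctx)
        if m.delta > IMPROVEMENT_TOL
    ]
    moves.sort(key=Move.sort_key)

    while moves:
        m = moves.pop(0)
        # the stored delta may be stale: re-check legality and recompute
        if m.kind in ("add_pair", "add_block"):
            if any(p in a.pairs for p in m.pairs):
                continue
        else:
            if not all(p in set(a.pairs) for p in m.pairs):
                continue
        new_pairs = _apply(a.pairs, m.kind, m.pairs)
        new_a = Alignment(new_pairs)
        if validate(new_a, c):
            continue
        new_score = ctx.objective(new_pairs)
        if new_score - cur <= IMPROVEMENT_TOL:
            continue
        # accept
        a = new_a
        cur = new_score
        trace.append(cur)
        n_accepted += 1
        ti = {i for i, _ in m.pairs}
        tj = {j for _, j in m.pairs}
        moves = [
            mm
            for mm in moves
            if not any(i in ti or j in tj for i, j in mm.pairs)
        ]
        # re-enumerate around the change: the affected residues plus
        # their chain neighbors, whose move admissibility (block
        # extension/merging) the accepted move may have altered
        wi = {k for i in ti for k in (i - 1, i, i + 1) if 0 <= k < ctx.LA}
        wj = {k for j in tj for k in (j - 1, j, j + 1) if 0 <= k < ctx.LB}
        fresh_edits = _candidate_edits(a, c, ctx.LA, ctx.LB, touched=(wi, wj))
        present = {(mm.kind, mm.pairs) for mm in moves}
        fresh = [
            mm
            for mm in _evaluate_edits(fresh_edits, a.pairs, cur, ctx)
            if mm.delta > IMPROVEMENT_TOL and (mm.kind, mm.pairs) not in present
        ]
        moves.extend(fresh)
        moves.sort(key=Move.sort_key)

    return RefinementResult(
        alignment=a,
        score=cur,
        score_trace=trace,
        n_accepted=n_accepted,
        n_evaluated=ctx.n_evaluated - n_eval_start,
    )
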