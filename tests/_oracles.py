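"""Independent test oracles.

Everything here is deliberately written without reference to the
package's own implementation paths: brute-force double loops, explicit
enumeration, and a quaternion-parameterized numerical minimizer, so
the main code can be checked against genuinely independent
computations.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize

from nsalign.alignment import Alignment, Constraints, validate


# ---------------------------------------------------------------------------
# Quaternion-grid + polish RMSD minimizer (independent of Kabsch)
# ---------------------------------------------------------------------------


def _quat_to_rot(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    q = q / np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def brute_force_rmsd(P: np.ndarray, Q: np.ndarray, n_starts: int = 300, seed: int = 0) -> float:
    """Minimum RMSD over proper rotations, by quaternion sampling + polish.

    For each rotation the optimal translation matches the centroids, so
    the objective reduces to a function of the unit quaternion alone.
    Random starts followed by Nelder-Mead polish from the best few.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    n = len(P)

    def cost(q: np.ndarray) -> float:
        R = _quat_to_rot(q)
        dev = Pc - Qc @ R.T
        return float(np.sum(dev * dev)) / n

    rng = np.random.default_rng(seed)
    quats = rng.normal(size=(n_starts, 4))
    costs = np.array([cost(q) for q in quats])
    best = np.inf
    for k in np.argsort(costs)[:5]:
        res = minimize(
            cost,
            quats[k],
            method="Nelder-Mead",
            options={"xatol": 1e-12, "fatol": 1e-16, "maxiter": 5000},
        )
        best = min(best, res.fun)
    return float(np.sqrt(best))


# ---------------------------------------------------------------------------
# Brute-force score evaluators (direct double loops)
# ---------------------------------------------------------------------------


def dali_double_loop(
    pairs, DA: np.ndarray, DB: np.ndarray, d0: float = 20.0, envelope: str = "deviation"
) -> float:
    total = 0.0
    for i1, j1 in pairs:
        for i2, j2 in pairs:
            if i1 == i2:
                total += 0.2
                continue
            da = DA[i1, i2]
            db = DB[j1, j2]
            mean = (da + db) / 2.0
            dev = abs(da - db)
            ratio = dev / mean if mean > 0 else 0.0
            arg = dev if envelope == "deviation" else mean
            total += (0.2 - ratio) * np.exp(-(arg**2) / d0**2)
    return total


def sp_direct(pairs, coords_a, coords_b, devs, d0: float = 4.0, alpha: float = 0.3) -> float:
    """SP-score from precomputed per-pair deviations, all loops explicit."""
    total = 0.0
    core = []
    for (i, j), d in zip(pairs, devs):
        if d < 2 * d0:
            total += 1.0 / (1.0 + (d / d0) ** 2) - 0.2
        if d <= 2 * d0:
            core.append((i, j))
    if not core:
        return 0.0
    core_i = {i for i, _ in core}
    core_j = {j for _, j in core}

    def neighbors(coords, core_idx):
        count = 0
        for r in range(len(coords)):
            if r in core_idx:
                continue
            for s in core_idx:
                if np.linalg.norm(coords[r] - coords[s]) <= 3 * d0:
                    count += 1
                    break
        return count

    L = len(core) + 0.5 * (neighbors(coords_a, core_i) + neighbors(coords_b, core_j))
    return total / (3.0 * L ** (1.0 - alpha))


# ---------------------------------------------------------------------------
# Exhaustive enumeration of constraint-satisfying alignments (tiny chains)
# ---------------------------------------------------------------------------


def all_block_placements(LA: int, LB: int, min_size: int, allow_reverse: bool):
    """Every forward/reverse run of length >= min_size that fits the chains."""
    out = []
    for length in range(min_size, min(LA, LB) + 1):
        for i0 in range(LA - length + 1):
            for j0 in range(LB - length + 1):
                out.append(tuple((i0 + k, j0 + k) for k in range(length)))
            if allow_reverse:
                for j0 in range(length - 1, LB):
                    out.append(tuple((i0 + k, j0 - k) for k in range(length)))
    return out


def enumerate_valid_alignments(
    LA: int, LB: int, c: Constraints
) -> set[frozenset]:
    """All constraint-satisfying alignments (as frozen pair sets, incl. empty).

    Valid alignments are unions of compatible block placements; the
    recursion enumerates those unions and dedupes, then re-validates
    each pair set against the constraints.  Feasible only for tiny
    chains (L <= ~8).
    """
    blocks = all_block_placements(LA, LB, c.min_block_size, c.allow_reverse)
    if c.min_block_size == 1:
        # singletons are included above as length-1 "runs"
        pass
    seen: set[frozenset] = {frozenset()}

    def rec(start: int, pairs: set, used_i: set, used_j: set) -> None:
        for k in range(start, len(blocks)):
            b = blocks[k]
            bi = {i for i, _ in b}
            bj = {j for _, j in b}
            if used_i & bi or used_j & bj:
                continue
            new = pairs | set(b)
            fs = frozenset(new)
            if fs not in seen and not validate(Alignment(new), c):
                seen.add(fs)
            rec(k + 1, new, used_i | bi, used_j | bj)

    rec(0, set(), set(), set())
    return seen


def exhaustive_best_score(ctx, LA: int, LB: int, c: Constraints) -> float:
    """Max objective over every constraint-satisfying alignment."""
    return max(
        ctx.objective(tuple(sorted(fs)))
        for fs in enumerate_valid_alignments(LA, LB, c)
    )


def hill_climb_local_optima(ctx, LA: int, LB: int, c: Constraints) -> set[float]:
    """Scores of all local optima of exhaustive single-step hill climbing.

    A state is locally optimal when no constraint-valid single edit
    improves the objective, where the edits are: add one pair; delete
    one pair; add one contiguous run of exactly ``min_block_size``
    pairs; delete one whole block.  Used to sanity-check that the
    refiner always lands on a member of this set for tiny instances.
    """
    from nsalign.alignment import blocks_of

    states = enumerate_valid_alignments(LA, LB, c)
    scores = {fs: ctx.objective(tuple(sorted(fs))) for fs in states}

    def is_single_edit(fs: frozenset, other: frozenset) -> bool:
        if fs < other:
            added = other - fs
            if len(added) == 1:
                return True
            if len(added) == c.min_block_size > 1:
                runs = blocks_of(Alignment(added))
                return len(runs) == 1  # the addition is one contiguous run
            return False
        if other < fs:
            removed = fs - other
            if len(removed) == 1:
                return True
            block_sets = {frozenset(b.pairs) for b in blocks_of(Alignment(fs))}
            return frozenset(removed) in block_sets
        return False

    optima: set[float] = set()
    for fs, sc in scores.items():
        improvable = any(
            scores[other] > sc + 1e-9 and is_single_edit(fs, other)
            for other in states
            if other != fs
        )
        if not improvable:
            optima.add(round(sc, 12))
    return optima
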