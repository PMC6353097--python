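"""Non-sequential alignment model.

An alignment between two chains is a one-to-one set of residue index
pairs ``(i, j)`` — residue *i* of chain A matched to residue *j* of
chain B — with no requirement that the pairing preserve chain order.
The pair set decomposes uniquely (given the tie rule below) into
*blocks*: maximal runs of pairs consecutive in both chains.  Forward
blocks advance both indices (``(i+1, j+1)`` follows ``(i, j)``); reverse
blocks advance A while B retreats (``(i+1, j-1)``), i.e. one segment is
matched against the other chain traversed C→N.

Two user-facing constraints shape the search space:

* ``min_block_size`` — forbid blocks smaller than a given size, which
  suppresses heavily fragmented alignments of dubious biological
  meaning;
* ``allow_reverse`` — whether reverse blocks (of size >= 2) are legal
  at all.  A single pair has no direction and is forward by convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

__all__ = [
    "Alignment",
    "Block",
    "Constraints",
    "ConstraintError",
    "blocks_of",
    "validate",
    "enforce_constraints",
    "alignment_distance",
    "read_alignment_tsv",
    "write_alignment_tsv",
]

FORWARD = "forward"
REVERSE = "reverse"


class ConstraintError(ValueError):
    """Raised when no nonempty constraint-satisfying alignment can be produced."""


@dataclass(frozen=True)
class Block:
    """A maximal run of aligned pairs consecutive in both chains."""

    pairs: tuple[tuple[int, int], ...]
    orientation: str  # "forward" | "reverse"

    @property
    def size(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class Constraints:
    """Minimum block size and reverse-alignment permission."""

    min_block_size: int = 1
    allow_reverse: bool = True

    def __post_init__(self) -> None:
        if self.min_block_size < 1:
            raise ValueError("min_block_size must be >= 1")


class Alignment:
    """An immutable one-to-one set of residue index pairs.

    Pairs are stored sorted by ``(i, j)``.  ``n`` (the match length) is
    the number of pairs.  Equality and hashing are by pair set.
    """

    __slots__ = ("pairs", "_blocks")

    def __init__(self, pairs: Iterable[tuple[int, int]] = ()):
        ps = tuple(sorted((int(i), int(j)) for i, j in pairs))
        seen_i: set[int] = set()
        seen_j: set[int] = set()
        for i, j in ps:
            if i < 0 or j < 0:
                raise ValueError(f"negative residue index in pair ({i}, {j})")
            if i in seen_i or j in seen_j:
                raise ValueError(f"alignment is not one-to-one at pair ({i}, {j})")
            seen_i.add(i)
            seen_j.add(j)
        self.pairs = ps
        self._blocks: list[Block] | None = None

    @property
    def n(self) -> int:
        """Match length: the number of aligned residue pairs."""
        return len(self.pairs)

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self) -> Iterator[tuple[int, int]]:
        return iter(self.pairs)

    def __contains__(self, pair: tuple[int, int]) -> bool:
        return pair in set(self.pairs)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Alignment) and self.pairs == other.pairs

    def __hash__(self) -> int:
        return hash(self.pairs)

    def __repr__(self) -> str:
        return f"Alignment(n={self.n})"

    def blocks(self) -> list[Block]:
        if self._blocks is None:
            self._blocks = blocks_of(self)
        return self._blocks


def blocks_of(a: Alignment) -> list[Block]:
    """Decompose an alignment into maximal oriented blocks.

    Runs are grown greedily in increasing ``i``, trying forward
    continuation before reverse; a singleton run is forward by
    convention.  The decomposition is deterministic and partitions the
    pair set exactly.
    """
    unassigned = set(a.pairs)
    blocks: list[Block] = []
    for p in a.pairs:  # ascending (i, j)
        if p not in unassigned:
            continue
        unassigned.discard(p)
        run = [p]
        while (run[-1][0] + 1, run[-1][1] + 1) in unassigned:
            q = (run[-1][0] + 1, run[-1][1] + 1)
            run.append(q)
            unassigned.discard(q)
        orientation = FORWARD
        if len(run) == 1:
            while (run[-1][0] + 1, run[-1][1] - 1) in unassigned:
                q = (run[-1][0] + 1, run[-1][1] - 1)
                run.append(q)
                unassigned.discard(q)
            if len(run) > 1:
                orientation = REVERSE
        blocks.append(Block(tuple(run), orientation))
    return blocks


def validate(a: Alignment, c: Constraints) -> list[str]:
    """Return a list of human-readable constraint violations (empty = valid)."""
    violations: list[str] = []
    for b in a.blocks():
        if b.size < c.min_block_size:
            violations.append(
                f"block starting at {b.pairs[0]} has size {b.size} "
                f"< min_block_size {c.min_block_size}"
            )
        if b.orientation == REVERSE and b.size >= 2 and not c.allow_reverse:
            violations.append(
                f"reverse block starting at {b.pairs[0]} (size {b.size}) "
                "but reverse alignment is not allowed"
            )
    return violations


def enforce_constraints(
    a: Alignment,
    c: Constraints,
    len_a: int | None = None,
    len_b: int | None = None,
) -> Alignment:
    """Project an alignment onto the constraint-satisfying set.

    Procedure, with the two fallbacks used when a removal step would
    empty the alignment:

    1. If reverse blocks are forbidden, delete them; if nothing
       survives, keep instead one pair per original block, taken at the
       block center.
    2. Delete blocks smaller than ``min_block_size``; if nothing
       survives, extend every block of the largest block size to
       ``min_block_size`` (symmetrically around the block, preferring
       the C-terminal side on odd remainders, dropping extension
       positions that hit chain bounds or one-to-one conflicts).
       ``len_a`` / ``len_b``, when given, bound the extension at the
       C-terminal chain ends.

    Raises :class:`ConstraintError` if both fallbacks fail to yield a
    nonempty valid alignment.  The empty alignment passes through
    unchanged (it has no blocks, hence no violations).  Idempotent on
    its own output.
    """
    if a.n == 0:
        return a
    work = a
    if not c.allow_reverse:
        blocks = work.blocks()
        kept = [p for b in blocks if b.orientation == FORWARD for p in b.pairs]
        if not kept:
            kept = [b.pairs[b.size // 2] for b in blocks]
        work = Alignment(kept)
    if c.min_block_size > 1:
        blocks = work.blocks()
        big = [b for b in blocks if b.size >= c.min_block_size]
        if big:
            work = Alignment([p for b in big for p in b.pairs])
        else:
            work = _extend_largest_blocks(work, c, len_a, len_b)
    if work.n == 0 or validate(work, c):
        raise ConstraintError(
            "could not produce a nonempty constraint-satisfying alignment"
        )
    return work


def _extend_largest_blocks(
    a: Alignment,
    c: Constraints,
    len_a: int | None = None,
    len_b: int | None = None,
) -> Alignment:
    """Fallback: grow every largest block of ``a`` to ``min_block_size``."""
    blocks = a.blocks()
    smax = max(b.size for b in blocks)
    targets = [b for b in blocks if b.size == smax]
    used_i = {i for b in targets for i, _ in b.pairs}
    used_j = {j for b in targets for _, j in b.pairs}
    out_pairs: list[tuple[int, int]] = [p for b in targets for p in b.pairs]

    for b in targets:
        need = c.min_block_size - b.size
        if need <= 0:
            continue
        dj = 1 if b.orientation == FORWARD else -1
        lo = b.pairs[0]
        hi = b.pairs[-1]
        # alternate sides starting C-terminal (so odd remainders favor
        # it); a blocked side falls through to the other side
        prefer_c = True
        while need > 0:
            cand_c = (hi[0] + 1, hi[1] + dj)
            cand_n = (lo[0] - 1, lo[1] - dj)
            order = (
                (("C", cand_c), ("N", cand_n))
                if prefer_c
                else (("N", cand_n), ("C", cand_c))
            )
            placed = False
            for side, cand in order:
                if _try_place(cand, used_i, used_j, len_a, len_b):
                    out_pairs.append(cand)
                    if side == "C":
                        hi = cand
                        prefer_c = False
                    else:
                        lo = cand
                        prefer_c = True
                    need -= 1
                    placed = True
                    break
            if not placed:
                break

    result = Alignment(out_pairs)
    survivors = [
        p for b in result.blocks() if b.size >= c.min_block_size for p in b.pairs
    ]
    return Alignment(survivors)


def _try_place(
    pair: tuple[int, int],
    used_i: set[int],
    used_j: set[int],
    len_a: int | None,
    len_b: int | None,
) -> bool:
    i, j = pair
    if i < 0 or j < 0 or i in used_i or j in used_j:
        return False
    if (len_a is not None and i >= len_a) or (len_b is not None and j >= len_b):
        return False
    used_i.add(i)
    used_j.add(j)
    return True


def alignment_distance(a: Alignment, b: Alignment) -> float:
    """Normalized-overlap distance between two alignments in [0, 1].

    ``1 - |a ∩ b| / max(|a|, |b|)``: 0 iff the pair sets are identical
    (two empty alignments have distance 0), 1 for disjoint pair sets and
    for anything compared with the empty alignment.  Symmetric.  Used as
    the solution-space metric for the annealed diversity cutoff.
    """
    if a.n == 0 and b.n == 0:
        return 0.0
    if a.n == 0 or b.n == 0:
        return 1.0
    overlap = len(set(a.pairs) & set(b.pairs))
    return 1.0 - overlap / max(a.n, b.n)


# ---------------------------------------------------------------------------
# TSV I/O
#
# Format (bit-exact writer):
#   #chainA <id> L=<n>
#   #chainB <id> L=<n>
#   i<TAB>j          one line per pair, 0-based
# Comment lines start with '#'.  The reader also accepts 1-based files
# via ``one_based=True``.
# ---------------------------------------------------------------------------


def write_alignment_tsv(
    path: str | Path,
    a: Alignment,
    *,
    chain_a_id: str = "A",
    chain_b_id: str = "B",
    len_a: int | None = None,
    len_b: int | None = None,
) -> None:
    """Write an alignment in the documented pair-list TSV format."""
    lines = []
    la = len_a if len_a is not None else (max((i for i, _ in a.pairs), default=-1) + 1)
    lb = len_b if len_b is not None else (max((j for _, j in a.pairs), default=-1) + 1)
    lines.append(f"#chainA {chain_a_id} L={la}")
    lines.append(f"#chainB {chain_b_id} L={lb}")
    for i, j in a.pairs:
        lines.append(f"{i}\t{j}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_alignment_tsv(
    path: str | Path, *, one_based: bool = False
) -> tuple[Alignment, dict]:
    """Read a pair-list TSV; returns the alignment and header metadata."""
    meta: dict = {}
    pairs: list[tuple[int, int]] = []
    offset = 1 if one_based else 0
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            fields = line[1:].split()
            if len(fields) >= 2 and fields[0] in ("chainA", "chainB"):
                entry = {"id": fields[1]}
                for f in fields[2:]:
                    if f.startswith("L="):
                        entry["L"] = int(f[2:])
                meta[fields[0]] = entry
            continue
        cols = line.split("\t") if "\t" in line else line.split()
        if len(cols) != 2:
            raise ValueError(f"{path}:{lineno}: expected two columns, got {line!r}")
        pairs.append((int(cols[0]) - offset, int(cols[1]) - offset))
    return Alignment(pairs), meta
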