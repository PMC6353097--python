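"""Alignment-quality metrics: summaries, precision/recall, Pareto dominance.

The quality of a structure alignment has two primary axes — the match
length ``n`` and the RMSD of the aligned Cα subsets — which trade off
against each other.  Alignment X *Pareto dominates* Y when X is at
least as long and at most as deviant, strictly better in one; only
then can X be called unambiguously better.  Against a curated
reference alignment, precision (fraction of test pairs present in the
reference) and recall (fraction of reference pairs recovered) measure
biological agreement; pair matching is exact — an off-by-one pairing
earns no credit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .alignment import Alignment
from .scoring import (
    ScoreSpec,
    dali_score,
    so_logistic,
    so_score,
    sp_score,
    tm_score,
)
from .structures import ProteinChain, distance_matrix
from .superposition import aligned_rmsd, mirror_rmsd

__all__ = ["AlignmentSummary", "summarize", "precision_recall", "pareto_compare"]


@dataclass
class AlignmentSummary:
    n: int
    rmsd: float
    mirror_rmsd: float
    scores: dict[str, float] = field(default_factory=dict)
    block_sizes: list[int] = field(default_factory=list)
    n_reverse_blocks: int = 0


def summarize(
    a: Alignment, A: ProteinChain, B: ProteinChain, spec: ScoreSpec | None = None
) -> AlignmentSummary:
    """Full quality summary: n, RMSD, mirror RMSD, all five scores, block stats."""
    if a.n == 0:
        raise ValueError("cannot summarize an empty alignment")
    base = spec or ScoreSpec()
    DA, DB = distance_matrix(A), distance_matrix(B)
    blocks = a.blocks()
    return AlignmentSummary(
        n=a.n,
        rmsd=aligned_rmsd(a, A, B),
        mirror_rmsd=mirror_rmsd(a, A, B),
        scores={
            "dali": dali_score(a, DA, DB, base),
            "sp": sp_score(a, A, B, base),
            "so": so_score(a, A, B, base),
            "so_l": so_logistic(a, A, B, base),
            "tm": tm_score(a, A, B, base),
        },
        block_sizes=[b.size for b in blocks],
        n_reverse_blocks=sum(1 for b in blocks if b.orientation == "reverse"),
    )


def precision_recall(
    test: Alignment, reference: Alignment
) -> tuple[float, float]:
    """Exact-pair precision and recall of a test alignment against a reference.

    TP counts identical ``(i, j)`` pairs.  Degenerate conventions: an
    empty test has precision 0 unless the reference is also empty (then
    1); an empty reference gives recall 1 for an empty test, else 0.
    """
    t = set(test.pairs)
    r = set(reference.pairs)
    tp = len(t & r)
    if not t:
        precision = 1.0 if not r else 0.0
    else:
        precision = tp / len(t)
    if not r:
        recall = 1.0 if not t else 0.0
    else:
        recall = tp / len(r)
    return precision, recall


def pareto_compare(s1: AlignmentSummary, s2: AlignmentSummary) -> str:
    """Compare two summaries on (match length, RMSD).

    Returns ``"first_wins"``, ``"second_wins"``, ``"tie"`` (both equal)
    or ``"incomparable"`` (the usual longer-but-worse-RMSD trade-off).
    """
    if s1.n == s2.n and s1.rmsd == s2.rmsd:
        return "tie"
    if s1.n >= s2.n and s1.rmsd <= s2.rmsd:
        return "first_wins"
    if s2.n >= s1.n and s2.rmsd <= s1.rmsd:
        return "second_wins"
    return "incomparable"
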