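"""Alignment scoring functions: DALI, SP, SO / SO_L, and TM.

Given an alignment of ``n`` residue pairs between chains A and B:

* **DALI** compares internal Cα–Cα distance matrices only — no
  superposition is performed.  Each ordered pair of aligned positions
  contributes ``(0.2 - |dA - dB| / d̄) · w`` (0.2 on the diagonal),
  where ``d̄ = (dA + dB) / 2`` and the envelope ``w`` is either
  ``exp(-|dA - dB|² / d0²)`` (the "deviation" variant, the default) or
  ``exp(-d̄² / d0²)`` (the classic "mean_distance" elastic weight), with
  ``d0 = 20 Å``.  Because only internal distances enter, the score is
  blind to chirality: mirroring either chain leaves it unchanged.

* **SP** superposes the aligned subsets and sums
  ``1/(1 + (d/d0)²) - 0.2`` over pairs with deviation ``d < 2·d0``
  (``d0 = 4 Å``), normalized by ``3·L^(1-α)`` with ``α = 0.3``.  ``L``
  counts the core residues (aligned pairs with ``d ≤ 2·d0``) plus the
  two-chain average number of neighboring residues — non-core residues
  within ``3·d0`` of any core Cα in their own chain.

* **SO** (structure overlap) is the fraction of aligned pairs within
  ``d0 = 3.5 Å`` after superposition, normalized by ``min(L_A, L_B)``.
  Its gradient is zero almost everywhere, so optimization uses the
  logistic surrogate **SO_L**, ``Σ [1 - 1/(1+exp(-k(d-d0)))]`` with
  ``k = 10 Å⁻¹``; final reports re-evaluate the original SO.

* **TM** sums ``1/(1 + (d/d0_TM)²)`` over aligned pairs with
  ``d0_TM = 1.24·(L_N - 15)^(1/3) - 1.8`` (clamped below at 0.5 Å for
  short chains), normalized by ``L_N`` = the length of chain A, chain
  B, or — the default optimization objective — the average of both
  normalized values.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.special import expit

from .alignment import Alignment
from .structures import ProteinChain, distance_matrix

__all__ = [
    "ScoreSpec",
    "dali_score",
    "sp_score",
    "so_score",
    "so_logistic",
    "tm_score",
    "score",
    "ScoreContext",
]

FUNCTIONS = ("dali", "sp", "so", "so_l", "tm")


@dataclass(frozen=True)
class ScoreSpec:
    """Which scoring function to use, with its constants.

    Defaults are the standard literature values; ``tm_normalization``
    selects which chain length normalizes the TM sum and
    ``dali_envelope`` selects the exponential envelope variant.
    """

    function: str = "tm"
    d0_dali: float = 20.0
    d0_sp: float = 4.0
    alpha: float = 0.3
    d0_so: float = 3.5
    k: float = 10.0
    tm_normalization: str = "average"  # "A" | "B" | "average"
    dali_envelope: str = "deviation"  # "deviation" | "mean_distance"

    def __post_init__(self) -> None:
        fn = self.function.lower()
        if fn not in FUNCTIONS:
            raise ValueError(f"unknown scoring function {self.function!r}")
        object.__setattr__(self, "function", fn)
        for name in ("d0_dali", "d0_sp", "d0_so"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.tm_normalization not in ("A", "B", "average"):
            raise ValueError(f"bad tm_normalization {self.tm_normalization!r}")
        if self.dali_envelope not in ("deviation", "mean_distance"):
            raise ValueError(f"bad dali_envelope {self.dali_envelope!r}")


def _pair_indices(a: Alignment) -> tuple[np.ndarray, np.ndarray]:
    ia = np.fromiter((i for i, _ in a.pairs), dtype=np.intp, count=a.n)
    jb = np.fromiter((j for _, j in a.pairs), dtype=np.intp, count=a.n)
    return ia, jb


# ---------------------------------------------------------------------------
# DALI
# ---------------------------------------------------------------------------


def _dali_kernel(
    ia: np.ndarray, jb: np.ndarray, DA: np.ndarray, DB: np.ndarray, spec: ScoreSpec
) -> float:
    n = len(ia)
    if n == 0:
        return 0.0
    dA = DA[np.ix_(ia, ia)]
    dB = DB[np.ix_(jb, jb)]
    diff = np.abs(dA - dB)
    mean = 0.5 * (dA + dB)
    safe = np.where(mean > 0, mean, 1.0)
    ratio = np.where(mean > 0, diff / safe, 0.0)
    if spec.dali_envelope == "deviation":
        w = np.exp(-(diff * diff) / spec.d0_dali**2)
    else:
        w = np.exp(-(mean * mean) / spec.d0_dali**2)
    terms = (0.2 - ratio) * w
    off = float(terms.sum() - np.trace(terms))
    return off + 0.2 * n


def dali_score(
    a: Alignment, DA: np.ndarray, DB: np.ndarray, spec: ScoreSpec | None = None
) -> float:
    """DALI elastic similarity score from the two internal distance matrices."""
    spec = spec or ScoreSpec(function="dali")
    ia, jb = _pair_indices(a)
    return _dali_kernel(ia, jb, np.asarray(DA), np.asarray(DB), spec)


# ---------------------------------------------------------------------------
# Superposition-based scores
# ---------------------------------------------------------------------------


def _fit_deviations(
    ia: np.ndarray, jb: np.ndarray, ca: np.ndarray, cb: np.ndarray
) -> np.ndarray:
    """Per-pair Cα deviations (Å) after the least-RMSD proper superposition."""
    from .superposition import kabsch

    sup = kabsch(ca[ia], cb[jb])
    dev = ca[ia] - sup.apply(cb[jb])
    return np.linalg.norm(dev, axis=1)


def _sp_kernel(
    ia: np.ndarray,
    jb: np.ndarray,
    d: np.ndarray,
    DA: np.ndarray,
    DB: np.ndarray,
    spec: ScoreSpec,
) -> float:
    d0 = spec.d0_sp
    # summation uses strict <, core membership uses <=, as printed
    in_sum = d < 2.0 * d0
    total = float((1.0 / (1.0 + (d[in_sum] / d0) ** 2) - 0.2).sum())
    core = d <= 2.0 * d0
    n_core = int(core.sum())
    if n_core == 0:
        return 0.0
    core_i = ia[core]
    core_j = jb[core]
    nbr_a = _neighbor_count(DA, core_i, 3.0 * d0)
    nbr_b = _neighbor_count(DB, core_j, 3.0 * d0)
    L = n_core + 0.5 * (nbr_a + nbr_b)
    if L <= 0:
        return 0.0
    return total / (3.0 * L ** (1.0 - spec.alpha))


def _neighbor_count(D: np.ndarray, core_idx: np.ndarray, cutoff: float) -> int:
    """Non-core residues of one chain within ``cutoff`` of any core Cα."""
    mask = np.zeros(len(D), dtype=bool)
    mask[core_idx] = True
    if mask.all():
        return 0
    near = (D[~mask][:, core_idx] <= cutoff).any(axis=1)
    return int(near.sum())


def sp_score(
    a: Alignment, A: ProteinChain, B: ProteinChain, spec: ScoreSpec | None = None
) -> float:
    """SP-score of an alignment (superposition-based, size-normalized)."""
    if a.n == 0:
        raise ValueError("SP-score is undefined for an empty alignment")
    spec = spec or ScoreSpec(function="sp")
    ia, jb = _pair_indices(a)
    d = _fit_deviations(ia, jb, A.coords, B.coords)
    return _sp_kernel(ia, jb, d, distance_matrix(A), distance_matrix(B), spec)


def so_score(
    a: Alignment, A: ProteinChain, B: ProteinChain, spec: ScoreSpec | None = None
) -> float:
    """Structure overlap: fraction of aligned pairs within d0 after superposition."""
    spec = spec or ScoreSpec(function="so")
    if a.n == 0:
        return 0.0
    ia, jb = _pair_indices(a)
    d = _fit_deviations(ia, jb, A.coords, B.coords)
    return float((d <= spec.d0_so).sum()) / min(len(A), len(B))


def so_logistic(
    a: Alignment, A: ProteinChain, B: ProteinChain, spec: ScoreSpec | None = None
) -> float:
    """Logistic surrogate of the SO-score (smooth, optimizable)."""
    spec = spec or ScoreSpec(function="so_l")
    if a.n == 0:
        return 0.0
    ia, jb = _pair_indices(a)
    d = _fit_deviations(ia, jb, A.coords, B.coords)
    return float(expit(-spec.k * (d - spec.d0_so)).sum()) / min(len(A), len(B))


def tm_d0(L_N: int) -> float:
    """TM-score distance scale; clamped at 0.5 Å where the formula degenerates."""
    return max(1.24 * float(np.cbrt(L_N - 15)) - 1.8, 0.5)


def tm_score(
    a: Alignment, A: ProteinChain, B: ProteinChain, spec: ScoreSpec | None = None
) -> float:
    """TM-score under the spec's normalization mode (A, B, or their average)."""
    spec = spec or ScoreSpec(function="tm")
    if a.n == 0:
        return 0.0
    ia, jb = _pair_indices(a)
    d = _fit_deviations(ia, jb, A.coords, B.coords)
    return _tm_from_devs(d, len(A), len(B), spec.tm_normalization)


def _tm_from_devs(d: np.ndarray, LA: int, LB: int, mode: str) -> float:
    def one(LN: int) -> float:
        d0 = tm_d0(LN)
        return float((1.0 / (1.0 + (d / d0) ** 2)).sum()) / LN

    if mode == "A":
        return one(LA)
    if mode == "B":
        return one(LB)
    return 0.5 * (one(LA) + one(LB))


def score(
    a: Alignment, A: ProteinChain, B: ProteinChain, spec: ScoreSpec
) -> float:
    """Dispatch to the requested scoring function.

    The DALI path needs only the internal distance matrices; all other
    paths perform a Kabsch fit of the aligned subsets first.
    """
    fn = spec.function
    if fn == "dali":
        return dali_score(a, distance_matrix(A), distance_matrix(B), spec)
    if fn == "sp":
        return sp_score(a, A, B, spec)
    if fn == "so":
        return so_score(a, A, B, spec)
    if fn == "so_l":
        return so_logistic(a, A, B, spec)
    if fn == "tm":
        return tm_score(a, A, B, spec)
    raise ValueError(f"unknown scoring function {fn!r}")


def score_report(
    a: Alignment, A: ProteinChain, B: ProteinChain, spec: ScoreSpec
) -> dict:
    """Key-value score report (JSON-ready): value, n, rmsd, TM per normalization."""
    from .superposition import aligned_rmsd, mirror_rmsd

    report = {
        "function": spec.function,
        "dali_envelope": spec.dali_envelope,
        "n": a.n,
        "value": score(a, A, B, spec) if a.n else 0.0,
    }
    if a.n:
        report["rmsd"] = aligned_rmsd(a, A, B)
        report["mirror_rmsd"] = mirror_rmsd(a, A, B)
        report["tm_A"] = tm_score(a, A, B, replace(spec, function="tm", tm_normalization="A"))
        report["tm_B"] = tm_score(a, A, B, replace(spec, function="tm", tm_normalization="B"))
    return report


# ---------------------------------------------------------------------------
# ScoreContext: cached + batched evaluation for the optimizers
# ---------------------------------------------------------------------------

_CHUNK = 256


class ScoreContext:
    """Precomputed evaluation context for one chain pair and one ScoreSpec.

    ``objective`` is the quantity the optimizers maximize: for
    ``function="so"`` it is the logistic surrogate SO_L (the original SO
    is re-evaluated for final reports); for ``function="tm"`` it follows
    ``tm_normalization`` (default: the A/B average).  Empty alignments
    score 0 under every objective — the refiner may transiently produce
    them.

    ``objective_batch`` evaluates many same-length candidate alignments
    at once, each with its own full Kabsch refit (vectorized 3×3 SVD);
    this is the exact same computation as ``objective``, chunked for
    memory, not an approximation.
    """

    def __init__(self, A: ProteinChain, B: ProteinChain, spec: ScoreSpec):
        self.A = A
        self.B = B
        self.spec = spec
        self.ca = A.coords
        self.cb = B.coords
        self.LA = len(A)
        self.LB = len(B)
        self._DA: np.ndarray | None = None
        self._DB: np.ndarray | None = None
        if spec.function in ("dali", "sp"):
            self._DA = distance_matrix(A)
            self._DB = distance_matrix(B)
        self.n_evaluated = 0

    @property
    def DA(self) -> np.ndarray:
        if self._DA is None:
            self._DA = distance_matrix(self.A)
        return self._DA

    @property
    def DB(self) -> np.ndarray:
        if self._DB is None:
            self._DB = distance_matrix(self.B)
        return self._DB

    def objective(self, pairs) -> float:
        """Objective value of a pair set (tuple/list of (i, j))."""
        self.n_evaluated += 1
        pairs = tuple(pairs)
        if not pairs:
            return 0.0
        ia = np.fromiter((i for i, _ in pairs), dtype=np.intp, count=len(pairs))
        jb = np.fromiter((j for _, j in pairs), dtype=np.intp, count=len(pairs))
        fn = self.spec.function
        if fn == "dali":
            return _dali_kernel(ia, jb, self.DA, self.DB, self.spec)
        d = _fit_deviations(ia, jb, self.ca, self.cb)
        if fn == "sp":
            return _sp_kernel(ia, jb, d, self.DA, self.DB, self.spec)
        if fn == "so":
            return float(expit(-self.spec.k * (d - self.spec.d0_so)).sum()) / min(
                self.LA, self.LB
            )
        if fn == "so_l":
            return float(expit(-self.spec.k * (d - self.spec.d0_so)).sum()) / min(
                self.LA, self.LB
            )
        return _tm_from_devs(d, self.LA, self.LB, self.spec.tm_normalization)

    def final_score(self, a: Alignment) -> float:
        """The reportable score: identical to ``objective`` except that
        ``function="so"`` re-evaluates the original (counting) SO."""
        if a.n == 0:
            return 0.0
        return score(a, self.A, self.B, self.spec)

    # -- batched path --------------------------------------------------

    def objective_batch(self, ia: np.ndarray, jb: np.ndarray) -> np.ndarray:
        """Objective for M candidate alignments given as (M, n) index arrays."""
        ia = np.asarray(ia, dtype=np.intp)
        jb = np.asarray(jb, dtype=np.intp)
        M, n = ia.shape
        self.n_evaluated += M
        if n == 0:
            return np.zeros(M)
        fn = self.spec.function
        out = np.empty(M)
        for lo in range(0, M, _CHUNK):
            hi = min(lo + _CHUNK, M)
            if fn == "dali":
                out[lo:hi] = self._dali_batch(ia[lo:hi], jb[lo:hi])
            elif fn == "sp":
                for m in range(lo, hi):
                    d = _fit_deviations(ia[m], jb[m], self.ca, self.cb)
                    out[m] = _sp_kernel(ia[m], jb[m], d, self.DA, self.DB, self.spec)
            else:
                d = _batch_deviations(self.ca[ia[lo:hi]], self.cb[jb[lo:hi]])
                if fn in ("so", "so_l"):
                    out[lo:hi] = expit(-self.spec.k * (d - self.spec.d0_so)).sum(
                        axis=1
                    ) / min(self.LA, self.LB)
                else:  # tm
                    out[lo:hi] = self._tm_batch(d)
        return out

    def _dali_batch(self, ia: np.ndarray, jb: np.ndarray) -> np.ndarray:
        dA = self.DA[ia[:, :, None], ia[:, None, :]]
        dB = self.DB[jb[:, :, None], jb[:, None, :]]
        diff = np.abs(dA - dB)
        mean = 0.5 * (dA + dB)
        safe = np.where(mean > 0, mean, 1.0)
        ratio = np.where(mean > 0, diff / safe, 0.0)
        if self.spec.dali_envelope == "deviation":
            w = np.exp(-(diff * diff) / self.spec.d0_dali**2)
        else:
            w = np.exp(-(mean * mean) / self.spec.d0_dali**2)
        terms = (0.2 - ratio) * w
        n = ia.shape[1]
        off = terms.sum(axis=(1, 2)) - np.trace(terms, axis1=1, axis2=2)
        return off + 0.2 * n

    def _tm_batch(self, d: np.ndarray) -> np.ndarray:
        mode = self.spec.tm_normalization

        def one(LN: int) -> np.ndarray:
            d0 = tm_d0(LN)
            return (1.0 / (1.0 + (d / d0) ** 2)).sum(axis=1) / LN

        if mode == "A":
            return one(self.LA)
        if mode == "B":
            return one(self.LB)
        return 0.5 * (one(self.LA) + one(self.LB))


def _batch_deviations(PA: np.ndarray, PB: np.ndarray) -> np.ndarray:
    """Per-pair deviations for M stacked point-set pairs, each refit by Kabsch.

    PA, PB: (M, n, 3).  Returns (M, n) distances after superposing each
    PB[m] onto PA[m] with the proper (det = +1) least-RMSD rotation.
    """
    mu_p = PA.mean(axis=1, keepdims=True)
    mu_q = PB.mean(axis=1, keepdims=True)
    Pc = PA - mu_p
    Qc = PB - mu_q
    H = np.einsum("mni,mnj->mij", Qc, Pc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U) * np.linalg.det(Vt))
    d = np.where(d == 0, 1.0, d)
    Vt = Vt.copy()
    Vt[:, 2, :] *= d[:, None]
    R = np.matmul(np.transpose(Vt, (0, 2, 1)), np.transpose(U, (0, 2, 1)))
    Qrot = np.matmul(Qc, np.transpose(R, (0, 2, 1)))
    dev = Pc - Qrot
    return np.linalg.norm(dev, axis=2)
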