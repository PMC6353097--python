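"""Cα-only chain models, PDB I/O, and synthetic-structure generators.

Everything in this package operates on the Cα trace alone: a chain is
an ordered list of residue labels plus an ``(L, 3)`` coordinate array in
Å.  The synthetic generators build ideal α-helices, self-avoiding
random walks, and permuted / reversed / noisy copies with known
ground-truth alignments, so the whole test surface runs without any
downloaded structures.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .alignment import Alignment

__all__ = [
    "ProteinChain",
    "read_chain",
    "distance_matrix",
    "make_synthetic_chain",
    "make_permuted_pair",
    "mirror",
    "write_chain_pdb",
    "write_pair_pdb",
]

#: (author residue number, insertion code, residue name)
ResidueLabel = tuple[int, str, str]


@dataclass(frozen=True)
class ProteinChain:
    """One chain's ordered Cα trace.

    Residue indexing throughout the package is 0-based and contiguous
    over this extracted Cα list; the author residue numbers in
    ``residue_labels`` are metadata only (insertion codes and gaps make
    them unsafe as array indices).
    """

    chain_id: str
    residue_labels: tuple[ResidueLabel, ...]
    coords: np.ndarray  # (L, 3) float64, Å

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError("coords must have shape (L, 3)")
        if len(self.residue_labels) != len(coords):
            raise ValueError("residue_labels and coords lengths differ")
        if len(coords) == 0:
            raise ValueError("empty chain")
        if not np.all(np.isfinite(coords)):
            raise ValueError("non-finite coordinates")
        steps = np.linalg.norm(np.diff(coords, axis=0), axis=1)
        if len(steps) and not np.all(steps > 0):
            raise ValueError("duplicated consecutive Cα positions")
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "residue_labels", tuple(self.residue_labels))

    def __len__(self) -> int:
        return len(self.coords)


def read_chain(path: str | os.PathLike, chain_id: str, model_index: int = 0) -> ProteinChain:
    """Extract one chain's Cα trace from a PDB file.

    One Cα per residue, in chain order; residues lacking a Cα are
    skipped.  For alternate locations the highest-occupancy Cα is taken
    (ties broken by file order).
    """
    import gemmi

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such PDB file: {path}")
    structure = gemmi.read_structure(str(path))
    if not len(structure):
        raise ValueError(f"{path}: no models in structure")
    if model_index < 0 or model_index >= len(structure):
        raise ValueError(
            f"{path}: model index {model_index} out of range (have {len(structure)})"
        )
    model = structure[model_index]
    chain = None
    for ch in model:
        if ch.name == chain_id:
            chain = ch
            break
    if chain is None:
        available = ", ".join(ch.name for ch in model)
        raise ValueError(
            f"{path}: unknown chain {chain_id!r} (available: {available})"
        )
    labels: list[ResidueLabel] = []
    coords: list[tuple[float, float, float]] = []
    for res in chain:
        best = None
        for atom in res:
            if atom.name != "CA" or atom.element.name != "C":
                continue  # excludes calcium ions also named CA
            if best is None or atom.occ > best.occ:
                best = atom  # ties keep the first-listed altloc
        if best is None:
            continue
        icode = res.seqid.icode.strip() if res.seqid.icode else ""
        labels.append((res.seqid.num, icode, res.name))
        coords.append((best.pos.x, best.pos.y, best.pos.z))
    if not coords:
        raise ValueError(f"{path}: chain {chain_id!r} contains no Cα atoms")
    return ProteinChain(chain_id, tuple(labels), np.asarray(coords, dtype=float))


def distance_matrix(chain: ProteinChain) -> np.ndarray:
    """Symmetric L×L matrix of Cα–Cα distances in Å (zero diagonal)."""
    return squareform(pdist(chain.coords))


# ---------------------------------------------------------------------------
# Synthetic structures
# ---------------------------------------------------------------------------

_HELIX_RISE = 1.5  # Å per residue along the axis
_HELIX_TURN = math.radians(100.0)  # rotation per residue
_HELIX_RADIUS = 2.3  # Å
_WALK_STEP = 3.8  # Å, consecutive Cα distance
_WALK_MIN_SEP = 3.5  # Å, minimum non-bonded separation


def make_synthetic_chain(kind: str, length: int, seed: int = 0) -> ProteinChain:
    """Generate a synthetic Cα chain: an ideal α-helix or a self-avoiding walk.

    The helix uses the canonical right-handed geometry (1.5 Å rise,
    100° turn, 2.3 Å radius), giving consecutive Cα distances of
    ≈3.8 Å.  The walk takes 3.8 Å steps in random directions subject to
    a 3.5 Å minimum separation between non-bonded residues, emulating
    the excluded volume of a compact but irregular fold.  Deterministic
    given ``seed``.
    """
    if length < 2:
        raise ValueError("length must be >= 2")
    if kind == "helix":
        t = np.arange(length)
        coords = np.column_stack(
            [
                _HELIX_RADIUS * np.cos(_HELIX_TURN * t),
                _HELIX_RADIUS * np.sin(_HELIX_TURN * t),
                _HELIX_RISE * t,
            ]
        )
    elif kind == "walk":
        coords = _self_avoiding_walk(length, seed)
    else:
        raise ValueError(f"unknown synthetic chain kind {kind!r}")
    labels = tuple((k + 1, "", "ALA") for k in range(length))
    return ProteinChain("A", labels, coords)


def _self_avoiding_walk(length: int, seed: int, restarts: int = 200) -> np.ndarray:
    rng = np.random.default_rng(seed)
    for _ in range(restarts):
        pts = [np.zeros(3)]
        direction = _random_unit(rng)
        pts.append(pts[0] + _WALK_STEP * direction)
        failed = False
        while len(pts) < length:
            placed = False
            for _ in range(100):
                step = _WALK_STEP * _random_unit(rng)
                cand = pts[-1] + step
                prior = np.asarray(pts[:-1])
                if len(prior) and np.min(
                    np.linalg.norm(prior - cand, axis=1)
                ) < _WALK_MIN_SEP:
                    continue
                pts.append(cand)
                placed = True
                break
            if not placed:
                failed = True
                break
        if not failed:
            return np.asarray(pts)
    raise RuntimeError(
        f"self-avoiding walk of length {length} unsatisfiable within retry budget"
    )


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    while True:
        v = rng.normal(size=3)
        norm = np.linalg.norm(v)
        if norm > 1e-8:
            return v / norm


def make_permuted_pair(
    chain: ProteinChain,
    segment_plan: Sequence[tuple[int, int, str]],
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> tuple[ProteinChain, Alignment]:
    """Build a segment-permuted copy of a chain plus its ground-truth alignment.

    ``segment_plan`` lists disjoint source segments as half-open
    ``(start, end, orientation)`` tuples; the new chain's residue order
    is their concatenation, each segment optionally reversed, with
    i.i.d. Gaussian noise of scale ``noise_sigma`` added per coordinate.
    The returned alignment maps source indices to indices in the
    permuted chain; reversed segments produce reverse-orientation
    blocks.
    """
    L = len(chain)
    segs = []
    for start, end, orientation in segment_plan:
        if orientation not in ("forward", "reverse"):
            raise ValueError(f"bad orientation {orientation!r}")
        if not (0 <= start < end <= L):
            raise ValueError(f"segment ({start}, {end}) out of chain bounds")
        segs.append((int(start), int(end), orientation))
    for a, b in zip(sorted(segs), sorted(segs)[1:]):
        if b[0] < a[1]:
            raise ValueError(f"overlapping segments {a[:2]} and {b[:2]}")

    rng = np.random.default_rng(seed)
    coords: list[np.ndarray] = []
    labels: list[ResidueLabel] = []
    pairs: list[tuple[int, int]] = []
    pos = 0
    for start, end, orientation in segs:
        src = range(start, end) if orientation == "forward" else range(end - 1, start - 1, -1)
        for s in src:
            coords.append(chain.coords[s])
            labels.append(chain.residue_labels[s])
            pairs.append((s, pos))
            pos += 1
    arr = np.asarray(coords, dtype=float)
    if noise_sigma > 0:
        arr = arr + rng.normal(scale=noise_sigma, size=arr.shape)
    return ProteinChain("B", tuple(labels), arr), Alignment(pairs)


def mirror(chain: ProteinChain) -> ProteinChain:
    """Reflect a chain through the yz-plane (negate x).

    The internal distance matrix is unchanged, but the handedness of
    the fold flips — the source of the mirror-image pathology of
    distance-matrix-only scores.
    """
    return ProteinChain(
        chain.chain_id, chain.residue_labels, chain.coords * np.array([-1.0, 1.0, 1.0])
    )


# ---------------------------------------------------------------------------
# Minimal PDB writing (CA-only ATOM records)
# ---------------------------------------------------------------------------


def _atom_record(
    serial: int, label: ResidueLabel, chain_id: str, xyz: np.ndarray
) -> str:
    resseq, icode, resname = label
    return (
        f"ATOM  {serial:5d}  CA  {resname:<3.3s} {chain_id[:1]}{resseq:4d}"
        f"{(icode or ' '):1.1s}   {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
        f"{1.00:6.2f}{0.00:6.2f}          {'C':>2s}"
    )


def write_chain_pdb(path: str | os.PathLike, chain: ProteinChain) -> None:
    """Write a single chain's Cα trace as PDB ATOM records."""
    lines = [
        _atom_record(k + 1, lab, chain.chain_id, chain.coords[k])
        for k, lab in enumerate(chain.residue_labels)
    ]
    lines += ["TER", "END"]
    Path(path).write_text("\n".join(lines) + "\n")


def write_pair_pdb(
    path: str | os.PathLike,
    chain_a: ProteinChain,
    chain_b: ProteinChain,
    transform_b: "tuple[np.ndarray, np.ndarray] | None" = None,
) -> None:
    """Write two chains to one PDB file, optionally transforming chain B.

    ``transform_b`` is an optional ``(rotation, translation)`` applied
    to B's coordinates (e.g. from a superposition) so the two traces
    can be inspected in a viewer.
    """
    coords_b = chain_b.coords
    if transform_b is not None:
        rot, trans = transform_b
        coords_b = coords_b @ np.asarray(rot).T + np.asarray(trans)
    lines = [
        _atom_record(k + 1, lab, "A", chain_a.coords[k])
        for k, lab in enumerate(chain_a.residue_labels)
    ]
    lines.append("TER")
    offset = len(chain_a)
    lines += [
        _atom_record(offset + k + 1, lab, "B", coords_b[k])
        for k, lab in enumerate(chain_b.residue_labels)
    ]
    lines += ["TER", "END"]
    Path(path).write_text("\n".join(lines) + "\n")
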