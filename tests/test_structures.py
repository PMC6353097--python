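import numpy as np
import pytest

from nsalign.alignment import Alignment
from nsalign.structures import (
    distance_matrix,
    make_permuted_pair,
    make_synthetic_chain,
    mirror,
    read_chain,
    write_chain_pdb,
    write_pair_pdb,
)
from nsalign.superposition import aligned_rmsd

PDB_3RES = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   ALA A   1      10.674   6.710  -4.147  1.00  0.00           C
ATOM      4  CA  GLY A   2       9.580   9.002  -3.905  1.00  0.00           C
ATOM      5  CA  SER A   3       7.248  10.322  -1.215  1.00  0.00           C
TER
END
"""

PDB_ALTLOC = """\
ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.40  0.00           C
ATOM      2  CA BALA A   1       9.000   9.000   9.000  0.60  0.00           C
ATOM      3  CA  GLY A   2       3.800   0.000   0.000  1.00  0.00           C
TER
END
"""


class TestReadChain:
    def test_parses_all_ca(self, tmp_path):
        p = tmp_path / "toy.pdb"
        p.write_text(PDB_3RES)
        chain = read_chain(p, "A")
        assert len(chain) == 3
        assert [lab[0] for lab in chain.residue_labels] == [1, 2, 3]
        np.testing.assert_allclose(chain.coords[0], [11.639, 6.071, -5.147])

    def test_residue_without_ca_is_skipped(self, tmp_path):
        # drop residue 2's CA line
        text = "\n".join(
            l for l in PDB_3RES.splitlines() if not ("GLY" in l and " CA " in l)
        )
        p = tmp_path / "gap.pdb"
        p.write_text(text + "\n")
        chain = read_chain(p, "A")
        assert len(chain) == 2
        assert [lab[0] for lab in chain.residue_labels] == [1, 3]

    def test_unknown_chain_raises(self, tmp_path):
        p = tmp_path / "toy.pdb"
        p.write_text(PDB_3RES)
        with pytest.raises(ValueError, match="unknown chain"):
            read_chain(p, "Z")

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_chain(tmp_path / "nope.pdb", "A")

    def test_altloc_highest_occupancy_wins(self, tmp_path):
        p = tmp_path / "alt.pdb"
        p.write_text(PDB_ALTLOC)
        chain = read_chain(p, "A")
        assert len(chain) == 2
        np.testing.assert_allclose(chain.coords[0], [9.0, 9.0, 9.0])

    def test_pdb_writer_round_trip(self, tmp_path, walk30):
        p = tmp_path / "out.pdb"
        write_chain_pdb(p, walk30)
        back = read_chain(p, "A")
        assert len(back) == len(walk30)
        np.testing.assert_allclose(back.coords, walk30.coords, atol=1e-3)

    def test_pair_writer_two_chains(self, tmp_path, walk30):
        p = tmp_path / "pair.pdb"
        write_pair_pdb(p, walk30, walk30)
        a = read_chain(p, "A")
        b = read_chain(p, "B")
        assert len(a) == len(b) == len(walk30)


class TestDistanceMatrix:
    def test_two_points(self):
        from nsalign.structures import ProteinChain

        chain = ProteinChain(
            "A", ((1, "", "ALA"), (2, "", "ALA")), np.array([[0.0, 0, 0], [3.8, 0, 0]])
        )
        D = distance_matrix(chain)
        assert D[0, 1] == pytest.approx(3.8)
        assert D[0, 0] == 0.0

    def test_unit_square_hand_computed(self):
        from nsalign.structures import ProteinChain

        pts = np.array([[0.0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]])
        chain = ProteinChain("A", tuple((k, "", "GLY") for k in range(4)), pts)
        D = distance_matrix(chain)
        s2 = np.sqrt(2.0)
        expected = np.array(
            [[0, 1, s2, 1], [1, 0, 1, s2], [s2, 1, 0, 1], [1, s2, 1, 0]]
        )
        np.testing.assert_allclose(D, expected)

    def test_invariant_under_rigid_motion_and_mirror(self, walk30, rng):
        from scipy.spatial.transform import Rotation
        from nsalign.structures import ProteinChain

        R = Rotation.random(random_state=1).as_matrix()
        moved = ProteinChain(
            "A", walk30.residue_labels, walk30.coords @ R.T + np.array([5.0, -3, 2])
        )
        np.testing.assert_allclose(
            distance_matrix(moved), distance_matrix(walk30), atol=1e-9
        )
        np.testing.assert_allclose(
            distance_matrix(mirror(walk30)), distance_matrix(walk30), atol=1e-12
        )


class TestSyntheticChains:
    def test_helix_step_length(self, helix20):
        steps = np.linalg.norm(np.diff(helix20.coords, axis=0), axis=1)
        np.testing.assert_allclose(steps, 3.8, atol=0.05)

    def test_walk_determinism_and_seed_sensitivity(self):
        w1 = make_synthetic_chain("walk", 30, 5)
        w2 = make_synthetic_chain("walk", 30, 5)
        w3 = make_synthetic_chain("walk", 30, 6)
        np.testing.assert_array_equal(w1.coords, w2.coords)
        assert not np.allclose(w1.coords, w3.coords)

    def test_walk_self_avoidance(self, walk60):
        D = distance_matrix(walk60)
        nonbonded = np.abs(np.subtract.outer(range(60), range(60))) >= 2
        assert D[nonbonded].min() >= 3.5
        steps = np.diag(D, k=1)
        np.testing.assert_allclose(steps, 3.8, atol=1e-9)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            make_synthetic_chain("helix", 1, 0)


class TestPermutedPair:
    def test_identity_plan_noise_free(self, walk30):
        other, truth = make_permuted_pair(walk30, [(0, 30, "forward")], 0.0, 0)
        assert truth.pairs == tuple((i, i) for i in range(30))
        assert aligned_rmsd(truth, walk30, other) == pytest.approx(0.0, abs=1e-12)

    def test_swapped_halves_two_forward_blocks(self, circular_pair):
        _, _, truth = circular_pair
        blocks = truth.blocks()
        assert len(blocks) == 2
        assert all(b.orientation == "forward" for b in blocks)
        assert sorted(b.size for b in blocks) == [30, 30]

    def test_reversed_segment_gives_reverse_block(self, reversed_pair):
        _, _, truth = reversed_pair
        orientations = [b.orientation for b in truth.blocks()]
        assert "reverse" in orientations

    def test_per_segment_rmsd_zero_noise_free(self, circular_pair):
        A, B, truth = circular_pair
        for b in truth.blocks():
            assert aligned_rmsd(Alignment(b.pairs), A, B) == pytest.approx(0.0, abs=1e-9)

    def test_overlapping_segments_rejected(self, walk30):
        with pytest.raises(ValueError, match="overlap"):
            make_permuted_pair(walk30, [(0, 20, "forward"), (10, 30, "forward")], 0.0, 0)


class TestMirror:
    def test_involution(self, walk30):
        np.testing.assert_array_equal(mirror(mirror(walk30)).coords, walk30.coords)

    def test_helix_handedness_flips(self, helix20):
        def chirality(coords):
            v1, v2, v3 = np.diff(coords[:4], axis=0)
            return np.sign(np.dot(np.cross(v1, v2), v3))

        assert chirality(helix20.coords) == -chirality(mirror(helix20).coords)
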