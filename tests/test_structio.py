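"""CA-trace extraction, Kabsch superposition, and the single-column file formats."""

import io
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from modict import (
    CaTrace,
    ContractError,
    FormatError,
    RmsdProfile,
    make_backbone,
    read_ca_trace,
    read_rmsd_file,
    read_score_file,
    superpose,
    write_pdb,
    write_rmsd_file,
)
from oracles import quaternion_superpose, random_trace_pair


def _rigid_move(coords: np.ndarray, angle_deg: float, shift) -> np.ndarray:
    a = math.radians(angle_deg)
    rot = np.array([[math.cos(a), -math.sin(a), 0], [math.sin(a), math.cos(a), 0], [0, 0, 1]])
    return coords @ rot.T + np.asarray(shift, dtype=float)


class TestReadCaTrace:
    def test_single_chain_copies_ca_records(self, three_residue_pdb):
        trace = read_ca_trace(three_residue_pdb)
        assert len(trace) == 3
        assert trace.positions == [1, 2, 3]
        assert trace.residues[0][1] == "ALA"
        np.testing.assert_allclose(trace.coords[0], [11.639, 6.071, -5.147])

    def test_residue_without_ca_is_skipped(self):
        pdb = (
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "ATOM      2  N   GLY A   2       1.000   0.000   0.000  1.00  0.00           N\n"
            "ATOM      3  CA  SER A   3       2.000   0.000   0.000  1.00  0.00           C\n"
            "ATOM      4  CA  LEU A   4       3.000   0.000   0.000  1.00  0.00           C\n"
            "END\n"
        )
        trace = read_ca_trace(pdb)
        assert trace.positions == [1, 3, 4]

    def test_two_chains_without_chain_id_is_ambiguous(self, three_residue_pdb):
        two_chain = three_residue_pdb.replace("END\n", "") + (
            "ATOM      6  CA  ALA B   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "ATOM      7  CA  GLY B   2       1.000   0.000   0.000  1.00  0.00           C\n"
            "ATOM      8  CA  SER B   3       2.000   0.000   0.000  1.00  0.00           C\n"
            "END\n"
        )
        with pytest.raises(FormatError, match="chain"):
            read_ca_trace(two_chain)
        assert len(read_ca_trace(two_chain, "B")) == 3

    def test_altloc_resolves_to_highest_occupancy(self):
        pdb = (
            "ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.40  0.00           C\n"
            "ATOM      2  CA BALA A   1       9.000   9.000   9.000  0.60  0.00           C\n"
            "ATOM      3  CA  GLY A   2       1.000   0.000   0.000  1.00  0.00           C\n"
            "ATOM      4  CA  SER A   3       2.000   0.000   0.000  1.00  0.00           C\n"
            "END\n"
        )
        trace = read_ca_trace(pdb)
        np.testing.assert_allclose(trace.coords[0], [9.0, 9.0, 9.0])

    def test_no_ca_atoms_is_format_error(self):
        with pytest.raises(FormatError):
            read_ca_trace(
                "ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00\nEND\n"
            )

    def test_pdb_round_trip(self, helix10):
        buf = io.StringIO()
        write_pdb(helix10, buf)
        back = read_ca_trace(buf.getvalue())
        np.testing.assert_allclose(back.coords, helix10.coords, atol=1e-3)


class TestSuperpose:
    def test_identity_gives_zero_deviations(self, helix10):
        result = superpose(helix10, helix10)
        assert np.all(result.per_residue_dev < 1e-9)
        assert result.overall_rmsd < 1e-9

    def test_rigid_motion_is_removed_exactly(self, helix10):
        moved = helix10.with_coords(_rigid_move(helix10.coords, 90.0, (5, 5, 5)))
        result = superpose(helix10, moved)
        assert np.all(result.per_residue_dev <= 1e-6)

    def test_rotation_is_proper(self, helix10):
        moved = helix10.with_coords(_rigid_move(helix10.coords, 37.0, (1, -2, 3)))
        result = superpose(helix10, moved)
        assert abs(np.linalg.det(result.rotation) - 1.0) < 1e-9

    def test_overall_rmsd_is_rms_of_deviations(self, helix10):
        rng = np.random.default_rng(3)
        moved = helix10.with_coords(helix10.coords + rng.normal(scale=0.5, size=(10, 3)))
        result = superpose(helix10, moved)
        assert result.overall_rmsd == pytest.approx(
            math.sqrt(np.mean(result.per_residue_dev**2)), abs=1e-9
        )

    def test_displaced_residue_matches_quaternion_oracle(self, helix10):
        coords = helix10.coords
        coords[4] += [0.0, 0.0, 2.0]
        mutant = helix10.with_coords(coords)
        result = superpose(helix10, mutant)
        expected = quaternion_superpose(helix10.coords, mutant.coords)
        np.testing.assert_allclose(result.per_residue_dev, expected, atol=1e-6)

    @pytest.mark.parametrize("seed", range(100))
    def test_kabsch_agrees_with_quaternion_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 51))
        ref, mov = random_trace_pair(rng, n)
        trace_ref = make_backbone(n).with_coords(ref)
        trace_mov = make_backbone(n).with_coords(mov)
        result = superpose(trace_ref, trace_mov)
        expected = quaternion_superpose(ref, mov)
        np.testing.assert_allclose(result.per_residue_dev, expected, atol=1e-6)

    def test_length_mismatch_is_pairing_error(self, helix10):
        with pytest.raises(ContractError, match="length"):
            superpose(helix10, make_backbone(11))

    def test_position_mismatch_is_pairing_error(self, helix10):
        shifted = CaTrace(tuple((p + 1, c, xyz) for p, c, xyz in helix10.residues))
        with pytest.raises(ContractError, match="position"):
            superpose(helix10, shifted)

    @settings(deadline=None, max_examples=25)
    @given(st.integers(min_value=0, max_value=10_000), st.integers(min_value=3, max_value=40))
    def test_self_superposition_is_always_zero(self, seed, n):
        rng = np.random.default_rng(seed)
        trace = make_backbone(n).with_coords(rng.normal(scale=4.0, size=(n, 3)))
        assert superpose(trace, trace).overall_rmsd < 1e-9

    @settings(deadline=None, max_examples=25)
    @given(
        st.integers(min_value=0, max_value=10_000),
        st.floats(min_value=-180, max_value=180),
    )
    def test_rigid_motion_invariance(self, seed, angle):
        rng = np.random.default_rng(seed)
        base = make_backbone(15)
        noisy = base.with_coords(base.coords + rng.normal(scale=0.4, size=(15, 3)))
        plain = superpose(base, noisy)
        moved = noisy.with_coords(_rigid_move(noisy.coords, angle, rng.normal(size=3)))
        again = superpose(base, moved)
        np.testing.assert_allclose(plain.per_residue_dev, again.per_residue_dev, atol=1e-6)


class TestRmsdFile:
    def test_round_trip_identity(self):
        profile = RmsdProfile([0.1, 0.2, 0.3], 0.216)
        buf = io.StringIO()
        write_rmsd_file(profile, buf)
        buf.seek(0)
        back = read_rmsd_file(buf)
        np.testing.assert_allclose(back.deviations, profile.deviations, atol=1e-9)
        assert back.overall_rmsd == pytest.approx(0.216, abs=1e-9)

    def test_missing_header_recomputes_overall_as_rms(self):
        back = read_rmsd_file(io.StringIO("3.0\n4.0\n"))
        assert back.overall_rmsd == pytest.approx(math.sqrt((9 + 16) / 2), abs=1e-9)

    def test_parse_error_names_line(self):
        with pytest.raises(FormatError, match="line 4"):
            read_rmsd_file(io.StringIO("#h\n1.0\n2.0\nabc\n"))

    def test_empty_file_is_format_error(self):
        with pytest.raises(FormatError):
            read_rmsd_file(io.StringIO(""))

    @settings(deadline=None, max_examples=25)
    @given(
        st.lists(
            st.floats(min_value=0, max_value=100, allow_nan=False), min_size=1, max_size=50
        )
    )
    def test_round_trip_any_profile(self, values):
        buf = io.StringIO()
        write_rmsd_file(RmsdProfile.from_deviations(values), buf)
        buf.seek(0)
        np.testing.assert_allclose(read_rmsd_file(buf).deviations, values, atol=1e-6, rtol=1e-6)


class TestScoreFile:
    def test_absent_weight_file_fills_default_ten(self):
        np.testing.assert_array_equal(read_score_file(None, "weight", 5), [10] * 5)

    def test_absent_conservation_file_fills_default_one(self):
        np.testing.assert_array_equal(read_score_file(None, "conservation", 4), [1] * 4)

    def test_conservation_above_max_rejected(self):
        with pytest.raises(FormatError, match="line 1"):
            read_score_file(io.StringIO("12\n1\n1\n"), "conservation", 3)

    def test_length_mismatch_rejected(self):
        with pytest.raises(FormatError, match="expected 5"):
            read_score_file(io.StringIO("1\n2\n3\n4\n"), "weight", 5)
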