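"""Distance maps, RMSD traces, and secondary-structure occupancy rules."""

import numpy as np
import pytest

from ecdyn import errors
from ecdyn.structure_metrics import (
    annotate_regions,
    mean_shortest_distance_map,
    occupancy_report,
    parse_dssp_timeline,
    parse_ss_table,
    rmsd_trace,
    ss_occupancy,
    write_ss_table,
)
from ecdyn.traj_model import AtomRecord, SelectionMask, TrajectorySegment, select
from tests.conftest import make_atoms


def residue_pair_segment(dist_per_frame):
    """Two single-atom residues separated along x by the given distances."""
    atoms = [AtomRecord(0, "CA", "C", 1, "ALA", "A"),
             AtomRecord(1, "CA", "C", 2, "ALA", "A")]
    coords = np.zeros((len(dist_per_frame), 2, 3))
    coords[:, 1, 0] = dist_per_frame
    return TrajectorySegment(coords, atoms, 1.0)


class TestDistanceMap:
    def test_constant_separation(self):
        m = mean_shortest_distance_map(residue_pair_segment([0.5, 0.5]))
        assert m.matrix[0, 1] == pytest.approx(0.5)
        assert m.matrix[1, 0] == pytest.approx(0.5)

    def test_self_distance_is_zero(self):
        m = mean_shortest_distance_map(residue_pair_segment([0.5]))
        assert m.matrix[0, 0] == 0.0 and m.matrix[1, 1] == 0.0

    def test_frame_average(self):
        m = mean_shortest_distance_map(residue_pair_segment([0.4, 0.6]))
        assert m.matrix[0, 1] == pytest.approx(0.5)

    def test_superset_selection_never_increases_entries(self, alpha_seq):
        from ecdyn.construct_builder import ConstructSpec, assemble_construct

        seg = assemble_construct(
            ConstructSpec(kind="monomer", sequence=alpha_seq[:8])).structure
        full = mean_shortest_distance_map(seg, select(seg, "heavy")).matrix
        ca = mean_shortest_distance_map(seg, select(seg, "calpha")).matrix
        assert (full <= ca + 1e-12).all()

    def test_residue_without_selected_atoms_is_an_error(self, alpha_seq):
        from ecdyn.construct_builder import ConstructSpec, assemble_construct

        # residue 7 of the packaged sequence is glycine -> no CB atom
        seg = assemble_construct(
            ConstructSpec(kind="monomer", sequence=alpha_seq[:8])).structure
        cb_only = [a.atom_index for a in seg.atoms if a.atom_name == "CB"]
        assert len(cb_only) == 7
        with pytest.raises(errors.SelectionError):
            mean_shortest_distance_map(seg, SelectionMask(tuple(cb_only)))


class TestRmsd:
    def test_reference_frame_has_zero_rmsd(self):
        rng = np.random.default_rng(1)
        coords = rng.random((4, 5, 3))
        seg = TrajectorySegment(coords, make_atoms(5), 1.0)
        r = rmsd_trace(seg, 0)
        assert r[0] == pytest.approx(0.0, abs=1e-12)

    def test_rigid_translation_fits_to_zero(self):
        rng = np.random.default_rng(2)
        base = rng.random((6, 3))
        coords = np.array([base, base + [0.3, -0.1, 0.2]])
        seg = TrajectorySegment(coords, make_atoms(6), 1.0)
        r = rmsd_trace(seg, 0)
        assert np.abs(r).max() < 1e-12

    def test_rigid_motion_invariance(self):
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(3)
        coords = rng.random((5, 6, 3))
        seg = TrajectorySegment(coords, make_atoms(6), 1.0)
        rot = Rotation.random(random_state=np.random.RandomState(0))
        moved = TrajectorySegment(
            rot.apply(coords.reshape(-1, 3)).reshape(coords.shape) + 1.5,
            make_atoms(6), 1.0)
        np.testing.assert_allclose(rmsd_trace(seg, 0), rmsd_trace(moved, 0),
                                   atol=1e-10)

    def test_known_residual_closed_form(self):
        """4 atoms, one displaced by delta: RMSD after fit matches hand SVD."""
        base = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1.0]])
        moved = base.copy()
        moved[3, 2] += 0.2
        seg = TrajectorySegment(np.array([base, moved]), make_atoms(4), 1.0)
        r = rmsd_trace(seg, 0)

        # independent oracle: brute-force optimal fit via scipy on this case
        from scipy.spatial.transform import Rotation

        rot, rssd = Rotation.align_vectors(base - base.mean(0),
                                           moved - moved.mean(0))
        expected = rssd / np.sqrt(4)
        assert r[1] == pytest.approx(expected, abs=1e-12)


class TestTimelineParsing:
    def test_single_frame_table(self):
        tl = parse_ss_table(["EEEE"])
        assert tl.codes.shape == (1, 4)
        assert (tl.codes == "E").all()

    def test_unknown_code_is_a_parse_error(self):
        with pytest.raises(errors.ParseError):
            parse_ss_table(["EHXF"])

    def test_blank_variants_map_to_coil(self):
        tl = parse_ss_table(["E-~C"])
        assert list(tl.codes[0]) == ["E", "C", "C", "C"]

    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(4)
        rows = ["".join(rng.choice(list("HGIEBTSC"), size=12))
                for _ in range(5)]
        tl = parse_ss_table(rows, frame_interval=2.0)
        p = tmp_path / "ss.txt"
        write_ss_table(tl, p)
        back = parse_ss_table(p, frame_interval=2.0)
        np.testing.assert_array_equal(tl.codes, back.codes)

    def test_residue_set_drift_is_rejected(self):
        with pytest.raises(errors.ConsistencyError):
            parse_ss_table(["EEEE", "EEE"])

    def test_per_frame_files(self, tmp_path):
        for i, row in enumerate(["HHHH", "EEEE"]):
            (tmp_path / f"f{i}.txt").write_text(row + "\n")
        tl = parse_dssp_timeline([tmp_path / "f0.txt", tmp_path / "f1.txt"])
        assert tl.codes.shape == (2, 4)


class TestOccupancy:
    @staticmethod
    def _timeline(e_frames, total=100, code="E"):
        rows = [code if f < e_frames else "C" for f in range(total)]
        return parse_ss_table([r for r in rows])

    def test_beta_above_80_percent_is_stable(self):
        t = ss_occupancy(self._timeline(85))
        assert t.stable_beta[0]
        assert t.occupancy["E"].iloc[0] == pytest.approx(0.85)

    def test_exactly_half_helix_is_not_stable(self):
        t = ss_occupancy(self._timeline(50, code="H"))
        assert not t.stable_helix["H"][0]  # strict inequality at 50%

    def test_exactly_80_percent_beta_is_not_stable(self):
        t = ss_occupancy(self._timeline(80))
        assert not t.stable_beta[0]

    def test_all_coil_has_zero_occupancy_everywhere(self):
        t = ss_occupancy(parse_ss_table(["CCC", "CCC"]))
        assert not t.stable_beta.any()
        assert not any(v.any() for v in t.stable_helix.values())
        assert (t.occupancy[list("HGIEBTS")].to_numpy() == 0).all()

    def test_occupancies_sum_to_one(self):
        rng = np.random.default_rng(5)
        rows = ["".join(rng.choice(list("HGIEBTSC"), size=9))
                for _ in range(40)]
        t = ss_occupancy(parse_ss_table(rows))
        np.testing.assert_allclose(t.occupancy.sum(axis=1), 1.0)

    def test_trailing_window(self):
        rows = ["C"] * 50 + ["E"] * 50
        t = ss_occupancy(parse_ss_table(rows), window=50.0)
        assert t.occupancy["E"].iloc[0] == pytest.approx(1.0)
        assert t.window_frames == 50

    def test_stable_runs_reported_as_ranges(self):
        rows = ["CEECCEEEC"] * 10
        t = ss_occupancy(parse_ss_table(rows))
        spans = [(e.start, e.stop) for e in t.elements if e.ss_class == "E"]
        assert spans == [(2, 3), (6, 8)]


class TestRegions:
    @staticmethod
    def _table_with_strand(start, stop, n=140):
        row = "".join("E" if start <= i + 1 <= stop else "C"
                      for i in range(n))
        return ss_occupancy(parse_ss_table([row] * 10))

    def test_nac_strand(self):
        t = annotate_regions(self._table_with_strand(75, 80))
        (el,) = t.elements
        assert "NAC" in el.regions and "amyloidogenic-core" in el.regions

    def test_n_terminal_strand(self):
        t = annotate_regions(self._table_with_strand(2, 6))
        assert t.elements[0].regions == ("N-terminal",)

    def test_element_spanning_two_regions(self):
        t = annotate_regions(self._table_with_strand(94, 98))
        regions = t.elements[0].regions
        assert "NAC" in regions and "C-terminal" in regions

    def test_duplicate_region_names_rejected(self):
        t = self._table_with_strand(2, 6)
        with pytest.raises(errors.ConfigError):
            annotate_regions(t, [("X", (1, 10)), ("X", (5, 20))])

    def test_report_table(self):
        t = annotate_regions(self._table_with_strand(75, 80))
        df = occupancy_report(t)
        assert df.loc[0, "mean_occupancy"] == pytest.approx(1.0)
        assert df.loc[0, "class"] == "E"
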