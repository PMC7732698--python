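import warnings

import numpy as np
import pytest
from hypothesis import given, strategies as st

from fabdyn import (
    ResidueSelection,
    center_of_mass,
    read_models,
    read_structure,
    read_trajectory,
    resolve_selection,
    write_pdb,
)
from fabdyn.config import FabPartition
from fabdyn.errors import (
    EmptySelectionError,
    EmptyStructureError,
    TopologyError,
    ValidationError,
)
from conftest import make_pdb_text

THREE_ATOMS = [
    (1, "N", "ALA", "A", 1, 1.0, 2.0, 3.0, "N"),
    (2, "CA", "ALA", "A", 1, 2.0, 3.0, 4.0, "C"),
    (3, "CA", "GLY", "B", 2, -1.5, 0.25, 9.0, "C"),
]


class TestReadStructure:
    def test_single_model_round_trip(self, pdb_writer):
        frame = read_structure(pdb_writer("one.pdb", [THREE_ATOMS]))
        assert frame.n_atoms == 3
        assert list(frame.chain_ids) == ["A", "A", "B"]
        assert list(frame.res_ids) == [1, 1, 2]
        np.testing.assert_allclose(frame.coords[2], [-1.5, 0.25, 9.0])
        # masses from the element column
        assert frame.masses[0] == pytest.approx(14.007)
        assert frame.masses[1] == pytest.approx(12.011)

    def test_two_models_identical_ordering(self, pdb_writer):
        shifted = [(s, n, r, c, q, x + 1, y, z, e)
                   for (s, n, r, c, q, x, y, z, e) in THREE_ATOMS]
        frames = read_models(pdb_writer("two.pdb", [THREE_ATOMS, shifted]))
        assert len(frames) == 2
        assert list(frames[0].atom_names) == list(frames[1].atom_names)
        np.testing.assert_allclose(frames[1].coords[:, 0],
                                   frames[0].coords[:, 0] + 1.0)

    def test_waters_only_with_protein_filter(self, pdb_writer):
        waters = [(1, "O", "HOH", "A", 1, 0.0, 0.0, 0.0, "O"),
                  (2, "O", "HOH", "A", 2, 3.0, 0.0, 0.0, "O")]
        path = pdb_writer("wat.pdb", [waters])
        with pytest.raises(EmptyStructureError):
            read_structure(path, protein_only=True)

    def test_mass_fallback_from_atom_name(self, pdb_writer):
        atoms = [(1, "CA", "ALA", "A", 1, 0.0, 0.0, 0.0, ""),
                 (2, "N", "ALA", "A", 1, 1.0, 0.0, 0.0, ""),
                 (3, "O", "ALA", "A", 1, 2.0, 0.0, 0.0, "")]
        frame = read_structure(pdb_writer("noelem.pdb", [atoms]))
        assert frame.masses[0] == pytest.approx(12.011)
        assert frame.masses[1] == pytest.approx(14.007)


class TestReadTrajectory:
    def _ten_frames(self):
        return [[(s, n, r, c, q, x + 0.5 * i, y, z, e)
                 for (s, n, r, c, q, x, y, z, e) in THREE_ATOMS]
                for i in range(10)]

    def test_discard_and_rezero(self, pdb_writer):
        top = pdb_writer("top.pdb", [THREE_ATOMS])
        traj = pdb_writer("traj.pdb", self._ten_frames())
        frames = read_trajectory(top, traj, dt_ps=10.0,
                                 equilibration_frames_discarded=2)
        assert len(frames) == 8
        assert [f.time_ps for f in frames] == [10.0 * i for i in range(8)]
        # retained frames are the later ones, re-timed from zero
        np.testing.assert_allclose(frames[0].coords[0, 0], 1.0 + 0.5 * 2)

    def test_nonpositive_dt_rejected(self, pdb_writer):
        top = pdb_writer("top.pdb", [THREE_ATOMS])
        with pytest.raises(ValidationError):
            read_trajectory(top, top, dt_ps=0.0)

    def test_atom_count_mismatch(self, pdb_writer):
        top = pdb_writer("top.pdb", [THREE_ATOMS])
        traj = pdb_writer("bad.pdb", [THREE_ATOMS[:2]])
        with pytest.raises(TopologyError):
            read_trajectory(top, traj, dt_ps=1.0)

    def test_out_of_order_models_warn_but_load(self, tmp_path):
        text = make_pdb_text(self._ten_frames()[:2])
        text = text.replace("MODEL        1", "MODEL        9", 1)
        p = tmp_path / "swapped.pdb"
        p.write_text(text)
        with pytest.warns(UserWarning, match="not strictly increasing"):
            frames = read_models(p)
        assert len(frames) == 2


class TestWriteRoundTrip:
    def test_coordinates_preserved_to_pdb_precision(self, toy_fab, tmp_path):
        path = tmp_path / "fab.pdb"
        write_pdb(toy_fab.frame, path)
        back = read_structure(path)
        assert back.n_atoms == toy_fab.frame.n_atoms
        np.testing.assert_allclose(back.coords, toy_fab.frame.coords,
                                   atol=5.1e-4)

    def test_multimodel_round_trip(self, toy_fab, tmp_path):
        f0 = toy_fab.frame
        f1 = f0.with_coords(f0.coords + [1.0, 0, 0], frame_index=1)
        path = tmp_path / "two.pdb"
        write_pdb([f0, f1], path)
        frames = read_models(path)
        assert len(frames) == 2
        np.testing.assert_allclose(frames[1].coords - frames[0].coords,
                                   np.broadcast_to([1.0, 0, 0],
                                                   (f0.n_atoms, 3)),
                                   atol=1.1e-3)


class TestSelections:
    def test_full_range_selects_whole_chain(self, pdb_writer):
        frame = read_structure(pdb_writer("one.pdb", [THREE_ATOMS]))
        sel = ResidueSelection("A", ((1, 999),), "all_a")
        assert list(resolve_selection(frame, sel)) == [0, 1]

    def test_inverted_range_rejected(self):
        with pytest.raises(ValidationError):
            ResidueSelection("A", ((5, 4),), "bad")

    def test_insertion_coded_residue_inside_range(self, pdb_writer):
        atoms = [(1, "CA", "ALA", "A", 100, 0.0, 0.0, 0.0, "C"),
                 (2, "CA", "ALA", "A", 100, 3.8, 0.0, 0.0, "C"),
                 (3, "CA", "ALA", "A", 101, 7.6, 0.0, 0.0, "C")]
        path = pdb_writer("icode.pdb", [atoms],
                          icodes={("A", 100, 2): "A"})
        frame = read_structure(path)
        assert frame.ins_codes[1] == "A"
        sel = ResidueSelection("A", ((100, 101),), "span")
        assert len(resolve_selection(frame, sel)) == 3

    def test_missing_chain_and_empty_result(self, pdb_writer):
        frame = read_structure(pdb_writer("one.pdb", [THREE_ATOMS]))
        with pytest.raises(EmptySelectionError):
            resolve_selection(frame, ResidueSelection("Z", ((1, 2),), "z"))
        with pytest.raises(EmptySelectionError):
            resolve_selection(frame, ResidueSelection("A", ((50, 60),), "far"))


class TestCenterOfMass:
    def test_examples(self, pdb_writer):
        atoms = [(1, "CA", "ALA", "A", 1, 0.0, 0.0, 0.0, "C"),
                 (2, "CA", "ALA", "A", 2, 2.0, 0.0, 0.0, "C"),
                 (3, "N", "ALA", "A", 3, 2.0, 0.0, 0.0, "N")]
        frame = read_structure(pdb_writer("com.pdb", [atoms]))
        # equal masses at 0 and 2
        np.testing.assert_allclose(
            center_of_mass(frame, np.array([0, 1])), [1.0, 0, 0])
        # single atom is its own COM
        np.testing.assert_allclose(
            center_of_mass(frame, np.array([2])), [2.0, 0, 0])
        # unequal masses: weighted toward the heavier atom
        frame.masses[:] = [1.0, 3.0, 1.0]
        np.testing.assert_allclose(
            center_of_mass(frame, np.array([0, 1])), [1.5, 0, 0])
        np.testing.assert_allclose(
            center_of_mass(frame, np.array([0, 1]), weighting="geometric"),
            [1.0, 0, 0])

    def test_rigid_equivariance(self, toy_fab):
        from conftest import apply_rigid, random_rigid_transform
        rng = np.random.default_rng(11)
        idx = np.arange(0, toy_fab.frame.n_atoms, 3)
        for _ in range(20):
            rot, t = random_rigid_transform(rng)
            com = center_of_mass(toy_fab.frame, idx)
            moved = apply_rigid(toy_fab.frame, rot, t)
            np.testing.assert_allclose(center_of_mass(moved, idx),
                                       rot.apply(com) + t, atol=1e-9)


@given(
    a_lo=st.integers(1, 80), a_len=st.integers(0, 40),
    b_lo=st.integers(1, 80), b_len=st.integers(0, 40),
)
def test_partition_rejects_overlapping_domains(a_lo, a_len, b_lo, b_len):
    """Any overlap between two same-chain domain ranges must be rejected."""
    a = (a_lo, a_lo + a_len)
    b = (b_lo, b_lo + b_len)
    overlapping = a[0] <= b[1] and b[0] <= a[1]

    def build():
        FabPartition(
            vh=ResidueSelection("H", (a,), "vh"),
            vl=ResidueSelection("L", ((1, 50),), "vl"),
            ch1=ResidueSelection("H", (b,), "ch1"),
            cl=ResidueSelection("L", ((61, 120),), "cl"),
            switch_heavy=ResidueSelection("H", ((201, 203),), "switch_heavy"),
            switch_light=ResidueSelection("L", ((51, 60),), "switch_light"),
            ch1_cterm_loops=ResidueSelection("H", (b,), "ch1_cterm_loops"),
            cl_cterm_loops=ResidueSelection("L", ((100, 120),), "cl_cterm_loops"),
        )

    if overlapping:
        with pytest.raises(ValidationError):
            build()
    else:
        # overlap is not the only validation rule (switch bridging may also
        # fail), but non-overlapping ranges must never raise the overlap error
        try:
            build()
        except ValidationError as exc:
            assert "overlap" not in str(exc)
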