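"""Symmetry expansion, sheet detection, interface enumeration and
double-layer construction."""

import numpy as np
import pytest

import gemmi

from crossbeta import LatticeSpec, build_ideal_strand, build_lattice
from crossbeta.lattice import (
    AmbiguousFibrilAxisError,
    InconsistentSenseError,
    NoCrossBetaError,
    build_double_layer,
    build_sheets,
    detect_fibril_axis,
    enumerate_interfaces,
    expand_lattice,
)
from crossbeta.structure import CrystalStructure, SymOp, UnitCell


def toy_structure(cell, space_group="P 1", shift=(0.0, 0.0, 0.0)):
    atoms = [a.moved_to(a.xyz + np.asarray(shift)) for a in build_ideal_strand("LYIQNL")]
    if space_group == "P 1":
        ops = [SymOp.identity()]
    else:
        sg = gemmi.find_spacegroup_by_name(space_group)
        ops = [SymOp.from_gemmi(o) for o in sg.operations()]
    return CrystalStructure(
        atoms=atoms, cell=cell, space_group=space_group, sym_ops=ops, source_id="toy"
    )


class TestFibrilAxis:
    def test_monoclinic_cell_picks_a_axis(self):
        s = toy_structure(UnitCell(4.840, 42.425, 22.256, 90.0, 94.57, 90.0))
        axis, length, repeat = detect_fibril_axis(s)
        assert length == pytest.approx(4.840)
        assert repeat == 1
        assert abs(axis[0]) > 0.99

    def test_orthorhombic_cell_picks_a_axis(self):
        s = toy_structure(UnitCell(4.848, 20.005, 42.650))
        _, length, _ = detect_fibril_axis(s)
        assert length == pytest.approx(4.848)

    def test_cubic_toy_cell_is_ambiguous(self):
        s = toy_structure(UnitCell(10.0, 10.0, 10.0))
        with pytest.raises(AmbiguousFibrilAxisError):
            detect_fibril_axis(s)

    def test_override_names_axis(self):
        s = toy_structure(UnitCell(10.0, 10.0, 10.0))
        axis, length, _ = detect_fibril_axis(s, override="b")
        assert length == pytest.approx(10.0)
        assert abs(axis[1]) > 0.99

    def test_two_strand_repeat_window(self):
        s = toy_structure(UnitCell(30.0, 9.6, 25.0))
        _, length, repeat = detect_fibril_axis(s)
        assert repeat == 2 and length == pytest.approx(9.6)


class TestExpansion:
    def test_pure_translation_row(self):
        """P 1 cell, radius 1.5x the cell edge: exactly the -1/0/+1 row."""
        # strand spans ~18 A in x; huge b/c edges isolate the a-row
        s = toy_structure(UnitCell(25.0, 200.0, 200.0), shift=(0.0, 0.0, 0.0))
        strands = expand_lattice(s, radius=1.5 * 25.0)
        shifts = sorted(st.lattice_shift for st in strands)
        assert shifts == [(-1, 0, 0), (0, 0, 0), (1, 0, 0)]

    def test_copies_are_rigid_transforms(self, class3_lattice):
        strands = expand_lattice(class3_lattice, radius=20.0)
        ref = strands[0].coords
        d_ref = np.linalg.norm(ref[0] - ref[-1])
        for st in strands:
            if st.source_chain != strands[0].source_chain:
                continue
            c = st.coords
            assert np.linalg.norm(c[0] - c[-1]) == pytest.approx(d_ref, abs=1e-6)

    def test_screw_operator_copies_present(self):
        s = toy_structure(
            UnitCell(4.84, 42.4, 22.3, 90.0, 94.6, 90.0),
            space_group="P 1 21 1",
            shift=(5.0, 10.0, 5.0),
        )
        strands = expand_lattice(s, radius=25.0)
        assert any(st.op_index != 0 for st in strands)

    def test_duplicate_free(self, class3_lattice):
        strands = expand_lattice(class3_lattice, radius=20.0)
        cents = {tuple(np.round(st.centroid, 3)) for st in strands}
        assert len(cents) == len(strands)

    def test_bad_radius(self, class3_lattice):
        with pytest.raises(ValueError):
            expand_lattice(class3_lattice, radius=-1.0)


class TestSheets:
    def test_parallel_sheet_by_construction(self):
        s = build_lattice(LatticeSpec(class_id=2, sequence="LYIQNL"))
        axis, _, _ = detect_fibril_axis(s)
        sheets = build_sheets(expand_lattice(s, 18.0), axis)
        assert all(sh.sense == "parallel" and sh.repeat_len == 1 for sh in sheets)

    def test_antiparallel_sheet_by_construction(self):
        s = build_lattice(LatticeSpec(class_id=8, sequence="LYIQNL"))
        axis, _, _ = detect_fibril_axis(s)
        sheets = build_sheets(expand_lattice(s, 20.0), axis)
        assert all(sh.sense == "antiparallel" and sh.repeat_len == 2 for sh in sheets)

    def test_strands_ordered_along_axis(self, class3_lattice):
        axis, _, _ = detect_fibril_axis(class3_lattice)
        sheets = build_sheets(expand_lattice(class3_lattice, 18.0), axis)
        for sh in sheets:
            proj = [float(st.centroid @ axis) for st in sh.strands]
            assert proj == sorted(proj)

    def test_isolated_strands_raise_no_cross_beta(self):
        s = toy_structure(UnitCell(100.0, 100.0, 100.0))
        with pytest.raises(NoCrossBetaError):
            build_sheets(expand_lattice(s, 30.0), np.array([0.0, 1.0, 0.0]))

    def test_membership_invariant_under_rigid_motion(self, class3_lattice):
        from scipy.spatial.transform import Rotation

        axis, _, _ = detect_fibril_axis(class3_lattice)
        sheets0 = build_sheets(expand_lattice(class3_lattice, 18.0), axis)
        R = Rotation.from_euler("zyx", [17.0, -31.0, 5.0], degrees=True).as_matrix()
        t = np.array([3.0, -7.0, 11.0])
        moved = CrystalStructure(
            atoms=[a.moved_to(R @ a.xyz + t) for a in class3_lattice.atoms],
            cell=class3_lattice.cell,
            space_group=class3_lattice.space_group,
            sym_ops=list(class3_lattice.sym_ops),
            source_id="moved",
        )
        # cell axes no longer match Cartesian axes, so hand the rotated axis
        # in; strand copies at the expansion-sphere boundary may differ, so
        # compare the architecture rather than exact counts
        sheets1 = build_sheets(expand_lattice(moved, 18.0), R @ axis)
        assert len(sheets1) == len(sheets0)
        assert sorted(sh.sense for sh in sheets1) == sorted(
            sh.sense for sh in sheets0
        )
        assert max(len(sh.strands) for sh in sheets1) == max(
            len(sh.strands) for sh in sheets0
        )


class TestInterfaces:
    def test_far_sheets_give_empty_list(self):
        s = build_lattice(
            LatticeSpec(class_id=1, sequence="LYIQNL", sheet_spacing=50.0, n_strands=4),
            mode="explicit",
        )
        sheets = build_sheets(
            expand_lattice(s, 120.0), np.array([0.0, 1.0, 0.0])
        )
        assert len(sheets) == 2
        with pytest.warns(UserWarning):
            assert enumerate_interfaces(sheets) == []

    def test_single_interface_type_for_face_to_back(self):
        s = build_lattice(LatticeSpec(class_id=4, sequence="LYIQNL"))
        axis, _, _ = detect_fibril_axis(s)
        ifaces = enumerate_interfaces(build_sheets(expand_lattice(s, 30.0), axis))
        assert len(ifaces) == 1
        # opposite faces meet: odd residues on one side, even on the other
        names_a = {n for n, _ in ifaces[0].contact_residues("a")}
        names_b = {n for n, _ in ifaces[0].contact_residues("b")}
        assert names_a != names_b

    def test_two_interfaces_for_face_to_face(self, class3_result):
        ifaces = class3_result.interfaces
        assert [f.label for f in ifaces] == ["S1", "S2"]
        assert (
            ifaces[0].buried_area_per_strand >= ifaces[1].buried_area_per_strand
        )

    def test_labels_deterministic(self, class3_lattice):
        axis, _, _ = detect_fibril_axis(class3_lattice)
        runs = []
        for _ in range(2):
            sheets = build_sheets(expand_lattice(class3_lattice, 30.0), axis)
            ifaces = enumerate_interfaces(sheets)
            runs.append(
                [(f.label, f.signature, round(f.buried_area_per_strand, 6)) for f in ifaces]
            )
        assert runs[0] == runs[1]

    def test_min_contacts_respected(self, class3_lattice):
        axis, _, _ = detect_fibril_axis(class3_lattice)
        sheets = build_sheets(expand_lattice(class3_lattice, 30.0), axis)
        with pytest.warns(UserWarning):
            assert enumerate_interfaces(sheets, min_contacts=10**6) == []


class TestDoubleLayer:
    def test_parallel_2x3(self, class3_result):
        dl = build_double_layer(class3_result.interfaces[0])
        assert dl.n_strands_per_sheet == 3
        assert sum(len(sh.strands) for sh in dl.sheets) == 6
        assert sum(len(c) for c in dl.central_strands) == 2

    def test_antiparallel_2x6(self, class8_result):
        dl = build_double_layer(class8_result.interfaces[0])
        assert dl.n_strands_per_sheet == 6
        assert sum(len(sh.strands) for sh in dl.sheets) == 12
        assert sum(len(c) for c in dl.central_strands) == 4

    def test_central_strands_are_mid_stack(self, class3_result):
        dl = build_double_layer(class3_result.interfaces[0])
        for sh, central in zip(dl.sheets, dl.central_strands):
            axis = sh.fibril_axis
            proj = [float(st.centroid @ axis) for st in sh.strands]
            mid = 0.5 * (proj[0] + proj[-1])
            for ci in central:
                assert abs(proj[ci] - mid) <= abs(proj[-1] - proj[0]) / 4

    def test_mixed_sense_raises(self, class3_result, class8_result):
        import copy

        bad = copy.copy(class3_result.interfaces[0])
        bad.sheet_b = class8_result.interfaces[0].sheet_b
        with pytest.raises(InconsistentSenseError):
            build_double_layer(bad)
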