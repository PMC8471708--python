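"""Structure parsing, molecule partitioning, centers of mass, dipole
estimation and helix-geometry fitting."""

import numpy as np
import pytest

from helichir import (
    Atom,
    MoleculeGroup,
    center_of_mass,
    chi_total_backbone,
    extract_calpha_trace,
    fit_helix_params,
    order_groups_along_helix,
    partition_molecules,
    point_charge_dipole,
    read_pqr,
    read_structure,
)
from helichir.errors import (
    DegenerateFitError,
    EmptyTraceError,
    InsufficientVectorsError,
    MassLookupError,
    MissingChargeError,
    PartitionError,
    StructureFormatError,
)
from helichir.structure import E_ANGSTROM_TO_DEBYE, attach_charges
from helichir.synthetic import (
    HelixSpec,
    RosetteSpec,
    make_calpha_helix,
    make_dipole_rosette,
    make_molecular_coil,
    write_calpha_pdb,
    write_coil_pdb,
    write_coil_pqr,
)


@pytest.fixture(scope="module")
def coil_files(tmp_path_factory):
    """Synthetic 6x43-atom charged coil written as PDB + PQR."""
    tmp = tmp_path_factory.mktemp("coil")
    atoms = make_molecular_coil(n_molecules=6, with_charges=True, seed=3)
    pdb = write_coil_pdb(atoms, tmp / "coil.pdb")
    pqr = write_coil_pqr(atoms, tmp / "coil.pqr")
    return pdb, pqr


class TestReading:
    def test_two_molecule_fixture(self, tmp_path):
        atoms_out = make_molecular_coil(n_molecules=2, seed=1)
        pdb = write_coil_pdb(atoms_out, tmp_path / "two.pdb")
        atoms = read_structure(pdb)
        assert len(atoms) == 86
        assert {a.chain_id for a in atoms} == {"A", "B"}

    def test_unknown_element_is_mass_lookup_error(self, tmp_path):
        pdb = tmp_path / "xx.pdb"
        pdb.write_text(
            "ATOM      1  XX1 UNK A   1       0.000   0.000   0.000  1.00  0.00          XX\n"
            "END\n"
        )
        with pytest.raises(MassLookupError):
            read_structure(pdb)

    def test_missing_file(self, tmp_path):
        with pytest.raises(StructureFormatError):
            read_structure(tmp_path / "missing.pdb")

    def test_four_residue_helix_round_trip(self, tmp_path):
        trace = make_calpha_helix(HelixSpec(n_residues=4))
        pdb = write_calpha_pdb(trace, tmp_path / "h4.pdb")
        again = extract_calpha_trace(read_structure(pdb), "A")
        assert len(again) == 4
        np.testing.assert_allclose(again.coordinates, trace.coordinates, atol=1e-3)


class TestCalphaTrace:
    def test_extraction_and_handedness(self, tmp_path):
        trace = make_calpha_helix(HelixSpec(n_residues=10, handedness="right"))
        pdb = write_calpha_pdb(trace, tmp_path / "h10.pdb")
        extracted = extract_calpha_trace(read_structure(pdb), "A")
        assert len(extracted) == 10
        assert chi_total_backbone(extracted).handedness == "right"

    def test_three_residue_chain_fails_downstream(self, tmp_path):
        trace = make_calpha_helix(HelixSpec(n_residues=4))
        pdb = write_calpha_pdb(trace, tmp_path / "h3.pdb")
        atoms = [a for a in read_structure(pdb) if a.residue_number <= 3]
        short = extract_calpha_trace(atoms, "A")
        with pytest.raises(InsufficientVectorsError):
            chi_total_backbone(short)

    def test_missing_chain(self, tmp_path):
        trace = make_calpha_helix(HelixSpec(n_residues=4))
        pdb = write_calpha_pdb(trace, tmp_path / "h.pdb")
        with pytest.raises(EmptyTraceError):
            extract_calpha_trace(read_structure(pdb), "Z")

    def test_numbering_gap_reported(self):
        atoms = []
        for resnum, x in [(1, 0.0), (2, 1.0), (5, 2.0), (6, 3.0)]:
            atoms.append(
                Atom(
                    element="C",
                    position=np.array([x, x * 0.5, x * 0.25]),
                    atom_name="CA",
                    residue_number=resnum,
                    chain_id="A",
                )
            )
        with pytest.warns(UserWarning, match="non-consecutive"):
            trace = extract_calpha_trace(atoms, "A")
        assert trace.residue_numbers == [1, 2, 5, 6]


class TestPartitioning:
    @pytest.mark.parametrize(
        "rule", ["by_chain", "by_residue_block", "by_connectivity_distance"]
    )
    def test_coil_partitions_into_six_molecules(self, coil_files, rule):
        atoms = read_structure(coil_files[0])
        groups = partition_molecules(atoms, rule=rule, expected_atom_count=43)
        assert len(groups) == 6
        assert all(len(g) == 43 for g in groups)
        ids = [a.molecule_id for g in groups for a in g.atoms]
        assert len(ids) == len(atoms)  # every atom in exactly one group

    def test_single_chain_identity_partition(self):
        atoms = make_molecular_coil(n_molecules=1, atoms_per_molecule=10, seed=2)
        groups = partition_molecules(atoms, rule="by_chain")
        assert len(groups) == 1 and len(groups[0]) == 10

    def test_empty_atom_list(self):
        with pytest.raises(PartitionError):
            partition_molecules([], rule="by_chain")

    def test_wrong_expected_count(self, coil_files):
        atoms = read_structure(coil_files[0])
        with pytest.raises(PartitionError):
            partition_molecules(atoms, rule="by_chain", expected_atom_count=44)

    def test_degenerate_coordinates_ambiguity(self):
        pos = np.array([0.0, 0.0, 0.0])
        atoms = [
            Atom(element="C", position=pos, atom_name="C1", chain_id="A"),
            Atom(element="C", position=pos, atom_name="C2", chain_id="B"),
            Atom(element="C", position=np.array([9.0, 0, 0]), atom_name="C3", chain_id="B"),
        ]
        with pytest.raises(PartitionError, match="degenerate"):
            partition_molecules(atoms, rule="by_connectivity_distance")


class TestCenterOfMass:
    def test_midpoint_and_identity(self):
        a = Atom(element="C", position=np.zeros(3))
        b = Atom(element="C", position=np.array([2.0, 0, 0]))
        com = center_of_mass(MoleculeGroup(atoms=[a, b]))
        np.testing.assert_allclose(com.as_array(), [1.0, 0, 0])
        solo = center_of_mass(MoleculeGroup(atoms=[b]))
        np.testing.assert_allclose(solo.as_array(), [2.0, 0, 0])

    def test_43_atom_weighted_mean_oracle(self):
        rng = np.random.default_rng(11)
        elements = rng.choice(["C", "N", "O", "H", "S"], size=43)
        positions = rng.normal(0, 5, (43, 3))
        group = MoleculeGroup(
            atoms=[Atom(element=e, position=p) for e, p in zip(elements, positions)]
        )
        # independent explicit weighted-sum oracle
        num = np.zeros(3)
        den = 0.0
        for atom in group.atoms:
            num += atom.mass * atom.position
            den += atom.mass
        np.testing.assert_allclose(center_of_mass(group).as_array(), num / den, rtol=1e-12)

    def test_equivariance(self):
        rng = np.random.default_rng(4)
        group = MoleculeGroup(
            atoms=[Atom(element="O", position=p) for p in rng.normal(0, 3, (8, 3))]
        )
        base = center_of_mass(group).as_array()
        t = np.array([1.5, -2.0, 0.25])
        shifted = MoleculeGroup(
            atoms=[Atom(element="O", position=a.position + t) for a in group.atoms]
        )
        np.testing.assert_allclose(center_of_mass(shifted).as_array(), base + t, atol=1e-12)


class TestPointChargeDipole:
    def test_textbook_two_charge_dipole(self):
        plus = Atom(element="H", position=np.array([1.0, 0, 0]), charge=1.0)
        minus = Atom(element="H", position=np.zeros(3), charge=-1.0)
        rec = point_charge_dipole(
            MoleculeGroup(atoms=[plus, minus]), reference="center_of_charge"
        )
        np.testing.assert_allclose(
            rec.components.as_array(), [E_ANGSTROM_TO_DEBYE, 0, 0], atol=1e-12
        )

    def test_neutral_group_reference_independence(self):
        rng = np.random.default_rng(5)
        charges = rng.uniform(-0.4, 0.4, 5)
        charges -= charges.mean()
        atoms = [
            Atom(element="C", position=p, charge=float(q))
            for p, q in zip(rng.normal(0, 2, (5, 3)), charges)
        ]
        group = MoleculeGroup(atoms=atoms)
        d1 = point_charge_dipole(group, reference="center_of_mass").components.as_array()
        d2 = point_charge_dipole(group, reference="center_of_charge").components.as_array()
        np.testing.assert_allclose(d1, d2, atol=1e-9)
        # independent explicit charge-sum oracle about the center of mass
        com = center_of_mass(group).as_array()
        oracle = sum(
            a.charge * (a.position - com) for a in atoms
        ) * E_ANGSTROM_TO_DEBYE
        np.testing.assert_allclose(d1, oracle, rtol=1e-12)

    def test_missing_charges_named(self):
        atoms = [
            Atom(element="C", position=np.zeros(3), atom_name="C1", charge=0.1),
            Atom(element="N", position=np.ones(3), atom_name="N2"),
        ]
        with pytest.raises(MissingChargeError, match="N2"):
            point_charge_dipole(MoleculeGroup(atoms=atoms))

    def test_pqr_round_trip(self, coil_files):
        pdb, pqr = coil_files
        atoms = read_structure(pdb)
        charged = read_pqr(pqr)
        assert len(charged) == len(atoms)
        attach_charges(atoms, charged)
        groups = partition_molecules(atoms, rule="by_chain", expected_atom_count=43)
        for g in groups:
            total = sum(a.charge for a in g.atoms)
            assert total == pytest.approx(0.0, abs=1e-5)  # written to 6 decimals


class TestHelixFit:
    def test_recovers_published_coil_geometry(self):
        coil = make_dipole_rosette(RosetteSpec(turns=2))  # 12 origins, 2 turns
        params = fit_helix_params(coil.origins())
        assert params.radius == pytest.approx(8.15, abs=0.01)
        assert params.pitch == pytest.approx(5.456, abs=0.01)
        assert params.points_per_turn == pytest.approx(6.0, abs=0.01)
        assert abs(np.linalg.norm(params.axis_direction.as_array()) - 1) < 1e-9

    def test_noisy_recovery_within_three_sigma(self):
        sigma = 0.05
        coil = make_dipole_rosette(RosetteSpec(turns=2, noise_sigma=sigma, seed=9))
        params = fit_helix_params(coil.origins())
        assert params.radius == pytest.approx(8.15, abs=3 * sigma)
        assert params.pitch == pytest.approx(5.456, abs=3 * sigma)

    def test_planar_circle_degenerate(self):
        t = np.linspace(0, 2 * np.pi, 9)[:-1]
        circle = np.column_stack([np.cos(t), np.sin(t), np.zeros_like(t)])
        with pytest.raises(DegenerateFitError):
            fit_helix_params(circle)

    def test_collinear_degenerate(self):
        line = np.outer(np.arange(6), [1.0, 2.0, 3.0])
        with pytest.raises(DegenerateFitError, match="collinear"):
            fit_helix_params(line)

    def test_too_few_points(self):
        with pytest.raises(DegenerateFitError, match="4"):
            fit_helix_params(np.eye(3))


class TestHelixOrdering:
    def test_shuffled_coil_reordered_by_azimuth(self):
        atoms = make_molecular_coil(n_molecules=6, seed=13)
        groups = partition_molecules(atoms, rule="by_chain")
        original = [g.molecule_id for g in groups]
        rng = np.random.default_rng(0)
        shuffled = [groups[i] for i in rng.permutation(6)]
        ordered = order_groups_along_helix(shuffled)
        recovered = [g.molecule_id for g in ordered]
        # traversal must start at the lowest molecule and follow the helix
        assert recovered == original
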