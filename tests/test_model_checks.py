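"""Model parsing, trace classification, and geometry checks."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import emvalid as ev
from emvalid.model_checks import (
    Atom,
    AtomModel,
    Chain,
    Residue,
    DEFAULT_VDW_RADII,
    pseudo_bond_angle,
    pseudo_torsion_angle,
)

CA_PDB = """\
ATOM      1  CA  ALA A   1      10.000  10.000  10.000  1.00 20.00           C
ATOM      2  CA  GLY A   2      13.800  10.000  10.000  1.00 20.00           C
ATOM      3  CA  SER A   3      17.600  10.000  10.000  1.00 20.00           C
END
"""

CA_MMCIF = """\
data_fixture
loop_
_atom_site.group_PDB
_atom_site.id
_atom_site.type_symbol
_atom_site.label_atom_id
_atom_site.label_alt_id
_atom_site.label_comp_id
_atom_site.label_asym_id
_atom_site.label_entity_id
_atom_site.label_seq_id
_atom_site.pdbx_PDB_ins_code
_atom_site.Cartn_x
_atom_site.Cartn_y
_atom_site.Cartn_z
_atom_site.occupancy
_atom_site.B_iso_or_equiv
_atom_site.auth_seq_id
_atom_site.auth_asym_id
ATOM 1 C CA . ALA A 1 1 ? 10.000 10.000 10.000 1.00 20.00 1 A
ATOM 2 C CA . GLY A 1 2 ? 13.800 10.000 10.000 1.00 20.00 2 A
ATOM 3 C CA . SER A 1 3 ? 17.600 10.000 10.000 1.00 20.00 3 A
"""

ALTLOC_PDB = """\
ATOM      1  CA AALA A   1      10.000  10.000  10.000  0.60 20.00           C
ATOM      2  CA BALA A   1      11.000  10.000  10.000  0.40 20.00           C
END
"""


def trace_model(positions, atom_name="CA", polymer="protein", numbers=None, chain_id="A"):
    residue_name = "ALA" if polymer == "protein" else "U"
    element = "C" if atom_name == "CA" else "P"
    numbers = numbers or list(range(1, len(positions) + 1))
    residues = [
        Residue(number=n, icode="", name=residue_name,
                atoms=[Atom(name=atom_name, element=element, position=np.asarray(p, float))])
        for n, p in zip(numbers, positions)
    ]
    return AtomModel(chains=[Chain(chain_id=chain_id, polymer_type=polymer, residues=residues)])


class TestParseModel:
    def test_ca_only_pdb(self, tmp_path):
        path = tmp_path / "m.pdb"
        path.write_text(CA_PDB)
        model = ev.parse_model(path)
        assert len(model.chains) == 1
        assert len(model.chains[0].residues) == 3
        assert model.n_atoms == 3
        assert model.chains[0].polymer_type == "protein"

    def test_mmcif_matches_pdb(self, tmp_path):
        pdb_path = tmp_path / "m.pdb"
        cif_path = tmp_path / "m.cif"
        pdb_path.write_text(CA_PDB)
        cif_path.write_text(CA_MMCIF)
        from_pdb = ev.parse_model(pdb_path, format="pdb")
        from_cif = ev.parse_model(cif_path, format="mmcif")
        assert len(from_cif.chains) == len(from_pdb.chains) == 1
        for res_a, res_b in zip(from_pdb.chains[0].residues, from_cif.chains[0].residues):
            assert (res_a.number, res_a.name) == (res_b.number, res_b.name)
            np.testing.assert_allclose(res_a.atoms[0].position, res_b.atoms[0].position)

    def test_altloc_highest_occupancy_wins(self, tmp_path):
        path = tmp_path / "alt.pdb"
        path.write_text(ALTLOC_PDB)
        model = ev.parse_model(path)
        residue = model.chains[0].residues[0]
        assert len(residue.atoms) == 1
        assert residue.atoms[0].occupancy == pytest.approx(0.6)
        assert residue.atoms[0].position[0] == pytest.approx(10.0)

    def test_missing_file(self, tmp_path):
        with pytest.raises(ValueError, match="cannot parse|no models"):
            ev.parse_model(tmp_path / "absent.pdb")


class TestClassifyTrace:
    def test_calpha_only(self):
        model = trace_model([(0, 0, 0), (3.8, 0, 0)])
        assert ev.classify_trace(model).per_chain["A"] == "calpha-only"

    def test_p_only(self):
        model = trace_model([(i * 5.9, 0, 0) for i in range(10)], atom_name="P", polymer="nucleic")
        annotation = ev.classify_trace(model)
        assert annotation.per_chain["A"] == "p-only"
        assert annotation.is_trace("A")

    def test_full_atom_chain_is_none(self):
        residues = [
            Residue(number=1, icode="", name="GLY", atoms=[
                Atom(name="N", element="N", position=np.zeros(3)),
                Atom(name="CA", element="C", position=np.array([1.5, 0, 0])),
                Atom(name="C", element="C", position=np.array([2.5, 1, 0])),
            ])
        ]
        model = AtomModel(chains=[Chain("A", "protein", residues)])
        assert ev.classify_trace(model).per_chain["A"] == "none"

    def test_mixed_chain_is_none(self):
        model = trace_model([(0, 0, 0), (3.8, 0, 0)])
        model.chains[0].residues[1].atoms.append(
            Atom(name="CB", element="C", position=np.array([3.8, 1.5, 0]))
        )
        assert ev.classify_trace(model).per_chain["A"] == "none"


class TestCacaOutliers:
    ref = ev.ReferenceDistributions()  # trans (3.81, 0.02), cis (2.935, 0.05)

    def test_all_trans_mean_no_outliers(self):
        model = trace_model([(i * 3.81, 0, 0) for i in range(5)])
        findings = ev.caca_distance_outliers(model, self.ref)
        assert findings.outliers == [] and findings.n_evaluated == 4

    def test_just_past_three_sigma_flagged(self):
        d = 3.81 + 3.1 * 0.02
        model = trace_model([(0, 0, 0), (d, 0, 0)])
        findings = ev.caca_distance_outliers(model, self.ref)
        assert len(findings.outliers) == 1
        outlier = findings.outliers[0]
        assert outlier.nearest_class == "trans"
        assert outlier.deviation_sigma == pytest.approx(3.1)
        assert outlier.distance == pytest.approx(d)

    def test_cis_mean_is_acceptable(self):
        """Two-window rule: a distance at the cis mean is fine even though it
        is tens of sigma from the trans mode."""
        model = trace_model([(0, 0, 0), (2.935, 0, 0)])
        assert ev.caca_distance_outliers(model, self.ref).outliers == []

    def test_numbering_gap_skipped(self):
        model = trace_model([(0, 0, 0), (50.0, 0, 0)], numbers=[1, 5])
        findings = ev.caca_distance_outliers(model, self.ref)
        assert findings.n_evaluated == 0 and findings.outliers == []

    def test_single_residue_chain_empty(self):
        model = trace_model([(0, 0, 0)])
        assert ev.caca_distance_outliers(model, self.ref).n_evaluated == 0

    def test_flagged_distances_recomputable(self):
        rng = np.random.default_rng(4)
        positions = np.cumsum(rng.uniform(2.0, 6.0, size=(10, 1)) * [1, 0, 0], axis=0)
        model = trace_model([tuple(p) for p in positions])
        findings = ev.caca_distance_outliers(model, self.ref)
        residues = model.chains[0].residues
        for outlier in findings.outliers:
            res_a = next(r for r in residues if r.number == outlier.residue_a[0])
            res_b = next(r for r in residues if r.number == outlier.residue_b[0])
            d = np.linalg.norm(res_a.atoms[0].position - res_b.atoms[0].position)
            assert outlier.distance == pytest.approx(d, abs=1e-6)


class TestPPOutliers:
    def test_paper_thresholds_fixture(self):
        model = ev.p_trace(spacing=[4.3, 6.0, 8.1])
        findings = ev.pp_distance_outliers(model)
        reasons = sorted(o.reason for o in findings.outliers)
        assert reasons == ["long", "short"]
        assert findings.n_evaluated == 3

    @pytest.mark.parametrize("boundary", [4.4, 8.0])
    def test_boundaries_not_flagged(self, boundary):
        model = ev.p_trace(spacing=[boundary])
        assert ev.pp_distance_outliers(model).outliers == []

    def test_typical_spacing_clean(self):
        model = ev.p_trace(n_res=10, spacing=5.9)
        assert ev.pp_distance_outliers(model).outliers == []

    def test_chain_order_permutation_invariant(self):
        model_a = ev.p_trace(spacing=[4.3, 6.0])
        model_b = ev.p_trace(spacing=[8.5, 6.0])
        combined = AtomModel(chains=model_a.chains + model_b.chains)
        flipped = AtomModel(chains=model_b.chains + model_a.chains)
        key = lambda o: (o.reason, round(o.distance, 6))
        assert sorted(map(key, ev.pp_distance_outliers(combined).outliers)) == sorted(
            map(key, ev.pp_distance_outliers(flipped).outliers)
        )


class TestPseudoRamachandran:
    def test_geometry_primitives(self):
        assert pseudo_bond_angle(
            np.array([1.0, 0, 0]), np.zeros(3), np.array([0, 1.0, 0])
        ) == pytest.approx(90.0)
        # classic +/- 90 degree dihedral
        eta = pseudo_torsion_angle(
            np.array([1.0, 0, 0]), np.zeros(3), np.array([0, 0, 1.0]), np.array([0, 1.0, 1.0])
        )
        assert abs(eta) == pytest.approx(90.0)

    def test_ideal_helix_clean_against_self_consistent_grid(self):
        """A grid built from jittered copies of the helix accepts the helix."""
        rng = np.random.default_rng(7)
        thetas, etas = [], []
        for _ in range(100):
            model = ev.helix_trace(8)
            for chain in model.chains:
                for residue in chain.residues:
                    residue.atoms[0].position += rng.normal(0, 0.05, size=3)
            for w in range(len(model.chains[0].residues) - 3):
                pos = [model.chains[0].residues[w + k].atoms[0].position for k in range(4)]
                thetas.append(pseudo_bond_angle(pos[0], pos[1], pos[2]))
                etas.append(pseudo_torsion_angle(pos[0], pos[1], pos[2], pos[3]))
        grid = ev.grid_from_samples(thetas, etas)
        ref = ev.ReferenceDistributions(pseudo_rama_grid=grid)
        findings = ev.pseudo_ramachandran(ev.helix_trace(10), ref)
        assert findings.outliers == []
        assert findings.n_evaluated == 7

    def test_adversarial_grid_flags_everything(self):
        helix = ev.helix_trace(8)
        positions = [r.atoms[0].position for r in helix.chains[0].residues[:4]]
        theta = pseudo_bond_angle(*positions[:3])
        eta = pseudo_torsion_angle(*positions)
        frequencies = np.full((36, 72), 1.0)
        i = int(theta // 5)
        j = int(np.ceil((eta + 180) / 5)) - 1
        frequencies[i, j] = 0.0
        grid = ev.RamaGrid(frequencies / frequencies.sum())
        ref = ev.ReferenceDistributions(pseudo_rama_grid=grid)
        findings = ev.pseudo_ramachandran(helix, ref)
        assert findings.n_evaluated == 5  # 8 residues -> 5 four-CA windows
        assert len(findings.outliers) == findings.n_evaluated

    def test_four_residue_chain_scores_one(self):
        grid = ev.RamaGrid(np.full((36, 72), 1.0 / (36 * 72)))
        ref = ev.ReferenceDistributions(pseudo_rama_grid=grid, rama_outlier_cutoff=0.0)
        findings = ev.pseudo_ramachandran(ev.helix_trace(4), ref)
        assert findings.n_evaluated == 1

    def test_missing_grid_errors(self):
        ref = ev.ReferenceDistributions(pseudo_rama_grid=None)
        with pytest.raises(ValueError, match="reference required"):
            ev.pseudo_ramachandran(ev.helix_trace(5), ref)

    def test_default_reference_accepts_ideal_helix(self):
        findings = ev.pseudo_ramachandran(ev.helix_trace(15), ev.default_reference())
        assert findings.outliers == []


def random_cluster_model(rng, n_residues=10, atoms_per_residue=20, box=18.0):
    residues = []
    elements = ["C", "N", "O", "S"]
    for number in range(1, n_residues + 1):
        atoms = [
            Atom(
                name=f"X{i}",
                element=elements[int(rng.integers(len(elements)))],
                position=rng.uniform(0, box, size=3),
            )
            for i in range(atoms_per_residue)
        ]
        residues.append(Residue(number=number, icode="", name="UNK", atoms=atoms))
    return AtomModel(chains=[Chain("A", "other", residues)])


class TestCloseContacts:
    def test_no_clash_beyond_sum_of_radii(self):
        model = trace_model([(0, 0, 0), (4.0, 0, 0)], numbers=[1, 5])
        assert ev.close_contacts(model).outliers == []

    def test_overlap_arithmetic(self):
        model = trace_model([(0, 0, 0), (2.5, 0, 0)], numbers=[1, 5])
        clashes = ev.close_contacts(model).outliers
        assert len(clashes) == 1
        assert clashes[0].overlap == pytest.approx(2 * 1.7 - 2.5)

    def test_consecutive_trace_bond_excluded(self):
        model = trace_model([(0, 0, 0), (2.5, 0, 0)], numbers=[1, 2])
        assert ev.close_contacts(model).outliers == []

    def test_same_residue_pairs_excluded(self):
        residues = [Residue(number=1, icode="", name="UNK", atoms=[
            Atom(name="X1", element="C", position=np.zeros(3)),
            Atom(name="X2", element="C", position=np.array([1.0, 0, 0])),
        ])]
        model = AtomModel(chains=[Chain("A", "other", residues)])
        assert ev.close_contacts(model).outliers == []

    def test_unknown_element_skipped_with_warning(self, caplog):
        residues = [Residue(number=1, icode="", name="UNK", atoms=[
            Atom(name="Q1", element="XX", position=np.zeros(3)),
        ]), Residue(number=5, icode="", name="UNK", atoms=[
            Atom(name="X1", element="C", position=np.array([0.5, 0, 0])),
        ])]
        model = AtomModel(chains=[Chain("A", "other", residues)])
        import logging

        with caplog.at_level(logging.WARNING, logger="emvalid.model_checks"):
            findings = ev.close_contacts(model)
        assert findings.outliers == []
        assert any("vdW table" in r.message for r in caplog.records)

    def test_matches_all_pairs_brute_force(self, rng):
        """k-d-tree clash list equals the quadratic oracle on 200 atoms."""
        model = random_cluster_model(rng)
        findings = ev.close_contacts(model)
        # independent O(N^2) enumeration with the same exclusion rule
        atoms = [(c, r, a) for c, r, a in model.all_atoms()]
        expected = set()
        for i in range(len(atoms)):
            for j in range(i + 1, len(atoms)):
                chain_i, res_i, atom_i = atoms[i]
                chain_j, res_j, atom_j = atoms[j]
                if res_i is res_j:
                    continue
                d = float(np.linalg.norm(atom_i.position - atom_j.position))
                limit = (
                    DEFAULT_VDW_RADII[atom_i.element]
                    + DEFAULT_VDW_RADII[atom_j.element]
                    - 0.4
                )
                if d < limit:
                    expected.add(
                        frozenset({(res_i.number, atom_i.name), (res_j.number, atom_j.name)})
                    )
        got = {
            frozenset({(c.atom_a[1], c.atom_a[3]), (c.atom_b[1], c.atom_b[3])})
            for c in findings.outliers
        }
        assert got == expected
        assert len(expected) > 0  # the fixture is dense enough to clash


class TestAtomInclusion:
    def grid_model(self, positions):
        return trace_model(positions, numbers=list(range(1, len(positions) + 1)))

    def test_contour_below_min_includes_all(self, rng):
        density_map = ev.DensityMap(rng.uniform(1, 2, size=(8, 8, 8)), voxel_size=1.0)
        model = self.grid_model([(2, 2, 2), (5, 5, 5)])
        result = ev.atom_inclusion(model, density_map, contour=0.0)
        assert result.fraction == 1.0

    def test_contour_above_max_excludes_all(self, rng):
        density_map = ev.DensityMap(rng.uniform(0, 1, size=(8, 8, 8)), voxel_size=1.0)
        model = self.grid_model([(2, 2, 2)])
        assert ev.atom_inclusion(model, density_map, contour=5.0).fraction == 0.0

    def test_interpolation_exact_at_voxel_centers(self, rng):
        data = rng.normal(size=(8, 8, 8))
        density_map = ev.DensityMap(data, voxel_size=1.5, origin=(2.0, 0.0, -1.0))
        indices = [(1, 2, 3), (4, 4, 4), (6, 0, 7)]
        positions = [density_map.origin + 1.5 * np.array(ijk) for ijk in indices]
        model = self.grid_model([tuple(p) for p in positions])
        contour = 0.0
        result = ev.atom_inclusion(model, density_map, contour)
        for (key, value, included, inside), ijk in zip(result.per_atom, indices):
            assert inside
            assert value == pytest.approx(data[ijk], abs=1e-9)
            assert included == (data[ijk] >= contour)
        direct = sum(data[ijk] >= contour for ijk in indices) / len(indices)
        assert result.fraction == pytest.approx(direct)

    def test_outside_atoms_counted_excluded(self, rng):
        density_map = ev.DensityMap(rng.uniform(1, 2, size=(8, 8, 8)), voxel_size=1.0)
        model = self.grid_model([(2, 2, 2), (100, 0, 0)])
        result = ev.atom_inclusion(model, density_map, contour=0.0)
        assert result.n_outside == 1
        assert result.fraction == 0.5

    def test_nearest_option(self, rng):
        data = rng.normal(size=(8, 8, 8))
        density_map = ev.DensityMap(data, voxel_size=1.0)
        model = self.grid_model([(2.3, 2.4, 1.6)])
        result = ev.atom_inclusion(model, density_map, 0.0, method="nearest")
        assert result.per_atom[0][1] == pytest.approx(data[2, 2, 2])

    def test_monotone_in_contour(self, rng):
        density_map = ev.DensityMap(rng.normal(size=(8, 8, 8)), voxel_size=1.0)
        model = self.grid_model([tuple(p) for p in rng.uniform(1, 6, size=(20, 3))])
        fractions = [
            ev.atom_inclusion(model, density_map, level).fraction
            for level in np.linspace(-2, 2, 9)
        ]
        assert all(a >= b for a, b in zip(fractions, fractions[1:]))

    def test_empty_model_errors(self, rng):
        density_map = ev.DensityMap(rng.normal(size=(4, 4, 4)), voxel_size=1.0)
        with pytest.raises(ValueError, match="no atoms"):
            ev.atom_inclusion(AtomModel(chains=[]), density_map, 0.0)


class TestRigidTranslationInvariance:
    @given(shift=st.tuples(*([st.floats(-20, 20)] * 3)))
    def test_findings_invariant_under_joint_translation(self, shift):
        rng = np.random.default_rng(3)
        data = rng.normal(size=(8, 8, 8))
        positions = [(2.2, 3.1, 4.0), (5.5, 2.0, 6.1), (1.1, 6.6, 2.2)]
        shift = np.asarray(shift)

        base_map = ev.DensityMap(data, voxel_size=1.0)
        base_model = trace_model(positions)
        moved_map = ev.DensityMap(data, voxel_size=1.0, origin=shift)
        moved_model = trace_model([tuple(np.asarray(p) + shift) for p in positions])

        ref = ev.ReferenceDistributions()
        base_caca = ev.caca_distance_outliers(base_model, ref)
        moved_caca = ev.caca_distance_outliers(moved_model, ref)
        assert [round(o.distance, 9) for o in base_caca.outliers] == [
            round(o.distance, 9) for o in moved_caca.outliers
        ]

        base_inc = ev.atom_inclusion(base_model, base_map, 0.0)
        moved_inc = ev.atom_inclusion(moved_model, moved_map, 0.0)
        assert base_inc.fraction == pytest.approx(moved_inc.fraction)
        for (_, va, ia, _), (_, vb, ib, _) in zip(base_inc.per_atom, moved_inc.per_atom):
            assert va == pytest.approx(vb, abs=1e-6)
            assert ia == ib
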