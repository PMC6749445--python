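import dataclasses

import numpy as np
import pytest

from strainscope.hbonds import (
    HBondCriteria,
    assign_secondary_structure,
    classify_motifs,
    find_hbonds,
    hbond_table,
    place_hydrogens,
)
from strainscope.structure_io import StructureModel
from strainscope.synthetic import build_chain, build_element


def backbone_nho_pairs(bonds):
    return sorted(
        (b.donor.chain_id, b.donor.residue_number, b.acceptor.chain_id, b.acceptor.residue_number)
        for b in bonds
        if b.bond_type == "NH_O" and b.donor.atom_name == "N" and b.acceptor.atom_name == "O"
    )


class TestPlaceHydrogens:
    def test_mid_chain_alanine_gains_five(self):
        model = build_chain(["GLY", "ALA", "GLY"], [-139.0] * 3, [135.0] * 3)
        ala = model.chains["A"][1]
        before = len(ala.atoms)
        place_hydrogens(model)
        added = {a.atom_name for a in ala.atoms if a.is_hydrogen}
        assert added == {"H", "HA", "HB1", "HB2", "HB3"}
        assert len(ala.atoms) == before + 5

    def test_bond_lengths(self):
        model = build_chain(["GLY", "ALA", "GLY"], [-139.0] * 3, [135.0] * 3)
        place_hydrogens(model)
        ala = model.chains["A"][1]
        atoms = ala.conformer()
        assert np.linalg.norm(atoms["H"].position - atoms["N"].position) == pytest.approx(1.01, abs=1e-9)
        assert np.linalg.norm(atoms["HA"].position - atoms["CA"].position) == pytest.approx(1.09, abs=1e-9)

    def test_keep_existing_adds_nothing(self):
        model = build_chain(["GLY", "ALA", "GLY"], [-139.0] * 3, [135.0] * 3)
        place_hydrogens(model)
        count = sum(1 for _ in model.atoms())
        place_hydrogens(model, mode="keep_existing")
        assert sum(1 for _ in model.atoms()) == count

    def test_rebuild_all_replaces(self):
        model = build_chain(["GLY", "ALA", "GLY"], [-139.0] * 3, [135.0] * 3)
        place_hydrogens(model)
        count = sum(1 for _ in model.atoms())
        place_hydrogens(model, mode="rebuild_all")
        assert sum(1 for _ in model.atoms()) == count

    def test_glycine_ha_mirror_symmetric(self):
        model = build_chain(["ALA", "GLY", "ALA"], [-139.0] * 3, [135.0] * 3)
        place_hydrogens(model)
        gly = model.chains["A"][1]
        atoms = gly.conformer()
        ha2, ha3 = atoms["HA2"].position, atoms["HA3"].position
        # Both HA equidistant from the N-CA-C plane, on opposite sides.
        from strainscope.geometry import fit_plane

        plane = fit_plane([atoms["N"].position, atoms["CA"].position, atoms["C"].position])
        d2 = plane.distance_to(ha2)
        d3 = plane.distance_to(ha3)
        assert d2 == pytest.approx(-d3, abs=1e-9)
        assert abs(d2) > 0.5

    def test_placed_atoms_flagged(self):
        model = build_chain(["ALA", "ALA"], [-139.0] * 2, [135.0] * 2)
        place_hydrogens(model)
        hydrogens = [a for a in model.atoms() if a.is_hydrogen]
        assert hydrogens
        assert all(a.source == "placed" for a in hydrogens)

    def test_proline_like_unknown_topology_left_alone(self):
        # A residue name outside the topology table is skipped, not broken.
        model = build_chain(["ALA", "ALA"], [-139.0] * 2, [135.0] * 2)
        model.chains["A"][1].residue_name = "XXX"
        for atom in model.chains["A"][1].atoms:
            atom.residue_name = "XXX"
        place_hydrogens(model)
        assert not any(a.is_hydrogen for a in model.chains["A"][1].atoms)

    def test_invalid_mode(self):
        model = build_chain(["ALA"], [-139.0], [135.0])
        with pytest.raises(ValueError):
            place_hydrogens(model, mode="maybe")


class TestFindHbonds:
    def test_distant_fragments_no_bonds(self):
        model_a = build_chain(["ALA", "ALA"], [-139.0] * 2, [135.0] * 2)
        model_b = build_chain(["ALA", "ALA"], [-139.0] * 2, [135.0] * 2, chain_id="B")
        for res in model_b.chains["B"]:
            for atom in res.atoms:
                atom.position = atom.position + np.array([100.0, 0.0, 0.0])
        model = StructureModel("X", {"A": model_a.chains["A"], "B": model_b.chains["B"]})
        place_hydrogens(model)
        assert find_hbonds(model) == []

    def test_no_hydrogens_raises(self):
        model = build_chain(["ALA", "ALA"], [-139.0] * 2, [135.0] * 2)
        with pytest.raises(ValueError, match="place_hydrogens"):
            find_hbonds(model)

    def test_helix_register(self, helix_model):
        model, truth = helix_model
        place_hydrogens(model)
        bonds = find_hbonds(model)
        found = backbone_nho_pairs(bonds)
        expected = sorted(tuple(t) for t in truth["register"])
        assert found == expected

    def test_sheet_register(self, sheet_model):
        model, truth = sheet_model
        place_hydrogens(model)
        bonds = find_hbonds(model)
        found = backbone_nho_pairs(bonds)
        expected = sorted(tuple(t) for t in truth["register"])
        assert found == expected

    def test_element_classes(self, turn_model):
        model, _ = turn_model
        place_hydrogens(model)
        for bond in find_hbonds(model):
            if bond.bond_type == "CH_O":
                assert bond.donor.element == "C"
            else:
                assert bond.donor.element == "N"
            assert bond.acceptor.element == "O"
            assert bond.d_ha <= bond.d_da
            assert 0.0 <= bond.theta_dha <= 180.0

    def test_criteria_monotonicity(self, turn_model):
        model, _ = turn_model
        place_hydrogens(model)
        default = {b.key for b in find_hbonds(model)}
        tight = HBondCriteria(ch_max_ha=2.4, ch_max_da=3.3, ch_min_angle=130.0,
                              nh_max_ha=2.1, nh_max_da=3.0, nh_min_angle=140.0)
        loose = HBondCriteria(ch_max_ha=3.2, ch_max_da=4.2, ch_min_angle=95.0,
                              nh_max_ha=2.9, nh_max_da=3.9, nh_min_angle=105.0)
        tight_keys = {b.key for b in find_hbonds(model, tight)}
        loose_keys = {b.key for b in find_hbonds(model, loose)}
        assert tight_keys <= default <= loose_keys

    def test_determinism(self, turn_model):
        model, _ = turn_model
        place_hydrogens(model)
        table1 = hbond_table(find_hbonds(model), "X").to_csv(sep="\t", index=False)
        table2 = hbond_table(find_hbonds(model), "X").to_csv(sep="\t", index=False)
        assert table1 == table2

    def test_through_bond_backbone_contact_excluded(self):
        model = build_chain(["ALA"] * 4, [-139.0] * 4, [135.0] * 4)
        place_hydrogens(model)
        bonds = find_hbonds(model, HBondCriteria(nh_max_ha=3.5, nh_max_da=4.5, nh_min_angle=0.0))
        for b in bonds:
            if b.donor.atom_name == "N" and b.acceptor.atom_name == "O":
                assert b.acceptor_residue is not b.donor_residue.prev


class TestSecondaryStructure:
    def test_helix_mostly_h(self, helix_model):
        model, _ = helix_model
        labels = [assign_secondary_structure(model).label(r) for r in model.chains["A"]]
        assert labels.count("H") >= 8

    def test_hairpin_style_sheet(self, sheet_model):
        model, truth = sheet_model
        ss = assign_secondary_structure(model)
        matches = 0
        total = 0
        for res in list(model.chains["A"]) + list(model.chains["B"]):
            intended = truth["ss"][(res.chain_id, res.residue_number)]
            got = ss.label(res)
            total += 1
            # Edge residues may fray to C; interior must be E.
            if got == intended or (intended == "E" and got == "C" and res.residue_number in (1, model.chains["A"][-1].residue_number)):
                matches += 1
        assert matches / total >= 0.9

    def test_lone_strand_is_coil(self):
        model = build_chain(["ALA"] * 8, [-139.0] * 8, [135.0] * 8)
        ss = assign_secondary_structure(model)
        assert all(ss.label(r) == "C" for r in model.chains["A"])

    def test_turn_apex_labeled_t(self, turn_model):
        model, truth = turn_model
        ss = assign_secondary_structure(model)
        labels = "".join(ss.label(r) for r in model.chains["A"])
        assert labels[1:3] == "TT"

    def test_short_chain_all_coil(self):
        model = build_chain(["ALA", "ALA"], [-139.0] * 2, [135.0] * 2)
        ss = assign_secondary_structure(model)
        assert all(ss.label(r) == "C" for r in model.chains["A"])


class TestMotifs:
    def test_empty_bond_list(self, helix_model):
        model, _ = helix_model
        ss = assign_secondary_structure(model)
        annotated, counts = classify_motifs([], ss, model)
        assert annotated == []
        assert all(v == 0 for v in counts.values())

    def test_helix_leu_cap_i3_i4(self):
        seq = ["ALA"] * 10
        seq[7] = "LEU"
        model, _ = build_element("helix", 10, sequence=seq)
        place_hydrogens(model)
        bonds = find_hbonds(model)
        ss = assign_secondary_structure(model, bonds=bonds)
        annotated, counts = classify_motifs(bonds, ss, model)
        leu_motifs = {
            b.motif for b in annotated
            if b.donor.residue_number == 8 and b.donor_class == "side_chain"
        }
        assert "helix_sc_cap_i4" in leu_motifs
        assert counts["helix_sc_cap_i4"] >= 1

    def test_turn_cap(self, turn_model):
        model, _ = turn_model
        place_hydrogens(model)
        bonds = find_hbonds(model)
        ss = assign_secondary_structure(model, bonds=bonds)
        annotated, counts = classify_motifs(bonds, ss, model)
        assert counts["turn_i_i3_sc_cap"] == 1
        cap = next(b for b in annotated if b.motif == "turn_i_i3_sc_cap")
        assert cap.donor.residue_number == 4
        assert cap.acceptor.residue_number == 1
        assert cap.bond_type == "CH_O"

    def test_turn_cap_coexists_with_backbone_bond(self, turn_model):
        # Every side-chain turn cap must ride on an i->i+3 backbone bond.
        model, _ = turn_model
        place_hydrogens(model)
        bonds = find_hbonds(model)
        ss = assign_secondary_structure(model, bonds=bonds)
        annotated, _ = classify_motifs(bonds, ss, model)
        backbone = backbone_nho_pairs(bonds)
        for b in annotated:
            if b.motif == "turn_i_i3_sc_cap":
                assert (
                    b.donor.chain_id, b.donor.residue_number,
                    b.acceptor.chain_id, b.acceptor.residue_number,
                ) in backbone

    def test_sheet_mc_mc(self, sheet_model):
        model, _ = sheet_model
        place_hydrogens(model)
        bonds = find_hbonds(model)
        ss = assign_secondary_structure(model, bonds=bonds)
        _, counts = classify_motifs(bonds, ss, model)
        assert counts["sheet_mc_mc"] >= 2


class TestCriteria:
    def test_frozen_and_replaceable(self):
        criteria = HBondCriteria()
        looser = dataclasses.replace(criteria, ch_max_ha=3.0)
        assert looser.ch_max_ha == 3.0
        assert criteria.ch_max_ha == 2.8
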