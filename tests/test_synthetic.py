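import filecmp
import json

import numpy as np
import pytest

from strainscope import strain
from strainscope.geometry import dihedral
from strainscope.structure_io import read_structure
from strainscope.synthetic import (
    SUPPORTED_RESIDUES,
    DistortionSpec,
    attach_adps,
    build_chain,
    build_element,
    build_residue,
    generate_fixture_suite,
    place_atom,
)


class TestPlaceAtom:
    def test_round_trip_internal_coordinates(self, rng):
        from strainscope.geometry import angle

        for _ in range(50):
            a, b, c = rng.uniform(-5, 5, size=(3, 3))
            if np.linalg.norm(np.cross(b - a, c - b)) < 1e-3:
                continue
            bond = rng.uniform(1.0, 2.0)
            ang = rng.uniform(30.0, 150.0)
            tor = rng.uniform(-179.0, 179.0)
            d = place_atom(a, b, c, bond, ang, tor)
            assert np.linalg.norm(d - c) == pytest.approx(bond, abs=1e-9)
            assert angle(b, c, d) == pytest.approx(ang, abs=1e-9)
            assert dihedral(a, b, c, d) == pytest.approx(tor, abs=1e-9)


class TestBuildChain:
    def test_phi_psi_omega_reproduced(self):
        phi = [-57.0, -60.0, -70.0, -57.0]
        psi = [-47.0, -40.0, -50.0, -47.0]
        omega = [180.0, 175.0, 180.0]
        model = build_chain(["ALA"] * 4, phi, psi, omega)
        residues = model.chains["A"]
        coords = [r.conformer() for r in residues]
        for i in range(1, 4):
            measured_phi = dihedral(
                coords[i - 1]["C"].position, coords[i]["N"].position,
                coords[i]["CA"].position, coords[i]["C"].position,
            )
            assert measured_phi == pytest.approx(phi[i], abs=1e-6)
            measured_omega = dihedral(
                coords[i - 1]["CA"].position, coords[i - 1]["C"].position,
                coords[i]["N"].position, coords[i]["CA"].position,
            )
            assert abs(measured_omega) == pytest.approx(abs(omega[i - 1]), abs=1e-6)

    def test_residues_linked(self):
        model = build_chain(["ALA"] * 3, [-139.0] * 3, [135.0] * 3)
        residues = model.chains["A"]
        assert residues[0].next is residues[1]
        assert residues[2].prev is residues[1]

    def test_unsupported_type(self):
        with pytest.raises(ValueError, match="unsupported residue type"):
            build_chain(["ABC"], [0.0], [0.0])

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            build_chain(["ALA", "ALA"], [0.0], [0.0, 0.0])

    @pytest.mark.parametrize("residue_type", sorted(SUPPORTED_RESIDUES))
    def test_all_supported_types_build(self, residue_type):
        model = build_chain([residue_type], [-139.0], [135.0])
        res = model.chains["A"][0]
        assert res.get("CA") is not None
        if residue_type != "GLY":
            assert res.get("CB") is not None


class TestBuildResidue:
    def test_unsupported_lists_supported(self):
        with pytest.raises(ValueError, match="ALA"):
            build_residue("HIS")

    def test_ground_truth_zero_for_ideal(self):
        _, truth = build_residue("ARG")
        assert truth["applied"] == 0.0
        assert truth["distortion"] is None

    def test_invalid_distortion_magnitude(self):
        with pytest.raises(ValueError):
            DistortionSpec(kind="guanidinium_twist", magnitude=200.0)

    def test_twist_on_non_arg_rejected(self):
        with pytest.raises(ValueError):
            build_residue("PHE", DistortionSpec(kind="guanidinium_twist", magnitude=5.0))

    def test_recovery_closure_tolerance(self):
        # Ground-truth closure at the documented tolerance (0.05 deg).
        for residue_type, kind in [
            ("ARG", "guanidinium_twist"), ("PHE", "cb_bend"),
            ("TRP", "cb_bend"), ("TYR", "cb_bend"),
        ]:
            for delta in (1.0, 5.0, 20.0):
                res, truth = build_residue(residue_type, DistortionSpec(kind=kind, magnitude=delta))
                measured = strain.measure_residue(res).value
                assert measured == pytest.approx(truth["applied"], abs=0.05)


class TestBuildElement:
    def test_invalid_kind(self):
        with pytest.raises(ValueError, match="unknown element kind"):
            build_element("pi_helix")

    def test_too_short(self):
        with pytest.raises(ValueError):
            build_element("helix", length=2)

    def test_helix_truth_labels(self):
        model, truth = build_element("helix", 8)
        assert all(label == "H" for label in truth["ss"].values())
        assert len(truth["register"]) == 4

    def test_sheet_has_two_chains(self):
        model, truth = build_element("antiparallel_sheet", 5)
        assert set(model.chains) == {"A", "B"}
        assert len(truth["register"]) >= 4

    def test_sheet_register_distances(self):
        model, truth = build_element("antiparallel_sheet", 6)
        residues = {
            (r.chain_id, r.residue_number): r
            for r in list(model.chains["A"]) + list(model.chains["B"])
        }
        for donor_chain, donor_num, acceptor_chain, acceptor_num in truth["register"]:
            n = residues[(donor_chain, donor_num)].conformer()["N"].position
            o = residues[(acceptor_chain, acceptor_num)].conformer()["O"].position
            assert np.linalg.norm(n - o) == pytest.approx(2.9, abs=0.15)

    def test_turn_truth(self):
        model, truth = build_element("beta_turn_I", 5)
        assert truth["register"] == [("A", 4, "A", 1)]
        assert truth["ss"][("A", 2)] == "T"

    def test_omega_override(self):
        model, truth = build_element("helix", 6, omega_overrides={2: 170.0})
        devs = strain.omega_scan(model.chains["A"])
        values = {d.residue_number: d.value for d in devs}
        assert values[4] == pytest.approx(-10.0, abs=1e-6)


class TestAttachAdps:
    def test_invalid_anisotropy(self):
        model, _ = build_element("helix", 4)
        with pytest.raises(ValueError):
            attach_adps(model, 0.0)

    def test_zero_axis_rejected(self):
        model, _ = build_element("helix", 4)
        with pytest.raises(ValueError, match="axis"):
            attach_adps(model, 0.5, axis=(0.0, 0.0, 0.0))

    def test_non_unit_axis_normalized(self):
        from strainscope.adp import atom_anisotropy

        model, _ = build_element("helix", 4)
        attach_adps(model, 0.3, axis=(0.0, 0.0, 17.0), b_eq=9.0)
        tensor = atom_anisotropy(next(model.atoms()))
        assert abs(abs(tensor.major_axis[2]) - 1.0) < 1e-9

    def test_isotropic_limit(self):
        model, _ = build_element("helix", 4)
        attach_adps(model, 1.0, b_eq=7.0)
        atom = next(model.atoms())
        assert np.allclose(atom.uij, np.eye(3) * atom.uij[0, 0])


class TestFixtureSuite:
    def test_manifest_and_reproducibility(self, tmp_path):
        dir1 = tmp_path / "one"
        dir2 = tmp_path / "two"
        manifest1 = generate_fixture_suite(dir1, seed=7)
        generate_fixture_suite(dir2, seed=7)
        files = sorted(p.name for p in dir1.glob("*"))
        assert "manifest.json" in files
        for name in files:
            assert filecmp.cmp(dir1 / name, dir2 / name, shallow=False), name

    def test_manifest_ground_truth_closure(self, tmp_path):
        out = tmp_path / "fx"
        manifest = generate_fixture_suite(out, seed=0)
        for name, info in manifest["files"].items():
            if info["kind"] != "bend":
                continue
            model = read_structure(out / name)
            res = model.chains["A"][0]
            measured = strain.measure_residue(res).value
            # PDB coordinates carry 3 decimals; the quantization noise on a
            # short-lever pseudo-torsion can reach ~0.2 deg (in-memory
            # closure at 0.05 deg is covered by the acceptance tests).
            assert measured == pytest.approx(info["ground_truth"], abs=0.25)

    def test_manifest_omega_closure(self, tmp_path):
        out = tmp_path / "fx"
        manifest = generate_fixture_suite(out, seed=0)
        for name, info in manifest["files"].items():
            if info["kind"] != "omega":
                continue
            model = read_structure(out / name)
            devs = strain.omega_scan(model.chains["A"])
            measured = devs[info["bond_index"]].value
            assert measured == pytest.approx(info["ground_truth"], abs=0.05)

    def test_manifest_is_valid_json(self, tmp_path):
        out = tmp_path / "fx"
        generate_fixture_suite(out, seed=0)
        manifest = json.loads((out / "manifest.json").read_text())
        assert manifest["seed"] == 0
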