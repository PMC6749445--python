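import numpy as np
import pytest

from strainscope import strain, synthetic
from strainscope.strain import OutlierPolicy, flag_outliers
from strainscope.synthetic import DistortionSpec, build_chain, build_residue

from .conftest import random_rigid_transform

DELTAS = [1.0, 2.0, 5.0, 10.0, 20.0]


def transform_model(model, rotation, translation):
    for atom in model.atoms():
        atom.position = rotation @ atom.position + translation
    return model


class TestIdealResidues:
    @pytest.mark.parametrize("residue_type", ["ARG", "PHE", "TRP", "TYR"])
    def test_ideal_is_zero(self, residue_type):
        res, _ = build_residue(residue_type)
        measurement = strain.measure_residue(res)
        assert abs(measurement.value) <= 0.01

    def test_wrong_type_raises(self):
        res, _ = build_residue("PHE")
        with pytest.raises(ValueError):
            strain.arg_twist(res)

    def test_missing_atom_returns_none(self):
        res, _ = build_residue("ARG")
        res.atoms = [a for a in res.atoms if a.atom_name != "NH1"]
        res.atoms = [a for a in res.atoms if a.atom_name != "NH2"]
        assert strain.arg_twist(res) is None


class TestDistortionRecovery:
    @pytest.mark.parametrize("delta", DELTAS)
    @pytest.mark.parametrize(
        "residue_type,kind",
        [("ARG", "guanidinium_twist"), ("PHE", "cb_bend"), ("TRP", "cb_bend"), ("TYR", "cb_bend")],
    )
    def test_recovers_delta(self, residue_type, kind, delta):
        res, truth = build_residue(residue_type, DistortionSpec(kind=kind, magnitude=delta))
        measurement = strain.measure_residue(res)
        assert measurement.value == pytest.approx(truth["applied"], abs=1e-6)
        assert abs(measurement.value) == pytest.approx(delta, abs=0.05)

    def test_definition_forced_phe_example(self):
        # angle(CB, CG, CZ) = 173 deg must read as a 7 deg bend.
        res, _ = build_residue("PHE", DistortionSpec(kind="cb_bend", magnitude=7.0))
        from strainscope.geometry import angle

        atoms = res.conformer()
        assert angle(atoms["CB"].position, atoms["CG"].position, atoms["CZ"].position) == pytest.approx(173.0, abs=1e-6)
        assert strain.phe_bend(res).value == pytest.approx(7.0, abs=1e-6)

    def test_tyr_component_sum(self):
        res, _ = build_residue("TYR", DistortionSpec(kind="cb_bend", magnitude=10.0))
        assert strain.tyr_bend(res).value == pytest.approx(10.0, abs=1e-6)


class TestArgNamingNormalization:
    def test_swapped_eta_names_normalized(self):
        res, _ = build_residue("ARG")
        for atom in res.atoms:
            if atom.atom_name == "NH1":
                atom.atom_name = "NH2"
            elif atom.atom_name == "NH2":
                atom.atom_name = "NH1"
        measurement = strain.arg_twist(res)
        assert abs(measurement.value) <= 0.01
        assert "swapped" in measurement.note

    def test_planar_never_intermediate(self):
        # On an exactly planar guanidinium the raw torsion is 0 or 180; the
        # normalized report is always near 0.
        res, _ = build_residue("ARG")
        measurement = strain.arg_twist(res)
        assert abs(measurement.value) <= 0.01


class TestOmega:
    def test_ideal_chain_all_zero(self):
        model = build_chain(["ALA"] * 6, [-139.0] * 6, [135.0] * 6)
        devs = strain.omega_scan(model.chains["A"])
        assert len(devs) == 5
        assert all(abs(d.value) <= 0.01 for d in devs)
        assert all(d.reference == 180.0 for d in devs)

    def test_prescribed_bond(self):
        omega = [180.0, 180.0, 170.0, 180.0, 180.0]
        model = build_chain(["ALA"] * 6, [-139.0] * 6, [135.0] * 6, omega)
        devs = strain.omega_scan(model.chains["A"])
        values = {d.residue_number: d.value for d in devs}
        assert values[4] == pytest.approx(-10.0, abs=1e-6)
        for resnum in (2, 3, 5, 6):
            assert values[resnum] == pytest.approx(0.0, abs=1e-6)

    def test_cis_classification(self):
        model = build_chain(["ALA", "ALA", "ALA"], [-139.0] * 3, [135.0] * 3, [5.0, 180.0])
        devs = strain.omega_scan(model.chains["A"])
        by_res = {d.residue_number: d for d in devs}
        assert by_res[2].reference == 0.0
        assert "cis" in by_res[2].note
        assert by_res[2].value == pytest.approx(5.0, abs=1e-6)
        assert by_res[3].reference == 180.0
        assert "trans" in by_res[3].note

    def test_no_bond_is_both_cis_and_trans(self):
        model = build_chain(["ALA"] * 4, [-139.0] * 4, [135.0] * 4, [180.0, 5.0, 170.0])
        devs = strain.omega_scan(model.chains["A"])
        for d in devs:
            assert ("cis" in d.note) != ("trans" in d.note)

    def test_chain_break_skipped(self):
        model = build_chain(["ALA"] * 4, [-139.0] * 4, [135.0] * 4)
        residues = model.chains["A"]
        # Sever the link between residues 2 and 3.
        residues[1].next = None
        residues[2].prev = None
        devs = strain.omega_scan(residues)
        assert {d.residue_number for d in devs} == {2, 4}


class TestFlagOutliers:
    def test_all_zero_no_outliers(self):
        model = build_chain(["ALA"] * 4, [-139.0] * 4, [135.0] * 4)
        devs = strain.omega_scan(model.chains["A"])
        annotated, counts = flag_outliers(devs)
        assert counts == {}
        assert not any(m.is_outlier for m in annotated)

    def test_fixed_threshold_counting(self):
        base, _ = build_residue("ARG")
        measurements = []
        for value in (3.0, 9.0, 11.0, 25.0):
            measurements.append(
                strain.BendMeasurement("A", 1, "", "ARG", "arg_twist", value, 0.0)
            )
        annotated, counts = flag_outliers(
            measurements, OutlierPolicy(arg_twist=10.0)
        )
        assert counts == {"arg_twist": 2}
        assert [m.is_outlier for m in annotated] == [False, False, True, True]

    def test_threshold_recorded(self):
        measurements = [strain.BendMeasurement("A", 1, "", "PHE", "phe_bend", 6.0, 0.0)]
        annotated, _ = flag_outliers(measurements)
        assert annotated[0].threshold_used == 5.0
        assert annotated[0].is_outlier


class TestRigidBodyInvariance:
    @pytest.mark.parametrize("residue_type,kind", [("ARG", "guanidinium_twist"), ("TRP", "cb_bend")])
    def test_metrics_invariant(self, residue_type, kind, rng):
        res, _ = build_residue(residue_type, DistortionSpec(kind=kind, magnitude=7.0))
        before = strain.measure_residue(res).value
        rotation, translation = random_rigid_transform(rng)
        for atom in res.atoms:
            atom.position = rotation @ atom.position + translation
        after = strain.measure_residue(res).value
        assert after == pytest.approx(before, abs=1e-6)

    def test_omega_invariant(self, rng):
        model = build_chain(["ALA"] * 5, [-139.0] * 5, [135.0] * 5, [180.0, 172.0, 180.0, 180.0])
        before = [d.value for d in strain.omega_scan(model.chains["A"])]
        rotation, translation = random_rigid_transform(rng)
        transform_model(model, rotation, translation)
        after = [d.value for d in strain.omega_scan(model.chains["A"])]
        assert np.allclose(before, after, atol=1e-6)


class TestScanAndTable:
    def test_scan_structure_covers_all_metrics(self):
        model = build_chain(
            ["ARG", "PHE", "TRP", "TYR", "ALA"], [-139.0] * 5, [135.0] * 5
        )
        measurements = strain.scan_structure(model)
        metrics = {m.metric for m in measurements}
        assert metrics == {"arg_twist", "phe_bend", "trp_bend", "tyr_bend", "omega_dev"}

    def test_table_is_sorted_and_complete(self):
        model = build_chain(["ARG", "PHE"], [-139.0] * 2, [135.0] * 2)
        measurements, _ = flag_outliers(strain.scan_structure(model))
        table = strain.measurements_table(measurements, "TEST")
        assert list(table.columns)[:6] == ["entry", "chain", "resnum", "icode", "resname", "metric"]
        assert table["resnum"].is_monotonic_increasing
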