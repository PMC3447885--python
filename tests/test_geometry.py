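import math

import numpy as np
import pandas as pd
import pytest

from zincluster.connectivity import Assignment, MSL2_ASSIGNMENT
from zincluster.errors import AtomLookupError, DegenerateGeometryError
from zincluster.geometry import (
    TETRAHEDRAL_ANGLE,
    cluster_topology,
    coordination_report,
    detect_metal_sites,
    ensemble_rmsd,
    hbond_check,
    superpose,
    superpose_clusters,
)
from zincluster.pdbio import Model, StructureEnsemble, ensemble_to_pdb, read_pdb_string
from zincluster.synthetic import GeneratorConfig, make_cluster_coordinates

from _oracles import horn_superpose_rmsd, naive_bond_angles


def rigid_transform(xyz, axis, angle_deg, translation):
    axis = np.asarray(axis, float) / np.linalg.norm(axis)
    a = math.radians(angle_deg)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    R = np.eye(3) + math.sin(a) * K + (1 - math.cos(a)) * (K @ K)
    return xyz @ R.T + np.asarray(translation)


class TestDetectMetalSites:
    def test_ideal_cluster_composition(self, ideal_model):
        sites = detect_metal_sites(ideal_model)
        assert len(sites) == 1
        site = sites[0]
        assert len(site.metals) == 3
        assert len(site.ligands) == 9
        assert len(site.bonds) == 12

    def test_bridging_residues_recovered(self, ideal_model):
        site = detect_metal_sites(ideal_model)[0]
        assert site.bridging_residues == frozenset({525, 539, 553})
        assert site.terminal_residues == frozenset({527, 544, 546, 556, 558, 561})

    def test_apo_model_no_sites(self, ideal_model):
        apo = Model(ideal_model.atoms[ideal_model.atoms["element"] != "Zn"].copy())
        assert detect_metal_sites(apo) == []

    def test_isolated_mononuclear_sites_not_merged(self):
        a1 = Assignment(frozenset([("A", 1), ("A", 2), ("A", 3), ("A", 4)]))
        e1 = make_cluster_coordinates(GeneratorConfig(n_models=1), template=a1)
        m1 = e1[0]
        shifted = m1.with_xyz(m1.xyz + np.array([50.0, 0.0, 0.0]))
        df = shifted.atoms.copy()
        df["res_seq"] = df["res_seq"] + 100
        combined = Model(pd.concat([m1.atoms, df], ignore_index=True))
        sites = detect_metal_sites(combined)
        assert len(sites) == 2
        assert all(len(s.metals) == 1 for s in sites)

    def test_noised_cluster_keeps_topology(self):
        ens = make_cluster_coordinates(
            GeneratorConfig(seed=7, coordinate_noise=0.05, n_models=1)
        )
        site = detect_metal_sites(ens[0])[0]
        assert len(site.bonds) == 12
        assert site.bridging_residues == frozenset({525, 539, 553})


class TestClusterTopology:
    def test_msl2_fingerprint(self, ideal_model):
        site = detect_metal_sites(ideal_model)[0]
        topo = cluster_topology(site)
        assert topo.metal_ligand_indices == ((1, 2, 3, 4), (1, 5, 6, 7), (3, 6, 8, 9))
        assert topo.bridging_indices == (1, 3, 6)

    def test_renumbering_invariance(self, ideal_model):
        df = ideal_model.atoms.copy()
        df["res_seq"] = df["res_seq"] + 100
        topo_a = cluster_topology(detect_metal_sites(ideal_model)[0])
        topo_b = cluster_topology(detect_metal_sites(Model(df))[0])
        assert topo_a == topo_b

    def test_rigid_motion_invariance(self, ideal_model):
        moved = ideal_model.with_xyz(
            rigid_transform(ideal_model.xyz, [1, 2, 3], 77.0, [5.0, -3.0, 9.0])
        )
        topo_a = cluster_topology(detect_metal_sites(ideal_model)[0])
        topo_b = cluster_topology(detect_metal_sites(moved)[0])
        assert topo_a == topo_b

    def test_mononuclear_fingerprint(self):
        a1 = Assignment(frozenset([("A", 10), ("A", 20), ("A", 30), ("A", 40)]))
        ens = make_cluster_coordinates(GeneratorConfig(n_models=1), template=a1)
        topo = cluster_topology(detect_metal_sites(ens[0])[0])
        assert topo.metal_ligand_indices == ((1, 2, 3, 4),)
        assert topo.bridging_indices == ()

    def test_json_is_canonical(self, ideal_model):
        site = detect_metal_sites(ideal_model)[0]
        assert cluster_topology(site).to_json() == cluster_topology(site).to_json()


class TestCoordinationReport:
    def test_ideal_cluster_geometry(self, ideal_model):
        report = coordination_report(detect_metal_sites(ideal_model)[0])
        assert report.mean_bond_length == pytest.approx(2.3, abs=1e-9)
        assert report.mean_angle == pytest.approx(TETRAHEDRAL_ANGLE, abs=1e-9)
        assert report.mean_tetrahedrality == pytest.approx(0.0, abs=1e-9)
        assert round(report.mean_angle, 1) == 109.5

    def test_matches_naive_oracle_under_noise(self):
        ens = make_cluster_coordinates(
            GeneratorConfig(seed=3, coordinate_noise=0.05, n_models=1)
        )
        site = detect_metal_sites(ens[0])[0]
        report = coordination_report(site)
        for i, per_metal in enumerate(report.per_metal):
            donors = [site.ligands[j].xyz for mi, j in site.bonds if mi == i]
            bonds, angles = naive_bond_angles(site.metals[i].xyz, donors)
            assert np.allclose(sorted(per_metal.bond_lengths), sorted(bonds))
            assert np.allclose(sorted(per_metal.angles), sorted(angles))

    def test_two_coordinate_metal_single_angle(self):
        a = Assignment(frozenset([("A", 1), ("A", 2)]))
        ens = make_cluster_coordinates(GeneratorConfig(n_models=1), template=a)
        report = coordination_report(detect_metal_sites(ens[0])[0])
        assert len(report.per_metal[0].angles) == 1
        assert report.per_metal[0].tetrahedrality is not None


class TestSuperposition:
    def test_self_superposition_zero(self, ideal_model):
        site = detect_metal_sites(ideal_model)[0]
        pairing = [(i, i) for i in range(12)]
        res = superpose_clusters(site, site, pairing)
        assert res.rmsd == pytest.approx(0.0, abs=1e-12)

    def test_rigid_copy_zero(self, ideal_model):
        site = detect_metal_sites(ideal_model)[0]
        moved = ideal_model.with_xyz(
            rigid_transform(ideal_model.xyz, [0, 1, 1], 33.0, [1.0, 2.0, 3.0])
        )
        site_b = detect_metal_sites(moved)[0]
        res = superpose_clusters(site, site_b, [(i, i) for i in range(12)])
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)

    def test_matches_quaternion_oracle(self, ideal_model):
        site = detect_metal_sites(ideal_model)[0]
        coords = site.atom_coords()
        rng = np.random.default_rng(42)
        noised = rigid_transform(coords, [1, 0, 2], 25.0, [4, 5, 6]) + rng.normal(
            0, 0.1, coords.shape
        )
        res = superpose(coords, noised)
        assert res.rmsd == pytest.approx(horn_superpose_rmsd(coords, noised), abs=1e-6)

    def test_proper_rotation_only(self, ideal_model):
        site = detect_metal_sites(ideal_model)[0]
        coords = site.atom_coords()
        mirrored = coords * np.array([-1.0, 1.0, 1.0])
        res = superpose(coords, mirrored)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0)
        assert res.rmsd > 0.1  # a reflection is never matched exactly

    def test_collinear_pairing_rejected(self):
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(DegenerateGeometryError):
            superpose(line, line)

    def test_too_few_points_rejected(self):
        pts = np.array([[0.0, 0, 0], [1, 1, 1]])
        with pytest.raises(DegenerateGeometryError):
            superpose(pts, pts)


class TestEnsembleRMSD:
    def test_identical_models_zero(self, ideal_ensemble):
        res = ensemble_rmsd(ideal_ensemble, [(525, 561)], atom_set="heavy")
        assert res.mean_rmsd == pytest.approx(0.0, abs=1e-9)

    def test_closed_form_noise_prediction(self):
        sigma, n_models = 0.2, 20
        ens = make_cluster_coordinates(
            GeneratorConfig(
                seed=11, coordinate_noise=sigma,
                sidechain_noise_scale=1.0, n_models=n_models,
            )
        )
        res = ensemble_rmsd(ens, [(525, 561)], atom_set="heavy")
        predicted = math.sqrt(3) * sigma * math.sqrt(1 - 1 / n_models)
        assert res.mean_rmsd == pytest.approx(predicted, rel=0.10)

    def test_backbone_not_larger_than_heavy(self):
        ens = make_cluster_coordinates(
            GeneratorConfig(seed=2, coordinate_noise=0.15, n_models=10)
        )  # side chains noisier by construction
        rb = ensemble_rmsd(ens, [(525, 561)], atom_set="backbone")
        rh = ensemble_rmsd(ens, [(525, 561)], atom_set="heavy")
        assert rb.mean_rmsd <= rh.mean_rmsd

    def test_missing_atoms_excluded_and_reported(self, ideal_ensemble):
        m0, m1 = ideal_ensemble[0], ideal_ensemble[1]
        df = m1.atoms
        trimmed = Model(df[~((df["res_seq"] == 527) & (df["name"] == "CA"))].copy())
        ens = StructureEnsemble(models=[m0, trimmed])
        res = ensemble_rmsd(ens, [(525, 561)], atom_set="backbone")
        assert ("A", 527, "CA") in res.excluded_atoms

    def test_single_model_rejected(self, ideal_ensemble):
        with pytest.raises(ValueError):
            ensemble_rmsd(
                StructureEnsemble(models=[ideal_ensemble[0]]), [(525, 561)]
            )


class TestHbond:
    def hbond_model(self, da_dist, with_h=True, h_on_axis=True):
        rows = [
            dict(serial=1, name="OG1", element="O", res_name="THR", res_seq=538,
                 chain="A", x=0.0, y=0.0, z=0.0),
            dict(serial=2, name="O", element="O", res_name="GLY", res_seq=560,
                 chain="A", x=da_dist, y=0.0, z=0.0),
        ]
        if with_h:
            hx = 1.0 if h_on_axis else -1.0
            rows.append(
                dict(serial=3, name="HG1", element="H", res_name="THR", res_seq=538,
                     chain="A", x=hx, y=0.0, z=0.0)
            )
        return Model(pd.DataFrame(rows))

    def test_short_contact_with_aligned_h(self):
        res = hbond_check(self.hbond_model(2.9), (538, "OG1"), (560, "O"))
        assert res.present
        assert res.angle == pytest.approx(180.0)

    def test_long_contact_rejected(self):
        res = hbond_check(self.hbond_model(5.0), (538, "OG1"), (560, "O"))
        assert not res.present

    def test_misdirected_hydrogen_rejected(self):
        res = hbond_check(
            self.hbond_model(2.9, h_on_axis=False), (538, "OG1"), (560, "O")
        )
        assert not res.present  # D-H...A angle 0 deg

    def test_distance_only_without_hydrogen(self):
        res = hbond_check(self.hbond_model(2.9, with_h=False), (538, "OG1"), (560, "O"))
        assert res.present and res.angle is None

    def test_missing_acceptor_named(self):
        with pytest.raises(AtomLookupError, match="560"):
            hbond_check(self.hbond_model(2.9), (538, "OG1"), (560, "OXT"))


class TestPdbRoundTrip:
    def test_ensemble_survives_pdb_serialization(self, ideal_ensemble):
        text = ensemble_to_pdb(ideal_ensemble)
        back = read_pdb_string(text)
        assert len(back) == len(ideal_ensemble)
        assert np.allclose(back[0].xyz, ideal_ensemble[0].xyz, atol=1e-3)
        site = detect_metal_sites(back[0])[0]
        assert len(site.bonds) == 12
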