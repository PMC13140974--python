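"""Topology/trajectory loading, COM geometry, binning and RMSD."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from conftest import toy_trajectory
from oxescape.errors import ConfigError, DataError
from oxescape.trajectory import (ELEMENT_MASSES, bin_series, distance_series,
                                 element_from_atom_name, load_trajectory,
                                 mass_of, rmsd_series, site_center)


class TestElements:
    @pytest.mark.parametrize("name,expected", [
        ("CA", "C"), ("N", "N"), ("1HB", "H"), ("OXT", "O"),
        ("FE", "FE"), ("CL1", "CL"), ("MG", "MG"),
    ])
    def test_element_inference(self, name, expected):
        assert element_from_atom_name(name) == expected

    def test_unknown_name_falls_back_to_carbon_mass(self):
        assert mass_of("XQ") == 12.0

    def test_explicit_element_wins(self):
        assert mass_of("CA", element="Ca") == ELEMENT_MASSES["CA"]


class TestSiteCenter:
    def test_equal_masses_midpoint(self):
        traj = toy_trajectory([[[0, 0, 0], [2, 0, 0]]], site=[0, 1])
        np.testing.assert_allclose(site_center(traj, 0), [1, 0, 0])

    def test_single_atom_identity(self):
        traj = toy_trajectory([[[3, 4, 0]]], site=[0])
        np.testing.assert_allclose(site_center(traj, 0), [3, 4, 0])

    def test_unequal_masses_match_direct_formula(self):
        rng = np.random.default_rng(11)
        xyz = rng.normal(size=(1, 5, 3))
        elems = ["C", "O", "N", "S", "H"]
        traj = toy_trajectory(xyz, elements=elems, site=range(5))
        m = np.array([ELEMENT_MASSES[e] for e in elems])
        expected = (m[:, None] * xyz[0]).sum(axis=0) / m.sum()
        np.testing.assert_allclose(site_center(traj, 0), expected, atol=1e-12)

    def test_empty_site_fatal(self):
        traj = toy_trajectory([[[0, 0, 0]]])
        with pytest.raises(ConfigError):
            site_center(traj, 0)


class TestDistanceSeries:
    def _two_atom(self, n_frames, lig_pos, dt=0.2):
        coords = np.zeros((n_frames, 2, 3))
        coords[:, 1] = lig_pos
        return toy_trajectory(coords, ligands={"lig": [1]}, site=[0], dt_ns=dt)

    def test_constant_distance_binned(self):
        traj = self._two_atom(200, [5.0, 0, 0])
        s = distance_series(traj, "lig", bin_factor=100)
        assert s.n_frames == 2
        np.testing.assert_allclose(s.values, 5.0)
        assert s.frame_interval_ns == pytest.approx(20.0)

    def test_binning_frame_arithmetic(self):
        traj = self._two_atom(1000, [1.0, 0, 0])
        assert distance_series(traj, "lig", bin_factor=100).n_frames == 10

    def test_binned_values_are_block_means(self):
        rng = np.random.default_rng(5)
        vals = np.abs(rng.normal(10, 2, size=437))
        coords = np.zeros((437, 2, 3))
        coords[:, 1, 0] = vals
        traj = toy_trajectory(coords, ligands={"lig": [1]}, site=[0])
        s = distance_series(traj, "lig", bin_factor=25)
        expected = np.array([vals[i * 25:(i + 1) * 25].mean()
                             for i in range(437 // 25)])
        np.testing.assert_allclose(s.values, expected, atol=1e-12)

    def test_bin_factor_one_is_identity(self):
        rng = np.random.default_rng(6)
        vals = np.abs(rng.normal(8, 1, size=50))
        coords = np.zeros((50, 2, 3))
        coords[:, 1, 2] = vals
        traj = toy_trajectory(coords, ligands={"lig": [1]}, site=[0])
        np.testing.assert_allclose(distance_series(traj, "lig", 1).values,
                                   vals, atol=1e-12)

    def test_rigid_transform_invariance(self):
        rng = np.random.default_rng(7)
        coords = rng.normal(size=(20, 6, 3))
        traj = toy_trajectory(coords, ligands={"lig": [5]}, site=[0, 1, 2])
        base = distance_series(traj, "lig").values
        rot = Rotation.from_euler("xyz", [0.3, -1.1, 2.0]).as_matrix()
        moved = coords @ rot.T + np.array([10.0, -3.0, 7.0])
        traj2 = toy_trajectory(moved, ligands={"lig": [5]}, site=[0, 1, 2])
        np.testing.assert_allclose(distance_series(traj2, "lig").values,
                                   base, atol=1e-9)

    def test_oversized_bin_factor_fatal(self):
        traj = self._two_atom(10, [1.0, 0, 0])
        with pytest.raises(DataError):
            distance_series(traj, "lig", bin_factor=11)

    @given(st.integers(1, 30), st.integers(30, 200))
    @settings(deadline=None, derandomize=True, max_examples=30)
    def test_bin_length_property(self, k, n):
        vals = np.linspace(0, 1, n)
        assert len(bin_series(vals, k)) == n // k


class TestRMSD:
    def _random_structure(self, seed, n_atoms=8, n_frames=1):
        rng = np.random.default_rng(seed)
        return rng.normal(size=(n_frames, n_atoms, 3))

    def test_identical_frames_zero(self):
        xyz = self._random_structure(1)
        traj = toy_trajectory(np.repeat(xyz, 3, axis=0))
        np.testing.assert_allclose(
            rmsd_series(traj, np.arange(8)), 0.0, atol=1e-7)

    def test_rigid_transform_zero(self):
        xyz = self._random_structure(2)[0]
        rot = Rotation.from_euler("zyx", [1.0, 0.2, -0.7]).as_matrix()
        frames = np.stack([xyz, xyz @ rot.T + [5, 5, 5]])
        traj = toy_trajectory(frames)
        r = rmsd_series(traj, np.arange(8))
        assert r[0] == 0.0
        assert r[1] == pytest.approx(0.0, abs=1e-7)

    def test_matches_independent_kabsch(self):
        rng = np.random.default_rng(3)
        ref = rng.normal(size=(10, 3))
        frames = [ref]
        for k in range(4):
            rot = Rotation.random(rng=np.random.default_rng(40 + k)).as_matrix()
            frames.append(ref @ rot.T + rng.normal(scale=0.3, size=(10, 3)))
        traj = toy_trajectory(np.array(frames))
        got = rmsd_series(traj, np.arange(10))

        def kabsch_rmsd(P, Q):
            # independent SVD superposition
            P = P - P.mean(axis=0)
            Q = Q - Q.mean(axis=0)
            U, S, Vt = np.linalg.svd(P.T @ Q)
            d = np.sign(np.linalg.det(U @ Vt))
            R = U @ np.diag([1, 1, d]) @ Vt
            return np.sqrt(((P - Q @ R.T) ** 2).sum() / len(P))

        expected = [kabsch_rmsd(np.array(frames)[0], f) for f in frames]
        np.testing.assert_allclose(got, expected, atol=1e-6)

    def test_too_few_atoms_fatal(self):
        traj = toy_trajectory(self._random_structure(4, n_atoms=2))
        with pytest.raises(DataError):
            rmsd_series(traj, np.arange(2))

    def test_non_negative(self):
        traj = toy_trajectory(self._random_structure(5, n_frames=6))
        assert np.all(rmsd_series(traj, np.arange(8)) >= 0)


class TestLoading:
    def test_single_frame_pdb_identity(self, tmp_path):
        pdb = tmp_path / "one.pdb"
        pdb.write_text(
            "ATOM      1  CA  ALA A   1       1.000   2.000   3.000"
            "  1.00  0.00           C\n"
            "ATOM      2  CB  ALA A   1       2.000   2.000   3.000"
            "  1.00  0.00           C\n"
            "ATOM      3  N   ALA A   1       0.000   1.000   3.000"
            "  1.00  0.00           N\n"
            "END\n")
        traj = load_trajectory(pdb, frame_interval_ns=0.2)
        assert traj.n_frames == 1
        np.testing.assert_allclose(traj.coords[0, 0], [1, 2, 3], atol=1e-3)

    def test_atom_count_mismatch_fatal(self, tmp_path, bundle):
        bundle_dir, manifest = bundle
        vinfo = manifest["variants"]["narrow"]
        top = bundle_dir / "narrow" / vinfo["topology"]
        bad = tmp_path / "bad.xyz"
        bad.write_text("3\nframe 0\nO 0 0 0\nO 1 0 0\nO 2 0 0\n")
        with pytest.raises(DataError, match="mismatch"):
            load_trajectory(top, bad, frame_interval_ns=0.2)

    def test_missing_frame_interval_for_text_fatal(self, bundle):
        bundle_dir, manifest = bundle
        vinfo = manifest["variants"]["narrow"]
        vdir = bundle_dir / "narrow"
        with pytest.raises(ConfigError, match="frame_interval"):
            load_trajectory(vdir / vinfo["topology"],
                            vdir / vinfo["replicates"][0])

    def test_generator_bundle_roundtrip(self, bundle):
        """Written XYZ coordinates reload to within PDB/XYZ precision."""
        from oxescape.brownian import LigandDynamics, make_variant_pair, \
            simulate_ligand
        from dataclasses import replace

        bundle_dir, manifest = bundle
        vinfo = manifest["variants"]["narrow"]
        vdir = bundle_dir / "narrow"
        traj = load_trajectory(
            vdir / vinfo["topology"], vdir / vinfo["replicates"][0],
            frame_interval_ns=manifest["design"]["frame_interval_ns"],
            ligand_selections=vinfo["ligand_selections"],
            site_selection=manifest["site_selection"])
        # regenerate the same ligand walk directly and compare
        narrow, _ = make_variant_pair()
        dyn = LigandDynamics(
            max_time_ns=manifest["design"]["durations_ns"][0]
            * manifest["time_scale"],
            seed=(42 * 1_000_003 + 0 * 10_007 + 0 * 101 + 0) % 2**31)
        res = simulate_ligand(narrow, dyn)
        lig_idx = traj.topology.ligand_selectors["O2_1"]
        np.testing.assert_allclose(
            traj.coords[:, lig_idx[0]], res.positions, atol=1e-3)
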