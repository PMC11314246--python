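import numpy as np
import pytest

from pepsurf import adsorption
from conftest import make_trajectory


class TestComSeparation:
    def test_single_atom_peptide(self):
        traj = make_trajectory([7.0], n_frames=3)
        series, (edges, probs) = adsorption.com_separation(traj)
        np.testing.assert_allclose(series.com_z, 7.0)
        assert probs.sum() == pytest.approx(1.0)

    def test_equal_mass_midpoint(self):
        traj = make_trajectory([4.0, 10.0])
        series, _ = adsorption.com_separation(traj)
        assert series.com_z[0] == pytest.approx(7.0)

    def test_histogram_mode_at_designed_height(self, samch3):
        traj, _ = samch3
        _, (edges, probs) = adsorption.com_separation(traj, bin_width=1.0)
        mode_bin = np.argmax(probs)
        assert edges[mode_bin] <= 7.0 < edges[mode_bin + 1]

    def test_surface_required(self, samch3):
        from pepsurf.synthetic import generate_trajectory, preset

        bulk, _ = generate_trajectory(preset("bulk", n_frames=5, seed=0))
        with pytest.raises(ValueError, match="surface"):
            adsorption.com_separation(bulk)

    def test_closest_distance_is_min_residue_profile(self, samch3):
        traj, _ = samch3
        series, _ = adsorption.com_separation(traj)
        dist, _ = adsorption._residue_min_z(traj)
        np.testing.assert_allclose(series.closest_distance, dist.min(axis=1))

    def test_closest_residue_counts_sum_to_frames(self, samch3):
        traj, _ = samch3
        series, _ = adsorption.com_separation(traj)
        counts = adsorption.closest_residue_counts(series)
        assert counts["count"].sum() == traj.n_frames


class TestResidueProfile:
    def test_rigid_pose_zero_sd(self):
        traj = make_trajectory([3.0, 8.0], n_frames=10, resids=[1, 2])
        prof = adsorption.residue_surface_profile(traj)
        np.testing.assert_allclose(prof["sd"], 0.0)
        np.testing.assert_allclose(prof["mean"], [3.0, 8.0])

    def test_nearest_heavy_atom_of_residue(self):
        traj = make_trajectory([3.0, 5.0], resids=[1, 1])
        prof = adsorption.residue_surface_profile(traj)
        assert prof["mean"][0] == pytest.approx(3.0)

    def test_designed_proximity_minimal_at_planted_residue(self, planted_contacts):
        traj, _ = planted_contacts
        prof = adsorption.residue_surface_profile(traj)
        # residue 17 planted in contact 70% of frames dominates the profile
        assert prof.loc[prof["mean"].idxmin(), "residue"] == 17


class TestContactProbability:
    def test_always_in_contact(self):
        traj = make_trajectory([2.0], n_frames=5)
        table, finger = adsorption.contact_probability(traj)
        assert table["probability"][0] == 1.0
        assert finger.all()

    def test_never_in_contact(self):
        traj = make_trajectory([10.0], n_frames=5)
        table, finger = adsorption.contact_probability(traj)
        assert table["probability"][0] == 0.0
        assert not finger.any()

    def test_invalid_cutoff_rejected(self):
        traj = make_trajectory([2.0])
        with pytest.raises(ValueError):
            adsorption.contact_probability(traj, cutoff=0.0)

    def test_planted_rates_recovered_within_binomial_error(self, planted_contacts):
        traj, truth = planted_contacts
        table, _ = adsorption.contact_probability(traj)
        n = traj.n_frames
        for resid, p in truth.contact_rate.items():
            est = float(table.loc[table["residue"] == resid, "probability"].iloc[0])
            assert abs(est - p) < 3 * np.sqrt(p * (1 - p) / n)


class TestAdsorbedFilter:
    def test_always_adsorbed_preset_keeps_all(self, samch3):
        traj, _ = samch3
        assert adsorption.adsorbed_mask(traj).all()

    def test_far_peptide_keeps_none(self):
        traj = make_trajectory([50.0], n_frames=4)
        assert len(adsorption.adsorbed_filter(traj).frames) == 0

    def test_two_state_kept_fraction_matches_truth(self, samoh):
        traj, truth = samoh
        kept = adsorption.adsorbed_mask(traj).mean()
        p = truth.adsorbed.mean()
        se = np.sqrt(p * (1 - p) / traj.n_frames)
        assert abs(kept - p) <= 3 * se


class TestContactClusters:
    def test_single_fingerprint_single_cluster(self):
        finger = np.tile([0, 1, 1, 0], (20, 1))
        df = adsorption.cluster_contacts(finger)
        assert len(df) == 1
        assert df["population"][0] == pytest.approx(1.0)

    def test_disjoint_fingerprints_split_60_40(self):
        finger = np.array([[1, 0, 0, 0]] * 60 + [[0, 0, 1, 1]] * 40)
        df = adsorption.cluster_contacts(finger)
        np.testing.assert_allclose(df["population"], [0.6, 0.4])

    def test_hamming_neighbors_merge(self):
        # fingerprints A and B differ at one residue -> merged; C disjoint
        A = [1, 1, 0, 0, 0]
        B = [1, 1, 1, 0, 0]
        C = [0, 0, 0, 1, 1]
        finger = np.array([A] * 5 + [B] * 3 + [C] * 2)
        df = adsorption.cluster_contacts(finger, merge_hamming=1)
        assert len(df) == 2
        np.testing.assert_allclose(df["population"], [0.8, 0.2])

    def test_populations_sum_to_adsorbed_fraction(self):
        rng = np.random.default_rng(0)
        finger = (rng.random((200, 31)) < 0.1).astype(np.uint8)
        df = adsorption.cluster_contacts(finger, merge_hamming=0)
        ads_fraction = finger.any(axis=1).mean()
        assert df["population"].sum() == pytest.approx(ads_fraction)

    def test_no_adsorbed_frames_warns_empty(self):
        with pytest.warns(UserWarning, match="no adsorbed frames"):
            df = adsorption.cluster_contacts(np.zeros((10, 31), dtype=np.uint8))
        assert df.empty


class TestSurfaceHbonds:
    def _hbond_trajectory(self, n_to_surface, ligand="OH"):
        """Protein amide N-H pointing straight down at a surface oxygen."""
        from pepsurf.model import build_sam_surface, build_topology
        from pepsurf.synthetic import Trajectory

        topo = build_topology("GG", start_index=1)
        surface = build_sam_surface(4, 4, ligand, chain_height=10.0)
        target = surface.atom_table().iloc[0]
        coords = np.zeros((1, topo.n_atoms, 3))
        coords[:, :, 0] = target["x"] + np.arange(topo.n_atoms) * 3.0
        coords[:, :, 1] = target["y"]
        coords[:, :, 2] = target["z"] + 20.0
        # place residue-2 N directly above the first surface O, H in between
        n2 = topo.atoms.index[(topo.atoms["name"] == "N") & (topo.atoms["resid"] == 2)][0]
        coords[0, n2] = [target["x"], target["y"], target["z"] + n_to_surface]
        coords[0, n2 + 1] = [target["x"], target["y"], target["z"] + n_to_surface - 1.0]
        return Trajectory(topology=topo, frames=coords, surface=surface)

    def test_ideal_linear_bond_counts_one(self):
        traj = self._hbond_trajectory(2.9)
        out = adsorption.surface_hbonds(traj)
        assert out.loc[out["residue"] == 2, "donor"].iloc[0] == pytest.approx(1.0)

    def test_beyond_cutoff_counts_zero(self):
        traj = self._hbond_trajectory(4.5)
        out = adsorption.surface_hbonds(traj)
        assert out["donor"].sum() == 0.0

    def test_ch3_surface_yields_zeros_with_notice(self):
        traj = self._hbond_trajectory(2.9, ligand="CH3")
        with pytest.warns(UserWarning, match="no hydrogen-bonding groups"):
            out = adsorption.surface_hbonds(traj)
        assert out[["donor", "acceptor"]].to_numpy().sum() == 0.0

    def test_planted_bonds_average_to_plant_count(self):
        # the same ideal bond in every frame -> mean exactly 1 per frame
        traj = self._hbond_trajectory(2.9)
        frames = np.repeat(traj.frames, 7, axis=0)
        from pepsurf.synthetic import Trajectory

        traj7 = Trajectory(topology=traj.topology, frames=frames, surface=traj.surface)
        out = adsorption.surface_hbonds(traj7)
        assert out.loc[out["residue"] == 2, "donor"].iloc[0] == pytest.approx(1.0)
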