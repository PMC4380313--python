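"""Kabsch fits, RMSD/RMSF oracles, native-contact retention."""

import numpy as np
import pytest

from channelgate import (
    Frame,
    Trajectory,
    contact_retention,
    native_contacts,
    rmsd_series,
    rmsf,
    simulate,
    superpose,
)
from channelgate.structure_metrics import apply_fit

from conftest import small_config


def random_rigid(rng):
    q = rng.normal(size=(3, 3))
    u, _, vt = np.linalg.svd(q)
    rot = u @ vt
    if np.linalg.det(rot) < 0:
        rot[:, 0] *= -1
    return rot, rng.normal(scale=10.0, size=3)


@pytest.fixture(scope="module")
def cloud():
    return np.random.default_rng(0).normal(scale=5.0, size=(200, 3))


class TestSuperpose:
    def test_identity_gives_zero_rmsd(self, cloud):
        res = superpose(cloud, cloud)
        assert res.rmsd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(res.rotation, np.eye(3), atol=1e-9)

    def test_rigid_transform_gives_zero_rmsd(self, cloud):
        rng = np.random.default_rng(1)
        for _ in range(5):
            rot, t = random_rigid(rng)
            moved = cloud @ rot.T + t
            res = superpose(moved, cloud)
            assert res.rmsd < 1e-9
            assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_rotation_is_proper_orthogonal(self, cloud):
        rng = np.random.default_rng(2)
        noisy = cloud + rng.normal(scale=0.5, size=cloud.shape)
        res = superpose(noisy, cloud)
        np.testing.assert_allclose(res.rotation @ res.rotation.T, np.eye(3),
                                   atol=1e-9)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_gaussian_noise_rmsd_follows_sigma_sqrt3(self):
        rng = np.random.default_rng(3)
        big = rng.normal(scale=8.0, size=(4000, 3))
        sigma = 0.25
        noisy = big + rng.normal(scale=sigma, size=big.shape)
        res = superpose(noisy, big)
        assert res.rmsd == pytest.approx(sigma * np.sqrt(3.0), rel=0.03)

    def test_symmetry_and_rigid_invariance(self, cloud):
        rng = np.random.default_rng(4)
        other = cloud + rng.normal(scale=1.0, size=cloud.shape)
        r1 = superpose(cloud, other).rmsd
        r2 = superpose(other, cloud).rmsd
        assert r1 == pytest.approx(r2, abs=1e-9)
        rot, t = random_rigid(rng)
        r3 = superpose(other @ rot.T + t, cloud).rmsd
        assert r3 == pytest.approx(r1, abs=1e-9)

    def test_degenerate_selection_errors(self):
        line = np.column_stack([np.arange(10.0), np.zeros(10), np.zeros(10)])
        with pytest.raises(ValueError, match="collinear"):
            superpose(line, line)
        with pytest.raises(ValueError):
            superpose(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_matches_mdanalysis_rmsd(self, cloud):
        rms = pytest.importorskip("MDAnalysis.analysis.rms")
        rng = np.random.default_rng(5)
        other = cloud + rng.normal(scale=1.3, size=cloud.shape)
        ours = superpose(other, cloud).rmsd
        theirs = rms.rmsd(other, cloud, center=True, superposition=True)
        assert ours == pytest.approx(theirs, abs=1e-6)


class TestRMSDSeries:
    def _static_traj(self, cloud, n=4):
        from channelgate.io_core import Atom, Topology
        atoms = [Atom(i, "CA", i + 1, "ALA", 1, "C", True, 1.7)
                 for i in range(len(cloud))]
        topo = Topology(atoms)
        frames = [Frame(cloud.copy(), box=(50, 50, 50), time=0.1 * k)
                  for k in range(n)]
        return Trajectory(topo, frames)

    def test_static_trajectory_is_all_zeros(self, cloud):
        traj = self._static_traj(cloud)
        series = rmsd_series(traj, traj.frames[0])
        np.testing.assert_allclose(series, 0.0, atol=1e-12)

    def test_single_frame_gives_one_value(self, cloud):
        traj = self._static_traj(cloud, n=1)
        assert rmsd_series(traj, traj.frames[0]).shape == (1,)

    def test_linear_divergence_is_monotone(self, cloud):
        rng = np.random.default_rng(6)
        direction = rng.normal(size=cloud.shape)
        direction[: len(direction) // 2] *= -1  # not a rigid motion
        traj = self._static_traj(cloud, n=6)
        frames = [Frame(cloud + 0.3 * k * direction, box=(50, 50, 50),
                        time=0.1 * k) for k in range(6)]
        traj = Trajectory(traj.topology, frames)
        series = rmsd_series(traj, traj.frames[0])
        assert np.all(np.diff(series) > 0)


class TestRMSF:
    def _traj_from_coords(self, coords_list):
        from channelgate.io_core import Atom, Topology
        n = len(coords_list[0])
        atoms = [Atom(i, "CA", i + 1, "ALA", 1, "C", True, 1.7)
                 for i in range(n)]
        topo = Topology(atoms)
        frames = [Frame(np.asarray(c), box=(50, 50, 50), time=0.1 * k)
                  for k, c in enumerate(coords_list)]
        return Trajectory(topo, frames)

    def test_static_trajectory_is_all_zeros(self, cloud):
        traj = self._traj_from_coords([cloud] * 3)
        np.testing.assert_allclose(rmsf(traj), 0.0, atol=1e-12)

    def test_oscillating_atom_full_period(self, cloud):
        """One atom moving +-a along x: RMSF = a / sqrt(2) over a period."""
        a = 2.0
        n_samples = 64
        coords = []
        for k in range(n_samples):
            c = cloud.copy()
            c[0, 0] += a * np.sin(2 * np.pi * k / n_samples)
            coords.append(c)
        traj = self._traj_from_coords(coords)
        fixed = np.arange(1, len(cloud))
        values = rmsf(traj, selection=np.arange(len(cloud)),
                      fit_selection=fixed)
        assert values[0] == pytest.approx(a / np.sqrt(2), rel=1e-3)
        np.testing.assert_allclose(values[1:], 0.0, atol=1e-6)

    def test_matches_direct_formula_when_no_fit_needed(self, cloud):
        """Jitter with the frame mean restored: fit is identity, RMSF is the
        plain per-atom standard deviation about the time mean."""
        rng = np.random.default_rng(7)
        coords = [cloud + rng.normal(scale=0.2, size=cloud.shape)
                  for _ in range(8)]
        traj = self._traj_from_coords(coords)
        ours = rmsf(traj)
        stack = np.stack([f.coordinates for f in traj.frames])
        # direct-definition oracle after the same superposition
        from channelgate.structure_metrics import superpose as sp
        mean = stack.mean(axis=0)
        for _ in range(60):
            fitted = np.stack([
                apply_fit(c, sp(c, mean)) for c in stack
            ])
            new_mean = fitted.mean(axis=0)
            if np.max(np.abs(new_mean - mean)) < 1e-9:
                mean = new_mean
                break
            mean = new_mean
        oracle = np.sqrt(np.mean(np.sum((fitted - mean) ** 2, axis=2), axis=0))
        np.testing.assert_allclose(ours, oracle, atol=1e-6)

    def test_requires_two_frames(self, cloud):
        traj = self._traj_from_coords([cloud])
        with pytest.raises(ValueError):
            rmsf(traj)


@pytest.fixture(scope="module")
def scaffold_traj():
    cfg = small_config(n_frames=3, planted_permeations=0, n_waters=0,
                       n_cations=0, n_anions=0, protein_jitter=0.0)
    traj, _ = simulate(cfg)
    return traj


class TestContacts:
    def test_contact_set_matches_brute_force(self, scaffold_traj):
        traj = scaffold_traj
        topo = traj.topology
        cs = native_contacts(traj.frames[0], topo, [(1, 2)],
                             residue_range=(15, 33), cutoff=8.0)
        i1 = topo.calpha_indices(subunit=1, residues=range(15, 34))
        i2 = topo.calpha_indices(subunit=2, residues=range(15, 34))
        expected = set()
        for a in i1:
            for b in i2:
                d = np.linalg.norm(traj.frames[0].coordinates[a]
                                   - traj.frames[0].coordinates[b])
                if d <= 8.0:
                    expected.add((int(a), int(b)))
        assert set(cs.pairs[(1, 2)]) == expected
        assert len(expected) > 0

    def test_zero_cutoff_gives_empty_set_with_warning(self, scaffold_traj):
        with pytest.warns(UserWarning, match="no native contacts"):
            cs = native_contacts(scaffold_traj.frames[0],
                                 scaffold_traj.topology, [(1, 2)],
                                 cutoff=0.0)
        assert cs.pairs[(1, 2)] == []

    def test_same_subunit_pair_is_rejected(self, scaffold_traj):
        with pytest.raises(ValueError, match="within one subunit"):
            native_contacts(scaffold_traj.frames[0], scaffold_traj.topology,
                            [(3, 3)])

    def test_static_trajectory_retains_everything(self, scaffold_traj):
        cs = native_contacts(scaffold_traj.frames[0], scaffold_traj.topology,
                             [(1, 2), (2, 3)])
        ret = contact_retention(scaffold_traj, cs)
        for fr in ret.fraction_per_frame.values():
            np.testing.assert_allclose(fr, 1.0)

    def test_everything_far_gives_zero_retention(self, scaffold_traj):
        cs = native_contacts(scaffold_traj.frames[0], scaffold_traj.topology,
                             [(1, 2)])
        shift = np.zeros((scaffold_traj.topology.n_atoms, 1))
        shift[25:50] = 1e6  # move subunit 2 away entirely
        far = [Frame(f.coordinates + shift * np.array([[1.0, 0.0, 0.0]]),
                     box=f.box, time=f.time)
               for f in scaffold_traj.frames]
        ret = contact_retention(Trajectory(scaffold_traj.topology, far), cs)
        np.testing.assert_allclose(ret.fraction_per_frame[(1, 2)], 0.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_displaced_subunit_loses_contacts_asymmetrically(self, seed):
        cfg = small_config(seed=seed, n_frames=60, planted_permeations=0,
                           n_waters=0, n_cations=0, n_anions=0,
                           subunit_displacement=(1, 3.0))
        traj, truth = simulate(cfg)
        pairs = [(1, 2), (1, 5), (2, 3), (4, 5)]
        cs = native_contacts(traj.frames[0], traj.topology, pairs,
                             residue_range=(15, 33), cutoff=8.0)
        ret = contact_retention(traj, cs, tolerance_factor=1.2)
        final = {p: ret.fraction_per_frame[p][-1] for p in pairs}
        displaced = [tuple(sorted(p)) for p in truth.displaced_contacts]
        for dp in displaced:
            for up in [p for p in pairs if tuple(sorted(p)) not in displaced]:
                assert final[dp] < final[up]
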