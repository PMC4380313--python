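"""Coordination profiles and 2D water maps vs constructed oracles."""

import numpy as np
import pytest

from channelgate import (
    Frame,
    TMBounds,
    Trajectory,
    channel_reference,
    coordination_profile,
    count_permeations,
    simulate,
    water_map_2d,
)
from channelgate.io_core import Atom, ChannelFrameReference, Topology

from conftest import small_config

ORIGIN = ChannelFrameReference(origin=(0.0, 0.0, 0.0))
BOUNDS = TMBounds()


def ion_water_system(ion_z, waters_xyz, extra_cations=(), box=(100, 100, 120),
                     n_frames=2):
    """One tracked K+ at (0,0,ion_z) plus explicit waters and cations."""
    atoms = [Atom(0, "K", 1, "K", 0, "K", False, 2.75)]
    ion_species = {0: "K"}
    for k, _ in enumerate(extra_cations):
        atoms.append(Atom(1 + k, "K", 1, "K", 0, "K", False, 2.75))
        ion_species[1 + k] = "K"
    n_cat = len(atoms)
    waters = set()
    for k, _ in enumerate(waters_xyz):
        atoms.append(Atom(n_cat + k, "OW", 1, "HOH", 0, "O", False, 1.52))
        waters.add(n_cat + k)
    topo = Topology(atoms, ion_species, frozenset(waters))
    coords = np.vstack([
        np.array([[0.0, 0.0, ion_z]]),
        np.asarray(extra_cations, dtype=float).reshape(-1, 3),
        np.asarray(waters_xyz, dtype=float).reshape(-1, 3),
    ])
    frames = [Frame(coords.copy(), box=box, time=k * 0.1) for k in range(n_frames)]
    return Trajectory(topo, frames)


def record_of(traj):
    return count_permeations(traj, "K", BOUNDS, burn_in=0.0, ref=ORIGIN)


def record_with_inside_ion(traj):
    """Mark ion 0 INSIDE at every frame (static test systems never cross)."""
    rec = record_of(traj)
    rec.state_history[:, 0] = 0  # INSIDE code
    return rec


class TestCoordinationProfile:
    def test_four_waters_at_three_angstrom(self):
        waters = [(3, 0, -2), (-3, 0, -2), (0, 3, -2), (0, 0, 1)]
        traj = ion_water_system(-2.0, waters)
        rec = record_with_inside_ion(traj)
        prof = coordination_profile(traj, rec, ORIGIN, water_cutoff=3.5,
                                    bin_width=1.0)
        b = np.searchsorted(prof.z_bins, -2.0, side="right") - 1
        assert prof.mean_water[b] == 4.0
        assert prof.sample_counts.sum() == 2  # one sample per frame

    def test_unsampled_bins_are_missing_not_zero(self):
        traj = ion_water_system(-2.0, [(3, 0, -2)])
        rec = record_with_inside_ion(traj)
        prof = coordination_profile(traj, rec, ORIGIN)
        sampled = prof.sample_counts > 0
        assert np.isnan(prof.mean_water[~sampled]).all()

    def test_uniform_density_matches_sphere_volume(self):
        rng = np.random.default_rng(12)
        side, n, n_frames = 40.0, 8000, 40  # rho = 0.125 per A^3
        base = ion_water_system(0.0, np.zeros((n, 3)), box=(50, 50, 50),
                                n_frames=n_frames)
        frames = []
        for f in base.frames:
            coords = f.coordinates.copy()
            coords[1:] = rng.uniform(-side / 2, side / 2, size=(n, 3))
            frames.append(Frame(coords, box=f.box, time=f.time))
        traj = Trajectory(base.topology, frames)
        rec = record_with_inside_ion(traj)
        cutoff = 3.5
        prof = coordination_profile(traj, rec, ORIGIN, water_cutoff=cutoff,
                                    bin_width=1.0)
        rho = n / side**3
        expected = rho * 4.0 / 3.0 * np.pi * cutoff**3
        b = np.searchsorted(prof.z_bins, 0.0, side="right") - 1
        assert prof.mean_water[b] == pytest.approx(expected, rel=0.05)

    def test_matches_brute_force_pairwise_oracle(self, planted_sim):
        cfg, traj, _ = planted_sim
        sub = Trajectory(traj.topology, list(traj.frames[100:110]))
        ref = channel_reference(sub.frames[0], sub.topology)
        rec = count_permeations(sub, "K", BOUNDS, burn_in=0.0, ref=ref)
        prof = coordination_profile(sub, rec, ref, water_cutoff=3.5,
                                    cation_cutoffs=(5.0, 4.0), bin_width=2.0,
                                    z_range=(-16.0, 16.0))
        waters = np.array(sorted(sub.topology.water_oxygen_indices))
        cations = rec.ion_indices
        w_sum = np.zeros_like(prof.mean_water)
        c_sum = {c: np.zeros_like(prof.mean_water) for c in (5.0, 4.0)}
        n = np.zeros(len(prof.mean_water))
        inside = rec.inside_mask()
        for a, fidx in enumerate(rec.frame_indices):
            for j in range(len(cations)):
                if not inside[a, j]:
                    continue
                z = rec.z_history[a, j]
                b = int((z + 16.0) // 2.0)
                if not 0 <= b < len(n):
                    continue
                center = sub.frames[fidx].coordinates[cations[j]]
                for w in waters:
                    if np.linalg.norm(
                            sub.frames[fidx].coordinates[w] - center) <= 3.5:
                        w_sum[b] += 1
                for jj, other in enumerate(cations):
                    if jj == j:
                        continue
                    d = np.linalg.norm(
                        sub.frames[fidx].coordinates[other] - center)
                    for c in (5.0, 4.0):
                        if d <= c:
                            c_sum[c][b] += 1
                n[b] += 1
        sampled = n > 0
        assert (prof.sample_counts == n).all()
        np.testing.assert_allclose(prof.mean_water[sampled],
                                   w_sum[sampled] / n[sampled])
        for c in (5.0, 4.0):
            np.testing.assert_allclose(prof.mean_cation[c][sampled],
                                       c_sum[c][sampled] / n[sampled])

    def test_nested_cutoffs_are_monotone(self, planted_sim):
        cfg, traj, _ = planted_sim
        sub = Trajectory(traj.topology, list(traj.frames[100:140]))
        ref = channel_reference(sub.frames[0], sub.topology)
        rec = count_permeations(sub, "K", BOUNDS, burn_in=0.0, ref=ref)
        prof = coordination_profile(sub, rec, ref, cation_cutoffs=(5.0, 4.0))
        sampled = prof.sample_counts > 0
        assert np.all(prof.mean_cation[4.0][sampled]
                      <= prof.mean_cation[5.0][sampled])

    def test_self_is_excluded_from_cation_count(self):
        traj = ion_water_system(0.0, [], extra_cations=[(0.0, 0.0, 50.0)])
        rec = record_with_inside_ion(traj)
        prof = coordination_profile(traj, rec, ORIGIN, cation_cutoffs=(5.0,))
        b = np.searchsorted(prof.z_bins, 0.0, side="right") - 1
        assert prof.mean_cation[5.0][b] == 0.0

    def test_rotation_invariance(self):
        rng = np.random.default_rng(3)
        waters = rng.uniform(-8, 8, size=(200, 3))
        traj = ion_water_system(0.0, waters)
        a = np.deg2rad(40)
        rot = np.array([[np.cos(a), -np.sin(a), 0],
                        [np.sin(a), np.cos(a), 0], [0, 0, 1]])
        frames = [Frame(f.coordinates @ rot.T, box=f.box, time=f.time)
                  for f in traj.frames]
        traj_rot = Trajectory(traj.topology, frames)
        p1 = coordination_profile(traj, record_with_inside_ion(traj), ORIGIN)
        p2 = coordination_profile(traj_rot, record_with_inside_ion(traj_rot),
                                  ORIGIN)
        np.testing.assert_allclose(np.nansum(p1.mean_water),
                                   np.nansum(p2.mean_water))

    def test_no_inside_samples_warns(self):
        traj = ion_water_system(50.0, [])  # far outside the slab
        rec = record_of(traj)
        with pytest.warns(UserWarning, match="no in-pore"):
            prof = coordination_profile(traj, rec, ORIGIN)
        assert prof.sample_counts.sum() == 0


class TestWaterMap:
    def test_single_water_single_cell(self):
        traj = ion_water_system(50.0, [(2.0, 0.0, 3.0)])
        wmap = water_map_2d(traj, ORIGIN, axial_halfwidth=10, radial_cutoff=10,
                            bin_widths=(1.0, 1.0))
        assert wmap.counts.sum() == 2  # the same water in both frames
        assert np.count_nonzero(wmap.counts) == 1
        az = np.searchsorted(wmap.axial_edges, 3.0, side="right") - 1
        rad = np.searchsorted(wmap.radial_edges, 2.0, side="right") - 1
        assert wmap.counts[az, rad] == 2

    def test_total_counts_equal_in_region_observations(self, planted_sim):
        cfg, traj, _ = planted_sim
        sub = Trajectory(traj.topology, list(traj.frames[:10]))
        ref = channel_reference(sub.frames[0], sub.topology)
        wmap = water_map_2d(sub, ref, axial_halfwidth=10, radial_cutoff=10)
        waters = np.array(sorted(sub.topology.water_oxygen_indices))
        total = 0
        for f in sub.frames:
            xyz = f.coordinates[waters] - np.asarray(ref.origin)
            zp, rp = xyz[:, 2], np.hypot(xyz[:, 0], xyz[:, 1])
            total += int(np.count_nonzero((np.abs(zp) < 10) & (rp < 10)))
        assert wmap.counts.sum() == pytest.approx(total, abs=2)

    def test_occluded_core_is_dry_in_closed_channel(self):
        cfg = small_config(n_frames=30, planted_permeations=0, n_waters=800,
                           hydrate_pore=False, protein_jitter=0.0)
        traj, truth = simulate(cfg)
        ref = channel_reference(traj.frames[0], traj.topology)
        wmap = water_map_2d(traj, ref, axial_halfwidth=10, radial_cutoff=10,
                            bin_widths=(1.0, 0.5))
        centers_z = 0.5 * (wmap.axial_edges[:-1] + wmap.axial_edges[1:])
        centers_r = 0.5 * (wmap.radial_edges[:-1] + wmap.radial_edges[1:])
        for i, zc in enumerate(centers_z):
            if abs(zc) >= cfg.occlusion_halflength - 1.0:
                continue
            rmax = truth.nominal_pore_radius(
                wmap.axial_edges[i:i + 2]).min() - 0.5
            for j, rc in enumerate(centers_r):
                if wmap.radial_edges[j + 1] <= rmax:
                    assert wmap.counts[i, j] == 0

    def test_hydrated_pore_has_no_empty_axial_stripe(self):
        cfg = small_config(n_frames=40, planted_permeations=0, n_waters=4000,
                           hydrate_pore=True, protein_jitter=0.0)
        traj, _ = simulate(cfg)
        ref = channel_reference(traj.frames[0], traj.topology)
        wmap = water_map_2d(traj, ref, axial_halfwidth=10, radial_cutoff=10,
                            bin_widths=(2.0, 10.0))
        assert np.all(wmap.counts.sum(axis=1) > 0)
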