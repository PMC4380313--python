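"""Shared fixtures: small synthetic systems reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from channelgate import SyntheticConfig, Topology, Frame, Trajectory, simulate
from channelgate.io_core import Atom


def small_config(**overrides) -> SyntheticConfig:
    """A fast desk-scale config: 20 ns, sparse ions, few waters."""
    base = dict(
        seed=42, n_frames=200, dt=0.1, n_cations=20, n_anions=10,
        n_waters=250, planted_permeations=4,
    )
    base.update(overrides)
    return SyntheticConfig(**base)


@pytest.fixture(scope="session")
def planted_sim():
    cfg = small_config()
    traj, truth = simulate(cfg)
    return cfg, traj, truth


@pytest.fixture(scope="session")
def quiet_scaffold_traj():
    """Three jitter-free frames of the bare scaffold (no ions/waters)."""
    cfg = SyntheticConfig(seed=1, n_frames=3, dt=0.05, n_cations=0,
                          n_anions=0, n_waters=0, protein_jitter=0.0)
    traj, truth = simulate(cfg)
    return cfg, traj, truth


def cylinder_trajectory(
    rho: float = 5.0,
    vdw: float = 1.7,
    z_min: float = -10.0,
    z_max: float = 10.0,
    ring_spacing: float = 0.5,
    atoms_per_ring: int = 24,
    box: tuple[float, float, float] = (60.0, 60.0, 60.0),
) -> Trajectory:
    """Ideal cylinder of atoms: measured pore radius is rho - vdw exactly."""
    zs = np.arange(z_min, z_max + 1e-9, ring_spacing)
    theta = 2 * np.pi * np.arange(atoms_per_ring) / atoms_per_ring
    atoms = []
    coords = []
    for z in zs:
        for t in theta:
            atoms.append(Atom(
                index=len(atoms), name="CA", residue_number=1,
                residue_name="ALA", subunit=1, element="C",
                is_calpha=True, vdw_radius=vdw,
            ))
            coords.append((rho * np.cos(t), rho * np.sin(t), z))
    topo = Topology(atoms)
    return Trajectory(topo, [Frame(np.array(coords), box=box, time=0.0)])


def single_ion_trajectory(z_path, r_path=None, box=(100.0, 100.0, 120.0),
                          dt: float = 0.1) -> Trajectory:
    """One K+ ion walked along an explicit (z, radial) path."""
    z_path = np.asarray(z_path, dtype=float)
    if r_path is None:
        r_path = np.zeros_like(z_path)
    r_path = np.asarray(r_path, dtype=float)
    atoms = [Atom(0, "K", 1, "K", 0, "K", False, 2.75)]
    topo = Topology(atoms, ion_species={0: "K"})
    frames = [
        Frame(np.array([[r, 0.0, z]]), box=box, time=k * dt)
        for k, (z, r) in enumerate(zip(z_path, r_path))
    ]
    return Trajectory(topo, frames)
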