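"""Pore geometry: radius profiles, constriction statistics, pentagon area.

The radius profile follows the HOLE objective restricted to planar slices:
at each axial position z the pore radius is the largest sphere centred in
the plane at z (centre constrained near the channel axis) that touches no
atom, i.e.

    R(z) = max_{|c_xy| <= s}  min_i ( |c - x_i| - vdw_i )

maximised over the in-plane centre by seeded simulated annealing followed
by a Nelder-Mead polish, and clamped at zero. The channel studied here is
straight, so a per-slice search suffices (no off-axis wandering path); the
test suite checks the optimiser against an exhaustive-lattice oracle.

The pentagon pore-area approximation scores the opening per residue ring:
the edge is the mean C-alpha distance between the five adjacent-subunit
pairs, and the area is that of the regular pentagon with this edge,
A = (5/4) e^2 / tan(36 deg).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io_core import ChannelFrameReference, SelectionError, Topology, Trajectory

__all__ = [
    "PoreProfile",
    "MinRadiusDistribution",
    "PoreArea",
    "pore_radius_profile",
    "min_radius_distribution",
    "pentagon_pore_area",
    "regular_pentagon_area",
    "sphere_radius_at",
]

PENTAGON_COEFF = 5.0 / (4.0 * math.tan(math.pi / 5.0))


@dataclass
class PoreProfile:
    z_grid: np.ndarray                 # A, relative to the channel frame
    radius_per_frame: np.ndarray       # (n_frames, n_z), A
    atom_subset: str
    flagged_empty: np.ndarray | None = None  # (n_frames, n_z) bool

    @property
    def mean_radius(self) -> np.ndarray:
        return self.radius_per_frame.mean(axis=0)

    @property
    def sd_radius(self) -> np.ndarray:
        return self.radius_per_frame.std(axis=0)


@dataclass
class MinRadiusDistribution:
    values: np.ndarray                 # one minimum radius per frame, A
    window: tuple[int, int]            # residue range (inclusive)
    z_window: tuple[float, float]      # the axial interval it mapped to


@dataclass
class PoreArea:
    residues: np.ndarray
    edge_lengths: np.ndarray           # mean adjacent-subunit Calpha distance, A
    per_residue_area: np.ndarray       # A^2


def regular_pentagon_area(edge: float | np.ndarray):
    """Area of the regular pentagon with the given edge length."""
    return PENTAGON_COEFF * np.square(edge)


def _min_clearance(center_xy: np.ndarray, z: float, atoms_xyz: np.ndarray,
                   radii: np.ndarray) -> float:
    d = atoms_xyz.copy()
    d[:, 0] -= center_xy[0]
    d[:, 1] -= center_xy[1]
    d[:, 2] -= z
    return float(np.min(np.linalg.norm(d, axis=1) - radii))


def sphere_radius_at(
    z: float,
    atoms_xyz: np.ndarray,
    radii: np.ndarray,
    axis_xy: tuple[float, float] = (0.0, 0.0),
    lateral_search: float = 5.0,
    n_moves: int = 200,
    rng: np.random.Generator | None = None,
) -> float:
    """Largest clearance sphere centred in the plane at z (see module doc).

    Simulated annealing over the in-plane centre with a geometric
    temperature schedule, then a Nelder-Mead polish; deterministic for a
    given generator state. Returns the clearance (may be negative before
    the caller clamps).
    """
    from scipy.optimize import minimize

    if rng is None:
        rng = np.random.default_rng(0)
    center = np.asarray(axis_xy, dtype=float)
    best = center.copy()
    f_cur = _min_clearance(center, z, atoms_xyz, radii)
    f_best = f_cur
    temp0, temp1 = 1.0, 0.01
    for m in range(n_moves):
        temp = temp0 * (temp1 / temp0) ** (m / max(1, n_moves - 1))
        cand = center + rng.normal(0.0, 0.6, size=2)
        lat = cand - np.asarray(axis_xy)
        if np.hypot(*lat) > lateral_search:
            continue
        f_cand = _min_clearance(cand, z, atoms_xyz, radii)
        if f_cand > f_cur or rng.random() < np.exp((f_cand - f_cur) / temp):
            center, f_cur = cand, f_cand
            if f_cur > f_best:
                best, f_best = center.copy(), f_cur

    def neg(c):
        lat = c - np.asarray(axis_xy)
        if np.hypot(*lat) > lateral_search:
            return 1e6
        return -_min_clearance(c, z, atoms_xyz, radii)

    res = minimize(neg, best, method="Nelder-Mead",
                   options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 400})
    return float(max(f_best, -res.fun))


def _subset_indices(topology: Topology, atom_subset: str) -> np.ndarray:
    if atom_subset == "backbone":
        idx = topology.backbone_indices()
    elif atom_subset == "all":
        idx = topology.protein_indices()
    else:
        raise ValueError(f"atom_subset must be 'backbone' or 'all', got {atom_subset!r}")
    if idx.size == 0:
        raise SelectionError(f"atom subset {atom_subset!r} selected no atoms")
    return idx


def pore_radius_profile(
    traj: Trajectory,
    ref: ChannelFrameReference,
    z_grid: np.ndarray,
    atom_subset: str = "backbone",
    lateral_search: float = 5.0,
    neighborhood: float = 10.0,
    cap_radius: float = 15.0,
    n_moves: int = 200,
    seed: int = 0,
) -> PoreProfile:
    """Per-frame and mean pore radius over an axial grid.

    ``z_grid`` is in channel coordinates (z' relative to ``ref``). Slices
    with no atom within ``neighborhood`` along z are reported at
    ``cap_radius`` and flagged. The annealing schedule is seeded per
    (frame, slice) from ``seed``, so results are reproducible.
    """
    z_grid = np.asarray(z_grid, dtype=float)
    if z_grid.ndim != 1 or z_grid.size == 0:
        raise ValueError("z_grid must be a non-empty 1D array")
    if np.any(np.diff(z_grid) <= 0):
        raise ValueError("z_grid must be strictly increasing")
    idx = _subset_indices(traj.topology, atom_subset)
    radii = traj.topology.vdw_radii(idx)
    origin = np.asarray(ref.origin)
    nf = len(traj.frames)
    out = np.zeros((nf, z_grid.size))
    flagged = np.zeros((nf, z_grid.size), dtype=bool)
    root = np.random.SeedSequence(seed)
    frame_seeds = root.spawn(nf)
    for k, frame in enumerate(traj.frames):
        xyz = frame.coordinates[idx] - origin  # channel coordinates
        slice_seeds = frame_seeds[k].spawn(z_grid.size)
        for j, z in enumerate(z_grid):
            near = np.abs(xyz[:, 2] - z) <= neighborhood
            if not np.any(near):
                out[k, j] = cap_radius
                flagged[k, j] = True
                continue
            rng = np.random.default_rng(slice_seeds[j])
            r = sphere_radius_at(z, xyz, radii, lateral_search=lateral_search,
                                 n_moves=n_moves, rng=rng)
            out[k, j] = max(0.0, min(r, cap_radius))
    return PoreProfile(z_grid=z_grid, radius_per_frame=out,
                       atom_subset=atom_subset, flagged_empty=flagged)


def min_radius_distribution(
    profile: PoreProfile,
    residue_window: tuple[int, int],
    topology: Topology,
    traj: Trajectory,
    ref: ChannelFrameReference,
) -> MinRadiusDistribution:
    """Per-frame minimum radius over the z-interval a residue window spans.

    The window (e.g. the constricted zone, residues 17-23) is mapped to z'
    through the mean C-alpha z' of its residues over subunits and frames.
    """
    lo, hi = residue_window
    if hi < lo:
        raise ValueError(f"empty residue window {residue_window}")
    res_z = []
    for r in range(lo, hi + 1):
        idx = topology.calpha_indices(residues=[r])
        if idx.size == 0:
            raise SelectionError(f"no C-alpha atoms for residue {r}")
        zs = [f.coordinates[idx, 2].mean() - ref.origin[2] for f in traj.frames]
        res_z.append(float(np.mean(zs)))
    z_lo, z_hi = min(res_z), max(res_z)
    mask = (profile.z_grid >= z_lo - 1e-9) & (profile.z_grid <= z_hi + 1e-9)
    if not np.any(mask):
        raise ValueError(
            f"residue window {residue_window} maps to z in [{z_lo:.2f}, {z_hi:.2f}] A, "
            "outside the profile grid"
        )
    values = profile.radius_per_frame[:, mask].min(axis=1)
    return MinRadiusDistribution(values=values, window=(lo, hi),
                                 z_window=(z_lo, z_hi))


def pentagon_pore_area(
    traj: Trajectory,
    topology: Topology,
    residue_range: tuple[int, int],
) -> PoreArea:
    """Pentagon pore-area approximation per residue ring, averaged over frames.

    For each residue, the edge is the C-alpha distance between the five
    adjacent subunit pairs (1-2, 2-3, 3-4, 4-5, 5-1), averaged over pairs
    and frames; the area is the regular pentagon's with that edge.
    """
    topology.require_pentamer()
    lo, hi = residue_range
    residues = np.arange(lo, hi + 1)
    edges = np.empty(residues.size)
    for n, r in enumerate(residues):
        per_sub = []
        for s in range(1, 6):
            idx = topology.calpha_indices(subunit=s, residues=[r])
            if idx.size == 0:
                raise SelectionError(f"no C-alpha for residue {r} in subunit {s}")
            per_sub.append(idx[0])
        dists = []
        for f in traj.frames:
            for s in range(5):
                a = f.coordinates[per_sub[s]]
                b = f.coordinates[per_sub[(s + 1) % 5]]
                dists.append(np.linalg.norm(a - b))
        edges[n] = np.mean(dists)
    return PoreArea(residues=residues, edge_lengths=edges,
                    per_residue_area=regular_pentagon_area(edges))
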