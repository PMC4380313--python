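"""Synthetic pentameric-channel trajectories with planted ground truth.

The generator emulates the study system at desk scale: a C5-symmetric
pentamer whose five inner C-alpha-only helix traces line an hourglass pore,
mobile K+/Cl- point ions drifting under a uniform axial field
E_z = -V / L_z, and water oxygens as uniform occupancy markers excluded
from the occluded hydrophobic core. Ion dynamics are overdamped Langevin
steps (not Newtonian MD): the analyses under test need plausible continuous
paths and exact bookkeeping, not thermodynamic fidelity.

Planted features with machine-readable ground truth:

* permeation events — selected cations steered through the pore at recorded
  frames (the channel is otherwise closed to free ions, so recovered events
  can be compared one-to-one against the plant);
* single-subunit radial displacement, ramped linearly over the trajectory
  (the asymmetric-gating signature: the displaced subunit loses contacts
  with its two neighbours);
* pore dilation — the constriction radius ramped between two values.

Sign convention, stated once: V = +1 Volt gives E_z = -V/L_z < 0, so
cations drift toward -z (periplasm -> cytoplasm) and anions toward +z.

All randomness flows from ``SyntheticConfig.seed``; identical configs give
bitwise-identical trajectories.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_core import (
    Atom,
    Frame,
    Topology,
    Trajectory,
    vdw_radius_for,
    write_pdb,
    write_topology_tsv,
    write_xyz_trajectory,
)

__all__ = ["SyntheticConfig", "GroundTruth", "build_scaffold", "simulate",
           "write_bundle", "pore_radius_function"]

KT_EV_PER_K = 8.617333262e-5  # Boltzmann constant, eV/K

_N_RESIDUES = 25          # residues per inner helix trace
_CENTER_RESIDUE = 21      # constriction residue; numbering 9..33
_FIRST_RESIDUE = _CENTER_RESIDUE - _N_RESIDUES // 2
_HELIX_RISE = 1.5         # A per residue (ideal alpha helix)
_HELIX_TWIST = 100.0      # deg per residue
_CA_RADIUS = vdw_radius_for("C")  # Bondi carbon, 1.70 A


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic run.

    Defaults reflect the simulated setup at desk scale: 1 Volt across a
    120 A box, 300 K, a closed-state constriction radius of 2 A opening to
    8 A mouths, and a 20 ns trajectory sampled every 0.05 ns.
    """

    seed: int = 0
    n_frames: int = 400
    dt: float = 0.05                      # ns between frames
    box: tuple[float, float, float] = (100.0, 100.0, 120.0)
    n_cations: int = 60
    n_anions: int = 60
    n_waters: int = 1500
    voltage: float = 1.0                  # Volt across L_z
    temperature: float = 300.0            # K
    r_min: float = 2.0                    # constriction radius, A
    r_mouth: float = 8.0                  # mouth radius, A
    constriction_center: float = 0.0      # A, lab z of the constriction
    constriction_width: float = 10.0      # A, hourglass opening scale
    tm_halflength: float = 16.0           # A, membrane slab half-height
    subunit_displacement: tuple[int, float] | None = None  # (subunit, A)
    planted_permeations: int = 0
    r_min_final: float | None = None      # ramp target for pore dilation
    hydrate_pore: bool = False            # allow waters in the occluded core
    occlusion_halflength: float = 4.0     # A, axial half-extent of dry core
    wall_outer_radius: float = 15.0       # A, protein/membrane wall extent
    diffusion: float = 20.0               # ion diffusion coefficient, A^2/ns
    protein_jitter: float = 0.05          # A, thermal noise on Calpha
    event_clearance: float = 10.0         # ns before the first planted event

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if not (self.r_mouth >= self.r_min > 0):
            raise ValueError("require r_mouth >= r_min > 0")
        if self.voltage < 0:
            raise ValueError("voltage must be >= 0")
        if self.constriction_width <= 0:
            raise ValueError("constriction_width must be positive")

    def pore_radius(self, z: np.ndarray | float, frame_fraction: float = 0.0):
        """Analytic pore radius R(z) at a point in the dilation schedule."""
        r_min = self.r_min
        if self.r_min_final is not None:
            r_min = self.r_min + (self.r_min_final - self.r_min) * frame_fraction
        u = (np.asarray(z, dtype=float) - self.constriction_center)
        u = np.minimum(1.0, (u / self.constriction_width) ** 2)
        return r_min + (self.r_mouth - r_min) * u


def pore_radius_function(config: SyntheticConfig, frame_fraction: float = 0.0):
    """R(z) as a plain callable, frozen at one point of the dilation ramp."""
    return lambda z: config.pore_radius(z, frame_fraction)


@dataclass
class GroundTruth:
    """Machine-readable record of everything the generator planted."""

    permeation_events: list[tuple[int, str, int, int]]  # (atom idx, dir, entry, exit)
    pore_params: dict
    displaced_subunit: int | None = None
    displaced_contacts: list[tuple[int, int]] = field(default_factory=list)

    def true_pore_radius(self, z, frame_fraction: float = 0.0):
        """Sphere-measurable pore radius at z (the profiler's ground truth).

        The scaffold parameterizes the wall surface, but a planar-slice
        probe sphere is also limited by atoms in neighbouring rings, so on
        steep stretches the largest admissible sphere is smaller than the
        nominal wall radius. This closed form is the exact on-axis optimum
        (off-axis centres only lose clearance for a C5 ring).
        """
        cfg = SyntheticConfig(**{**_DEFAULTS, **self.pore_params})
        return measured_pore_radius(cfg, z, frame_fraction)

    def nominal_pore_radius(self, z, frame_fraction: float = 0.0):
        """The wall-surface parameterization R(z) used to build the scaffold."""
        cfg = SyntheticConfig(**{**_DEFAULTS, **self.pore_params})
        return cfg.pore_radius(z, frame_fraction)

    def to_json(self) -> str:
        return json.dumps(
            {
                "permeation_events": [
                    {"ion": i, "direction": d, "entry_frame": a, "exit_frame": b}
                    for i, d, a, b in self.permeation_events
                ],
                "pore_params": self.pore_params,
                "displaced_subunit": self.displaced_subunit,
                "displaced_contacts": [list(p) for p in self.displaced_contacts],
            },
            indent=1,
        )


_DEFAULTS = {f.name: f.default for f in dataclasses.fields(SyntheticConfig)
             if f.default is not dataclasses.MISSING}


def measured_pore_radius(config: SyntheticConfig, z, frame_fraction: float = 0.0):
    """Analytic sphere-based pore radius of the scaffold (see GroundTruth)."""
    res = np.arange(_FIRST_RESIDUE, _FIRST_RESIDUE + _N_RESIDUES)
    z_ring = config.constriction_center + _HELIX_RISE * (res - _CENTER_RESIDUE)
    rho = config.pore_radius(z_ring, frame_fraction) + _CA_RADIUS
    zz = np.atleast_1d(np.asarray(z, dtype=float))
    d = np.sqrt(rho[None, :] ** 2 + (zz[:, None] - z_ring[None, :]) ** 2)
    out = d.min(axis=1) - _CA_RADIUS
    return out if np.ndim(z) else float(out[0])


def _scaffold_coordinates(config: SyntheticConfig, frame_fraction: float = 0.0,
                          displacement_fraction: float = 1.0) -> np.ndarray:
    """C-alpha positions for the 5 inner helix traces, shape (5*25, 3).

    Residue i of every subunit sits at z = center + rise*(i - 21); its
    radial distance is R(z) plus the carbon vdW radius, so the atom *surface*
    realizes the analytic pore profile. Subunits are C5 rotations of one
    trace; an ideal helical twist is shared by all subunits (preserving the
    symmetry and the per-ring radius).
    """
    res = np.arange(_FIRST_RESIDUE, _FIRST_RESIDUE + _N_RESIDUES)
    z = config.constriction_center + _HELIX_RISE * (res - _CENTER_RESIDUE)
    rho = config.pore_radius(z, frame_fraction) + _CA_RADIUS
    if np.any(rho <= 0):
        raise ValueError("infeasible geometry: pore radius too small for the trace")
    twist = np.deg2rad(_HELIX_TWIST) * (res - _CENTER_RESIDUE)
    coords = np.empty((5 * _N_RESIDUES, 3))
    disp_sub, disp_amp = (None, 0.0)
    if config.subunit_displacement is not None:
        disp_sub, disp_amp = config.subunit_displacement
        if not 1 <= disp_sub <= 5:
            raise ValueError(f"displaced subunit must be 1..5, got {disp_sub}")
    for s in range(5):
        theta = twist + 2.0 * np.pi * s / 5.0
        r = rho.copy()
        if disp_sub == s + 1:
            r = r + disp_amp * displacement_fraction
        block = slice(s * _N_RESIDUES, (s + 1) * _N_RESIDUES)
        coords[block, 0] = r * np.cos(theta)
        coords[block, 1] = r * np.sin(theta)
        coords[block, 2] = z
    return coords


def _build_topology(config: SyntheticConfig) -> Topology:
    atoms: list[Atom] = []
    for s in range(1, 6):
        for i in range(_N_RESIDUES):
            atoms.append(Atom(
                index=len(atoms), name="CA",
                residue_number=_FIRST_RESIDUE + i, residue_name="ALA",
                subunit=s, element="C", is_calpha=True,
                vdw_radius=_CA_RADIUS,
            ))
    ions: dict[int, str] = {}
    for _ in range(config.n_cations):
        idx = len(atoms)
        atoms.append(Atom(idx, "K", 1, "K", 0, "K", False, vdw_radius_for("K")))
        ions[idx] = "K"
    for _ in range(config.n_anions):
        idx = len(atoms)
        atoms.append(Atom(idx, "CL", 1, "CL", 0, "CL", False, vdw_radius_for("CL")))
        ions[idx] = "CL"
    waters: set[int] = set()
    for _ in range(config.n_waters):
        idx = len(atoms)
        atoms.append(Atom(idx, "OW", 1, "HOH", 0, "O", False, vdw_radius_for("O")))
        waters.add(idx)
    return Topology(atoms, ions, frozenset(waters))


def build_scaffold(config: SyntheticConfig) -> tuple[Topology, Frame]:
    """Static scaffold: topology plus one frame of the full system at t=0.

    Protein C-alphas realize the analytic pore profile; ions and waters are
    placed by the same seeded sampler ``simulate`` uses for its first frame.
    """
    topo = _build_topology(config)
    rng = np.random.default_rng(config.seed)
    coords = np.zeros((topo.n_atoms, 3))
    coords[: 5 * _N_RESIDUES] = _scaffold_coordinates(config)
    n_prot = 5 * _N_RESIDUES
    n_ions = config.n_cations + config.n_anions
    coords[n_prot:n_prot + n_ions] = _init_ion_positions(config, rng)
    coords[n_prot + n_ions:] = _sample_waters(config, rng, 0.0)
    return topo, Frame(coords, box=config.box, time=0.0)


# --- ion/water placement helpers -------------------------------------------

def _in_blocked_region(config: SyntheticConfig, xyz: np.ndarray,
                       frame_fraction: float, margin: float = 2.0) -> np.ndarray:
    """True where a point is inside the membrane slab but not in the pore.

    ``margin`` keeps ion centres a finite clearance from the pore wall; at
    the closed-state constriction R - margin <= 0, so free ions cannot pass.
    """
    z = xyz[:, 2]
    r = np.hypot(xyz[:, 0], xyz[:, 1])
    in_slab = np.abs(z - config.constriction_center) < config.tm_halflength
    allowed = config.pore_radius(z, frame_fraction) - margin
    return in_slab & (r >= allowed)


def _init_ion_positions(config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    n = config.n_cations + config.n_anions
    lx, ly, lz = config.box
    pos = np.empty((n, 3))
    filled = 0
    while filled < n:
        cand = rng.uniform(-0.5, 0.5, size=(2 * (n - filled) + 8, 3))
        cand *= np.array([lx, ly, lz])
        ok = ~_in_blocked_region(config, cand, 0.0)
        take = cand[ok][: n - filled]
        pos[filled:filled + len(take)] = take
        filled += len(take)
    return pos


def _sample_waters(config: SyntheticConfig, rng: np.random.Generator,
                   frame_fraction: float) -> np.ndarray:
    """Uniform water-oxygen markers, rejected from wall and occluded core."""
    n = config.n_waters
    lx, ly, lz = config.box
    c = config.constriction_center
    out = np.empty((n, 3))
    filled = 0
    while filled < n:
        cand = rng.uniform(-0.5, 0.5, size=(2 * (n - filled) + 8, 3))
        cand *= np.array([lx, ly, lz])
        z = cand[:, 2]
        r = np.hypot(cand[:, 0], cand[:, 1])
        rz = config.pore_radius(z, frame_fraction)
        in_slab = np.abs(z - c) < config.tm_halflength
        wall = in_slab & (r >= rz) & (r < config.wall_outer_radius)
        bad = wall
        if not config.hydrate_pore:
            core = (np.abs(z - c) < config.occlusion_halflength) & (r < rz)
            bad = bad | core
        take = cand[~bad][: n - filled]
        out[filled:filled + len(take)] = take
        filled += len(take)
    return out


def _plan_events(config: SyntheticConfig) -> list[tuple[int, int, int]]:
    """(cation slot, start frame, end frame) for each planted crossing."""
    p = config.planted_permeations
    if p == 0:
        return []
    if p > config.n_cations:
        raise ValueError("more planted permeations than cations")
    total_t = (config.n_frames - 1) * config.dt
    first = config.event_clearance + config.dt
    if first >= total_t * 0.9:
        raise ValueError("trajectory too short for planted events after clearance")
    duration = max(6, config.n_frames // 12)
    starts = np.linspace(first / config.dt,
                         0.92 * config.n_frames - duration, p)
    events = []
    for k in range(p):
        fs = int(round(starts[k]))
        fe = min(fs + duration, config.n_frames - 2)
        events.append((k, fs, fe))
    return events


def simulate(config: SyntheticConfig) -> tuple[Trajectory, GroundTruth]:
    """Run the seeded toy dynamics and return the trajectory plus its plant.

    Free ions take overdamped Langevin steps: axial drift q*E_z*D/kT with
    E_z = -V/L_z, isotropic diffusion, periodic wrapping in all three box
    dimensions, and rejection of moves into the membrane wall (the pore is
    closed to free ions, so every completed crossing is a planted one).
    Steered cations descend linearly through the pore between their event
    frames. Waters are resampled independently every frame. Protein
    C-alphas carry small Gaussian jitter; planted displacement/dilation
    ramps run linearly from frame 0 to the final frame.
    """
    topo = _build_topology(config)
    rng = np.random.default_rng(config.seed)
    n_prot = 5 * _N_RESIDUES
    n_ions = config.n_cations + config.n_anions
    lx, ly, lz = config.box
    c = config.constriction_center
    h = config.tm_halflength

    # per-ion drift (A/ns): q E_z D / kT, toward -z for cations when V > 0
    kt_ev = KT_EV_PER_K * config.temperature
    e_z = -config.voltage / lz  # V/A
    charges = np.concatenate([np.ones(config.n_cations), -np.ones(config.n_anions)])
    drift = charges * e_z * config.diffusion / kt_ev  # A/ns along z
    sigma_step = np.sqrt(2.0 * config.diffusion * config.dt)

    events = _plan_events(config)
    steered = {slot: (fs, fe) for slot, fs, fe in events}

    ion_pos = _init_ion_positions(config, rng)
    # park steered cations above the periplasmic mouth
    for slot, (fs, fe) in steered.items():
        ion_pos[slot] = (2.0, 0.0, c + h + 6.0)

    nf = config.n_frames
    frames: list[Frame] = []
    steered_z = {}
    for slot, (fs, fe) in steered.items():
        # linear descent spanning both mouths; entry/exit read off afterwards
        steered_z[slot] = np.linspace(c + h + 2.0, c - h - 2.0, fe - fs + 1)

    ion_paths = np.empty((nf, n_ions, 3))
    for k in range(nf):
        frac = k / (nf - 1)
        prot = _scaffold_coordinates(config, frac, displacement_fraction=frac)
        if config.protein_jitter > 0:
            prot = prot + rng.normal(0.0, config.protein_jitter, prot.shape)
        if k > 0:
            step = rng.normal(0.0, sigma_step, size=(n_ions, 3))
            step[:, 2] += drift * config.dt
            proposal = ion_pos + step
            # wrap into the centred box
            proposal -= np.array([lx, ly, lz]) * np.round(proposal / (lx, ly, lz))
            blocked = _in_blocked_region(config, proposal, frac)
            ion_pos = np.where(blocked[:, None], ion_pos, proposal)
        for slot, (fs, fe) in steered.items():
            if k < fs:
                jit = rng.normal(0.0, 0.3, size=3)
                ion_pos[slot] = (2.0 + jit[0], jit[1], c + h + 6.0 + jit[2])
            elif k <= fe:
                ion_pos[slot] = (
                    1.0 * np.cos(0.3 * (k - fs)),
                    1.0 * np.sin(0.3 * (k - fs)),
                    steered_z[slot][k - fs],
                )
        ion_paths[k] = ion_pos
        waters = _sample_waters(config, rng, frac)
        coords = np.concatenate([prot, ion_pos.copy(), waters])
        frames.append(Frame(coords, box=config.box, time=k * config.dt))

    truth_events = []
    for slot, (fs, fe) in sorted(steered.items(), key=lambda kv: kv[1][0]):
        zpath = ion_paths[:, slot, 2]
        entry = int(np.argmax(zpath <= c + h))
        exit_ = int(np.argmax(zpath < c - h))
        truth_events.append((n_prot + slot, "down", entry, exit_))

    pore_params = {
        "r_min": config.r_min, "r_mouth": config.r_mouth,
        "constriction_center": config.constriction_center,
        "constriction_width": config.constriction_width,
        "r_min_final": config.r_min_final,
    }
    disp = config.subunit_displacement
    truth = GroundTruth(
        permeation_events=truth_events,
        pore_params=pore_params,
        displaced_subunit=disp[0] if disp else None,
        displaced_contacts=(
            [tuple(sorted((disp[0], disp[0] % 5 + 1))),
             tuple(sorted((disp[0], (disp[0] - 2) % 5 + 1)))] if disp else []
        ),
    )
    return Trajectory(topo, frames), truth


def write_bundle(prefix: str | Path, traj: Trajectory, truth: GroundTruth) -> None:
    """Write prefix.pdb (first frame), .xyz, .topology.tsv and .truth.json."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    write_pdb(prefix.with_suffix(".pdb"), traj.topology, traj.frames[0])
    write_xyz_trajectory(prefix.with_suffix(".xyz"), traj)
    write_topology_tsv(prefix.with_suffix(".topology.tsv"), traj.topology)
    prefix.with_suffix(".truth.json").write_text(truth.to_json() + "\n")
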