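"""Core data model and structure/trajectory I/O.

The channel architecture this package targets is a C5-symmetric pentamer
(five identical subunits) whose inner helices line an hourglass-shaped pore
across a membrane. All analyses share a channel coordinate frame: the origin
sits at the geometric centroid of the five C-alpha atoms of a reference pore
residue (residue 21 by default, the most constricted site), and the axial
coordinate z' runs along the membrane normal, +z' toward the periplasmic
side. Every module reports axial positions as z' in Angstrom.

Formats handled here are deliberately minimal and text-only: single- or
multi-model PDB (ATOM/HETATM/MODEL/ENDMDL), multi-frame XYZ with an external
topology, a TSV topology table, and a YAML config. Binary trajectory formats
are out of scope; an adapter may delegate to a dedicated trajectory library.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Atom",
    "Topology",
    "Frame",
    "Trajectory",
    "ChannelFrameReference",
    "PDBParseError",
    "XYZFormatError",
    "SelectionError",
    "BONDI_RADII",
    "HOLE_AMBER_RADII",
    "vdw_radius_for",
    "read_pdb",
    "write_pdb",
    "read_xyz_trajectory",
    "write_xyz_trajectory",
    "read_topology_tsv",
    "write_topology_tsv",
    "channel_reference",
    "axial_coordinate",
    "radial_distance",
]


class PDBParseError(ValueError):
    """Malformed PDB record; message names the offending line number."""


class XYZFormatError(ValueError):
    """Malformed or inconsistent XYZ trajectory block."""


class SelectionError(KeyError):
    """A requested atom selection could not be resolved."""


# Bondi (1964) van der Waals radii, Angstrom. Default radius dialect.
BONDI_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
    "K": 2.75, "NA": 2.27, "MG": 1.73, "CA2": 2.31, "ZN": 1.39,
}

# AMBER-like united-radius dialect used by the HOLE pore profiler.
HOLE_AMBER_RADII: dict[str, float] = {
    "H": 1.00, "C": 1.85, "N": 1.75, "O": 1.65, "S": 2.00, "P": 2.10,
    "F": 1.47, "CL": 2.00, "BR": 1.85, "I": 1.98,
    "K": 2.75, "NA": 2.27, "MG": 1.73, "CA2": 2.31, "ZN": 1.39,
}

RADIUS_TABLES = {"bondi": BONDI_RADII, "hole": HOLE_AMBER_RADII}

_DEFAULT_RADIUS = 1.70


def vdw_radius_for(element: str, table: str = "bondi") -> float:
    """Van der Waals radius (A) for an element symbol from a named table."""
    return RADIUS_TABLES[table].get(element.upper(), _DEFAULT_RADIUS)


@dataclass(frozen=True)
class Atom:
    """One atom with the static annotations the analyses rely on.

    ``subunit`` is 1..5 for protein atoms of a pentamer and 0 for
    non-protein atoms (ions, water). ``vdw_radius`` is in Angstrom.
    """

    index: int
    name: str
    residue_number: int
    residue_name: str
    subunit: int
    element: str
    is_calpha: bool
    vdw_radius: float

    def __post_init__(self) -> None:
        if self.index < 0:
            raise ValueError(f"atom index must be >= 0, got {self.index}")
        if self.vdw_radius <= 0:
            raise ValueError(
                f"vdw_radius must be positive, got {self.vdw_radius} "
                f"for atom {self.index}"
            )


_ION_SPECIES = {
    "K": "K", "K+": "K", "POT": "K",
    "CL": "CL", "CL-": "CL", "CLA": "CL",
    "NA": "NA", "NA+": "NA", "SOD": "NA",
}

_WATER_RESNAMES = {"HOH", "WAT", "TIP3", "SPC", "SOL", "TIP"}


@dataclass
class Topology:
    """Static per-atom annotation table plus derived selection sets."""

    atoms: list[Atom]
    ion_species: dict[int, str] = field(default_factory=dict)
    water_oxygen_indices: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        n = len(self.atoms)
        for i in self.ion_species:
            if not 0 <= i < n:
                raise ValueError(f"ion index {i} out of range for {n} atoms")
        for i in self.water_oxygen_indices:
            if not 0 <= i < n:
                raise ValueError(f"water index {i} out of range for {n} atoms")
        if set(self.ion_species) & set(self.water_oxygen_indices):
            raise ValueError("ion and water index sets must be disjoint")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def subunits(self) -> list[int]:
        """Sorted distinct protein subunit labels (excluding 0)."""
        return sorted({a.subunit for a in self.atoms if a.subunit > 0})

    def protein_indices(self) -> np.ndarray:
        return np.array([a.index for a in self.atoms if a.subunit > 0], dtype=int)

    def calpha_indices(
        self, subunit: int | None = None, residues: Iterable[int] | None = None
    ) -> np.ndarray:
        resset = None if residues is None else set(residues)
        out = [
            a.index
            for a in self.atoms
            if a.is_calpha
            and (subunit is None or a.subunit == subunit)
            and (resset is None or a.residue_number in resset)
        ]
        return np.array(out, dtype=int)

    def backbone_indices(self) -> np.ndarray:
        bb = {"N", "CA", "C", "O"}
        return np.array(
            [a.index for a in self.atoms if a.subunit > 0 and a.name in bb],
            dtype=int,
        )

    def ion_indices(self, species: str | None = None) -> np.ndarray:
        if species is None:
            return np.array(sorted(self.ion_species), dtype=int)
        key = _ION_SPECIES.get(species.upper(), species.upper())
        return np.array(
            sorted(i for i, s in self.ion_species.items() if s == key), dtype=int
        )

    def vdw_radii(self, indices: np.ndarray | None = None) -> np.ndarray:
        r = np.array([a.vdw_radius for a in self.atoms], dtype=float)
        return r if indices is None else r[indices]

    def require_pentamer(self) -> None:
        subs = self.subunits()
        if len(subs) != 5:
            raise SelectionError(
                f"pentamer required: found {len(subs)} protein subunits {subs}"
            )


@dataclass
class Frame:
    """One trajectory frame: coordinates (A), box lengths (A), time (ns)."""

    coordinates: np.ndarray
    box: tuple[float, float, float]
    time: float = 0.0

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must have shape (n_atoms, 3)")
        if any(b <= 0 for b in self.box):
            raise ValueError(f"box lengths must be positive, got {self.box}")

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[0]


@dataclass
class Trajectory:
    """An ordered sequence of frames over a fixed topology."""

    topology: Topology
    frames: list[Frame]

    def __post_init__(self) -> None:
        n = self.topology.n_atoms
        for k, f in enumerate(self.frames):
            if f.n_atoms != n:
                raise ValueError(
                    f"frame {k} has {f.n_atoms} atoms, topology has {n}"
                )
        times = [f.time for f in self.frames]
        if any(t1 <= t0 for t0, t1 in zip(times, times[1:])):
            raise ValueError("frame times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames], dtype=float)

    def coordinates(self) -> np.ndarray:
        """Stacked coordinates, shape (n_frames, n_atoms, 3)."""
        return np.stack([f.coordinates for f in self.frames])


@dataclass(frozen=True)
class ChannelFrameReference:
    """Channel coordinate frame: origin and axis (unit membrane normal)."""

    origin: tuple[float, float, float]
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    reference_residue: int = 21

    def __post_init__(self) -> None:
        a = np.asarray(self.axis, dtype=float)
        if abs(np.linalg.norm(a) - 1.0) > 1e-9:
            raise ValueError(f"axis must be a unit vector, |axis|={np.linalg.norm(a)}")


def channel_reference(
    frame: Frame,
    topology: Topology,
    reference_residue: int = 21,
    axis: str = "z",
) -> ChannelFrameReference:
    """Channel frame with origin at the C-alpha centroid of a pore residue.

    The centroid is taken over the reference residue's C-alpha in every
    protein subunit. ``axis='z'`` uses the fixed membrane normal; ``'inertia'``
    uses the principal axis of the protein C-alpha cloud closest to z,
    re-signed to point toward +z.
    """
    subs = topology.subunits()
    positions = []
    missing = []
    for s in subs:
        idx = topology.calpha_indices(subunit=s, residues=[reference_residue])
        if idx.size == 0:
            missing.append(s)
        else:
            positions.append(frame.coordinates[idx[0]])
    if missing:
        raise SelectionError(
            f"no C-alpha for residue {reference_residue} in subunits {missing}"
        )
    origin = np.mean(positions, axis=0)
    if axis == "z":
        ax = np.array([0.0, 0.0, 1.0])
    elif axis == "inertia":
        ca = frame.coordinates[topology.calpha_indices()]
        centered = ca - ca.mean(axis=0)
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        # pick the principal direction most aligned with the membrane normal
        ax = vt[np.argmax(np.abs(vt[:, 2]))]
        ax = ax / np.linalg.norm(ax)
        if ax[2] < 0:
            ax = -ax
    else:
        raise ValueError(f"axis must be 'z' or 'inertia', got {axis!r}")
    return ChannelFrameReference(
        origin=tuple(float(v) for v in origin),
        axis=tuple(float(v) for v in ax),
        reference_residue=reference_residue,
    )


def axial_coordinate(xyz: np.ndarray, ref: ChannelFrameReference) -> np.ndarray:
    """z' = (r - origin) . axis for one point or an array of points."""
    rel = np.asarray(xyz, dtype=float) - np.asarray(ref.origin)
    return rel @ np.asarray(ref.axis)


def radial_distance(xyz: np.ndarray, ref: ChannelFrameReference) -> np.ndarray:
    """Distance from the channel axis line through the origin."""
    rel = np.asarray(xyz, dtype=float) - np.asarray(ref.origin)
    ax = np.asarray(ref.axis)
    axial = rel @ ax
    perp = rel - np.multiply.outer(axial, ax)
    return np.linalg.norm(perp, axis=-1)


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

def _element_from_record(line: str, atom_name: str) -> str:
    elem = line[76:78].strip() if len(line) >= 78 else ""
    if elem:
        return elem.upper()
    # fall back on the atom-name convention: first non-digit character(s)
    name = atom_name.strip()
    stripped = name.lstrip("0123456789")
    if stripped[:2].upper() in ("CL", "BR", "NA", "MG", "ZN") and len(name) > 1:
        return stripped[:2].upper()
    return stripped[:1].upper()


def read_pdb(
    path: str | Path,
    radius_table: str = "bondi",
    default_box: tuple[float, float, float] = (100.0, 100.0, 100.0),
) -> tuple[Topology, list[Frame]]:
    """Read a (possibly multi-model) PDB file.

    Chain identifiers map to subunit labels 1..5 in order of first
    appearance; non-protein records (ions, waters) get subunit 0. Van der
    Waals radii come from the bundled element table, CA atom names set the
    C-alpha flag, and CRYST1 (if present) sets the box. Returns the topology
    and one Frame per MODEL (a single frame for single-model files).
    """
    path = Path(path)
    atoms: list[Atom] = []
    ion_species: dict[int, str] = {}
    water_idx: set[int] = set()
    chain_order: dict[str, int] = {}
    frames_xyz: list[list[tuple[float, float, float]]] = [[]]
    box = default_box
    first_model_done = False

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            rec = raw[:6].strip()
            if rec == "CRYST1":
                try:
                    box = (float(raw[6:15]), float(raw[15:24]), float(raw[24:33]))
                except ValueError as exc:
                    raise PDBParseError(
                        f"{path}:{lineno}: malformed CRYST1 record"
                    ) from exc
            elif rec == "MODEL":
                if frames_xyz[-1]:
                    first_model_done = True
                    frames_xyz.append([])
            elif rec == "ENDMDL":
                first_model_done = True
            elif rec in ("ATOM", "HETATM"):
                try:
                    name = raw[12:16].strip()
                    resname = raw[17:20].strip()
                    chain = raw[21].strip()
                    resnum = int(raw[22:26])
                    x = float(raw[30:38])
                    y = float(raw[38:46])
                    z = float(raw[46:54])
                except (ValueError, IndexError) as exc:
                    raise PDBParseError(
                        f"{path}:{lineno}: malformed {rec} record: {raw.rstrip()!r}"
                    ) from exc
                frames_xyz[-1].append((x, y, z))
                if first_model_done:
                    continue  # topology fixed by the first model
                index = len(atoms)
                element = _element_from_record(raw, name)
                is_water = resname.upper() in _WATER_RESNAMES
                ion = None
                if rec == "HETATM" or resname.upper() in _ION_SPECIES:
                    ion = _ION_SPECIES.get(resname.upper())
                if is_water:
                    subunit = 0
                    if element == "O":
                        water_idx.add(index)
                elif ion is not None:
                    subunit = 0
                    ion_species[index] = ion
                else:
                    if chain not in chain_order:
                        chain_order[chain] = len(chain_order) + 1
                    subunit = chain_order[chain]
                atoms.append(
                    Atom(
                        index=index,
                        name=name,
                        residue_number=resnum,
                        residue_name=resname,
                        subunit=subunit,
                        element=element,
                        is_calpha=(name == "CA" and not is_water and ion is None),
                        vdw_radius=vdw_radius_for(element, radius_table),
                    )
                )

    if not atoms:
        raise PDBParseError(f"{path}: no ATOM/HETATM records found")
    if not frames_xyz[-1]:
        frames_xyz.pop()
    n = len(atoms)
    frames = []
    for k, xyz in enumerate(frames_xyz):
        if len(xyz) != n:
            raise PDBParseError(
                f"{path}: model {k + 1} has {len(xyz)} atoms, expected {n}"
            )
        frames.append(Frame(np.array(xyz), box=box, time=float(k)))
    topo = Topology(atoms, ion_species, frozenset(water_idx))
    return topo, frames


_CHAINS = "ABCDEFGHIJ"


def write_pdb(
    path: str | Path,
    topology: Topology,
    frames: Frame | Sequence[Frame],
) -> None:
    """Write a single- or multi-model PDB (fixed 8.3 coordinate precision)."""
    if isinstance(frames, Frame):
        frames = [frames]
    lines: list[str] = []
    box = frames[0].box
    lines.append(
        f"CRYST1{box[0]:9.3f}{box[1]:9.3f}{box[2]:9.3f}"
        f"{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1"
    )
    multi = len(frames) > 1
    for k, fr in enumerate(frames):
        if multi:
            lines.append(f"MODEL     {k + 1:4d}")
        for a, (x, y, z) in zip(topology.atoms, fr.coordinates):
            rec = "ATOM  " if a.subunit > 0 else "HETATM"
            chain = _CHAINS[a.subunit - 1] if a.subunit > 0 else "Z"
            name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
            serial = min(a.index + 1, 99999)
            lines.append(
                f"{rec}{serial:5d} {name:<4s} {a.residue_name:<3s} {chain}"
                f"{a.residue_number % 10000:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {a.element:>2s}"
            )
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# XYZ trajectory
# ---------------------------------------------------------------------------

def read_xyz_trajectory(
    path: str | Path,
    topology: Topology,
    dt: float,
    box: tuple[float, float, float],
) -> Trajectory:
    """Read a multi-frame XYZ file against a known topology.

    Frame k gets time k*dt (ns); the box is constant across frames.
    """
    path = Path(path)
    n = topology.n_atoms
    frames: list[Frame] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise XYZFormatError(f"{path}: empty file")
    pos = 0
    block = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            count = int(lines[pos].strip())
        except ValueError as exc:
            raise XYZFormatError(
                f"{path}: block {block}: bad atom-count line {lines[pos]!r}"
            ) from exc
        if count != n:
            raise XYZFormatError(
                f"{path}: block {block} declares {count} atoms, topology has {n}"
            )
        if pos + 2 + n > len(lines):
            raise XYZFormatError(f"{path}: block {block} truncated")
        xyz = np.empty((n, 3))
        for i in range(n):
            parts = lines[pos + 2 + i].split()
            if len(parts) < 4:
                raise XYZFormatError(
                    f"{path}: block {block}, atom {i}: bad line {lines[pos + 2 + i]!r}"
                )
            xyz[i] = [float(parts[1]), float(parts[2]), float(parts[3])]
        frames.append(Frame(xyz, box=box, time=block * dt))
        pos += 2 + n
        block += 1
    if not frames:
        raise XYZFormatError(f"{path}: no coordinate blocks found")
    return Trajectory(topology, frames)


def write_xyz_trajectory(path: str | Path, traj: Trajectory) -> None:
    """Write a multi-frame XYZ file (%.6f coordinate precision)."""
    out: list[str] = []
    elements = [a.element for a in traj.topology.atoms]
    for k, fr in enumerate(traj.frames):
        out.append(str(fr.n_atoms))
        out.append(f"frame {k} t={fr.time:.6f} ns")
        for el, (x, y, z) in zip(elements, fr.coordinates):
            out.append(f"{el:<2s} {x:14.6f} {y:14.6f} {z:14.6f}")
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# Topology TSV
# ---------------------------------------------------------------------------

_TSV_HEADER = "index\tname\tresnum\tresname\tsubunit\telement\tis_calpha\tradius\tkind"


def write_topology_tsv(path: str | Path, topology: Topology) -> None:
    rows = [_TSV_HEADER]
    for a in topology.atoms:
        if a.index in topology.ion_species:
            kind = f"ion:{topology.ion_species[a.index]}"
        elif a.index in topology.water_oxygen_indices:
            kind = "water_oxygen"
        else:
            kind = "protein" if a.subunit > 0 else "other"
        rows.append(
            f"{a.index}\t{a.name}\t{a.residue_number}\t{a.residue_name}\t"
            f"{a.subunit}\t{a.element}\t{int(a.is_calpha)}\t{a.vdw_radius:.4f}\t{kind}"
        )
    Path(path).write_text("\n".join(rows) + "\n")


def read_topology_tsv(path: str | Path) -> Topology:
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0] != _TSV_HEADER:
        raise ValueError(f"{path}: missing or unexpected topology header")
    atoms: list[Atom] = []
    ions: dict[int, str] = {}
    waters: set[int] = set()
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        f = line.split("\t")
        if len(f) != 9:
            raise ValueError(f"{path}:{lineno}: expected 9 fields, got {len(f)}")
        idx = int(f[0])
        atoms.append(
            Atom(
                index=idx, name=f[1], residue_number=int(f[2]), residue_name=f[3],
                subunit=int(f[4]), element=f[5], is_calpha=bool(int(f[6])),
                vdw_radius=float(f[7]),
            )
        )
        if f[8].startswith("ion:"):
            ions[idx] = f[8][4:]
        elif f[8] == "water_oxygen":
            waters.add(idx)
    return Topology(atoms, ions, frozenset(waters))
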