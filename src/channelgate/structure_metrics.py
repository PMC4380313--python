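"""Least-squares superposition, RMSD/RMSF, and inter-subunit contacts.

Superposition is the standard Kabsch fit: the proper rotation and
translation minimising the summed squared deviation over a selection, with
RMSD evaluated over the same selection after the fit. RMSF superposes all
frames onto the iteratively refined mean structure and reports each atom's
root-mean-square excursion about its mean position.

Native contacts are C-alpha pairs across two subunits' inner helices whose
distance in a reference structure is below a cutoff (8 A by default, the
standard C-alpha contact convention); retention is the per-frame fraction
of those pairs still within cutoff times a tolerance factor (1.2 default;
set 1.0 for the strict native cutoff). A single displaced subunit shows up
as selectively lost contacts with its two neighbours — the asymmetric
gating signature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io_core import Frame, SelectionError, Topology, Trajectory

__all__ = [
    "SuperpositionResult",
    "ContactSet",
    "ContactRetention",
    "superpose",
    "apply_fit",
    "rmsd_series",
    "rmsf",
    "native_contacts",
    "contact_retention",
]


@dataclass(frozen=True)
class SuperpositionResult:
    rotation: np.ndarray      # 3x3 proper orthogonal
    translation: np.ndarray   # applied as x -> R x + t
    rmsd: float               # A, over the fitted selection


def _check_nondegenerate(x: np.ndarray, what: str) -> None:
    if x.shape[0] < 3:
        raise ValueError(f"{what}: need >= 3 atoms for a rigid fit")
    centered = x - x.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s[1] < 1e-8 * max(1.0, s[0]):
        raise ValueError(f"{what}: selection is collinear or coincident")


def superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    selection: np.ndarray | None = None,
) -> SuperpositionResult:
    """Kabsch fit of ``mobile`` onto ``reference`` over ``selection``.

    Returns the proper rotation R (det +1), translation t such that
    R @ x + t best matches the reference, and the post-fit RMSD over the
    selection.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if selection is None:
        selection = np.arange(mobile.shape[0])
    m = mobile[selection]
    r = reference[selection]
    if m.shape != r.shape:
        raise ValueError(f"selection shapes differ: {m.shape} vs {r.shape}")
    _check_nondegenerate(m, "mobile")
    _check_nondegenerate(r, "reference")
    cm, cr = m.mean(axis=0), r.mean(axis=0)
    h = (m - cm).T @ (r - cr)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = cr - rot @ cm
    fitted = m @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - r) ** 2, axis=1))))
    return SuperpositionResult(rotation=rot, translation=trans, rmsd=rmsd)


def apply_fit(coords: np.ndarray, fit: SuperpositionResult) -> np.ndarray:
    return np.asarray(coords) @ fit.rotation.T + fit.translation


def rmsd_series(
    traj: Trajectory,
    reference: Frame,
    selection: np.ndarray | None = None,
) -> np.ndarray:
    """Per-frame RMSD to a reference after least-squares fitting."""
    ref = reference.coordinates
    return np.array([
        superpose(f.coordinates, ref, selection).rmsd for f in traj.frames
    ])


def rmsf(
    traj: Trajectory,
    selection: np.ndarray | None = None,
    fit_selection: np.ndarray | None = None,
    tol: float = 1e-6,
    max_iter: int = 50,
) -> np.ndarray:
    """Per-atom RMSF about the mean structure.

    Frames are superposed (over ``fit_selection``, defaulting to
    ``selection``) onto a mean structure refined iteratively until it moves
    by less than ``tol`` A. Returns one value per selected atom.
    """
    if len(traj.frames) < 2:
        raise ValueError("RMSF needs at least two frames")
    if selection is None:
        selection = np.arange(traj.topology.n_atoms)
    if fit_selection is None:
        fit_selection = selection
    coords = traj.coordinates()
    mean = coords[0].copy()
    for _ in range(max_iter):
        fitted = np.empty_like(coords)
        for k in range(coords.shape[0]):
            fit = superpose(coords[k], mean, fit_selection)
            fitted[k] = apply_fit(coords[k], fit)
        new_mean = fitted.mean(axis=0)
        shift = float(np.max(np.abs(new_mean - mean)))
        mean = new_mean
        if shift < tol:
            break
    dev = fitted[:, selection, :] - mean[selection]
    return np.sqrt(np.mean(np.sum(dev ** 2, axis=2), axis=0))


@dataclass
class ContactSet:
    """Native C-alpha contacts grouped by inter-subunit helix pair."""

    pairs: dict[tuple[int, int], list[tuple[int, int]]]
    cutoff: float
    reference_frame: int = 0

    def n_pairs(self) -> dict[tuple[int, int], int]:
        return {hp: len(p) for hp, p in self.pairs.items()}


@dataclass
class ContactRetention:
    fraction_per_frame: dict[tuple[int, int], np.ndarray]
    tolerance_factor: float


def native_contacts(
    reference: Frame,
    topology: Topology,
    helix_pairs: list[tuple[int, int]],
    residue_range: tuple[int, int] = (15, 40),
    cutoff: float = 8.0,
    reference_frame: int = 0,
) -> ContactSet:
    """All cross-subunit C-alpha pairs within ``cutoff`` in the reference.

    ``helix_pairs`` are subunit-label pairs, e.g. [(1, 2), (1, 5)] for the
    inner helix of subunit 1 against those of its neighbours. Same-subunit
    pairs are rejected: the analysis is inter-subunit by definition.
    """
    residues = range(residue_range[0], residue_range[1] + 1)
    out: dict[tuple[int, int], list[tuple[int, int]]] = {}
    for s1, s2 in helix_pairs:
        if s1 == s2:
            raise ValueError(f"helix pair ({s1}, {s2}) is within one subunit")
        i1 = topology.calpha_indices(subunit=s1, residues=residues)
        i2 = topology.calpha_indices(subunit=s2, residues=residues)
        if i1.size == 0 or i2.size == 0:
            raise SelectionError(
                f"no C-alpha atoms in residue range {residue_range} "
                f"for subunit pair ({s1}, {s2})"
            )
        a = reference.coordinates[i1]
        b = reference.coordinates[i2]
        d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2)
        ii, jj = np.nonzero(d <= cutoff)
        out[(s1, s2)] = [(int(i1[i]), int(i2[j])) for i, j in zip(ii, jj)]
        if not out[(s1, s2)]:
            warnings.warn(f"no native contacts for subunit pair ({s1}, {s2})")
    return ContactSet(pairs=out, cutoff=cutoff, reference_frame=reference_frame)


def contact_retention(
    traj: Trajectory,
    contacts: ContactSet,
    tolerance_factor: float = 1.2,
) -> ContactRetention:
    """Per-frame fraction of native pairs within cutoff * tolerance_factor."""
    if all(len(p) == 0 for p in contacts.pairs.values()):
        raise ValueError("contact set is empty")
    thresh = contacts.cutoff * tolerance_factor
    out: dict[tuple[int, int], np.ndarray] = {}
    for hp, pairs in contacts.pairs.items():
        if not pairs:
            out[hp] = np.full(len(traj.frames), np.nan)
            continue
        ai = np.array([p[0] for p in pairs])
        bi = np.array([p[1] for p in pairs])
        fr = np.empty(len(traj.frames))
        for k, f in enumerate(traj.frames):
            d = np.linalg.norm(f.coordinates[ai] - f.coordinates[bi], axis=1)
            fr[k] = np.count_nonzero(d <= thresh) / len(pairs)
        out[hp] = fr
    return ContactRetention(fraction_per_frame=out, tolerance_factor=tolerance_factor)
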