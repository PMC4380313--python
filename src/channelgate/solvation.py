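"""Solvation of permeating ions and water occupancy maps inside the pore.

Two views of pore hydration:

* a coordination profile — for every cation currently inside the TM slab
  (per the permeation state machine), the number of water oxygens within a
  first-shell cutoff (3.5 A default) and of other cations within wider
  cutoffs (5 and 4 A), binned by the central ion's axial position z' and
  averaged per bin;
* a 2D water map — a (z', radial distance) histogram of water-oxygen
  positions about the functionalized site, which makes an occluded
  (dehydrated) core visible as an empty region near the axis.

"Permeating" here means any ion in the INSIDE state, not only ions that
eventually complete a crossing; restrict via ``completed_only`` if desired.
The central ion never counts toward its own cation shell.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io_core import ChannelFrameReference, Trajectory
from .permeation import PermeationRecord

__all__ = ["CoordinationProfile", "WaterMap2D", "coordination_profile", "water_map_2d"]


@dataclass
class CoordinationProfile:
    z_bins: np.ndarray                   # bin edges, A
    mean_water: np.ndarray               # per bin; NaN where unsampled
    mean_cation: dict[float, np.ndarray]  # cutoff -> per-bin mean
    sample_counts: np.ndarray
    water_cutoff: float

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.z_bins[:-1] + self.z_bins[1:])


@dataclass
class WaterMap2D:
    axial_edges: np.ndarray
    radial_edges: np.ndarray
    counts: np.ndarray                   # (n_axial, n_radial)


def coordination_profile(
    traj: Trajectory,
    record: PermeationRecord,
    ref: ChannelFrameReference,
    water_cutoff: float = 3.5,
    cation_cutoffs: tuple[float, ...] = (5.0, 4.0),
    bin_width: float = 1.0,
    z_range: tuple[float, float] = (-16.0, 16.0),
    completed_only: bool = False,
) -> CoordinationProfile:
    """Water/cation coordination around in-pore cations, binned by z'.

    Samples are (frame, ion) pairs where the ion is INSIDE per ``record``.
    Bins with no samples are reported as NaN (missing), never as 0.
    """
    waters = np.array(sorted(traj.topology.water_oxygen_indices), dtype=int)
    cations = record.ion_indices
    inside = record.inside_mask()
    if completed_only:
        completed = {e.ion for e in record.events}
        keep = np.array([i in completed for i in cations])
        inside = inside & keep[None, :]

    n_bins = int(np.ceil((z_range[1] - z_range[0]) / bin_width))
    edges = z_range[0] + bin_width * np.arange(n_bins + 1)
    w_sum = np.zeros(n_bins)
    c_sum = {c: np.zeros(n_bins) for c in cation_cutoffs}
    n_samp = np.zeros(n_bins, dtype=int)

    if not inside.any():
        warnings.warn("no in-pore ion samples: coordination profile is empty")
    for a, fidx in enumerate(record.frame_indices):
        cols = np.nonzero(inside[a])[0]
        if cols.size == 0:
            continue
        coords = traj.frames[fidx].coordinates
        wat_xyz = coords[waters] if waters.size else np.empty((0, 3))
        cat_xyz = coords[cations]
        for j in cols:
            zc = record.z_history[a, j]
            b = int((zc - z_range[0]) // bin_width)
            if not 0 <= b < n_bins:
                continue
            center = coords[cations[j]]
            if waters.size:
                dw = np.linalg.norm(wat_xyz - center, axis=1)
                nw = int(np.count_nonzero(dw <= water_cutoff))
            else:
                nw = 0
            dc = np.linalg.norm(cat_xyz - center, axis=1)
            dc[j] = np.inf  # self-exclusion
            w_sum[b] += nw
            for c in cation_cutoffs:
                c_sum[c][b] += int(np.count_nonzero(dc <= c))
            n_samp[b] += 1

    with np.errstate(invalid="ignore", divide="ignore"):
        mean_w = np.where(n_samp > 0, w_sum / np.maximum(n_samp, 1), np.nan)
        mean_c = {
            c: np.where(n_samp > 0, s / np.maximum(n_samp, 1), np.nan)
            for c, s in c_sum.items()
        }
    return CoordinationProfile(
        z_bins=edges, mean_water=mean_w, mean_cation=mean_c,
        sample_counts=n_samp, water_cutoff=water_cutoff,
    )


def water_map_2d(
    traj: Trajectory,
    ref: ChannelFrameReference,
    axial_halfwidth: float = 10.0,
    radial_cutoff: float = 10.0,
    bin_widths: tuple[float, float] = (0.5, 0.5),
    burn_in: float = 0.0,
) -> WaterMap2D:
    """2D histogram of water oxygens in (z', radial distance) coordinates."""
    if bin_widths[0] <= 0 or bin_widths[1] <= 0:
        raise ValueError("bin widths must be positive")
    waters = np.array(sorted(traj.topology.water_oxygen_indices), dtype=int)
    origin = np.asarray(ref.origin)
    n_ax = int(np.ceil(2.0 * axial_halfwidth / bin_widths[0]))
    n_rad = int(np.ceil(radial_cutoff / bin_widths[1]))
    ax_edges = -axial_halfwidth + bin_widths[0] * np.arange(n_ax + 1)
    rad_edges = bin_widths[1] * np.arange(n_rad + 1)
    counts = np.zeros((n_ax, n_rad))
    for frame in traj.frames:
        if frame.time < burn_in or waters.size == 0:
            continue
        xyz = frame.coordinates[waters] - origin
        zp = xyz[:, 2]
        rp = np.hypot(xyz[:, 0], xyz[:, 1])
        h, _, _ = np.histogram2d(zp, rp, bins=(ax_edges, rad_edges))
        counts += h
    return WaterMap2D(axial_edges=ax_edges, radial_edges=rad_edges, counts=counts)
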