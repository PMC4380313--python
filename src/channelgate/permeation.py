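"""Ion permeation bookkeeping, rates, conductance, axial occupancy.

A permeation event is a full channel crossing: entry through one mouth of
the transmembrane (TM) slab and exit through the opposite mouth, while
staying within a radial cutoff of the channel axis (so ions diffusing
around the protein through bulk/periodic images are never counted). Each
ion runs a three-state machine on its axial channel coordinate z':

    OUTSIDE_TOP  --(crosses z_top, r <= cutoff)-->  INSIDE
    INSIDE       --(crosses z_bottom)-->            OUTSIDE_BOTTOM   [exit]
    INSIDE       --(returns past z_top)-->          OUTSIDE_TOP      [rejected]

and symmetrically for upward crossings. An ion that drifts radially out of
the cutoff while inside aborts its pending entry. Displacements between
frames are minimum-image corrected, so a periodic wrap in z is recognised
as such and never read as a crossing. Frames before the burn-in time are
ignored (the models relax structurally early in each run).

Conductance follows the counting definition: the mean current is the
permeated charge over the analysis window, and conductance is current over
applied voltage, reported in pS (with a helper rounding to the nearest
10 pS for display, matching how such estimates are quoted).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io_core import ChannelFrameReference, SelectionError, Trajectory

__all__ = [
    "TMBounds",
    "PermeationEvent",
    "PermeationRecord",
    "ConductanceEstimate",
    "ELEMENTARY_CHARGE",
    "count_permeations",
    "permeation_rate",
    "conductance",
    "report_conductance_ps",
    "ion_occupancy_histogram",
]

ELEMENTARY_CHARGE = 1.602176634e-19  # C

OUTSIDE_TOP, INSIDE, OUTSIDE_BOTTOM, OUTSIDE_SIDE = 1, 0, -1, 2


@dataclass(frozen=True)
class TMBounds:
    """TM slab in channel coordinates (A relative to the reference origin)."""

    z_top: float = 16.0
    z_bottom: float = -16.0
    radial_cutoff: float = 12.0

    def __post_init__(self) -> None:
        if self.z_top <= self.z_bottom:
            raise ValueError("z_top must exceed z_bottom")
        if self.radial_cutoff <= 0:
            raise ValueError("radial_cutoff must be positive")


@dataclass(frozen=True)
class PermeationEvent:
    ion: int            # topology atom index
    entry_frame: int    # trajectory frame index
    exit_frame: int
    direction: str      # "down" (top->bottom) or "up"


@dataclass
class PermeationRecord:
    species: str
    ion_indices: np.ndarray               # topology atom indices
    frame_indices: np.ndarray             # analysed frames (after burn-in)
    state_history: np.ndarray             # (n_kept_frames, n_ions) state codes
    z_history: np.ndarray                 # (n_kept_frames, n_ions) z', A
    entries: int
    exits: int
    entries_down: int = 0
    entries_up: int = 0
    exits_down: int = 0
    exits_up: int = 0
    events: list[PermeationEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.exits > self.entries:
            raise ValueError("exits cannot exceed entries")

    def inside_mask(self) -> np.ndarray:
        """(n_kept_frames, n_ions) bool: ion in the INSIDE state."""
        return self.state_history == INSIDE


@dataclass(frozen=True)
class ConductanceEstimate:
    n_permeated: int
    window: float           # ns
    voltage: float          # Volt
    current: float          # Ampere
    conductance_ps: float   # pS
    reported_ps: float      # rounded to the nearest 10 pS


def _classify(z: float, r: float, bounds: TMBounds) -> int:
    if z > bounds.z_top:
        return OUTSIDE_TOP
    if z < bounds.z_bottom:
        return OUTSIDE_BOTTOM
    if r <= bounds.radial_cutoff:
        return INSIDE
    return OUTSIDE_SIDE


def count_permeations(
    traj: Trajectory,
    species: str,
    bounds: TMBounds = TMBounds(),
    burn_in: float = 10.0,
    ref: ChannelFrameReference | None = None,
) -> PermeationRecord:
    """Run the per-ion crossing state machine over the trajectory.

    ``species`` selects ions by tag ("K", "CL", ...). ``ref`` defaults to
    the channel frame of the first analysed frame. Re-entries count as new
    entries; an entry pending when the trajectory ends is neither an exit
    nor a rejection.
    """
    from .io_core import channel_reference

    ions = traj.topology.ion_indices(species)
    if ions.size == 0:
        raise SelectionError(f"no ions of species {species!r} in topology")
    times = traj.times
    total = times[-1] - times[0]
    if burn_in >= total + times[0]:
        raise ValueError(f"burn_in {burn_in} ns >= trajectory end {times[-1]} ns")
    kept = np.nonzero(times >= burn_in)[0]
    if kept.size < 2:
        raise ValueError("fewer than two frames after burn-in")
    if ref is None:
        ref = channel_reference(traj.frames[kept[0]], traj.topology)
    origin = np.asarray(ref.origin)

    nf, ni = kept.size, ions.size
    z = np.empty((nf, ni))
    r = np.empty((nf, ni))
    lz = traj.frames[0].box[2]
    for a, fidx in enumerate(kept):
        xyz = traj.frames[fidx].coordinates[ions]
        z[a] = xyz[:, 2] - origin[2]
        r[a] = np.hypot(xyz[:, 0] - origin[0], xyz[:, 1] - origin[1])

    states = np.empty((nf, ni), dtype=np.int8)
    entries = exits = 0
    counts = {"entry_down": 0, "entry_up": 0, "exit_down": 0, "exit_up": 0}
    events: list[PermeationEvent] = []
    for j in range(ni):
        state = _classify(z[0, j], r[0, j], bounds)
        came_from = 0        # +1 entered from top, -1 from bottom, 0 not inside
        entry_at = -1
        if state == INSIDE:
            state = OUTSIDE_TOP if z[0, j] >= 0 else OUTSIDE_BOTTOM
        states[0, j] = state
        for a in range(1, nf):
            new = _classify(z[a, j], r[a, j], bounds)
            if state in (OUTSIDE_TOP, OUTSIDE_BOTTOM, OUTSIDE_SIDE):
                if (
                    {state, new} == {OUTSIDE_TOP, OUTSIDE_BOTTOM}
                    and abs(z[a, j] - z[a - 1, j]) < lz / 2.0
                    and r[a, j] <= bounds.radial_cutoff
                    and r[a - 1, j] <= bounds.radial_cutoff
                ):
                    # whole-slab traversal within one frame interval (a wrap
                    # through the periodic boundary shows a > L_z/2 raw jump
                    # and is excluded)
                    direction = "down" if state == OUTSIDE_TOP else "up"
                    entries += 1
                    exits += 1
                    counts[f"entry_{direction}"] += 1
                    counts[f"exit_{direction}"] += 1
                    events.append(PermeationEvent(
                        ion=int(ions[j]), entry_frame=int(kept[a]),
                        exit_frame=int(kept[a]), direction=direction))
                    state = new
                elif new == INSIDE and state != OUTSIDE_SIDE:
                    entries += 1
                    came_from = 1 if state == OUTSIDE_TOP else -1
                    counts["entry_down" if came_from == 1 else "entry_up"] += 1
                    entry_at = a
                    state = INSIDE
                elif new == INSIDE:
                    state = new  # radial re-entry: not a mouth crossing
                    came_from = 0
                else:
                    state = new
            elif state == INSIDE:
                if new == OUTSIDE_BOTTOM:
                    if came_from == 1:
                        exits += 1
                        counts["exit_down"] += 1
                        events.append(PermeationEvent(
                            ion=int(ions[j]), entry_frame=int(kept[entry_at]),
                            exit_frame=int(kept[a]), direction="down"))
                    came_from = 0
                    state = new
                elif new == OUTSIDE_TOP:
                    if came_from == -1:
                        exits += 1
                        counts["exit_up"] += 1
                        events.append(PermeationEvent(
                            ion=int(ions[j]), entry_frame=int(kept[entry_at]),
                            exit_frame=int(kept[a]), direction="up"))
                    came_from = 0
                    state = new
                elif new == OUTSIDE_SIDE:
                    came_from = 0   # abort the pending entry
                    state = new
            states[a, j] = state

    return PermeationRecord(
        species=species, ion_indices=ions, frame_indices=kept,
        state_history=states, z_history=z,
        entries=entries, exits=exits,
        entries_down=counts["entry_down"], entries_up=counts["entry_up"],
        exits_down=counts["exit_down"], exits_up=counts["exit_up"],
        events=events,
    )


def permeation_rate(record: PermeationRecord) -> float:
    """Permeation rate, percent: 100 * exits / entries (0 if no entries)."""
    if record.entries == 0:
        warnings.warn("no entries recorded: permeation rate defined as 0")
        return 0.0
    return 100.0 * record.exits / record.entries


def report_rate_percent(record: PermeationRecord) -> int:
    """Rate rounded to the nearest integer percent, as tabulated."""
    return int(round(permeation_rate(record)))


def conductance(
    record_or_exits: PermeationRecord | int,
    window: float,
    voltage: float,
) -> ConductanceEstimate:
    """Conductance from counted crossings: G = N e / (window * V), in pS."""
    if voltage <= 0:
        raise ValueError("voltage must be positive for a conductance estimate")
    if window <= 0:
        raise ValueError("analysis window must be positive")
    n = (record_or_exits.exits if isinstance(record_or_exits, PermeationRecord)
         else int(record_or_exits))
    current = n * ELEMENTARY_CHARGE / (window * 1e-9)  # A
    g_ps = current / voltage * 1e12
    return ConductanceEstimate(
        n_permeated=n, window=window, voltage=voltage, current=current,
        conductance_ps=g_ps, reported_ps=report_conductance_ps(g_ps),
    )


def report_conductance_ps(g_ps: float) -> float:
    """Round a conductance to the nearest 10 pS for display."""
    return 10.0 * round(g_ps / 10.0)


def ion_occupancy_histogram(
    traj: Trajectory,
    species: str,
    ref: ChannelFrameReference,
    axial_halfwidth: float = 10.0,
    radial_cutoff: float = 10.0,
    bin_width: float = 1.0,
    burn_in: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of ion counts along z', restricted to the pore region.

    Counts ions with |z'| <= axial_halfwidth and radial distance <=
    radial_cutoff, summed over frames after burn-in. Returns
    (bin_edges, counts).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    ions = traj.topology.ion_indices(species)
    if ions.size == 0:
        raise SelectionError(f"no ions of species {species!r} in topology")
    origin = np.asarray(ref.origin)
    n_bins = int(np.ceil(2.0 * axial_halfwidth / bin_width))
    edges = -axial_halfwidth + bin_width * np.arange(n_bins + 1)
    counts = np.zeros(n_bins)
    for frame in traj.frames:
        if frame.time < burn_in:
            continue
        xyz = frame.coordinates[ions] - origin
        zp = xyz[:, 2]
        rp = np.hypot(xyz[:, 0], xyz[:, 1])
        sel = (np.abs(zp) <= axial_halfwidth) & (rp <= radial_cutoff)
        h, _ = np.histogram(zp[sel], bins=edges)
        counts += h
    return edges, counts
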