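"""1D adaptive-biasing-force (ABF) free-energy estimation on toy systems.

ABF estimates the free-energy profile A(z) along a chosen coordinate by
accumulating the bin-wise mean of the instantaneous force on that
coordinate and applying its opposite as a bias. Once the running mean
converges, the biased dynamics diffuses freely (the flat-histogram
signature) and the potential of mean force follows by integration:

    A(z) = - integral of <F>(z) dz,  anchored so min A = 0.

The bias is ramped in linearly — scaled by min(1, n_b / N_ramp) in each
bin b — so that early, noisy force estimates are not applied at full
strength (N_ramp = 500 samples by default).

The estimator is exercised on single-particle overdamped Langevin systems
with known analytic potentials (flat, harmonic, double-well, or the
synthetic pore's effective potential), mirroring a windowed protocol: the
coordinate range is split into abutting windows (2 A wide by default),
each sampled with reflecting walls, and the per-window profiles are
stitched by matching values at the junctions. Units: kcal/mol, Angstrom,
ps; temperature in K.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "Potential",
    "ToySystem",
    "ABFWindow",
    "PMFProfile",
    "make_potential",
    "run_abf",
    "integrate_pmf",
    "stitch_windows",
    "run_windowed_abf",
    "KB_KCAL",
]

KB_KCAL = 0.0019872041  # kcal/mol/K


@dataclass(frozen=True)
class Potential:
    """Analytic 1D potential with its force, in kcal/mol and kcal/mol/A."""

    name: str
    u: Callable[[np.ndarray], np.ndarray]
    f: Callable[[np.ndarray], np.ndarray]


def make_potential(name: str, **params) -> Potential:
    """Named analytic potentials: 'flat', 'harmonic' (k), 'double_well'
    (barrier, half_width)."""
    if name == "flat":
        return Potential("flat", lambda z: np.zeros_like(np.asarray(z, float)),
                         lambda z: np.zeros_like(np.asarray(z, float)))
    if name == "harmonic":
        k = params.get("k", 1.0)
        return Potential("harmonic",
                         lambda z: 0.5 * k * np.square(z),
                         lambda z: -k * np.asarray(z, float))
    if name == "double_well":
        h = params.get("barrier", 3.0)
        w = params.get("half_width", 1.0)
        def u(z):
            s = np.square(np.asarray(z, float) / w)
            return h * np.square(s - 1.0)
        def f(z):
            z = np.asarray(z, float)
            s = np.square(z / w)
            return -4.0 * h * (s - 1.0) * z / w**2
        return Potential("double_well", u, f)
    raise ValueError(f"unknown potential {name!r}")


@dataclass(frozen=True)
class ToySystem:
    """Single-particle overdamped Langevin system along z."""

    potential: Potential
    temperature: float = 300.0   # K
    friction: float = 1.0        # effective drag, kcal/mol * ps / A^2
    dt: float = 0.01             # ps
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.friction <= 0:
            raise ValueError("friction must be positive")

    @property
    def kt(self) -> float:
        return KB_KCAL * self.temperature


@dataclass
class ABFWindow:
    """One sampling window: force accumulators over bins of [lo, hi]."""

    z_range: tuple[float, float]
    bins: int
    ramp_threshold: int = 500
    samples_per_bin: np.ndarray = field(default=None)  # set in __post_init__
    force_sum_per_bin: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        lo, hi = self.z_range
        if hi <= lo:
            raise ValueError("window must have positive width")
        if self.bins < 1:
            raise ValueError("need at least one bin")
        if self.samples_per_bin is None:
            self.samples_per_bin = np.zeros(self.bins, dtype=np.int64)
        if self.force_sum_per_bin is None:
            self.force_sum_per_bin = np.zeros(self.bins)

    @property
    def bin_width(self) -> float:
        lo, hi = self.z_range
        return (hi - lo) / self.bins

    @property
    def bin_centers(self) -> np.ndarray:
        lo, _ = self.z_range
        return lo + self.bin_width * (np.arange(self.bins) + 0.5)

    def mean_force(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.samples_per_bin > 0,
                            self.force_sum_per_bin / np.maximum(self.samples_per_bin, 1),
                            np.nan)


@dataclass
class PMFProfile:
    z_grid: np.ndarray
    free_energy: np.ndarray   # kcal/mol, min anchored to 0
    per_window: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)


def run_abf(
    system: ToySystem,
    window: ABFWindow,
    steps: int,
    z0: float | None = None,
) -> ABFWindow:
    """Advance the biased dynamics, accumulating bin-wise forces in place.

    Each step records the instantaneous system force into the particle's
    current bin, applies the ramped opposing bias, and takes an overdamped
    Langevin step with reflecting walls at the window edges. Deterministic
    for a given system seed.
    """
    lo, hi = window.z_range
    z = 0.5 * (lo + hi) if z0 is None else float(z0)
    if not lo <= z <= hi:
        raise ValueError(f"start position {z} outside window {window.z_range}")
    rng = np.random.default_rng(system.seed)
    noise = rng.standard_normal(steps)
    dt = system.dt
    mobility = 1.0 / system.friction
    sigma = math.sqrt(2.0 * system.kt * dt * mobility)
    width = window.bin_width
    nbins = window.bins
    samples = window.samples_per_bin
    fsum = window.force_sum_per_bin
    ramp = window.ramp_threshold
    pot_f = system.potential.f
    for i in range(steps):
        b = int((z - lo) / width)
        if b == nbins:  # z exactly at the upper wall
            b = nbins - 1
        f_sys = float(pot_f(z))
        samples[b] += 1
        fsum[b] += f_sys
        mean = fsum[b] / samples[b]
        bias = -mean * min(1.0, samples[b] / ramp)
        z = z + (f_sys + bias) * mobility * dt + sigma * noise[i]
        # reflecting walls must contain the particle
        for _ in range(4):
            if z < lo:
                z = 2.0 * lo - z
            elif z > hi:
                z = 2.0 * hi - z
            else:
                break
        if not lo <= z <= hi:
            raise RuntimeError("particle escaped the window walls")
    return window


def integrate_pmf(window: ABFWindow) -> tuple[np.ndarray, np.ndarray]:
    """Per-window PMF: A(z) = -int <F> dz by the trapezoid rule on centers.

    Requires every bin sampled at least ``ramp_threshold`` times; the left
    edge is anchored at 0 (global anchoring happens when stitching).
    """
    from scipy.integrate import cumulative_trapezoid

    under = np.nonzero(window.samples_per_bin < window.ramp_threshold)[0]
    if under.size:
        raise ValueError(
            f"bins {under.tolist()} sampled fewer than ramp_threshold="
            f"{window.ramp_threshold} times"
        )
    if window.bins < 2:
        raise ValueError("cannot integrate a single-bin window")
    centers = window.bin_centers
    grad = -window.mean_force()
    a = cumulative_trapezoid(grad, centers, initial=0.0)
    return centers, a


def _linear_extrapolate(z: np.ndarray, a: np.ndarray, z_target: float) -> float:
    if z.size < 2:
        return float(a[-1])
    if z_target >= z[-1]:
        slope = (a[-1] - a[-2]) / (z[-1] - z[-2])
        return float(a[-1] + slope * (z_target - z[-1]))
    slope = (a[1] - a[0]) / (z[1] - z[0])
    return float(a[0] + slope * (z_target - z[0]))


def stitch_windows(
    profiles: list[tuple[np.ndarray, np.ndarray]],
    gap_tolerance: float = 1.5,
) -> PMFProfile:
    """Join per-window PMFs into one profile anchored at min = 0.

    Windows are sorted by position (input order is irrelevant). Where two
    windows share grid points, the successor is offset so the mean
    discrepancy over the shared points vanishes; abutting windows are
    matched by linear extrapolation to the midpoint between their edge
    bins. A gap wider than ``gap_tolerance`` times the bin spacing is an
    error.
    """
    if not profiles:
        raise ValueError("no profiles to stitch")
    profs = sorted(((np.asarray(z, float), np.asarray(a, float))
                    for z, a in profiles), key=lambda p: p[0][0])
    z_all, a_all = [profs[0][0]], [profs[0][1].copy()]
    for z, a in profs[1:]:
        prev_z = np.concatenate(z_all)
        prev_a = np.concatenate(a_all)
        order = np.argsort(prev_z)
        prev_z, prev_a = prev_z[order], prev_a[order]
        spacing = np.median(np.diff(z)) if z.size > 1 else np.median(np.diff(prev_z))
        shared = np.isin(np.round(z / 1e-6).astype(np.int64),
                         np.round(prev_z / 1e-6).astype(np.int64))
        if shared.any():
            ref_vals = np.array([
                prev_a[np.argmin(np.abs(prev_z - zz))] for zz in z[shared]
            ])
            offset = float(np.mean(ref_vals - a[shared]))
        else:
            gap = z[0] - prev_z[-1]
            if gap > gap_tolerance * spacing:
                raise ValueError(
                    f"gap of {gap:.3f} A between windows exceeds "
                    f"{gap_tolerance} bin spacings"
                )
            mid = 0.5 * (prev_z[-1] + z[0])
            offset = (_linear_extrapolate(prev_z, prev_a, mid)
                      - _linear_extrapolate(z, a, mid))
        z_all.append(z)
        a_all.append(a + offset)
    z_cat = np.concatenate(z_all)
    a_cat = np.concatenate(a_all)
    # merge duplicate grid points by averaging
    keys = np.round(z_cat / 1e-6).astype(np.int64)
    uniq, inv = np.unique(keys, return_inverse=True)
    z_out = np.zeros(uniq.size)
    a_out = np.zeros(uniq.size)
    counts = np.bincount(inv)
    np.add.at(z_out, inv, z_cat)
    np.add.at(a_out, inv, a_cat)
    z_out /= counts
    a_out /= counts
    a_out -= a_out.min()
    return PMFProfile(z_grid=z_out, free_energy=a_out,
                      per_window=[(z, a) for z, a in profs])


def run_windowed_abf(
    system: ToySystem,
    z_min: float,
    z_max: float,
    window_width: float = 2.0,
    bin_width: float = 0.2,
    steps_per_window: int = 200_000,
    ramp_threshold: int = 500,
) -> PMFProfile:
    """The full windowed protocol: sample abutting windows, then stitch."""
    n_win = int(round((z_max - z_min) / window_width))
    if n_win < 1:
        raise ValueError("range shorter than one window")
    profiles = []
    for w in range(n_win):
        lo = z_min + w * window_width
        hi = lo + window_width
        win = ABFWindow(z_range=(lo, hi),
                        bins=max(2, int(round((hi - lo) / bin_width))),
                        ramp_threshold=ramp_threshold)
        sys_w = ToySystem(system.potential, system.temperature,
                          system.friction, system.dt,
                          seed=system.seed + 7919 * w)
        run_abf(sys_w, win, steps_per_window)
        profiles.append(integrate_pmf(win))
    return stitch_windows(profiles)
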