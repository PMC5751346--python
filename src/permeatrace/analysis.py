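"""Bilayer observables from bead trajectories.

Three families of observables characterize how a penetration enhancer
perturbs a stratum-corneum lipid bilayer:

* **z-density profiles** — per-species number (or mass) density along the
  bilayer normal, locating head-group planes, the hydrophobic core, solvent,
  and where enhancer beads partition;
* **z-restricted mean square displacement and diffusion coefficient** — the
  Einstein-relation estimate of permeant mobility along the bilayer normal,

      MSD(t) = (1/N) * sum_i (z_i(t) - z_i(0))^2,   D = slope(MSD vs t) / d

  with divisor d = 2 for a one-dimensional displacement (``physical_1d``)
  or d = 4 under the ``paper`` convention, which applies the two-dimensional
  Einstein divisor to the z-only displacement. Both are exposed; they differ
  by an exact factor of two on identical input.
* **transient pores** — short-lived channels of hydrophilic head beads
  reaching the bilayer midplane. A pore is scored from the per-frame count
  of head beads inside a midplane slab: a maximal run of frames with count
  >= ``min_count`` lasting >= ``min_persistence_frames`` is one pore event,
  reported with open/close times and duration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateFitError, InputError, ValidationError
from .trajectory import BeadSelection, Trajectory

__all__ = [
    "DensityProfile",
    "MSDSeries",
    "DiffusionEstimate",
    "OccupancySeries",
    "PoreEvent",
    "density_profile",
    "msd_z",
    "diffusion_coefficient",
    "pore_occupancy_series",
    "detect_pores",
    "NM2_PER_NS_TO_CM2_PER_S",
]

#: 1 nm^2/ns = 1e-14 cm^2 / 1e-9 s = 1e-5 cm^2/s
NM2_PER_NS_TO_CM2_PER_S = 1e-5


@dataclass(frozen=True)
class DensityProfile:
    """Frame-averaged density vs z.

    ``values`` has one entry per bin: number density (beads/nm^3) or mass
    density (u/nm^3) when bead masses were supplied. Bins are half-open
    [edge_k, edge_k+1) covering [0, Lz).
    """

    bin_edges_nm: np.ndarray
    values: np.ndarray
    species_label: str
    mode: str = "number"

    @property
    def bin_mid_nm(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_nm[:-1] + self.bin_edges_nm[1:])


@dataclass(frozen=True)
class MSDSeries:
    """Mean square z-displacement (nm^2) vs lag time (ns)."""

    lag_times_ns: np.ndarray
    msd_nm2: np.ndarray


@dataclass(frozen=True)
class DiffusionEstimate:
    """Diffusion coefficient from a linear fit to MSD(t).

    ``d_nm2_ns`` is the coefficient in nm^2/ns; ``d_cm2_s`` converts to the
    conventional cm^2/s. ``divisor`` records the Einstein convention used
    (2 = physical 1-D, 4 = paper convention on the same z-only MSD).
    """

    d_nm2_ns: float
    divisor: int
    fit_window_ns: tuple[float, float]
    stderr_nm2_ns: float
    intercept_nm2: float

    @property
    def d_cm2_s(self) -> float:
        return self.d_nm2_ns * NM2_PER_NS_TO_CM2_PER_S


@dataclass(frozen=True)
class OccupancySeries:
    """Per-frame count of selected beads inside the midplane slab."""

    times_ns: np.ndarray
    counts: np.ndarray
    slab_half_width_nm: float


@dataclass(frozen=True)
class PoreEvent:
    """One detected transient pore: open/close times and duration (ns)."""

    open_ns: float
    close_ns: float
    duration_ns: float
    max_occupancy: int
    open_at_end: bool = False


def _mean_box(traj: Trajectory) -> np.ndarray:
    # Density and slab geometry need one box; trajectories from a barostat
    # fluctuate slightly, so the frame-mean box is used.
    return traj.boxes_nm.mean(axis=0)


def density_profile(
    traj: Trajectory,
    selection: BeadSelection,
    bin_width_nm: float = 0.1,
    mode: str = "number",
    masses: dict[str, float] | None = None,
) -> DensityProfile:
    """Frame-averaged density of a bead selection along z.

    Bins are half-open intervals of width ``bin_width_nm`` covering [0, Lz);
    a trailing partial bin narrower than half a bin width is merged into its
    predecessor. z coordinates are wrapped into [0, Lz) before binning, so a
    centered trajectory gives a profile relative to the bilayer midplane at
    Lz/2. Number density integrates back to the mean selected-bead count:
    sum(values * bin_volume) = N_selected.

    Parameters
    ----------
    mode : "number" or "mass"
        Mass mode weights each bead by ``masses[species]`` (u) and requires
        the table to cover every selected species.
    """
    if bin_width_nm <= 0:
        raise InputError("bin_width_nm must be > 0")
    box = _mean_box(traj)
    lx, ly, lz = box
    if bin_width_nm > lz:
        raise InputError(f"bin_width_nm {bin_width_nm} exceeds Lz {lz}")
    edges = np.arange(0.0, lz, bin_width_nm)
    if lz - edges[-1] < 0.5 * bin_width_nm and len(edges) > 1:
        edges = edges[:-1]  # merge trailing sliver into the previous bin
    edges = np.append(edges, lz)

    if mode not in ("number", "mass"):
        raise InputError(f"unknown density mode {mode!r}")
    weights = None
    if mode == "mass":
        if masses is None:
            raise ValidationError("mass mode requires a species -> mass table")
        sel_species = traj.species[selection.indices]
        missing = sorted(set(sel_species.tolist()) - set(masses))
        if missing:
            raise ValidationError(f"masses missing for species {missing}")
        per_bead = np.array([masses[s] for s in sel_species])
        weights = np.tile(per_bead, traj.n_frames)

    z = traj.positions_nm[:, selection.indices, 2].ravel()
    z = np.mod(z, lz)
    counts, _ = np.histogram(z, bins=edges, weights=weights)
    widths = np.diff(edges)
    values = counts / traj.n_frames / (lx * ly * widths)
    return DensityProfile(edges, values, selection.label, mode)


def msd_z(
    traj: Trajectory,
    selection: BeadSelection,
    multiple_origins: bool = False,
) -> MSDSeries:
    """Mean square displacement along z, averaged over the selected beads.

    The default is the single-origin form MSD(t_k) = <(z(t_k) - z(t_0))^2>,
    evaluated at every frame; z must already be continuous (unwrapped or
    generated with reflecting boundaries well away from the walls).
    ``multiple_origins=True`` instead averages (z(t0+t) - z(t0))^2 over all
    time origins via an FFT autocorrelation, which reduces estimator
    variance at short lags but correlates the points differently; it assumes
    a uniform frame spacing.
    """
    if traj.n_frames < 2:
        raise InputError("MSD requires at least 2 frames")
    z = traj.positions_nm[:, selection.indices, 2]
    lags = traj.times_ns - traj.times_ns[0]
    if not multiple_origins:
        msd = ((z - z[0]) ** 2).mean(axis=1)
        return MSDSeries(lags, msd)
    dt = np.diff(traj.times_ns)
    if not np.allclose(dt, dt[0], rtol=1e-6):
        raise InputError("multiple-origin MSD requires uniform frame spacing")
    msd = _msd_all_origins(z)
    return MSDSeries(lags, msd)


def _msd_all_origins(z: np.ndarray) -> np.ndarray:
    """All-origin 1-D MSD via the standard FFT decomposition.

    For each bead, MSD(k) = S1(k) - 2*S2(k) where S1 comes from cumulative
    sums of z^2 and S2 is the positional autocorrelation computed with an
    FFT in O(F log F).
    """
    f, n = z.shape
    sq = z**2
    # autocorrelation S2 via zero-padded FFT, per bead
    size = 1 << (2 * f - 1).bit_length()
    fz = np.fft.rfft(z, n=size, axis=0)
    acf = np.fft.irfft(fz * np.conj(fz), n=size, axis=0)[:f].real
    counts = (f - np.arange(f)).astype(float)[:, None]
    s2 = acf / counts
    # S1 recursion: S1(k) = (Q - D(k-1) - D(f-k)) / (f-k), Q = 2*sum(z^2)
    q = 2.0 * sq.sum(axis=0)
    s1 = np.empty_like(s2)
    running = q.copy()
    for k in range(f):
        if k == 0:
            s1[0] = running / f
        else:
            running -= sq[k - 1] + sq[f - k]
            s1[k] = running / (f - k)
    msd = (s1 - 2.0 * s2).mean(axis=1)
    msd[0] = 0.0
    return np.maximum(msd, 0.0)


def diffusion_coefficient(
    msd: MSDSeries,
    convention: str = "paper",
    fit_window_ns: tuple[float, float] | None = None,
) -> DiffusionEstimate:
    """Einstein-relation diffusion coefficient from a linear MSD fit.

    D = slope(MSD vs t) / divisor, where the divisor is 4 under the
    ``paper`` convention and 2 under ``physical_1d`` (the standard Einstein
    divisor for a one-dimensional displacement). The default fit window is
    the second half of the lag range, approximating the long-time limit
    while keeping enough points for a stable slope.
    """
    divisors = {"paper": 4, "physical_1d": 2}
    if convention not in divisors:
        raise InputError(f"unknown convention {convention!r}; use paper | physical_1d")
    divisor = divisors[convention]
    lags = msd.lag_times_ns
    if fit_window_ns is None:
        fit_window_ns = (float(lags[-1]) / 2.0, float(lags[-1]))
    lo, hi = fit_window_ns
    mask = (lags >= lo) & (lags <= hi)
    t, y = lags[mask], msd.msd_nm2[mask]
    if len(t) < 2 or np.ptp(t) == 0:
        raise DegenerateFitError("diffusion fit window has < 2 distinct lag times")
    res = stats.linregress(t, y)
    return DiffusionEstimate(
        d_nm2_ns=float(res.slope) / divisor,
        divisor=divisor,
        fit_window_ns=(float(lo), float(hi)),
        stderr_nm2_ns=float(res.stderr) / divisor if res.stderr is not None else float("nan"),
        intercept_nm2=float(res.intercept),
    )


def pore_occupancy_series(
    traj: Trajectory,
    head_selection: BeadSelection,
    slab_half_width_nm: float = 0.5,
) -> OccupancySeries:
    """Per-frame count of head beads inside the midplane slab |z - Lz/2| < w.

    Expects a centered trajectory (midplane at Lz/2); z is wrapped into
    [0, Lz) before the test so periodic images count correctly.
    """
    if slab_half_width_nm <= 0:
        raise InputError("slab_half_width_nm must be > 0")
    lz = _mean_box(traj)[2]
    z = np.mod(traj.positions_nm[:, head_selection.indices, 2], lz)
    counts = (np.abs(z - lz / 2.0) < slab_half_width_nm).sum(axis=1)
    return OccupancySeries(traj.times_ns.copy(), counts.astype(int), slab_half_width_nm)


def detect_pores(
    occupancy: OccupancySeries,
    min_count: int = 3,
    min_persistence_frames: int = 2,
) -> list[PoreEvent]:
    """Transient-pore events from a midplane occupancy series.

    An event is a maximal run of consecutive frames with occupancy
    >= ``min_count`` that persists for >= ``min_persistence_frames`` frames.
    ``open_ns`` is the time of the first frame of the run; ``close_ns`` the
    time of the first frame after it, or the last frame time (with
    ``open_at_end=True``) when the run reaches the end of the trajectory.
    An empty list is a valid result.
    """
    if min_count < 1:
        raise InputError("min_count must be >= 1")
    if min_persistence_frames < 1:
        raise InputError("min_persistence_frames must be >= 1")
    counts = np.asarray(occupancy.counts)
    times = np.asarray(occupancy.times_ns)
    if len(counts) != len(times):
        raise InputError("occupancy counts and times must align")
    above = counts >= min_count
    # run boundaries: starts where above turns on, ends where it turns off
    padded = np.concatenate([[False], above, [False]])
    starts = np.nonzero(padded[1:] & ~padded[:-1])[0]
    ends = np.nonzero(~padded[1:] & padded[:-1])[0]  # exclusive
    events: list[PoreEvent] = []
    for s, e in zip(starts, ends):
        if e - s < min_persistence_frames:
            continue
        open_at_end = bool(e >= len(times))
        close = times[-1] if open_at_end else times[e]
        events.append(
            PoreEvent(
                open_ns=float(times[s]),
                close_ns=float(close),
                duration_ns=float(close - times[s]),
                max_occupancy=int(counts[s:e].max()),
                open_at_end=open_at_end,
            )
        )
    return events
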