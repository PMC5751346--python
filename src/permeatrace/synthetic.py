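"""Synthetic inputs with known ground truth.

Two generators produce the inputs the analyses expect, with every parameter
of interest known exactly so estimator correctness can be tested end to end:

* :func:`simulate_franz_series` inverts the cumulative-amount relation. A
  zero-order permeation profile Q(t) = max(0, J* (t - lag)) is converted to
  the receptor concentrations a sampler would have measured — including the
  dilution from replacing each withdrawn aliquot with blank medium — and
  multiplicative Gaussian measurement noise is applied. Feeding the result
  through the forward analysis recovers J* exactly at zero noise.

* :func:`simulate_bilayer_trajectory` builds a bilayer-like bead system:
  two head-group planes at Lz/2 +/- leaflet_offset with Gaussian jitter, a
  hydrophobic core filled uniformly between them, solvent outside, and
  permeant beads performing Brownian walks with a prescribed diffusion
  coefficient (step variance 2*D*dt per axis), reflecting at the z faces
  and periodic in x, y. :func:`inject_pore_event` then moves chosen head
  beads to the midplane for a scheduled frame interval, emulating a
  transient pore with known open/close frames.

The permeants are free Brownian particles, not membrane-partitioned walkers:
the generators target estimator validation, not membrane physics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import InputError, ValidationError
from .franz import DEFAULT_SCHEDULE, CellConfig, ConcentrationSeries
from .trajectory import DEFAULT_SPECIES_TABLE, Trajectory

__all__ = [
    "FranzSimConfig",
    "BilayerSimConfig",
    "simulate_franz_series",
    "simulate_bilayer_trajectory",
    "inject_pore_event",
]


@dataclass(frozen=True)
class FranzSimConfig:
    """Ground truth for one simulated Franz-cell condition.

    ``true_flux`` J* in ug/cm^2/h; ``lag_time_h`` shifts the onset of the
    zero-order regime; ``noise_sd`` is the relative SD of multiplicative
    measurement noise on each concentration.
    """

    true_flux: float
    cell: CellConfig = field(default_factory=CellConfig)
    schedule_h: tuple[float, ...] = DEFAULT_SCHEDULE
    lag_time_h: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_flux < 0:
            raise ValidationError("true_flux must be >= 0")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        sched = np.asarray(self.schedule_h, dtype=float)
        if len(sched) == 0 or np.any(np.diff(sched) <= 0):
            raise ValidationError("schedule must be non-empty and strictly increasing")


def simulate_franz_series(cfg: FranzSimConfig) -> ConcentrationSeries:
    """Receptor concentrations consistent with a known zero-order flux.

    The true profile Q_n = max(0, J* (t_n - lag)) is inverted sequentially,

        C_n = (Q_n * A - sum_{i<n} C_i * V_i) / V_r,

    so that the forward cumulative-amount computation reproduces Q exactly,
    then each C_n is scaled by (1 + eps_n), eps_n ~ N(0, noise_sd). Noisy
    draws are floored at zero (a measured concentration cannot be negative).
    Deterministic for a fixed seed.
    """
    times = np.asarray(cfg.schedule_h, dtype=float)
    cell = cfg.cell
    q = np.maximum(0.0, cfg.true_flux * (times - cfg.lag_time_h))
    conc = np.empty_like(q)
    withdrawn = 0.0
    for n, qn in enumerate(q):
        cn = (qn * cell.diffusion_area_cm2 - withdrawn) / cell.receptor_volume_ml
        if cn < -1e-12:
            raise ValidationError(
                "flux/lag configuration implies a negative receptor concentration"
            )
        conc[n] = max(cn, 0.0)
        withdrawn += conc[n] * cell.sample_volume_ml
    if cfg.noise_sd > 0:
        rng = np.random.default_rng(cfg.seed)
        conc = conc * (1.0 + rng.normal(0.0, cfg.noise_sd, size=conc.shape))
        conc = np.maximum(conc, 0.0)
    return ConcentrationSeries(times, conc)


#: Default desk-scale bead roster; the hydrophobic core stands in for CER
#: tails, CHOL, and FFA tails collectively, with an FFA-tagged subpopulation.
DEFAULT_COUNTS: dict[str, int] = {
    "CER_HEAD": 64,
    "CER_TAIL": 128,
    "FFA": 32,
    "SOLVENT": 200,
    "FU": 20,
}

#: beads/nm^3 above which a configuration is rejected as unphysically dense.
_DENSITY_CAP = 100.0


@dataclass(frozen=True)
class BilayerSimConfig:
    """Geometry, roster, and dynamics of a synthetic bilayer trajectory.

    ``counts`` maps species tags to bead counts (any subset of the species
    table, e.g. a pure-permeant Brownian box). ``permeant_d_true`` maps
    permeant species to their true diffusion coefficient in nm^2/ns.
    ``pore_schedule`` lists (n_beads, start_frame, end_frame) pore events
    applied after generation (frames inclusive). ``composition`` is a
    descriptive tag for the lipid mixture the roster emulates.
    """

    box_nm: tuple[float, float, float] = (6.0, 6.0, 10.0)
    counts: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_COUNTS))
    leaflet_offset_nm: float = 2.0
    head_jitter_sd_nm: float = 0.1
    permeant_d_true: Mapping[str, float] = field(default_factory=lambda: {"FU": 0.01})
    n_frames: int = 3000
    frame_dt_ns: float = 0.1
    pore_schedule: tuple[tuple[int, int, int], ...] = ()
    composition: str = "CER:CHOL:FFA 2:2:1"
    seed: int = 0

    def __post_init__(self) -> None:
        if any(b <= 0 for b in self.box_nm):
            raise ValidationError("box lengths must be positive")
        if not self.counts or any(c <= 0 for c in self.counts.values()):
            raise ValidationError("species counts must be positive")
        if self.frame_dt_ns <= 0:
            raise ValidationError("frame_dt_ns must be > 0")
        if self.n_frames < 1:
            raise ValidationError("n_frames must be >= 1")
        if not 0 < self.leaflet_offset_nm < self.box_nm[2] / 2:
            raise ValidationError("leaflet_offset_nm must lie in (0, Lz/2)")
        if any(d < 0 for d in self.permeant_d_true.values()):
            raise ValidationError("diffusion coefficients must be >= 0")
        for n_beads, start, end in self.pore_schedule:
            if not (0 <= start <= end < self.n_frames):
                raise ValidationError("pore intervals must lie within [0, n_frames)")
            if n_beads < 1:
                raise ValidationError("pore n_beads must be >= 1")
        total = sum(self.counts.values())
        volume = self.box_nm[0] * self.box_nm[1] * self.box_nm[2]
        if total / volume > _DENSITY_CAP:
            raise ValidationError(
                f"bead density {total / volume:.1f}/nm^3 exceeds sanity cap"
            )


def _reflect(z: np.ndarray, lz: float) -> np.ndarray:
    """Fold unbounded coordinates into [0, Lz] by specular reflection."""
    period = 2.0 * lz
    z = np.mod(z, period)
    return lz - np.abs(z - lz)


def simulate_bilayer_trajectory(cfg: BilayerSimConfig) -> Trajectory:
    """Generate a bilayer-like trajectory with known structure and dynamics.

    Head beads sit on two leaflet planes at Lz/2 +/- leaflet_offset with
    independent per-frame Gaussian z-jitter; hydrophobic and FFA beads fill
    the core slab uniformly; solvent fills the region outside the core;
    permeant species follow Brownian walks with step variance 2*D*dt per
    axis, reflecting at z = 0 and z = Lz and periodic in x, y. Permeants
    start in the central half of the box so that short walks rarely meet the
    walls. Bit-reproducible for a fixed seed.
    """
    rng = np.random.default_rng(cfg.seed)
    lx, ly, lz = cfg.box_nm
    f = cfg.n_frames
    mid = lz / 2.0
    off = cfg.leaflet_offset_nm

    species_list: list[str] = []
    blocks: list[np.ndarray] = []  # each (f, n_i, 3)

    for tag in cfg.counts:
        if tag not in DEFAULT_SPECIES_TABLE:
            raise ValidationError(f"unknown species tag {tag!r}")

    for tag, n in cfg.counts.items():
        cls = DEFAULT_SPECIES_TABLE[tag]
        if cls == "permeant":
            continue  # generated after the structural beads
        xy = rng.uniform(0.0, [lx, ly], size=(n, 2))
        if cls == "hydrophilic":
            half = n // 2
            base_z = np.where(np.arange(n) < half, mid - off, mid + off)
            zjit = rng.normal(0.0, cfg.head_jitter_sd_nm, size=(f, n))
            z = base_z[None, :] + zjit
        elif cls == "hydrophobic":
            z0 = rng.uniform(mid - off, mid + off, size=n)
            z = np.broadcast_to(z0, (f, n)).copy()
        else:  # solvent: uniform outside the core slab
            u = rng.uniform(0.0, lz - 2 * off, size=n)
            z0 = np.where(u < mid - off, u, u + 2 * off)
            z = np.broadcast_to(z0, (f, n)).copy()
        block = np.empty((f, n, 3))
        block[:, :, 0] = xy[:, 0]
        block[:, :, 1] = xy[:, 1]
        block[:, :, 2] = z
        species_list += [tag] * n
        blocks.append(block)

    for tag, n in cfg.counts.items():
        if DEFAULT_SPECIES_TABLE[tag] != "permeant":
            continue
        d = float(cfg.permeant_d_true.get(tag, 0.0))
        sigma = np.sqrt(2.0 * d * cfg.frame_dt_ns)
        start = np.empty((n, 3))
        start[:, 0] = rng.uniform(0.0, lx, size=n)
        start[:, 1] = rng.uniform(0.0, ly, size=n)
        start[:, 2] = rng.uniform(lz / 4.0, 3.0 * lz / 4.0, size=n)
        steps = rng.normal(0.0, sigma, size=(f - 1, n, 3)) if f > 1 else np.empty((0, n, 3))
        walk = np.concatenate([start[None], start[None] + np.cumsum(steps, axis=0)])
        block = np.empty((f, n, 3))
        block[:, :, 0] = np.mod(walk[:, :, 0], lx)
        block[:, :, 1] = np.mod(walk[:, :, 1], ly)
        block[:, :, 2] = _reflect(walk[:, :, 2], lz)
        species_list += [tag] * n
        blocks.append(block)

    positions = np.concatenate(blocks, axis=1)
    traj = Trajectory(
        times_ns=np.arange(f) * cfg.frame_dt_ns,
        boxes_nm=np.tile(np.array([lx, ly, lz]), (f, 1)),
        positions_nm=positions,
        species=np.array(species_list, dtype=object),
        bead_ids=np.arange(len(species_list)),
    )
    for n_beads, start_frame, end_frame in cfg.pore_schedule:
        traj = inject_pore_event(traj, n_beads, start_frame, end_frame)
    return traj


def inject_pore_event(
    traj: Trajectory,
    n_beads: int,
    start_frame: int,
    end_frame: int,
    jitter_sd_nm: float = 0.05,
    seed: int = 0,
) -> Trajectory:
    """Move hydrophilic head beads to the midplane for a frame interval.

    The ``n_beads`` lowest-index head beads not already used by an
    overlapping injection are placed at z = Lz/2 (plus small Gaussian
    jitter) for every frame in [start_frame, end_frame] inclusive, and keep
    their original coordinates outside the interval. The chosen bead
    indices and frame range are appended to ``Trajectory.injections``.

    Raises :class:`ValidationError` if a previous injection already uses
    overlapping beads in an overlapping frame range, and
    :class:`InputError` when too few head beads are available.
    """
    if not 0 <= start_frame <= end_frame < traj.n_frames:
        raise InputError("frame range must satisfy 0 <= start <= end < n_frames")
    head_idx = [
        i
        for i in range(traj.n_beads)
        if traj.species_table.get(traj.species[i]) == "hydrophilic"
    ]
    # beads already committed to an injection overlapping this interval
    busy: set[int] = set()
    for rec in traj.injections:
        if rec["start_frame"] <= end_frame and start_frame <= rec["end_frame"]:
            busy |= set(rec["bead_indices"])
    available = [i for i in head_idx if i not in busy]
    if n_beads > len(head_idx):
        raise InputError(
            f"requested {n_beads} pore beads but only {len(head_idx)} head beads exist"
        )
    if n_beads > len(available):
        raise ValidationError(
            "overlapping pore injections would reuse the same head beads"
        )
    chosen = available[:n_beads]
    out = traj.copy()
    lz = out.boxes_nm[:, 2]
    rng = np.random.default_rng(seed + 7919 * start_frame)
    frames = np.arange(start_frame, end_frame + 1)
    jitter = rng.normal(0.0, jitter_sd_nm, size=(len(frames), n_beads))
    out.positions_nm[frames[:, None], np.array(chosen)[None, :], 2] = (
        lz[frames, None] / 2.0 + jitter
    )
    out.injections.append(
        {
            "bead_indices": list(map(int, chosen)),
            "start_frame": int(start_frame),
            "end_frame": int(end_frame),
        }
    )
    return out
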