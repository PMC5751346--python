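"""Coarse-grained bead trajectories: containers, I/O, selection, centering.

A trajectory is a time-ordered stack of frames sharing one bead roster.
Coordinates are in nm and times in ns (GRO native units); frames are indexed
from 0. Two on-disk dialects are supported:

* multi-frame GRO (concatenated frames, orthorhombic boxes, velocities
  ignored), read and written through :mod:`mdtraj`, with GRO
  residue/atom names mapped to species tags via a configurable table;
* ``frames_csv``, a plain-text dialect with header
  ``frame,time_ns,bead_id,species,x_nm,y_nm,z_nm`` and one
  ``#box,Lx,Ly,Lz`` line preceding each frame's rows — diffable and exact
  to 1e-6 nm, convenient for fixtures.

Species tags classify beads by role (hydrophilic lipid head groups,
hydrophobic tails/core, solvent, permeant drug or enhancer beads); the
classification drives default selections for the bilayer observables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np

from .errors import FormatError, InputError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "Bead",
    "Frame",
    "Trajectory",
    "BeadSelection",
    "DEFAULT_SPECIES_TABLE",
    "DEFAULT_GRO_NAMES",
    "read_trajectory",
    "write_trajectory",
    "select_beads",
    "unwrap_and_center",
]

#: species tag -> hydrophilicity class. Hydrophilic head groups form the
#: pore-relevant selection; hydrophobic beads define the bilayer core and the
#: default midplane reference.
DEFAULT_SPECIES_TABLE: dict[str, str] = {
    "CER_HEAD": "hydrophilic",
    "CER_TAIL": "hydrophobic",
    "CHOL": "hydrophobic",
    "FFA": "hydrophobic",
    "SOLVENT": "solvent",
    "FU": "permeant",
    "BO": "permeant",
    "MEN": "permeant",
}

#: species tag -> (GRO residue name, GRO atom name). GRO name fields are
#: limited to 5 characters, so compound tags are split across the two fields.
DEFAULT_GRO_NAMES: dict[str, tuple[str, str]] = {
    "CER_HEAD": ("CER", "HD"),
    "CER_TAIL": ("CER", "TL"),
    "CHOL": ("CHOL", "CHOL"),
    "FFA": ("FFA", "FFA"),
    "SOLVENT": ("W", "W"),
    "FU": ("FU", "FU"),
    "BO": ("BO", "BO"),
    "MEN": ("MEN", "MEN"),
}


@dataclass(frozen=True)
class Bead:
    """One bead of one frame: id, species tag, and (x, y, z) in nm."""

    bead_id: int
    species: str
    position: np.ndarray


@dataclass(frozen=True)
class Frame:
    """A single configuration: time (ns), box (Lx, Ly, Lz in nm), positions."""

    time_ns: float
    box_nm: np.ndarray
    positions_nm: np.ndarray  # (n_beads, 3)

    def beads(self, species: np.ndarray, bead_ids: np.ndarray) -> Iterator[Bead]:
        for i in range(len(self.positions_nm)):
            yield Bead(int(bead_ids[i]), str(species[i]), self.positions_nm[i])


@dataclass
class Trajectory:
    """Time-ordered frames over a constant bead roster.

    Attributes
    ----------
    times_ns : (F,) array
        Strictly increasing frame times.
    boxes_nm : (F, 3) array
        Orthorhombic box lengths per frame, all positive.
    positions_nm : (F, N, 3) array
        Bead coordinates; bead order is identical in every frame.
    species : (N,) array of str
        Species tag per bead.
    bead_ids : (N,) array of int
        Stable bead identifiers.
    species_table : dict
        Species tag -> hydrophilicity class.
    injections : list
        Record of synthetic pore injections applied to this trajectory
        (bead indices and frame ranges); empty for read-in data.
    """

    times_ns: np.ndarray
    boxes_nm: np.ndarray
    positions_nm: np.ndarray
    species: np.ndarray
    bead_ids: np.ndarray
    species_table: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_SPECIES_TABLE))
    injections: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.times_ns = np.asarray(self.times_ns, dtype=float)
        self.boxes_nm = np.asarray(self.boxes_nm, dtype=float)
        self.positions_nm = np.asarray(self.positions_nm, dtype=float)
        self.species = np.asarray(self.species, dtype=object)
        self.bead_ids = np.asarray(self.bead_ids, dtype=int)
        f, n = self.n_frames, self.n_beads
        if self.positions_nm.shape != (f, n, 3):
            raise InputError(
                f"positions shape {self.positions_nm.shape} != ({f}, {n}, 3)"
            )
        if self.boxes_nm.shape != (f, 3):
            raise InputError("boxes must be (n_frames, 3)")
        if f > 1 and np.any(np.diff(self.times_ns) <= 0):
            raise ValidationError("frame times must be strictly increasing")
        if np.any(self.boxes_nm <= 0):
            raise ValidationError("box lengths must be positive")
        if not np.all(np.isfinite(self.positions_nm)):
            raise ValidationError("positions must be finite")

    @property
    def n_frames(self) -> int:
        return len(self.times_ns)

    @property
    def n_beads(self) -> int:
        return len(self.species)

    def frame(self, i: int) -> Frame:
        return Frame(float(self.times_ns[i]), self.boxes_nm[i], self.positions_nm[i])

    def copy(self) -> "Trajectory":
        return Trajectory(
            self.times_ns.copy(),
            self.boxes_nm.copy(),
            self.positions_nm.copy(),
            self.species.copy(),
            self.bead_ids.copy(),
            dict(self.species_table),
            list(self.injections),
        )


@dataclass(frozen=True)
class BeadSelection:
    """A named subset of a trajectory's beads (indices into the roster)."""

    trajectory: Trajectory
    indices: np.ndarray
    label: str = ""

    @property
    def bead_ids(self) -> np.ndarray:
        return self.trajectory.bead_ids[self.indices]

    def __len__(self) -> int:
        return len(self.indices)


def select_beads(
    traj: Trajectory, species: str | Sequence[str], label: str | None = None
) -> BeadSelection:
    """All and only the beads whose species tag is in ``species``.

    Raises :class:`ValidationError` for a tag absent from the trajectory and
    :class:`ValidationError` for an empty result.
    """
    if isinstance(species, str):
        species = [species]
    wanted = set(species)
    present = set(traj.species.tolist())
    unknown = wanted - present
    if unknown:
        raise ValidationError(f"species not present in trajectory: {sorted(unknown)}")
    mask = np.isin(traj.species, sorted(wanted))
    idx = np.nonzero(mask)[0]
    if len(idx) == 0:
        raise ValidationError(f"empty selection for species {sorted(wanted)}")
    return BeadSelection(traj, idx, label or "+".join(sorted(wanted)))


def _default_midplane_species(traj: Trajectory) -> list[str]:
    tags = [
        t
        for t in sorted(set(traj.species.tolist()))
        if traj.species_table.get(t) == "hydrophobic"
    ]
    if not tags:
        raise ValidationError(
            "no hydrophobic species found; pass midplane_species explicitly"
        )
    return tags


def unwrap_and_center(
    traj: Trajectory,
    midplane_species: Sequence[str] | None = None,
    center: bool = True,
) -> Trajectory:
    """Unwrap z across periodic images and center the bilayer midplane.

    z displacements between consecutive frames are mapped to the minimum
    image (|dz| <= Lz/2), removing box-crossing jumps, and then each frame is
    translated in z so the mean z of the midplane reference beads (default:
    all hydrophobic-class species) sits at Lz/2. Inter-bead z differences
    within a frame are preserved exactly (pure per-frame translation).

    A per-frame displacement close to Lz/2 cannot be disambiguated from the
    opposite crossing and is logged as a warning.
    """
    if traj.n_frames < 1:
        raise InputError("empty trajectory")
    out = traj.copy()
    z = out.positions_nm[:, :, 2]
    lz = out.boxes_nm[:, 2]
    if traj.n_frames > 1:
        dz = np.diff(z, axis=0)
        dz -= lz[1:, None] * np.round(dz / lz[1:, None])
        if np.any(np.abs(dz) > 0.49 * lz[1:, None]):
            logger.warning(
                "per-frame z displacement near Lz/2: unwrapping may be ambiguous"
            )
        z[1:] = z[0] + np.cumsum(dz, axis=0)
    if center:
        tags = list(midplane_species) if midplane_species else _default_midplane_species(traj)
        sel = select_beads(out, tags)
        mid = z[:, sel.indices].mean(axis=1)
        z += (lz / 2.0 - mid)[:, None]
    return out


# ---------------------------------------------------------------------------
# frames_csv dialect

_CSV_HEADER = "frame,time_ns,bead_id,species,x_nm,y_nm,z_nm"


def _write_frames_csv(traj: Trajectory, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(_CSV_HEADER + "\n")
        for f in range(traj.n_frames):
            box = traj.boxes_nm[f]
            fh.write(f"#box,{box[0]:.6f},{box[1]:.6f},{box[2]:.6f}\n")
            t = traj.times_ns[f]
            for i in range(traj.n_beads):
                x, y, z = traj.positions_nm[f, i]
                fh.write(
                    f"{f},{t:.6f},{traj.bead_ids[i]},{traj.species[i]},"
                    f"{x:.6f},{y:.6f},{z:.6f}\n"
                )


def _read_frames_csv(path: Path, species_table: Mapping[str, str] | None) -> Trajectory:
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0].strip() != _CSV_HEADER:
        raise FormatError(f"{path}: missing frames_csv header {_CSV_HEADER!r}")
    boxes: list[list[float]] = []
    frames: list[dict] = []
    current_box: list[float] | None = None
    for lineno, line in enumerate(lines[1:], 2):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#box,"):
            parts = line.split(",")[1:]
            if len(parts) != 3:
                raise FormatError(f"{path}:{lineno}: malformed #box line")
            current_box = [float(p) for p in parts]
            continue
        if line.startswith("#"):
            continue
        parts = line.split(",")
        if len(parts) != 7:
            raise FormatError(f"{path}:{lineno}: expected 7 fields, got {len(parts)}")
        f = int(parts[0])
        if f == len(frames):
            if current_box is None:
                raise FormatError(f"{path}:{lineno}: frame {f} has no #box line")
            frames.append({"time": float(parts[1]), "ids": [], "species": [], "xyz": []})
            boxes.append(current_box)
        elif f != len(frames) - 1:
            raise FormatError(f"{path}:{lineno}: frame indices out of order")
        rec = frames[f]
        rec["ids"].append(int(parts[2]))
        rec["species"].append(parts[3])
        rec["xyz"].append([float(parts[4]), float(parts[5]), float(parts[6])])
    if not frames:
        raise FormatError(f"{path}: no frames")
    n = len(frames[0]["ids"])
    for f, rec in enumerate(frames):
        if len(rec["ids"]) != n:
            raise FormatError(
                f"{path}: frame {f} has {len(rec['ids'])} beads, frame 0 has {n}"
            )
        if rec["ids"] != frames[0]["ids"] or rec["species"] != frames[0]["species"]:
            raise FormatError(f"{path}: bead roster differs between frames 0 and {f}")
    return Trajectory(
        times_ns=np.array([rec["time"] for rec in frames]),
        boxes_nm=np.array(boxes),
        positions_nm=np.array([rec["xyz"] for rec in frames]),
        species=np.array(frames[0]["species"], dtype=object),
        bead_ids=np.array(frames[0]["ids"]),
        species_table=dict(species_table) if species_table else dict(DEFAULT_SPECIES_TABLE),
    )


# ---------------------------------------------------------------------------
# GRO dialect (via mdtraj)


def _write_gro(traj: Trajectory, path: Path, gro_names: Mapping[str, tuple[str, str]]) -> None:
    import mdtraj as md
    from mdtraj.core import element as md_element

    missing = sorted(set(traj.species.tolist()) - set(gro_names))
    if missing:
        raise ValidationError(f"no GRO residue/atom names declared for {missing}")
    top = md.Topology()
    chain = top.add_chain()
    for tag in traj.species:
        resname, atomname = gro_names[tag]
        res = top.add_residue(resname, chain)
        top.add_atom(atomname, md_element.virtual, res)
    f = traj.n_frames
    md.Trajectory(
        traj.positions_nm.astype(np.float32),
        top,
        time=traj.times_ns,
        unitcell_lengths=traj.boxes_nm.astype(np.float32),
        unitcell_angles=np.full((f, 3), 90.0, dtype=np.float32),
    ).save_gro(str(path))


def _read_gro(
    path: Path,
    species_map: Mapping[tuple[str, str], str] | None,
    species_table: Mapping[str, str] | None,
) -> Trajectory:
    import mdtraj as md

    try:
        t = md.load(str(path))
    except Exception as exc:  # mdtraj raises bare Exception subclasses on bad GRO
        raise FormatError(f"{path}: not a parseable GRO file ({exc})") from exc
    if t.unitcell_lengths is None:
        raise FormatError(f"{path}: GRO file lacks a box line")
    angles = t.unitcell_angles
    if angles is not None and not np.allclose(angles, 90.0):
        raise FormatError(f"{path}: only orthorhombic boxes are supported")
    if species_map is None:
        species_map = {v: k for k, v in DEFAULT_GRO_NAMES.items()}
    species = []
    for atom in t.topology.atoms:
        key = (atom.residue.name, atom.name)
        if key not in species_map:
            raise ValidationError(
                f"{path}: no species mapping for GRO names {key}; "
                "pass species_map to declare it"
            )
        species.append(species_map[key])
    times = np.asarray(t.time, dtype=float)
    if len(times) > 1 and np.any(np.diff(times) <= 0):
        # concatenated GRO files often carry no usable t=; fall back to index
        times = np.arange(t.n_frames, dtype=float)
    return Trajectory(
        times_ns=times,
        boxes_nm=np.asarray(t.unitcell_lengths, dtype=float),
        positions_nm=np.asarray(t.xyz, dtype=float),
        species=np.array(species, dtype=object),
        bead_ids=np.arange(t.n_atoms),
        species_table=dict(species_table) if species_table else dict(DEFAULT_SPECIES_TABLE),
    )


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in ("gro", "frames_csv"):
            raise InputError(f"unknown trajectory format {fmt!r}")
        return fmt
    suffix = path.suffix.lower()
    if suffix == ".gro":
        return "gro"
    if suffix == ".csv":
        return "frames_csv"
    raise InputError(f"cannot infer trajectory format from {path.name!r}; pass format=")


def read_trajectory(
    path: str | Path,
    format: str | None = None,
    species_map: Mapping[tuple[str, str], str] | None = None,
    species_table: Mapping[str, str] | None = None,
) -> Trajectory:
    """Read a trajectory from GRO or frames_csv.

    ``format`` is inferred from the extension (.gro / .csv) when omitted.
    For GRO, ``species_map`` maps (residue name, atom name) pairs to species
    tags; the default map inverts :data:`DEFAULT_GRO_NAMES`.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"trajectory file not found: {path}")
    fmt = _infer_format(path, format)
    if fmt == "gro":
        return _read_gro(path, species_map, species_table)
    return _read_frames_csv(path, species_table)


def write_trajectory(
    traj: Trajectory,
    path: str | Path,
    format: str | None = None,
    gro_names: Mapping[str, tuple[str, str]] | None = None,
) -> None:
    """Write a trajectory; round-trips through :func:`read_trajectory`.

    frames_csv is exact to 1e-6 nm; GRO to its native 1e-3 nm field width.
    """
    if traj.n_frames == 0:
        raise InputError("cannot write an empty trajectory")
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "gro":
        _write_gro(traj, path, gro_names or DEFAULT_GRO_NAMES)
    else:
        _write_frames_csv(traj, path)
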