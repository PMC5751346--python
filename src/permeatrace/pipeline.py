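"""End-to-end orchestration: run configured stages and emit report tables.

A run is described by a flat TOML file with one section per stage (franz,
density, diffusion, pores); :func:`run_pipeline` executes the requested
stages, writes one TSV per output table into the output directory, and
records a machine-readable manifest (parameters, seed, package version,
input file hashes) so a run can be reproduced exactly. Identical config and
seed give byte-identical outputs. A stage failure aborts the run with a
stage-labeled error and removes that run's partial outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import __version__
from .analysis import (
    density_profile,
    detect_pores,
    diffusion_coefficient,
    msd_z,
    pore_occupancy_series,
)
from .errors import InputError, PermeatraceError
from .franz import (
    FranzExperiment,
    format_summary_table,
    read_cell_config,
    read_concentration_csv,
    summarize_experiment,
)
from .trajectory import read_trajectory, select_beads, unwrap_and_center

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "StageError", "run_pipeline", "write_tsv"]

_FLOAT_FMT = "%.8g"


class StageError(PermeatraceError):
    """A pipeline stage failed; the message is prefixed with the stage name."""


@dataclass
class RunConfig:
    """Parsed pipeline configuration.

    ``stages`` maps stage name -> parameter dict, in execution order.
    Paths inside stage sections are resolved relative to the config file's
    directory (or the current directory when built programmatically).
    """

    stages: dict[str, dict[str, Any]]
    out_dir: Path
    seed: int = 0
    base_dir: Path = field(default_factory=Path.cwd)

    @classmethod
    def from_toml(cls, path: str | Path, out_dir: str | Path, seed: int | None = None) -> "RunConfig":
        path = Path(path)
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        cfg_seed = int(raw.pop("seed", 0))
        stages = {k: dict(v) for k, v in raw.items() if isinstance(v, Mapping)}
        unknown = set(stages) - {"franz", "density", "diffusion", "pores"}
        if unknown:
            raise InputError(f"unknown pipeline stage(s): {sorted(unknown)}")
        return cls(
            stages=stages,
            out_dir=Path(out_dir),
            seed=seed if seed is not None else cfg_seed,
            base_dir=path.parent,
        )


def write_tsv(df: pd.DataFrame, path: Path) -> None:
    """Write a TSV with a fixed float format (stable across runs)."""
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_centered_trajectory(params: Mapping[str, Any], base: Path):
    traj_path = base / str(params["trajectory"])
    traj = read_trajectory(traj_path)
    if params.get("center", True):
        traj = unwrap_and_center(traj, midplane_species=params.get("midplane_species"))
    return traj, traj_path


def _stage_franz(params: Mapping[str, Any], base: Path, out_dir: Path) -> tuple[list[Path], list[Path]]:
    cell = read_cell_config(base / str(params["cell_config"]))
    control = FranzExperiment(
        str(params.get("control_label", "control")),
        read_concentration_csv(base / str(params["control"])),
        cell,
    )
    treated = [
        FranzExperiment(label, read_concentration_csv(base / str(p)), cell)
        for label, p in dict(params.get("treated", {})).items()
    ]
    window = params.get("fit_window")
    summaries = summarize_experiment(
        control, treated, window=tuple(window) if window else None
    )
    out = out_dir / "franz_summary.tsv"
    write_tsv(format_summary_table(summaries), out)
    inputs = [base / str(params["cell_config"]), base / str(params["control"])]
    inputs += [base / str(p) for p in dict(params.get("treated", {})).values()]
    return [out], inputs


def _stage_density(params: Mapping[str, Any], base: Path, out_dir: Path) -> tuple[list[Path], list[Path]]:
    traj, traj_path = _load_centered_trajectory(params, base)
    species = params.get("species") or sorted(set(traj.species.tolist()))
    bin_width = float(params.get("bin_width_nm", 0.1))
    mode = str(params.get("mode", "number"))
    masses = params.get("masses")
    table: dict[str, np.ndarray] = {}
    edges = None
    for tag in species:
        prof = density_profile(
            traj, select_beads(traj, tag), bin_width_nm=bin_width, mode=mode, masses=masses
        )
        edges = prof.bin_edges_nm
        table[tag] = prof.values
    df = pd.DataFrame({"z_mid_nm": 0.5 * (edges[:-1] + edges[1:]), **table})
    out = out_dir / "density.tsv"
    write_tsv(df, out)
    return [out], [traj_path]


def _stage_diffusion(params: Mapping[str, Any], base: Path, out_dir: Path) -> tuple[list[Path], list[Path]]:
    traj_path = base / str(params["trajectory"])
    traj = read_trajectory(traj_path)
    if params.get("center", False):
        traj = unwrap_and_center(traj, midplane_species=params.get("midplane_species"))
    species = params.get("species", ["FU"])
    window = params.get("fit_window_ns")
    rows = []
    msd_cols: dict[str, np.ndarray] = {}
    lags = None
    for tag in species:
        series = msd_z(
            traj, select_beads(traj, tag), multiple_origins=bool(params.get("multiple_origins", False))
        )
        lags = series.lag_times_ns
        msd_cols[tag] = series.msd_nm2
        for convention in params.get("conventions", ["paper", "physical_1d"]):
            est = diffusion_coefficient(
                series, convention=convention, fit_window_ns=tuple(window) if window else None
            )
            rows.append(
                {
                    "species": tag,
                    "convention": convention,
                    "D_nm2_ns": est.d_nm2_ns,
                    "D_cm2_s": est.d_cm2_s,
                    "stderr_nm2_ns": est.stderr_nm2_ns,
                    "fit_start_ns": est.fit_window_ns[0],
                    "fit_stop_ns": est.fit_window_ns[1],
                }
            )
    msd_out = out_dir / "msd.tsv"
    write_tsv(pd.DataFrame({"lag_ns": lags, **msd_cols}), msd_out)
    d_out = out_dir / "diffusion.tsv"
    write_tsv(pd.DataFrame(rows), d_out)
    return [msd_out, d_out], [traj_path]


def _stage_pores(params: Mapping[str, Any], base: Path, out_dir: Path) -> tuple[list[Path], list[Path]]:
    traj, traj_path = _load_centered_trajectory(params, base)
    species = params.get("species", ["CER_HEAD"])
    occ = pore_occupancy_series(
        traj,
        select_beads(traj, species),
        slab_half_width_nm=float(params.get("slab_half_width_nm", 0.5)),
    )
    events = detect_pores(
        occ,
        min_count=int(params.get("min_count", 3)),
        min_persistence_frames=int(params.get("min_persistence_frames", 2)),
    )
    df = pd.DataFrame(
        {
            "open_ns": [e.open_ns for e in events],
            "close_ns": [e.close_ns for e in events],
            "duration_ns": [e.duration_ns for e in events],
            "max_occupancy": [e.max_occupancy for e in events],
            "open_at_end": [e.open_at_end for e in events],
        }
    )
    out = out_dir / "pores.tsv"
    write_tsv(df, out)
    return [out], [traj_path]


_STAGES = {
    "franz": _stage_franz,
    "density": _stage_density,
    "diffusion": _stage_diffusion,
    "pores": _stage_pores,
}


def run_pipeline(cfg: RunConfig) -> dict[str, Any]:
    """Execute the configured stages and write outputs plus a manifest.

    Returns the manifest dict. On any stage failure the outputs written so
    far in this run are removed and :class:`StageError` is raised.
    """
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    manifest: dict[str, Any] = {
        "package": "permeatrace",
        "version": __version__,
        "seed": cfg.seed,
        "stages": {},
    }
    try:
        for name, params in cfg.stages.items():
            t0 = time.perf_counter()
            try:
                outputs, inputs = _STAGES[name](params, cfg.base_dir, cfg.out_dir)
            except PermeatraceError as exc:
                raise StageError(f"stage {name!r}: {exc}") from exc
            written.extend(outputs)
            elapsed = time.perf_counter() - t0
            input_hashes = {str(p): _hash_file(Path(p)) for p in inputs}
            logger.info(
                "stage %s: inputs %s, %.2f s", name, list(input_hashes), elapsed
            )
            manifest["stages"][name] = {
                "parameters": _jsonable(params),
                "outputs": [p.name for p in outputs],
                "input_sha256": input_hashes,
            }
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise
    manifest_path = cfg.out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj
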