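"""Franz diffusion-cell permeation kinetics.

A Franz cell mounts a skin sample between a donor chamber holding the drug
formulation and a stirred receptor chamber that is sampled over time. At each
sampling time a fixed aliquot is withdrawn and replaced with blank medium, so
the raw receptor concentrations under-report the permeated mass and must be
corrected for the withdrawn drug. The cumulative amount permeated per unit
skin area up to sampling ``n`` is

    Q_n = (C_n * V_r + sum_{i=1..n-1} C_i * V_i) / A            [ug/cm^2]

where ``C_n`` is the receptor concentration at sampling ``n`` (ug/mL),
``V_r`` the receptor volume (mL), ``V_i`` the withdrawn sample volume at
draw ``i`` (mL), and ``A`` the diffusion area (cm^2).

Under zero-order (steady-state) permeation Q grows linearly in time,
``Q = J*t + B``; the slope ``J`` (ug/cm^2/h) is the flux. The permeability
coefficient is the donor-normalized flux ``K_p = J / C_0`` (cm/h, with
``C_0`` in ug/mL = ug/cm^3), and a penetration enhancer is scored by its
enhancement ratio ``ER = K_p(enhancer) / K_p(control)``; when both arms share
the donor concentration this reduces to the ratio of fluxes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateFitError, InputError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "CellConfig",
    "ConcentrationSeries",
    "PermeationProfile",
    "FluxFit",
    "PermeationSummary",
    "FranzExperiment",
    "cumulative_amount",
    "fit_flux",
    "permeability_coefficient",
    "enhancement_ratio",
    "summarize_experiment",
    "summaries_to_frame",
    "format_summary_table",
    "read_concentration_csv",
    "write_concentration_csv",
    "read_cell_config",
]

#: Standard sampling schedule (h) for a 24 h permeation assay.
DEFAULT_SCHEDULE = (2.0, 4.0, 6.0, 8.0, 10.0, 12.0, 24.0)


@dataclass(frozen=True)
class CellConfig:
    """Geometry and loading of one Franz diffusion cell.

    Parameters
    ----------
    receptor_volume_ml : float
        Receptor chamber volume V_r (mL). Must be positive.
    sample_volume_ml : float
        Volume V_i withdrawn (and replaced) at each sampling (mL).
        ``0 <= V_i <= V_r``.
    diffusion_area_cm2 : float
        Effective skin area for diffusion A (cm^2). Must be positive.
    donor_concentration_ug_ml : float
        Initial drug concentration C_0 in the donor chamber (ug/mL).
        A 0.2% w/v solution corresponds to 2000 ug/mL.
    """

    receptor_volume_ml: float = 15.0
    sample_volume_ml: float = 1.5
    diffusion_area_cm2: float = 1.23
    donor_concentration_ug_ml: float = 2000.0

    def __post_init__(self) -> None:
        if self.receptor_volume_ml <= 0:
            raise ValidationError("receptor_volume_ml must be > 0")
        if not 0 <= self.sample_volume_ml <= self.receptor_volume_ml:
            raise ValidationError(
                "sample_volume_ml must lie in [0, receptor_volume_ml]"
            )
        if self.diffusion_area_cm2 <= 0:
            raise ValidationError("diffusion_area_cm2 must be > 0")
        if self.donor_concentration_ug_ml <= 0:
            raise ValidationError("donor_concentration_ug_ml must be > 0")


@dataclass(frozen=True)
class ConcentrationSeries:
    """Receptor-chamber concentrations at successive sampling times.

    ``times_h`` must be strictly increasing; concentrations are in ug/mL and
    must be non-negative, one per sampling time.
    """

    times_h: np.ndarray
    concentrations_ug_ml: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times_h, dtype=float)
        conc = np.asarray(self.concentrations_ug_ml, dtype=float)
        object.__setattr__(self, "times_h", times)
        object.__setattr__(self, "concentrations_ug_ml", conc)
        if times.ndim != 1 or conc.ndim != 1:
            raise InputError("times and concentrations must be 1-D")
        if len(times) != len(conc):
            raise InputError(
                f"length mismatch: {len(times)} times vs {len(conc)} concentrations"
            )
        if len(times) == 0:
            raise InputError("empty concentration series")
        if np.any(np.diff(times) <= 0):
            raise ValidationError("sampling times must be strictly increasing")
        if np.any(conc < 0):
            raise ValidationError("concentrations must be non-negative")

    def __len__(self) -> int:
        return len(self.times_h)


@dataclass(frozen=True)
class PermeationProfile:
    """Cumulative permeated amount Q_n (ug/cm^2) at each sampling time (h)."""

    times_h: np.ndarray
    cumulative_ug_cm2: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "times_h", np.asarray(self.times_h, dtype=float))
        object.__setattr__(
            self, "cumulative_ug_cm2", np.asarray(self.cumulative_ug_cm2, dtype=float)
        )
        if len(self.times_h) != len(self.cumulative_ug_cm2):
            raise InputError("times and cumulative amounts must have equal length")


@dataclass(frozen=True)
class FluxFit:
    """Zero-order fit Q = J*t + B.

    ``flux`` is J in ug/cm^2/h, ``intercept`` is B in ug/cm^2, ``r_squared``
    the coefficient of determination, and ``fit_times_h`` the sampling times
    that entered the regression.
    """

    flux: float
    intercept: float
    r_squared: float
    fit_times_h: np.ndarray


@dataclass(frozen=True)
class FranzExperiment:
    """One labeled permeation condition: a cell and its receptor series."""

    label: str
    series: ConcentrationSeries
    cell: CellConfig


@dataclass(frozen=True)
class PermeationSummary:
    """Per-condition permeation parameters, one row of the report table."""

    condition: str
    profile: PermeationProfile
    flux_fit: FluxFit
    kp_cm_h: float
    er: float | None = None


def cumulative_amount(
    series: ConcentrationSeries,
    cell: CellConfig,
    sample_volumes_ml: Sequence[float] | None = None,
) -> PermeationProfile:
    """Sampling-corrected cumulative amount Q_n from receptor concentrations.

    Q_n = (C_n * V_r + sum_{i<n} C_i * V_i) / A. The correction term adds
    back the drug removed by earlier draws; the first sample carries no
    correction.

    Parameters
    ----------
    series : ConcentrationSeries
        Measured receptor concentrations.
    cell : CellConfig
        Cell geometry; ``sample_volume_ml`` is used for every draw unless
        ``sample_volumes_ml`` overrides it per draw.
    sample_volumes_ml : sequence of float, optional
        Per-draw withdrawn volumes, same length as the series.
    """
    conc = series.concentrations_ug_ml
    n = len(conc)
    if sample_volumes_ml is None:
        v_i = np.full(n, cell.sample_volume_ml)
    else:
        v_i = np.asarray(sample_volumes_ml, dtype=float)
        if v_i.shape != (n,):
            raise InputError("sample_volumes_ml must match the series length")
        if np.any(v_i < 0):
            raise ValidationError("sample volumes must be non-negative")
    # sum_{i<n} C_i * V_i, zero for the first sample
    withdrawn = np.concatenate([[0.0], np.cumsum(conc[:-1] * v_i[:-1])])
    q = (conc * cell.receptor_volume_ml + withdrawn) / cell.diffusion_area_cm2
    return PermeationProfile(series.times_h, q)


def fit_flux(
    profile: PermeationProfile,
    window: tuple[float, float] | None = None,
) -> FluxFit:
    """Ordinary least-squares fit of Q on t; the slope is the flux J.

    Parameters
    ----------
    profile : PermeationProfile
        Cumulative-amount profile.
    window : (t_min, t_max), optional
        Inclusive time range restricting the fit, e.g. to a steady-state
        region. Default: all points.
    """
    t = profile.times_h
    q = profile.cumulative_ug_cm2
    if window is not None:
        lo, hi = window
        mask = (t >= lo) & (t <= hi)
        t, q = t[mask], q[mask]
    if len(t) < 2:
        raise InputError("flux fit requires at least 2 points in the window")
    if np.ptp(t) == 0:
        raise DegenerateFitError("zero time variance in fit window")
    res = stats.linregress(t, q)
    if res.slope < 0:
        logger.warning("fitted flux is negative (%g ug/cm^2/h)", res.slope)
    # rvalue is nan for exactly constant q; r^2 = 0 slope is still exact there
    r2 = 0.0 if np.isnan(res.rvalue) else float(res.rvalue) ** 2
    return FluxFit(float(res.slope), float(res.intercept), r2, t.copy())


def permeability_coefficient(fit: FluxFit, cell: CellConfig) -> float:
    """Permeability coefficient K_p = J / C_0 in cm/h.

    C_0 in ug/mL equals ug/cm^3, so ug/cm^2/h divided by ug/cm^3 is cm/h.
    """
    if cell.donor_concentration_ug_ml <= 0:
        raise ValidationError("donor concentration must be > 0")
    return fit.flux / cell.donor_concentration_ug_ml


def enhancement_ratio(treated_kp: float, control_kp: float) -> float:
    """ER = K_p(treated) / K_p(control).

    When both arms share the donor concentration this equals the flux ratio
    J(treated)/J(control), so ER is independent of C_0.
    """
    if control_kp <= 0:
        raise ValidationError("control K_p must be > 0 to form an ER")
    return treated_kp / control_kp


def summarize_experiment(
    control: FranzExperiment,
    treated: Sequence[FranzExperiment] = (),
    window: tuple[float, float] | None = None,
) -> list[PermeationSummary]:
    """Permeation parameters for a control and any number of treated arms.

    Returns one :class:`PermeationSummary` per condition, control first with
    ER fixed at 1; treated ERs are relative to the control K_p.
    """

    def _one(exp: FranzExperiment) -> tuple[PermeationProfile, FluxFit, float]:
        profile = cumulative_amount(exp.series, exp.cell)
        fit = fit_flux(profile, window=window)
        return profile, fit, permeability_coefficient(fit, exp.cell)

    profile, fit, kp0 = _one(control)
    out = [PermeationSummary(control.label, profile, fit, kp0, er=1.0)]
    for exp in treated:
        profile, fit, kp = _one(exp)
        out.append(
            PermeationSummary(exp.label, profile, fit, kp, er=enhancement_ratio(kp, kp0))
        )
    return out


def summaries_to_frame(summaries: Sequence[PermeationSummary]) -> pd.DataFrame:
    """Full-precision summary table: condition, J, B, r2, Q_last, Kp, ER."""
    return pd.DataFrame(
        {
            "condition": [s.condition for s in summaries],
            "J_ug_cm2_h": [s.flux_fit.flux for s in summaries],
            "B_ug_cm2": [s.flux_fit.intercept for s in summaries],
            "r2": [s.flux_fit.r_squared for s in summaries],
            "Q_last_ug_cm2": [s.profile.cumulative_ug_cm2[-1] for s in summaries],
            "Kp_cm_h": [s.kp_cm_h for s in summaries],
            "ER": [s.er for s in summaries],
        }
    )


def format_summary_table(summaries: Sequence[PermeationSummary]) -> pd.DataFrame:
    """Report-style table with J, Q_last and ER rounded to 2 decimal places.

    Internal values keep full precision; only the presentation rounds. K_p is
    formatted in scientific notation because it is orders of magnitude below
    the 2-decimal scale of the other columns.
    """
    df = summaries_to_frame(summaries)
    out = pd.DataFrame({"condition": df["condition"]})
    for col in ("J_ug_cm2_h", "B_ug_cm2", "Q_last_ug_cm2", "ER"):
        # + 0.0 collapses the negative zero that rounding can produce
        out[col] = df[col].map(lambda v: f"{round(v, 2) + 0.0:.2f}")
    out["r2"] = df["r2"].map(lambda v: f"{v:.4f}")
    out["Kp_cm_h"] = df["Kp_cm_h"].map(lambda v: f"{v:.3e}")
    return out[["condition", "J_ug_cm2_h", "B_ug_cm2", "r2", "Q_last_ug_cm2", "Kp_cm_h", "ER"]]


# ---------------------------------------------------------------------------
# File interfaces

CSV_HEADER = ("time_h", "concentration_ug_per_ml")


def read_concentration_csv(path: str | Path) -> ConcentrationSeries:
    """Read a receptor series from CSV with header time_h,concentration_ug_per_ml."""
    df = pd.read_csv(path)
    missing = [c for c in CSV_HEADER if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing column(s) {missing}")
    return ConcentrationSeries(
        df["time_h"].to_numpy(float), df["concentration_ug_per_ml"].to_numpy(float)
    )


def write_concentration_csv(series: ConcentrationSeries, path: str | Path) -> None:
    pd.DataFrame(
        {"time_h": series.times_h, "concentration_ug_per_ml": series.concentrations_ug_ml}
    ).to_csv(path, index=False)


_CELL_KEYS = {
    "receptor_volume_ml": "receptor_volume_ml",
    "sample_volume_ml": "sample_volume_ml",
    "area_cm2": "diffusion_area_cm2",
    "donor_ug_per_ml": "donor_concentration_ug_ml",
}


def read_cell_config(path: str | Path) -> CellConfig:
    """Read cell geometry from a flat ``key = value`` file.

    Recognized keys: receptor_volume_ml, sample_volume_ml, area_cm2,
    donor_ug_per_ml. Lines starting with ``#`` and blank lines are ignored;
    omitted keys take the dataclass defaults.
    """
    kwargs: dict[str, float] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise InputError(f"{path}:{lineno}: expected 'key = value'")
        key, value = (part.strip() for part in line.split("=", 1))
        if key not in _CELL_KEYS:
            raise InputError(f"{path}:{lineno}: unknown key {key!r}")
        try:
            kwargs[_CELL_KEYS[key]] = float(value)
        except ValueError as exc:
            raise InputError(f"{path}:{lineno}: non-numeric value {value!r}") from exc
    return CellConfig(**kwargs)
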