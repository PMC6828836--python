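"""Gaussian-puff smoke-dispersion surrogate and hotspot processing.

The transport step of the original workflow (a Lagrangian trajectory model
driven by global reanalysis meteorology) is replaced here by a documented
Gaussian-puff surrogate: each hotspot releases a train of puffs over the
release duration; puffs advect with the daily wind, spread horizontally
with sigma = sqrt(2 K t), are vertically well mixed over the plume layer
(default 100 m AGL), and lose mass to first-order dry deposition and wet
scavenging, mass(t) = exp[-(v_d / H + Lambda) t].

Absolute emission units are arbitrary: the final field is calibrated
multiplicatively to the monitoring station's observed annual mean, which
makes the calibrated result invariant to the emission-rate choice.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

from .grid import ConcentrationField, Grid
from .synthetic import DEEP_CODES, SHALLOW_CODES, PeatMap

__all__ = [
    "DispersionParams",
    "filter_hotspots",
    "classify_peat",
    "classify_peat_table",
    "peat_class_from_code",
    "sample_hotspots",
    "mass_fraction_remaining",
    "puff_snapshot",
    "puff_field",
    "mean_plume_per_class",
    "hotspot_density",
    "scale_up",
    "calibrate",
]

logger = logging.getLogger(__name__)

PEAT_CLASSES = ("shallow", "deep")


@dataclass(frozen=True)
class DispersionParams:
    """Puff-model parameters.

    Release/averaging durations, the 100-m plume layer and the deposition
    rates follow the original transport-model configuration; horizontal
    diffusivity, initial puff size and the numerical step sizes are
    surrogate-specific choices.
    """

    release_duration_h: float = 24.0
    averaging_period_h: float = 24.0
    plume_layer_top_m: float = 100.0
    dry_deposition_velocity_ms: float = 0.001
    wet_scavenging_rate_s: float = 8.0e-5
    emission_rate: float = 1.0  # mass units / s, arbitrary before calibration
    horizontal_diffusivity_m2s: float = 3000.0
    sigma0_m: float = 500.0  # initial puff sigma (~1-km detection pixel)
    n_puffs: int = 24
    dt_sample_h: float = 1.0

    def __post_init__(self) -> None:
        if self.release_duration_h < 0 or self.averaging_period_h <= 0:
            raise ValueError("durations must be non-negative (averaging > 0)")
        if self.plume_layer_top_m <= 0:
            raise ValueError("plume_layer_top_m must be positive")
        if self.dry_deposition_velocity_ms < 0 or self.wet_scavenging_rate_s < 0:
            raise ValueError("deposition rates must be non-negative")
        if self.horizontal_diffusivity_m2s < 0 or self.sigma0_m <= 0:
            raise ValueError("diffusivity must be >= 0 and sigma0 > 0")
        if self.n_puffs <= 0 or self.dt_sample_h <= 0:
            raise ValueError("n_puffs and dt_sample_h must be positive")

    @property
    def total_loss_rate_s(self) -> float:
        """First-order loss coefficient v_d / H + Lambda (1/s)."""
        return (
            self.dry_deposition_velocity_ms / self.plume_layer_top_m
            + self.wet_scavenging_rate_s
        )


# --------------------------------------------------------------------------
# hotspot table processing


def filter_hotspots(records: pd.DataFrame, min_confidence: float = 80.0) -> pd.DataFrame:
    """Keep detections with confidence >= min_confidence (order preserved).

    The retention band is inclusive at the threshold: a confidence of
    exactly 80 denotes a high-likelihood real fire and is kept.
    """
    if "confidence" not in records.columns:
        raise KeyError("hotspot table has no 'confidence' column")
    return records[records["confidence"] >= min_confidence].copy()


def peat_class_from_code(depth_code: str | None) -> str | None:
    """Map depth codes to classes: D1/D2 -> shallow, D3/D4 -> deep."""
    if depth_code in SHALLOW_CODES:
        return "shallow"
    if depth_code in DEEP_CODES:
        return "deep"
    return None


def classify_peat(record, peat_map: PeatMap) -> str | None:
    """Peat class of one hotspot from its location on the peat map.

    Returns 'shallow', 'deep' or None (off-peat; excluded from the
    peat-fire analysis). Overlapping polygons at the point raise.
    """
    code = peat_map.classify_point(record["x_km"], record["y_km"])
    return peat_class_from_code(code)


def classify_peat_table(records: pd.DataFrame, peat_map: PeatMap) -> pd.DataFrame:
    """Add a peat_class column from the map; drop and count off-peat rows."""
    xy = records[["x_km", "y_km"]].to_numpy()
    codes = peat_map.classify_points(xy)
    out = records.copy()
    out["depth_code"] = codes
    out["peat_class"] = [peat_class_from_code(c) for c in codes]
    n_off = int(out["peat_class"].isna().sum())
    if n_off:
        logger.info("excluding %d off-peat hotspots", n_off)
    return out[out["peat_class"].notna()].copy()


def sample_hotspots(
    records: pd.DataFrame,
    n_per_class: int,
    year: int,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Uniform without-replacement sample of n hotspots per peat class in
    a year; if a class has fewer, all of it is taken with a warning."""
    if n_per_class <= 0:
        raise ValueError("n_per_class must be positive")
    rng = np.random.default_rng(seed)
    yr = records[pd.to_datetime(records["datetime"]).dt.year == year]
    parts = []
    for cls in PEAT_CLASSES:
        pool = yr[yr["peat_class"] == cls]
        if len(pool) < n_per_class:
            warnings.warn(
                f"year {year}: only {len(pool)} {cls} hotspots available "
                f"(requested {n_per_class}); using all",
                stacklevel=2,
            )
            parts.append(pool)
        else:
            idx = rng.choice(len(pool), size=n_per_class, replace=False)
            parts.append(pool.iloc[np.sort(idx)])
    return pd.concat(parts, ignore_index=True)


# --------------------------------------------------------------------------
# puff kernel


def mass_fraction_remaining(t_s: float, params: DispersionParams) -> float:
    """Fraction of released puff mass still airborne after t seconds."""
    return float(np.exp(-params.total_loss_rate_s * t_s))


def _puff_release_schedule(params: DispersionParams) -> tuple[np.ndarray, float]:
    """Release times (s, mid-interval) and mass per puff."""
    dur_s = params.release_duration_h * 3600.0
    t_rel = (np.arange(params.n_puffs) + 0.5) * dur_s / params.n_puffs
    mass = params.emission_rate * dur_s / params.n_puffs
    return t_rel, mass


def puff_snapshot(
    hotspot_xy: tuple[float, float],
    wind_uv: tuple[float, float],
    params: DispersionParams,
    grid: Grid,
    t_s: float,
    mixing_height_m: float = 1000.0,
) -> ConcentrationField:
    """Instantaneous concentration field t seconds after release begins.

    Each active puff contributes a 2-D Gaussian of total (decayed) mass
    spread uniformly over the plume layer depth; units are mass / m^3 in
    the emission units of ``params.emission_rate``.
    """
    if mixing_height_m <= 0:
        raise ValueError("mixing height must be positive")
    x0, y0 = hotspot_xy
    if not grid.contains(x0, y0):
        raise ValueError(f"hotspot ({x0}, {y0}) lies outside the grid")
    u, v = wind_uv
    t_rel, mass = _puff_release_schedule(params)
    ages = t_s - t_rel
    ages = ages[ages > 0]
    vals = np.zeros((grid.ny, grid.nx))
    xm = grid.x * 1000.0  # m
    ym = grid.y * 1000.0
    H = params.plume_layer_top_m
    lam = params.total_loss_rate_s
    K = params.horizontal_diffusivity_m2s
    for a in ages:
        cx = x0 * 1000.0 + u * a
        cy = y0 * 1000.0 + v * a
        sig2 = 2.0 * K * a + params.sigma0_m**2
        gx = np.exp(-((xm - cx) ** 2) / (2.0 * sig2))
        gy = np.exp(-((ym - cy) ** 2) / (2.0 * sig2))
        amp = mass * np.exp(-lam * a) / (2.0 * np.pi * sig2 * H)
        vals += amp * np.outer(gy, gx)
    return ConcentrationField(grid, vals, label=f"snapshot t={t_s:.0f}s")


def puff_field(
    hotspot_xy: tuple[float, float],
    wind_uv: tuple[float, float],
    params: DispersionParams,
    grid: Grid,
    mixing_height_m: float = 1000.0,
) -> ConcentrationField:
    """24-h (averaging-period) mean concentration field of one hotspot.

    The mean is taken over mid-interval snapshots every ``dt_sample_h``
    across the averaging period.
    """
    if mixing_height_m <= 0:
        raise ValueError("mixing height must be positive")
    n_steps = int(round(params.averaging_period_h / params.dt_sample_h))
    t_samples = (np.arange(n_steps) + 0.5) * params.dt_sample_h * 3600.0
    acc = np.zeros((grid.ny, grid.nx))
    for t in t_samples:
        acc += puff_snapshot(hotspot_xy, wind_uv, params, grid, t, mixing_height_m).values
    return ConcentrationField(grid, acc / n_steps, label="24h mean")


# --------------------------------------------------------------------------
# averaging, scale-up, calibration


def mean_plume_per_class(
    sampled: pd.DataFrame,
    met: pd.DataFrame,
    params: DispersionParams,
    plume_grid: Grid,
    recenter: bool = True,
    full_grid: Grid | None = None,
    classes: tuple[str, ...] = PEAT_CLASSES,
) -> dict[str, ConcentrationField]:
    """Cell-wise mean per-hotspot 24-h plume for each peat class.

    By default each hotspot's plume is computed in source-relative
    coordinates (the hotspot at the origin of ``plume_grid``) so the mean
    is a transferable "average plume of one peat-fire hotspot"; the
    alternative (recenter=False) averages in absolute coordinates on
    ``full_grid``.
    """
    met_by_date = met.set_index(pd.to_datetime(met["date"]).dt.normalize())
    out: dict[str, ConcentrationField] = {}
    for cls in classes:
        rows = sampled[sampled["peat_class"] == cls]
        if len(rows) == 0:
            raise ValueError(f"no sampled hotspots in class {cls!r}")
        grid = plume_grid if recenter else full_grid
        if grid is None:
            raise ValueError("full_grid is required when recenter=False")
        acc = np.zeros((grid.ny, grid.nx))
        for row in rows.itertuples():
            day = pd.Timestamp(row.datetime).normalize()
            try:
                m = met_by_date.loc[day]
            except KeyError:
                raise KeyError(f"no meteorology for {day.date()}") from None
            origin = (0.0, 0.0) if recenter else (row.x_km, row.y_km)
            f = puff_field(
                origin, (float(m["u_ms"]), float(m["v_ms"])), params, grid,
                mixing_height_m=float(m["mixing_height_m"]),
            )
            acc += f.values
        out[cls] = ConcentrationField(grid, acc / len(rows), label=f"mean plume ({cls})")
    return out


def hotspot_density(records: pd.DataFrame, grid: Grid) -> ConcentrationField:
    """Per-cell hotspot density (sums to 1; zeros if no records)."""
    xmin, ymin, xmax, ymax = grid.bounds
    h, _, _ = np.histogram2d(
        records["y_km"], records["x_km"],
        bins=(grid.ny, grid.nx), range=((ymin, ymax), (xmin, xmax)),
    )
    total = h.sum()
    if total > 0:
        h = h / total
    return ConcentrationField(grid, h, label="hotspot density")


def scale_up(
    mean_fields: dict[str, ConcentrationField],
    class_counts: dict[str, int],
    density_maps: dict[str, ConcentrationField],
) -> ConcentrationField:
    """Annual uncalibrated field: per class, the mean recentred plume is
    re-placed by convolution with the class hotspot density map and
    multiplied by the class hotspot count; classes are summed.

    Linear in the counts: doubling both counts doubles every cell.
    """
    ref_grid = next(iter(density_maps.values())).grid
    acc = np.zeros((ref_grid.ny, ref_grid.nx))
    for cls, count in class_counts.items():
        if count < 0:
            raise ValueError(f"negative hotspot count for class {cls!r}")
        if count == 0:
            continue
        plume = mean_fields[cls]
        dens = density_maps[cls]
        placed = fftconvolve(dens.values, plume.values, mode="same")
        # FFT ringing can leave tiny negatives around sharp density peaks
        np.clip(placed, 0.0, None, out=placed)
        acc += count * placed
    return ConcentrationField(ref_grid, acc, label="annual uncalibrated")


def calibrate(
    field: ConcentrationField,
    station_annual_mean: float,
    station_location: tuple[float, float],
) -> ConcentrationField:
    """Scale the whole field so the station cell matches the observed
    annual mean exactly (single multiplicative factor, one station)."""
    modeled = field.value_at(*station_location)
    if modeled <= 0:
        raise ValueError(
            "modeled concentration at the station cell is zero; calibration "
            "impossible — re-site the station or increase emissions"
        )
    k = station_annual_mean / modeled
    return field.scaled(k, label=f"{field.label} [calibrated]")
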