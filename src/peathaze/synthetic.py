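"""Synthetic scenario generator: hotspots, peat map, villages, met, station.

The real study inputs (MODIS active-fire detections, a 1:250,000 peat-depth
map, village administrative boundaries with census populations, GDAS
meteorology and one urban air-quality monitoring station) are not publicly
deposited, so this module generates inputs with the same statistical
structure on a simplified rectangular region in projected km coordinates.

Geometry is deliberately simple — rectangular peat-depth polygons and
square-ish tile villages that partition the region exactly — because the
exposure and health arithmetic downstream is invariant to polygon shape and
tiles make zonal statistics exactly checkable.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import box, mapping

from .grid import ConcentrationField, Grid

__all__ = [
    "WindRegime",
    "SyntheticScenario",
    "PeatMap",
    "ScenarioData",
    "generate_scenario",
    "generate_station_series",
    "write_scenario",
]

SHALLOW_CODES = ("D1", "D2")  # 50-200 cm peat
DEEP_CODES = ("D3", "D4")  # > 200 cm peat

#: extra sampling weight for dry-season months (Jul-Nov), when most thick
#: smoke occurs; 1.0 means uniform through the year
DRY_SEASON_MONTHS = (7, 8, 9, 10, 11)


@dataclass(frozen=True)
class WindRegime:
    """Daily-wind climatology: speeds m/s, directions are the compass
    bearing the wind blows *toward* (0 = north, 90 = east)."""

    mean_speed: float = 1.5
    mean_direction_deg: float = 315.0
    speed_sd: float = 0.6
    direction_sd_deg: float = 70.0
    mixing_height_m: float = 1000.0


@dataclass
class SyntheticScenario:
    """Configuration fully determining one synthetic study region.

    Defaults reproduce the study conditions: five fire years with the
    recorded per-year hotspot totals (deep exceeding shallow by 8% overall),
    ~1,569 villages and ~2.5 million people, and one monitoring station.
    """

    seed: int = 0
    years: tuple[int, ...] = (2011, 2012, 2013, 2014, 2015)
    #: year -> (deep count, shallow count); totals 3155/3604/1246/7454/21408
    hotspot_counts_per_year: dict[int, tuple[int, int]] = field(default_factory=lambda: {
        year: (round(total * 1.08 / 2.08), total - round(total * 1.08 / 2.08))
        for year, total in {
            2011: 3155, 2012: 3604, 2013: 1246, 2014: 7454, 2015: 21408,
        }.items()
    })
    region_extent: tuple[float, float] = (240.0, 160.0)  # km (width, height)
    n_villages: int = 1569
    total_population: int = 2_500_000
    station_location: tuple[float, float] = (100.0, 72.0)  # km
    wind_regime: WindRegime = field(default_factory=WindRegime)
    #: station-observed annual-mean PM2.5 per year (ug/m3); the 2015 analogue
    #: is 65, the five-year average ~38, matching the single urban station
    station_annual_means: dict[int, float] = field(default_factory=lambda: {
        2011: 30.0, 2012: 33.0, 2013: 18.0, 2014: 44.0, 2015: 65.0,
    })
    station_noise_sd: float = 5.0  # ug/m3 day-to-day observation noise
    dry_season_weight: float = 4.0
    #: fraction of hotspots drawn from tight clusters (ex-Mega-Rice analogue)
    #: versus diffuse over the whole peat belt; higher = more clustered
    cluster_fraction: float = 0.55
    cluster_sd_km: float = 14.0
    population_lognorm_sd: float = 1.2

    def __post_init__(self) -> None:
        problems = self.validate()
        if problems:
            raise ValueError("invalid scenario config: " + "; ".join(problems))

    def validate(self) -> list[str]:
        problems: list[str] = []
        w, h = self.region_extent
        if w <= 0 or h <= 0:
            problems.append("region_extent: both dimensions must be positive")
        if self.n_villages <= 0:
            problems.append("n_villages: must be positive")
        if self.total_population <= 0:
            problems.append("total_population: must be positive")
        for year, (deep, shallow) in self.hotspot_counts_per_year.items():
            if deep < 0 or shallow < 0:
                problems.append(f"hotspot_counts_per_year[{year}]: counts must be >= 0")
        for year in self.years:
            if year not in self.hotspot_counts_per_year:
                problems.append(f"hotspot_counts_per_year: missing year {year}")
        sx, sy = self.station_location
        if not (0 <= sx <= w and 0 <= sy <= h):
            problems.append("station_location: must lie inside the region")
        if self.wind_regime.mixing_height_m <= 0:
            problems.append("wind_regime.mixing_height_m: must be positive")
        return problems


@dataclass
class PeatMap:
    """Peat-depth polygons with Ritung-style depth codes D1-D4."""

    polygons: list[tuple[object, str]]  # (shapely geometry, depth code)

    def classify_point(self, x: float, y: float) -> str | None:
        """Depth code of the polygon containing the point, or None off-peat.

        Raises if the point lies in more than one polygon (ambiguous map).
        """
        from shapely.geometry import Point

        p = Point(x, y)
        hits = [code for geom, code in self.polygons if geom.covers(p)]
        if len(hits) > 1:
            raise ValueError(f"point ({x}, {y}) lies in {len(hits)} overlapping peat polygons")
        return hits[0] if hits else None

    def classify_points(self, xy: np.ndarray) -> np.ndarray:
        """Vectorised depth codes for an (n, 2) array; None where off-peat."""
        import shapely

        points = shapely.points(np.asarray(xy, dtype=float))
        codes = np.full(len(points), None, dtype=object)
        n_hits = np.zeros(len(points), dtype=int)
        for geom, code in self.polygons:
            hit = shapely.covers(geom, points)
            codes[hit] = code
            n_hits += hit
        if np.any(n_hits > 1):
            raise ValueError("peat polygons overlap at one or more query points")
        return codes

    def polygons_for_class(self, peat_class: str) -> list[tuple[object, str]]:
        codes = SHALLOW_CODES if peat_class == "shallow" else DEEP_CODES
        return [(g, c) for g, c in self.polygons if c in codes]

    def to_geojson(self, path: str | Path) -> None:
        features = [
            {
                "type": "Feature",
                "geometry": mapping(geom),
                "properties": {"depth_code": code},
            }
            for geom, code in self.polygons
        ]
        Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": features}))


@dataclass
class ScenarioData:
    """Everything a pipeline run needs, generated from one seed."""

    config: SyntheticScenario
    peat_map: PeatMap
    hotspots: pd.DataFrame  # id, x_km, y_km, datetime, confidence, depth_code
    villages: pd.DataFrame  # village_id, geometry, population, ...
    met: pd.DataFrame  # date, u_ms, v_ms, mixing_height_m
    station_series: pd.DataFrame  # date, pm25_ugm3


def _default_peat_map(extent: tuple[float, float]) -> PeatMap:
    """Four adjacent depth-code rectangles forming a southern peat belt."""
    w, h = extent
    y0, y1 = 0.05 * h, 0.45 * h
    edges = [0.05, 0.30, 0.50, 0.72, 0.95]
    codes = ["D1", "D2", "D3", "D4"]
    polys = [
        (box(edges[i] * w, y0, edges[i + 1] * w, y1), codes[i])
        for i in range(4)
    ]
    return PeatMap(polys)


def _cluster_centers(extent: tuple[float, float]) -> dict[str, np.ndarray]:
    """Fixed fire-cluster centres per peat class (inside the belt)."""
    w, h = extent
    return {
        "shallow": np.array([[0.17 * w, 0.25 * h], [0.40 * w, 0.18 * h]]),
        "deep": np.array([[0.58 * w, 0.30 * h], [0.80 * w, 0.22 * h]]),
    }


def _sample_points_in_class(
    rng: np.random.Generator,
    n: int,
    peat_map: PeatMap,
    peat_class: str,
    extent: tuple[float, float],
    cluster_fraction: float,
    cluster_sd_km: float,
) -> np.ndarray:
    """Rejection-sample n points inside the class's peat polygons from a
    cluster-mixture proposal (clusters + diffuse-over-belt background)."""
    import shapely

    polys = [g for g, _ in peat_map.polygons_for_class(peat_class)]
    if not polys:
        raise ValueError(f"peat map has no polygons for class {peat_class!r}")
    centers = _cluster_centers(extent)[peat_class]
    bounds = np.array([g.bounds for g in polys])  # (k, 4)
    out = np.empty((n, 2))
    filled = 0
    while filled < n:
        m = max(256, 2 * (n - filled))
        use_cluster = rng.random(m) < cluster_fraction
        # cluster component
        idx = rng.integers(0, len(centers), size=m)
        pts = centers[idx] + rng.normal(0.0, cluster_sd_km, size=(m, 2))
        # diffuse component: uniform over a random class polygon's bbox
        k = rng.integers(0, len(polys), size=m)
        bb = bounds[k]
        u = rng.random((m, 2))
        diffuse = np.column_stack([
            bb[:, 0] + u[:, 0] * (bb[:, 2] - bb[:, 0]),
            bb[:, 1] + u[:, 1] * (bb[:, 3] - bb[:, 1]),
        ])
        pts[~use_cluster] = diffuse[~use_cluster]
        points = shapely.points(pts)
        inside = np.zeros(m, dtype=bool)
        for g in polys:
            inside |= shapely.covers(g, points)
        accepted = pts[inside]
        take = min(n - filled, len(accepted))
        out[filled:filled + take] = accepted[:take]
        filled += take
    return out


def _sample_dates(
    rng: np.random.Generator, n: int, year: int, dry_season_weight: float
) -> pd.DatetimeIndex:
    days = pd.date_range(f"{year}-01-01", f"{year}-12-31", freq="D")
    w = np.where(np.isin(days.month, DRY_SEASON_MONTHS), dry_season_weight, 1.0)
    w = w / w.sum()
    chosen = rng.choice(len(days), size=n, p=w)
    hours = rng.integers(0, 24, size=n)
    return days[chosen] + pd.to_timedelta(hours, unit="h")


def _tile_villages(extent: tuple[float, float], n: int) -> list:
    """Partition the region into exactly n rectangular tiles (row strips)."""
    w, h = extent
    nrows = max(1, int(round(np.sqrt(n * h / w))))
    base, extra = divmod(n, nrows)
    tiles = []
    y = 0.0
    row_h = h / nrows
    for r in range(nrows):
        ncols = base + (1 if r < extra else 0)
        if ncols == 0:
            continue
        col_w = w / ncols
        for c in range(ncols):
            tiles.append(box(c * col_w, y, (c + 1) * col_w, y + row_h))
        y += row_h
    assert len(tiles) == n
    return tiles


def _allocate_population(
    rng: np.random.Generator, n: int, total: int, sigma: float
) -> np.ndarray:
    """Log-normal village sizes rescaled to the exact configured total.

    The heavy right tail mimics one dominant city; largest-remainder
    rounding keeps every village >= 1 and the sum exact.
    """
    raw = rng.lognormal(mean=0.0, sigma=sigma, size=n)
    target = raw / raw.sum() * (total - n)  # reserve 1 per village
    floors = np.floor(target).astype(int)
    remainder = total - n - floors.sum()
    order = np.argsort(target - floors)[::-1]
    floors[order[:remainder]] += 1
    return floors + 1


def _daily_met(
    rng: np.random.Generator, years: tuple[int, ...], regime: WindRegime
) -> pd.DataFrame:
    frames = []
    for year in years:
        days = pd.date_range(f"{year}-01-01", f"{year}-12-31", freq="D")
        speed = np.maximum(0.1, rng.normal(regime.mean_speed, regime.speed_sd, len(days)))
        bearing = rng.normal(regime.mean_direction_deg, regime.direction_sd_deg, len(days))
        theta = np.deg2rad(90.0 - bearing)  # compass -> math angle
        frames.append(pd.DataFrame({
            "date": days,
            "u_ms": speed * np.cos(theta),
            "v_ms": speed * np.sin(theta),
            "mixing_height_m": np.full(len(days), regime.mixing_height_m),
        }))
    return pd.concat(frames, ignore_index=True)


def _station_series(
    rng: np.random.Generator,
    years: tuple[int, ...],
    annual_means: dict[int, float],
    noise_sd: float,
    dry_season_weight: float,
) -> pd.DataFrame:
    """Daily station observations with dry-season elevation and noise,
    rescaled so each year's mean equals the configured annual mean."""
    frames = []
    for year in years:
        days = pd.date_range(f"{year}-01-01", f"{year}-12-31", freq="D")
        season = np.where(np.isin(days.month, DRY_SEASON_MONTHS), dry_season_weight, 1.0)
        target = annual_means[year]
        base = target * season / season.mean()
        vals = np.maximum(0.0, base + rng.normal(0.0, noise_sd, len(days)))
        vals *= target / vals.mean()
        frames.append(pd.DataFrame({"date": days, "pm25_ugm3": vals}))
    return pd.concat(frames, ignore_index=True)


def generate_scenario(config: SyntheticScenario) -> ScenarioData:
    """Generate the full synthetic study region from one seed.

    Deterministic: the same config (including seed) yields byte-identical
    tables. Hotspot confidences are uniform integers on 0-100, so both
    retained (>= 80) and discarded detections exist.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_hs, rng_pop, rng_met, rng_sta = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )

    peat_map = _default_peat_map(config.region_extent)

    # hotspots: exact per-class counts per year
    rows = []
    hid = 0
    for year in config.years:
        deep_n, shallow_n = config.hotspot_counts_per_year[year]
        for peat_class, n in (("deep", deep_n), ("shallow", shallow_n)):
            if n == 0:
                continue
            pts = _sample_points_in_class(
                rng_hs, n, peat_map, peat_class, config.region_extent,
                config.cluster_fraction, config.cluster_sd_km,
            )
            codes = peat_map.classify_points(pts)
            dates = _sample_dates(rng_hs, n, year, config.dry_season_weight)
            conf = rng_hs.integers(0, 101, size=n)
            for i in range(n):
                rows.append((hid + i, pts[i, 0], pts[i, 1], dates[i], int(conf[i]), codes[i]))
            hid += n
    hotspots = pd.DataFrame(
        rows, columns=["id", "x_km", "y_km", "datetime", "confidence", "depth_code"]
    )

    # villages: exact tiling, exact population total
    tiles = _tile_villages(config.region_extent, config.n_villages)
    pops = _allocate_population(
        rng_pop, config.n_villages, config.total_population, config.population_lognorm_sd
    )
    villages = pd.DataFrame({
        "village_id": [f"V{i:04d}" for i in range(config.n_villages)],
        "geometry": tiles,
        "population": pops,
    })

    met = _daily_met(rng_met, config.years, config.wind_regime)
    station = _station_series(
        rng_sta, config.years, config.station_annual_means,
        config.station_noise_sd, config.dry_season_weight,
    )
    return ScenarioData(config, peat_map, hotspots, villages, met, station)


def generate_station_series(
    true_field: ConcentrationField,
    station_location: tuple[float, float],
    noise_sd: float,
    n_days: int = 365,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Daily station observations: field value at the station cell plus
    independent Gaussian noise. With noise_sd=0 every value equals the
    field value exactly."""
    x, y = station_location
    truth = true_field.value_at(x, y)  # raises IndexError outside the grid
    rng = np.random.default_rng(rng)
    noise = rng.normal(0.0, noise_sd, n_days) if noise_sd > 0 else np.zeros(n_days)
    return pd.DataFrame({
        "day": np.arange(n_days),
        "pm25_ugm3": truth + noise,
    })


def write_scenario(data: ScenarioData, out_dir: str | Path) -> dict[str, Path]:
    """Write hotspot CSV, peat/village GeoJSON, met and station CSVs.

    The seed is recorded in a metadata JSON alongside the files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "hotspots": out / "hotspots.csv",
        "peat": out / "peat.geojson",
        "villages": out / "villages.geojson",
        "met": out / "met.csv",
        "station": out / "station.csv",
        "meta": out / "scenario_meta.json",
    }
    data.hotspots.to_csv(paths["hotspots"], index=False)
    data.peat_map.to_geojson(paths["peat"])
    features = [
        {
            "type": "Feature",
            "geometry": mapping(row.geometry),
            "properties": {"village_id": row.village_id, "population": int(row.population)},
        }
        for row in data.villages.itertuples()
    ]
    paths["villages"].write_text(json.dumps({"type": "FeatureCollection", "features": features}))
    data.met.to_csv(paths["met"], index=False)
    data.station_series.to_csv(paths["station"], index=False)
    paths["meta"].write_text(json.dumps({
        "seed": data.config.seed,
        "years": list(data.config.years),
        "n_villages": int(data.config.n_villages),
        "total_population": int(data.config.total_population),
    }))
    return paths
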