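"""GPS-derived mobility summaries.

From a day's event-driven GPS fixes we derive the mobility measures used to
discuss a mother's movement through her community:

* radius of movement (radius of gyration) — the RMS great-circle distance of
  the day's fixes from their spherical centroid, a dispersion measure of
  daily mobility;
* farthest distance from home — the maximum great-circle distance of any fix
  from the estimated home location;
* fraction of time outside the home — among 15-minute bins containing at
  least one fix, the share whose last fix lies beyond a home radius
  (default 100 m);
* heat-map grids — 2-D fix counts on a lat/lon grid (default cell 0.0005°,
  about 55 m), the data behind the counselor's daily movement map.

Home is estimated as the centroid of the modal night-window (00:00–06:00)
heat-map cell, falling back to the modal all-day cell when no night fixes
exist.  Distances use the haversine formula with a 6,371,000 m Earth radius.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date, time
from typing import Iterable, Sequence

import numpy as np

from .ebm_io import GpsFix
from .rhythm import bin_index

__all__ = [
    "EARTH_RADIUS_M",
    "DEFAULT_CELL_SIZE_DEG",
    "DEFAULT_HOME_RADIUS_M",
    "HomeEstimate",
    "HeatmapGrid",
    "MobilityFeatures",
    "haversine",
    "spherical_centroid",
    "estimate_home",
    "radius_of_movement",
    "farthest_distance_from_home",
    "fraction_time_outside_home",
    "build_heatmap",
    "mobility_features",
]

EARTH_RADIUS_M = 6_371_000.0
DEFAULT_CELL_SIZE_DEG = 0.0005  # ~55 m of latitude; resolves within-village movement
DEFAULT_HOME_RADIUS_M = 100.0
NIGHT_WINDOW = (time(0, 0), time(6, 0))


def haversine(lat1, lon1, lat2, lon2) -> float | np.ndarray:
    """Great-circle distance in meters; accepts scalars or arrays."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float)) for x in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    return float(d) if np.ndim(d) == 0 else d


def _latlon(fixes: Sequence[GpsFix]) -> tuple[np.ndarray, np.ndarray]:
    return (
        np.array([f.lat for f in fixes], dtype=float),
        np.array([f.lon for f in fixes], dtype=float),
    )


def spherical_centroid(lats: np.ndarray, lons: np.ndarray) -> tuple[float, float]:
    """Centroid of points on the unit sphere, returned as (lat, lon) degrees."""
    lat_r, lon_r = np.radians(lats), np.radians(lons)
    x = np.mean(np.cos(lat_r) * np.cos(lon_r))
    y = np.mean(np.cos(lat_r) * np.sin(lon_r))
    z = np.mean(np.sin(lat_r))
    lon_c = math.atan2(y, x)
    lat_c = math.atan2(z, math.hypot(x, y))
    return math.degrees(lat_c), math.degrees(lon_c)


@dataclass(frozen=True)
class HomeEstimate:
    lat: float
    lon: float
    support: int  # fixes in the modal cell

    def __post_init__(self) -> None:
        if self.support < 1:
            raise ValueError("a home estimate needs at least one supporting fix")


@dataclass
class HeatmapGrid:
    """Fix counts on a lat/lon grid over the fixes' bounding box."""

    min_lat: float
    max_lat: float
    min_lon: float
    max_lon: float
    cell_size: float
    counts: np.ndarray  # shape (n_lat, n_lon), int

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_text(self) -> str:
        header = (
            f"# heatmap cell_size={self.cell_size} "
            f"lat=[{self.min_lat},{self.max_lat}] lon=[{self.min_lon},{self.max_lon}]\n"
        )
        body = "\n".join(" ".join(str(int(v)) for v in row) for row in self.counts)
        return header + body + "\n"


@dataclass
class MobilityFeatures:
    """Per-day GPS summary."""

    date: date
    n_fixes: int
    radius_of_movement_m: float | None
    farthest_distance_from_home_m: float | None
    fraction_time_outside_home: float | None


def _cell_of(lat: float, lon: float, cell: float) -> tuple[int, int]:
    return (math.floor(lat / cell), math.floor(lon / cell))


def estimate_home(
    fixes: Sequence[GpsFix],
    *,
    cell_size: float = DEFAULT_CELL_SIZE_DEG,
    night_window: tuple[time, time] = NIGHT_WINDOW,
) -> HomeEstimate | None:
    """Modal night-window grid cell, as the centroid of its member fixes.

    Falls back to the modal all-day cell when no night fixes exist; returns
    None when there are no fixes at all.
    """
    fixes = list(fixes)
    if not fixes:
        return None
    start, end = night_window
    night = [f for f in fixes if start <= f.timestamp.time() < end]
    pool = night if night else fixes
    cells: dict[tuple[int, int], list[GpsFix]] = {}
    for f in pool:
        cells.setdefault(_cell_of(f.lat, f.lon, cell_size), []).append(f)
    # deterministic tie-break: largest cell, then smallest cell index
    modal = max(cells.items(), key=lambda kv: (len(kv[1]), (-kv[0][0], -kv[0][1])))[1]
    lats, lons = _latlon(modal)
    return HomeEstimate(float(lats.mean()), float(lons.mean()), len(modal))


def radius_of_movement(fixes: Sequence[GpsFix]) -> float | None:
    """Radius of gyration: RMS haversine distance from the spherical centroid."""
    fixes = list(fixes)
    if not fixes:
        return None
    lats, lons = _latlon(fixes)
    lat_c, lon_c = spherical_centroid(lats, lons)
    d = haversine(lats, lons, lat_c, lon_c)
    return float(np.sqrt(np.mean(np.square(d))))


def farthest_distance_from_home(
    fixes: Sequence[GpsFix], home: HomeEstimate | None
) -> float | None:
    """Maximum haversine distance of any fix from home; None without home/fixes."""
    fixes = list(fixes)
    if home is None or not fixes:
        return None
    lats, lons = _latlon(fixes)
    return float(np.max(haversine(lats, lons, home.lat, home.lon)))


def fraction_time_outside_home(
    fixes: Sequence[GpsFix],
    home: HomeEstimate | None,
    *,
    radius_m: float = DEFAULT_HOME_RADIUS_M,
) -> float | None:
    """Share of observed 15-minute bins whose last fix is > radius_m from home.

    Bins with no fix carry no evidence and are excluded from the denominator;
    returns None when no bin is observed or home is unknown.
    """
    if home is None:
        return None
    last_in_bin: dict[int, GpsFix] = {}
    for f in sorted(fixes, key=lambda f: f.timestamp):
        last_in_bin[bin_index(f.timestamp)] = f
    if not last_in_bin:
        return None
    outside = sum(
        1
        for f in last_in_bin.values()
        if haversine(f.lat, f.lon, home.lat, home.lon) > radius_m
    )
    return outside / len(last_in_bin)


def build_heatmap(
    fixes: Sequence[GpsFix], cell_size: float = DEFAULT_CELL_SIZE_DEG
) -> HeatmapGrid:
    """Histogram the fixes onto a lat/lon grid covering their bounding box."""
    fixes = list(fixes)
    if not fixes:
        raise ValueError("cannot build a heat map from zero fixes")
    lats, lons = _latlon(fixes)
    min_lat, max_lat = float(lats.min()), float(lats.max())
    min_lon, max_lon = float(lons.min()), float(lons.max())
    n_lat = max(1, math.ceil((max_lat - min_lat) / cell_size))
    n_lon = max(1, math.ceil((max_lon - min_lon) / cell_size))
    lat_edges = min_lat + np.arange(n_lat + 1) * cell_size
    lon_edges = min_lon + np.arange(n_lon + 1) * cell_size
    counts, _, _ = np.histogram2d(lats, lons, bins=[lat_edges, lon_edges])
    return HeatmapGrid(
        min_lat, max_lat, min_lon, max_lon, cell_size, counts.astype(int)
    )


def mobility_features(
    day_fixes: Sequence[GpsFix],
    home: HomeEstimate | None,
    day: date,
    *,
    home_radius_m: float = DEFAULT_HOME_RADIUS_M,
) -> MobilityFeatures:
    """Bundle the per-day mobility metrics for one participant-day."""
    day_fixes = [f for f in day_fixes if f.timestamp.date() == day]
    return MobilityFeatures(
        date=day,
        n_fixes=len(day_fixes),
        radius_of_movement_m=radius_of_movement(day_fixes),
        farthest_distance_from_home_m=farthest_distance_from_home(day_fixes, home),
        fraction_time_outside_home=fraction_time_outside_home(
            day_fixes, home, radius_m=home_radius_m
        ),
    )
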