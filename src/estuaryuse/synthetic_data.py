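"""Synthetic tracks, tides, discharge, geometry and surveys.

Every downstream stage of the pipeline is exercisable on data from this
module, which emulates the statistical structure the analysis assumes:

* ~13 tagged whales, July–September, each with an estuarine-residency phase
  (mean-reverting movement around a centre in the outer estuary, displaced
  on/offshore with the tide) followed by a coastal-migration phase that
  begins on a configurable day of year in early August;
* Argos-style location classes with class-specific position error and a
  duty-cycled (Poisson) number of fixes per day, so missing whale-days occur;
* a daily river-discharge series whose 14 July–31 Aug mean is controllable
  per year, for wet/dry classification round trips;
* semidiurnal (M2) tides with fortnightly spring/neap modulation;
* repeated high-tide strip-transect surveys over a funnel-shaped estuary.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._geodesy import LocalProjection, destination_point, validate_lonlat

__all__ = [
    "SimConfig",
    "Shoreline",
    "DensitySurface",
    "PORT_NELSON",
    "simulate_track",
    "simulate_tracks",
    "simulate_discharge",
    "simulate_tides",
    "make_shoreline_fixture",
    "simulate_survey",
]

PORT_NELSON = (-92.5967, 57.0552)

#: Argos location classes from best to worst; Z carries no position estimate
#: quality and exists to exercise the quality filter.
ARGOS_CLASSES = ("3", "2", "1", "0", "A", "B")

_DEFAULT_CLASS_PROBS = {"3": 0.08, "2": 0.12, "1": 0.15, "0": 0.20, "A": 0.20, "B": 0.25}
#: 1-sigma isotropic position error per class, km. Classes 3/2/1 span the
#: 0.25–1.5 km "guaranteed" accuracy band; 0/A/B are nominal large values.
_DEFAULT_CLASS_ERR = {"3": 0.25, "2": 0.5, "1": 1.5, "0": 5.0, "A": 10.0, "B": 20.0}


@dataclass(frozen=True)
class Shoreline:
    """Shoreline polyline (WGS84 lon/lat vertices) with its river mouth."""

    vertices: tuple
    river_mouth: tuple

    def __post_init__(self):
        if len(self.vertices) < 1:
            raise ValueError("shoreline requires at least one vertex")
        for lon, lat in self.vertices:
            validate_lonlat(lon, lat)
        validate_lonlat(*self.river_mouth)

    def to_geojson(self) -> dict:
        return {
            "type": "FeatureCollection",
            "features": [
                {
                    "type": "Feature",
                    "properties": {"name": "shoreline"},
                    "geometry": {
                        "type": "LineString",
                        "coordinates": [list(v) for v in self.vertices],
                    },
                },
                {
                    "type": "Feature",
                    "properties": {"name": "river_mouth"},
                    "geometry": {
                        "type": "Point",
                        "coordinates": list(self.river_mouth),
                    },
                },
            ],
        }

    @classmethod
    def from_geojson(cls, obj: dict) -> "Shoreline":
        verts, mouth = None, None
        for feat in obj["features"]:
            geom = feat["geometry"]
            if geom["type"] == "LineString":
                verts = tuple(tuple(c) for c in geom["coordinates"])
            elif geom["type"] == "Point":
                mouth = tuple(geom["coordinates"])
        if verts is None or mouth is None:
            raise ValueError("GeoJSON must contain a LineString and a Point feature")
        return cls(vertices=verts, river_mouth=mouth)


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters for the track generator.

    Defaults emulate the deployment the analysis targets: 13 whales tracked
    July–September with a residency→migration switch on day of year 221
    (9 August in a non-leap year).
    """

    n_whales: int = 13
    start_date: str = "2003-07-10"
    #: the estuarine analysis season runs mid-July to early September
    end_date: str = "2003-09-09"
    switch_doy: int = 221
    #: residency centre ~50 km seaward (NE) of the river mouth
    residency_center: tuple = destination_point(*PORT_NELSON, 35.0, 50.0)
    residency_sd_km: float = 6.0
    #: correlation timescale of the mean-reverting residency walk, days
    residency_tau_days: float = 0.5
    #: cross-shore displacement per metre of tide height (negative = shoreward
    #: at high tide, i.e. greater estuary use on the flood)
    tide_coupling_km_per_m: float = -1.5
    tide_amplitude_m: float = 2.0
    migration_bearing_deg: float = 35.0
    migration_speed_km_day: float = 40.0
    fixes_per_day: float = 12.0
    argos_class_probs: dict = field(default_factory=lambda: dict(_DEFAULT_CLASS_PROBS))
    argos_error_sd_km: dict = field(default_factory=lambda: dict(_DEFAULT_CLASS_ERR))
    seed: int = 0

    def __post_init__(self):
        if self.residency_sd_km < 0 or self.migration_speed_km_day < 0:
            raise ValueError("residency_sd_km and migration_speed_km_day must be >= 0")
        total = sum(self.argos_class_probs.values())
        if not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-9):
            raise ValueError(f"argos_class_probs must sum to 1 (got {total})")
        if not 1 <= self.switch_doy <= 366:
            raise ValueError("switch_doy must be in 1..366")


def _tide_height(t_days: np.ndarray, amplitude_m: float, spring_neap_days: float = 14.765) -> np.ndarray:
    """Semidiurnal M2 tide (12.42 h period) with fortnightly modulation."""
    m2_period_days = 12.4206012 / 24.0
    envelope = 1.0 + 0.4 * np.cos(2.0 * np.pi * t_days / spring_neap_days)
    return amplitude_m * envelope * np.cos(2.0 * np.pi * t_days / m2_period_days)


def simulate_track(config: SimConfig, whale_index: int) -> pd.DataFrame:
    """Simulate one whale's Argos-style fix table.

    Movement runs in a local km plane centred on the residency centre.
    Before the switch day the true position follows a discrete-time
    mean-reverting (Ornstein–Uhlenbeck-like) walk whose stationary SD per
    axis is ``residency_sd_km``, plus a tide-coupled cross-shore offset.
    From the switch day onward the mean drifts along ``migration_bearing_deg``
    at ``migration_speed_km_day``. Argos noise is added per fix according to
    the sampled location class. Output is time-sorted with strictly
    increasing timestamps.
    """
    start = pd.Timestamp(config.start_date)
    end = pd.Timestamp(config.end_date)
    if not start < end:
        raise ValueError("start_date must precede end_date")
    if whale_index >= config.n_whales:
        raise ValueError("whale_index out of range")
    if config.fixes_per_day <= 0:
        raise ValueError("fixes_per_day must be positive")

    rng = np.random.default_rng([config.seed, 1, whale_index])
    proj = LocalProjection(*config.residency_center)
    n_days = (end - start).days

    # duty cycle: Poisson fixes per day, uniform times within the day
    times_days: list[float] = []
    for d in range(n_days):
        k = rng.poisson(config.fixes_per_day)
        if k > 0:
            times_days.extend(np.sort(d + rng.uniform(0.0, 1.0, size=k)))
    t = np.asarray(times_days)
    if t.size == 0:  # pathological duty cycle; keep the contract simple
        return _empty_track_frame()
    # enforce strictly increasing timestamps at 1 s resolution
    secs = np.round(t * 86400.0).astype(np.int64)
    secs = np.maximum.accumulate(secs + np.arange(secs.size) * 0)
    dup = np.r_[False, np.diff(secs) <= 0]
    while dup.any():
        secs[dup] = secs[dup] + 1
        dup = np.r_[False, np.diff(secs) <= 0]
    t = secs / 86400.0

    switch_t = (config.switch_doy - 1) - (start.dayofyear - 1)  # days from start
    dt = np.diff(t, prepend=t[0])

    # OU deviation with stationary per-axis SD = residency_sd_km
    a = np.exp(-dt / config.residency_tau_days)
    sd_step = config.residency_sd_km * np.sqrt(np.clip(1.0 - a**2, 0.0, None))
    eps = rng.standard_normal((t.size, 2))
    dev = np.empty((t.size, 2))
    prev = (
        rng.standard_normal(2) * config.residency_sd_km
        if config.residency_sd_km > 0
        else np.zeros(2)
    )
    # first entry uses the stationary draw directly
    dev[0] = prev
    for i in range(1, t.size):
        prev = a[i] * prev + sd_step[i] * eps[i]
        dev[i] = prev

    # mean path: residency centre, then linear drift after the switch
    brg = np.radians(config.migration_bearing_deg)
    u_mig = np.array([np.sin(brg), np.cos(brg)])  # x east, y north
    drift = np.clip(t - switch_t, 0.0, None)[:, None] * (
        config.migration_speed_km_day * u_mig
    )

    # tide-coupled cross-shore (offshore = migration bearing) displacement
    tide = _tide_height(t, config.tide_amplitude_m)
    tide_off = (config.tide_coupling_km_per_m * tide)[:, None] * u_mig

    pos = drift + dev + tide_off

    # Argos class and error
    classes = np.array(list(config.argos_class_probs.keys()))
    probs = np.array(list(config.argos_class_probs.values()))
    cls_idx = rng.choice(len(classes), size=t.size, p=probs)
    cls = classes[cls_idx]
    err_sd = np.array([config.argos_error_sd_km[c] for c in cls])
    pos = pos + rng.standard_normal((t.size, 2)) * err_sd[:, None]

    lon, lat = proj.inverse(pos[:, 0], pos[:, 1])
    timestamps = start + pd.to_timedelta(secs, unit="s")
    frame = pd.DataFrame(
        {
            "whale_id": f"SIM{whale_index:02d}",
            "timestamp": timestamps,
            "lon": np.atleast_1d(lon),
            "lat": np.atleast_1d(lat),
            "location_class": cls,
        }
    )
    return frame


def _empty_track_frame() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["whale_id", "timestamp", "lon", "lat", "location_class"]
    )


def simulate_tracks(config: SimConfig) -> pd.DataFrame:
    """All whales' tracks concatenated (one fix table)."""
    frames = [simulate_track(config, i) for i in range(config.n_whales)]
    frames = [f for f in frames if len(f)]
    if not frames:
        return _empty_track_frame()
    return pd.concat(frames, ignore_index=True)


def simulate_discharge(
    year_means: dict,
    noise_sd: float = 150.0,
    seed: int = 0,
    season_start: str = "06-15",
    season_end: str = "09-15",
) -> pd.DataFrame:
    """Daily discharge series (m³/s) per year with a controlled seasonal mean.

    For each year a smoothed noise series (AR-like, SD ``noise_sd``) is added
    to the requested mean and then recentred so that the 14 July–31 August
    window mean equals ``year_means[year]`` exactly. ``noise_sd=0`` yields a
    constant series. Columns: date, discharge_m3s.
    """
    if not year_means:
        raise ValueError("year_means must not be empty")
    if any(m <= 0 for m in year_means.values()):
        raise ValueError("all year means must be positive")
    rng = np.random.default_rng([seed, 2])
    frames = []
    for year in sorted(year_means):
        dates = pd.date_range(f"{year}-{season_start}", f"{year}-{season_end}", freq="D")
        n = len(dates)
        white = rng.standard_normal(n)
        noise = np.empty(n)
        noise[0] = white[0]
        rho = 0.8
        for i in range(1, n):  # smooth day-to-day variation
            noise[i] = rho * noise[i - 1] + math.sqrt(1 - rho**2) * white[i]
        noise *= noise_sd
        values = year_means[year] + noise
        window = (dates >= f"{year}-07-14") & (dates <= f"{year}-08-31")
        values = values - (values[window].mean() - year_means[year])
        values = np.clip(values, 1.0, None)
        frames.append(pd.DataFrame({"date": dates, "discharge_m3s": values}))
    return pd.concat(frames, ignore_index=True)


def simulate_tides(
    amplitude_m: float = 2.0,
    spring_neap_days: float = 14.765,
    seed: int = 0,
    start: str = "2003-07-01",
    n_days: int = 90,
    step_minutes: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Semidiurnal tide series with fortnightly modulation, plus flagged highs.

    Returns ``(series, highs)``: the series has columns timestamp/height_m;
    ``highs`` lists each local high tide with its height and a spring/neap
    flag assigned by splitting high-tide heights at their median. A small
    seeded noise term (2 cm) keeps peak heights non-degenerate.
    ``amplitude_m=0`` gives a flat series and no flagged highs.
    """
    if amplitude_m < 0:
        raise ValueError("amplitude_m must be >= 0")
    from scipy.signal import find_peaks

    rng = np.random.default_rng([seed, 3])
    times = pd.date_range(start, periods=int(n_days * 24 * 60 / step_minutes), freq=f"{step_minutes}min")
    t_days = (times - times[0]) / pd.Timedelta(days=1)
    h = _tide_height(np.asarray(t_days), amplitude_m, spring_neap_days)
    if amplitude_m > 0:
        h = h + 0.02 * rng.standard_normal(h.size)
    series = pd.DataFrame({"timestamp": times, "height_m": h})

    if amplitude_m == 0:
        highs = pd.DataFrame(columns=["timestamp", "height_m", "tide_type"])
        return series, highs
    # semidiurnal peaks are ~12.42 h apart; require 10 h separation
    min_sep = int(10 * 60 / step_minutes)
    idx, _ = find_peaks(h, distance=min_sep)
    heights = h[idx]
    cutoff = np.median(heights)
    highs = pd.DataFrame(
        {
            "timestamp": times[idx],
            "height_m": heights,
            "tide_type": np.where(heights > cutoff, "spring", "neap"),
        }
    )
    return series, highs


def make_shoreline_fixture(scale_km: float = 60.0, river_mouth=PORT_NELSON) -> Shoreline:
    """Funnel (V-shaped) estuary shoreline opening seaward from the river mouth.

    ``scale_km`` sets the offshore extent of the funnel along the estuary
    axis (default ≈60 km); the arms then run ≈75 km of coastline each side,
    mimicking the study estuary's proportions. The seaward axis is the
    default migration bearing (35° from north).
    """
    if scale_km <= 0:
        raise ValueError("scale_km must be positive")
    axis = 35.0
    half_angle = 37.0  # arm length = scale / cos(37°) ≈ 1.25 × scale
    arm_len = scale_km / math.cos(math.radians(half_angle))
    n_seg = 15
    left, right = [], []
    for i in range(1, n_seg + 1):
        d = arm_len * i / n_seg
        left.append(destination_point(*river_mouth, axis - half_angle, d))
        right.append(destination_point(*river_mouth, axis + half_angle, d))
    vertices = tuple(
        [tuple(map(float, v)) for v in reversed(left)]
        + [tuple(map(float, river_mouth))]
        + [tuple(map(float, v)) for v in right]
    )
    return Shoreline(vertices=vertices, river_mouth=tuple(river_mouth))


@dataclass(frozen=True)
class DensitySurface:
    """Gridded whale intensity (animals per km²) in local km coordinates.

    ``x_edges``/``y_edges`` are cell edges; ``intensity[i, j]`` is the
    Poisson intensity in cell (x bin i, y bin j). The projection ties the
    plane back to geographic coordinates.
    """

    x_edges: np.ndarray
    y_edges: np.ndarray
    intensity: np.ndarray
    projection: LocalProjection

    @classmethod
    def uniform(cls, density_per_km2, x_range, y_range, projection, cell_km=1.0):
        xe = np.arange(x_range[0], x_range[1] + cell_km / 2, cell_km)
        ye = np.arange(y_range[0], y_range[1] + cell_km / 2, cell_km)
        inten = np.full((len(xe) - 1, len(ye) - 1), float(density_per_km2))
        return cls(xe, ye, inten, projection)

    def sample_positions(self, rng: np.random.Generator) -> np.ndarray:
        """Draw whale positions (x, y km) from the inhomogeneous Poisson field."""
        dx = np.diff(self.x_edges)
        dy = np.diff(self.y_edges)
        area = np.outer(dx, dy)
        mean_counts = self.intensity * area
        total = float(mean_counts.sum())
        n = rng.poisson(total)
        if n == 0:
            return np.empty((0, 2))
        flat = (mean_counts / total).ravel()
        cells = rng.choice(flat.size, size=n, p=flat)
        ci, cj = np.unravel_index(cells, mean_counts.shape)
        x = self.x_edges[ci] + rng.uniform(0, 1, n) * dx[ci]
        y = self.y_edges[cj] + rng.uniform(0, 1, n) * dy[cj]
        return np.column_stack([x, y])


def simulate_survey(design, surface: DensitySurface, seed: int = 0) -> pd.DataFrame:
    """Simulate one strip-transect survey pass over a density surface.

    Whale positions are drawn from ``surface``; each whale is recorded at
    most once, in the 1-km (15-second) interval of the first transect whose
    strip contains it, on the left or right side of the track line. Returns
    records with columns transect, interval, side, count (only non-zero
    intervals are listed).

    A zero strip half-width produces all-zero counts with a warning.
    """
    import warnings

    rng = np.random.default_rng([seed, 4])
    if design.strip_halfwidth_km == 0:
        warnings.warn("strip half-width is zero: all counts will be zero")
    pos = surface.sample_positions(rng)
    proj = surface.projection

    records: dict[tuple, int] = {}
    assigned = np.zeros(len(pos), dtype=bool)
    for t_idx, (start, end) in enumerate(design.transects):
        sx, sy = proj.forward(*start)
        ex, ey = proj.forward(*end)
        seg = np.array([ex - sx, ey - sy], dtype=float)
        length = float(np.hypot(*seg))
        if length == 0:
            continue
        u = seg / length
        n_perp = np.array([-u[1], u[0]])  # left of travel direction
        rel = pos - np.array([float(sx), float(sy)])
        along = rel @ u
        cross = rel @ n_perp
        inside = (
            ~assigned
            & (along >= 0)
            & (along < length)
            & (np.abs(cross) <= design.strip_halfwidth_km)
            & (np.abs(cross) > 0)
        )
        for k in np.flatnonzero(inside):
            interval = int(along[k] // design.interval_length_km)
            side = "left" if cross[k] > 0 else "right"
            key = (t_idx, interval, side)
            records[key] = records.get(key, 0) + 1
            assigned[k] = True
    rows = [
        {"transect": t, "interval": i, "side": s, "count": c}
        for (t, i, s), c in sorted(records.items())
    ]
    return pd.DataFrame(rows, columns=["transect", "interval", "side", "count"])
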