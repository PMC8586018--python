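"""GPS fix ingest, filtering, and foraging-trip segmentation.

The preprocessing contract follows standard seabird-tracking practice:
fixes are subsampled to a 10-min interval, speed-filtered at 80 km/h,
segmented into trips (maximal runs of fixes > 200 m from the colony
centroid lasting >= 50 min), and trips with >= 50% of locations over land
are discarded.  The pipeline order is fixed; see :class:`TripParams`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely

from .geo import great_circle_km

log = logging.getLogger(__name__)

_CANONICAL_ORDER = ("subsample", "speed_filter", "segment", "land_filter")

_COLUMN_ALIASES = {
    "timestamp_iso8601_utc": "timestamp",
    "lon_wgs84": "lon",
    "lat_wgs84": "lat",
}


class FixParseError(ValueError):
    """A record in a fix table could not be parsed or is out of bounds."""


@dataclass(frozen=True)
class Colony:
    id: str
    lon: float
    lat: float
    size: int  # breeding pairs
    survey_year: int | None = None

    def __post_init__(self):
        if self.size <= 0:
            raise ValueError(f"colony {self.id}: size must be > 0")

    @property
    def centroid(self) -> tuple[float, float]:
        return (self.lon, self.lat)


@dataclass
class Trip:
    individual_id: str
    colony_id: str
    fixes: pd.DataFrame  # columns timestamp, lon, lat; time-ordered
    complete: bool
    trip_index: int
    land_fraction: float | None = None

    @property
    def trip_id(self) -> str:
        return f"{self.individual_id}_T{self.trip_index + 1:02d}"

    @property
    def start(self) -> pd.Timestamp:
        return self.fixes["timestamp"].iloc[0]

    @property
    def end(self) -> pd.Timestamp:
        return self.fixes["timestamp"].iloc[-1]

    @property
    def duration_min(self) -> float:
        return (self.end - self.start).total_seconds() / 60.0

    def max_range_km(self, colony: Colony) -> float:
        pts = self.fixes[["lon", "lat"]].to_numpy()
        return float(
            np.max(great_circle_km(pts, np.asarray(colony.centroid, dtype=float)))
        )


@dataclass(frozen=True)
class TripParams:
    """Preprocessing thresholds; defaults are the study's standard values."""

    interval_min: float = 10.0
    tolerance_min: float = 1.0
    vmax_kmh: float = 80.0
    colony_radius_m: float = 200.0
    min_duration_min: float = 50.0
    land_threshold: float = 0.5
    pipeline_order: tuple[str, ...] = _CANONICAL_ORDER

    def __post_init__(self):
        if tuple(self.pipeline_order) != _CANONICAL_ORDER:
            raise ValueError(
                f"pipeline order is fixed to {_CANONICAL_ORDER}; "
                f"got {tuple(self.pipeline_order)}"
            )


def read_fixes(path) -> dict[str, pd.DataFrame]:
    """Read a delimited fix table and group it by individual.

    Output frames are time-sorted with duplicate timestamps collapsed to the
    first occurrence (warned).  Unparseable timestamps/coordinates and
    out-of-bounds coordinates raise :class:`FixParseError` naming the line.
    """
    raw = pd.read_csv(path, dtype=str)
    raw = raw.rename(columns=_COLUMN_ALIASES)
    required = {"individual_id", "timestamp", "lon", "lat"}
    missing = required - set(raw.columns)
    if missing:
        raise FixParseError(f"{path}: missing columns {sorted(missing)}")

    ts = pd.to_datetime(raw["timestamp"], utc=True, errors="coerce", format="ISO8601")
    lon = pd.to_numeric(raw["lon"], errors="coerce")
    lat = pd.to_numeric(raw["lat"], errors="coerce")
    bad = ts.isna() | lon.isna() | lat.isna()
    oob = (~bad) & ((lon < -180) | (lon > 180) | (lat < -90) | (lat > 90))
    problems = bad | oob
    if problems.any():
        line = int(np.flatnonzero(problems.to_numpy())[0]) + 2  # header is line 1
        reason = "unparseable record" if bad.any() else "coordinate out of bounds"
        raise FixParseError(f"{path}: {reason} at line {line}")

    df = raw[["individual_id"]].copy()
    if "colony_id" in raw.columns:
        df["colony_id"] = raw["colony_id"]
    df["timestamp"] = ts
    df["lon"] = lon.astype(float)
    df["lat"] = lat.astype(float)

    out: dict[str, pd.DataFrame] = {}
    for ind, grp in df.groupby("individual_id", sort=True):
        grp = grp.sort_values("timestamp", kind="stable")
        dup = grp["timestamp"].duplicated()
        if dup.any():
            log.warning(
                "%s: dropped %d duplicate timestamp(s) for %s",
                path,
                int(dup.sum()),
                ind,
            )
            grp = grp[~dup]
        out[ind] = grp.reset_index(drop=True)
    return out


def filter_speed(fixes: pd.DataFrame, vmax_kmh: float = 80.0) -> pd.DataFrame:
    """Iteratively drop the later fix of any consecutive pair implying
    speed > vmax, recomputing against the last retained fix."""
    if len(fixes) <= 1:
        return fixes.reset_index(drop=True)
    t = fixes["timestamp"].to_numpy()
    pts = fixes[["lon", "lat"]].to_numpy(dtype=float)
    keep = [0]
    for i in range(1, len(fixes)):
        j = keep[-1]
        dt_h = (t[i] - t[j]) / np.timedelta64(1, "h")
        if dt_h <= 0:
            continue
        if great_circle_km(pts[j], pts[i]) / dt_h <= vmax_kmh:
            keep.append(i)
    return fixes.iloc[keep].reset_index(drop=True)


def subsample_interval(
    fixes: pd.DataFrame, interval_min: float = 10.0, tolerance_min: float = 1.0
) -> pd.DataFrame:
    """Greedy subsampling to a target interval.

    Keeps the first fix, then repeatedly the fix closest to (last kept +
    interval) within +/- tolerance; where no fix falls in that window the
    next later fix is kept as-is (longer gaps are retained, shorter-gap
    runs are thinned).
    """
    n = len(fixes)
    if n <= 1:
        return fixes.reset_index(drop=True)
    t_min = (
        (fixes["timestamp"] - fixes["timestamp"].iloc[0]).dt.total_seconds() / 60.0
    ).to_numpy()
    keep = [0]
    i = 0
    while True:
        target = t_min[keep[-1]] + interval_min
        lo, hi = target - tolerance_min, target + tolerance_min
        j = int(np.searchsorted(t_min, lo, side="left"))
        if j >= n:
            break
        window = [k for k in range(j, n) if t_min[k] <= hi]
        if window:
            best = min(window, key=lambda k: (abs(t_min[k] - target), k))
        else:
            best = j  # first fix after the window: gap retained
        keep.append(best)
        i = best
    return fixes.iloc[keep].reset_index(drop=True)


def segment_trips(
    fixes: pd.DataFrame,
    colony: Colony,
    radius_m: float = 200.0,
    min_duration_min: float = 50.0,
) -> list[Trip]:
    """Maximal runs of consecutive fixes > ``radius_m`` from the colony
    centroid, kept when spanning at least ``min_duration_min`` first-to-last.

    A trip is complete iff an at-colony fix follows the run.
    """
    if len(fixes) == 0:
        return []
    pts = fixes[["lon", "lat"]].to_numpy(dtype=float)
    d_m = great_circle_km(pts, np.asarray(colony.centroid, dtype=float)) * 1000.0
    away = np.atleast_1d(d_m) > radius_m
    trips: list[Trip] = []
    idx = 0
    n = len(fixes)
    ti = 0
    while idx < n:
        if not away[idx]:
            idx += 1
            continue
        j = idx
        while j + 1 < n and away[j + 1]:
            j += 1
        run = fixes.iloc[idx : j + 1].reset_index(drop=True)
        duration = (
            run["timestamp"].iloc[-1] - run["timestamp"].iloc[0]
        ).total_seconds() / 60.0
        if duration >= min_duration_min:
            colony_id = (
                str(fixes["colony_id"].iloc[idx])
                if "colony_id" in fixes.columns
                else colony.id
            )
            trips.append(
                Trip(
                    individual_id=str(fixes["individual_id"].iloc[idx])
                    if "individual_id" in fixes.columns
                    else "",
                    colony_id=colony_id,
                    fixes=run,
                    complete=j + 1 < n,  # an at-colony fix follows
                    trip_index=ti,
                )
            )
            ti += 1
        idx = j + 1
    return trips


def land_fraction(trip: Trip, land: shapely.Polygon) -> float:
    """Fraction of the trip's fixes strictly inside the land polygon."""
    if land.is_empty or land.area == 0:
        raise ValueError("degenerate land polygon")
    pts = shapely.points(
        trip.fixes["lon"].to_numpy(), trip.fixes["lat"].to_numpy()
    )
    inside = shapely.contains(land, pts)
    return float(np.mean(inside))


def filter_overland(
    trips: list[Trip], land: shapely.Polygon, threshold: float = 0.5
) -> list[Trip]:
    """Drop trips whose land fraction is >= threshold; annotate the rest."""
    kept = []
    for tr in trips:
        frac = land_fraction(tr, land)
        tr.land_fraction = frac
        if frac < threshold:
            kept.append(tr)
    return kept


def sex_from_headbill(length_mm: float, cutoff_mm: float = 90.5) -> str:
    """Morphometric sexing on head-bill length: female <= cutoff < male."""
    if length_mm <= 0:
        raise ValueError("head-bill length must be positive")
    return "female" if length_mm <= cutoff_mm else "male"


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Mann–Whitney U (for the first sample) with a tie-corrected normal
    approximation and continuity correction; two-sided p.

    All values identical across both samples -> p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    from scipy.stats import rankdata

    ranks = rankdata(pooled)  # midranks
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    n = n1 + n2
    mu = n1 * n2 / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts)
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1))) if n > 1 else 0.0
    if var <= 0:
        return float(u1), 1.0
    from scipy.stats import norm

    z = (abs(u1 - mu) - 0.5) / np.sqrt(var)
    p = float(min(1.0, 2.0 * norm.sf(max(z, 0.0))))
    return float(u1), p


@dataclass
class PreprocessReport:
    """Record counts logged at every filtering stage."""

    counts: dict[str, int] = field(default_factory=dict)

    def note(self, stage: str, n: int) -> None:
        self.counts[stage] = n
        log.info("preprocess %s: %d records", stage, n)


def preprocess_individual(
    fixes: pd.DataFrame,
    colony: Colony,
    land: shapely.Polygon | None,
    params: TripParams = TripParams(),
    report: PreprocessReport | None = None,
) -> list[Trip]:
    """Run the fixed pipeline (subsample -> speed filter -> segment ->
    land filter) for one individual's time-sorted fixes."""
    report = report if report is not None else PreprocessReport()
    report.note("input_fixes", len(fixes))
    out = subsample_interval(fixes, params.interval_min, params.tolerance_min)
    report.note("after_subsample", len(out))
    out = filter_speed(out, params.vmax_kmh)
    report.note("after_speed_filter", len(out))
    trips = segment_trips(out, colony, params.colony_radius_m, params.min_duration_min)
    report.note("trips_segmented", len(trips))
    if land is not None:
        trips = filter_overland(trips, land, params.land_threshold)
    report.note("trips_after_land_filter", len(trips))
    return trips
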