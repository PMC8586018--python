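"""Synthetic seascapes and central-place-forager GPS tracks with known truth.

The generator emulates a glacial-fjord tracking study: a handful of cliff
colonies, up to a few dozen tidewater glacier fronts within a 50-km study
radius, and breeding birds that alternate colony attendance with foraging
trips.  Each trip either targets a glacier front — chosen by a multinomial
logit whose log-odds decay with colony-to-front distance — or a pelagic
destination in open water.  Movement is deliberately simple: straight
commutes at constant ground speed, an Ornstein–Uhlenbeck (OU, optionally
OUF with correlated velocity) dwell around the destination, and isotropic
GPS noise, so that true trip boundaries, destinations and front-use
proportions are known exactly (the :class:`TruthRecord`).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geo import LocalProjection, great_circle_km

# Study centre: inner Kongsfjorden, Svalbard.
DEFAULT_CENTRE = (12.3, 78.95)


class PlacementError(RuntimeError):
    """Raised when colonies/fronts cannot be placed within the retry budget."""


@dataclass(frozen=True)
class SimConfig:
    """Configuration of the synthetic tracking study.

    Defaults mirror the emulated field study: 5 colonies, 25 fronts within a
    50-km radius, 10-min fixes, 1–10 trips per bird averaging ~4.3, and a
    front-choice logit slope of −0.22 per km of colony-to-front distance.
    """

    seed: int = 0
    n_colonies: int = 5
    n_fronts: int = 25
    study_radius_km: float = 50.0
    centre: tuple[float, float] = DEFAULT_CENTRE
    colony_positions: tuple[tuple[float, float], ...] | None = None
    colony_sizes: tuple[int, ...] | None = None
    front_polylines: tuple[tuple[tuple[float, float], ...], ...] | None = None
    land_polygon: tuple[tuple[float, float], ...] | None = None
    fix_interval: float = 10.0  # minutes
    trips_per_individual: tuple[int, int] = (1, 10)  # inclusive bounds, mean ~4.3
    individuals_per_colony: int = 8
    beta_distance: float = -0.22  # logit slope per km for front choice
    alpha: float = 0.0  # logit intercept (cancels in the softmax)
    p_pelagic: float = 0.3
    p_overland_trip: float = 0.0  # planted trips with a destination on land
    dwell_time: float = 90.0  # minutes at the chosen patch
    commute_speed_kmh: float = 40.0
    ou_sigma: float = 400.0  # dwell spatial SD (m)
    ou_tau_pos: float = 30.0  # position autocorrelation timescale (min)
    ou_tau_vel: float = 0.0  # velocity timescale (min); 0 -> plain OU dwell
    gps_noise_sd: float = 20.0  # m
    p_truncate: float = 0.1  # logger stops recording during the last trip
    fjord_front_fraction: float = 0.25  # share of fronts in the inner fjord
    fjord_radius_km: float = 15.0
    start_time: str = "2017-07-15T00:00:00Z"

    def __post_init__(self):
        if self.fix_interval <= 0:
            raise ValueError("fix_interval must be > 0")
        if not (0.0 <= self.p_pelagic <= 1.0):
            raise ValueError("p_pelagic must be in [0, 1]")
        if not (0.0 <= self.p_overland_trip <= 1.0):
            raise ValueError("p_overland_trip must be in [0, 1]")
        if self.ou_sigma <= 0:
            raise ValueError("ou_sigma must be > 0")
        lo, hi = self.trips_per_individual
        if lo < 1 or hi < lo:
            raise ValueError("trips_per_individual bounds must be positive and ordered")
        if self.ou_tau_pos <= 0:
            raise ValueError("ou_tau_pos must be > 0")
        if self.ou_tau_vel < 0:
            raise ValueError("ou_tau_vel must be >= 0")
        if self.n_colonies < 1:
            raise ValueError("need at least one colony")
        if self.n_fronts < 0:
            raise ValueError("n_fronts must be >= 0")
        if not (0.0 <= self.p_truncate <= 1.0):
            raise ValueError("p_truncate must be in [0, 1]")
        if not (0.0 <= self.fjord_front_fraction <= 1.0):
            raise ValueError("fjord_front_fraction must be in [0, 1]")


@dataclass
class Seascape:
    """Colonies, glacier-front polylines and a land ring, in lon/lat degrees."""

    centre: tuple[float, float]
    colony_ids: list[str]
    colony_positions: list[tuple[float, float]]
    colony_sizes: list[int]
    front_ids: list[str]
    front_polylines: list[list[tuple[float, float]]]
    land_polygon: list[tuple[float, float]]

    @property
    def projection(self) -> LocalProjection:
        return LocalProjection(*self.centre)

    def front_centroids(self) -> list[tuple[float, float]]:
        """Arc-length midpoint of each front polyline, in lon/lat."""
        proj = self.projection
        out = []
        for line in self.front_polylines:
            arr = np.asarray(line, dtype=float)
            x, y = proj.forward(arr[:, 0], arr[:, 1])
            seg = np.hypot(np.diff(x), np.diff(y))
            total = float(seg.sum())
            if total == 0.0:
                cx, cy = float(x[0]), float(y[0])
            else:
                target = total / 2.0
                cum = np.concatenate([[0.0], np.cumsum(seg)])
                i = int(np.searchsorted(cum, target, side="right")) - 1
                i = min(i, len(seg) - 1)
                f = (target - cum[i]) / seg[i] if seg[i] > 0 else 0.0
                cx = float(x[i] + f * (x[i + 1] - x[i]))
                cy = float(y[i] + f * (y[i + 1] - y[i]))
            lon, lat = proj.inverse(cx, cy)
            out.append((float(lon), float(lat)))
        return out

    def to_geojson(self) -> dict:
        feats = []
        for cid, pos, size in zip(
            self.colony_ids, self.colony_positions, self.colony_sizes
        ):
            feats.append(
                {
                    "type": "Feature",
                    "geometry": {"type": "Point", "coordinates": list(pos)},
                    "properties": {"kind": "colony", "id": cid, "size": int(size)},
                }
            )
        for fid, line in zip(self.front_ids, self.front_polylines):
            feats.append(
                {
                    "type": "Feature",
                    "geometry": {
                        "type": "LineString",
                        "coordinates": [list(p) for p in line],
                    },
                    "properties": {"kind": "front", "front_id": fid},
                }
            )
        ring = [list(p) for p in self.land_polygon]
        if ring and ring[0] != ring[-1]:
            ring.append(ring[0])
        feats.append(
            {
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [ring]},
                "properties": {"kind": "land"},
            }
        )
        return {
            "type": "FeatureCollection",
            "features": feats,
            "properties": {"centre": list(self.centre)},
        }

    def write_geojson(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_geojson(), fh, indent=1)

    @classmethod
    def from_geojson(cls, obj_or_path) -> "Seascape":
        if isinstance(obj_or_path, (str,)) or hasattr(obj_or_path, "__fspath__"):
            with open(obj_or_path) as fh:
                obj = json.load(fh)
        else:
            obj = obj_or_path
        colony_ids, colony_positions, colony_sizes = [], [], []
        front_ids, front_polylines = [], []
        land = []
        for feat in obj["features"]:
            kind = feat.get("properties", {}).get("kind")
            geom = feat["geometry"]
            if kind == "colony":
                colony_ids.append(feat["properties"]["id"])
                colony_positions.append(tuple(geom["coordinates"]))
                colony_sizes.append(int(feat["properties"].get("size", 1)))
            elif kind == "front":
                front_ids.append(feat["properties"]["front_id"])
                front_polylines.append([tuple(p) for p in geom["coordinates"]])
            elif kind == "land":
                land = [tuple(p) for p in geom["coordinates"][0]]
        centre = tuple(obj.get("properties", {}).get("centre", DEFAULT_CENTRE))
        return cls(
            centre=centre,
            colony_ids=colony_ids,
            colony_positions=colony_positions,
            colony_sizes=colony_sizes,
            front_ids=front_ids,
            front_polylines=front_polylines,
            land_polygon=land,
        )


@dataclass
class TruthRecord:
    """Ground truth of a simulated track set.

    ``trips`` holds one dict per true trip: individual, trip index, first/last
    off-colony fix time, destination kind (front/pelagic/overland), front id
    and the planar destination.  ``p_ik`` maps individual -> {front_id:
    proportion of front-directed trips}.
    """

    beta_distance: float
    trips: list[dict] = field(default_factory=list)
    p_ik: dict[str, dict[str, float]] = field(default_factory=dict)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, default=str)

    @classmethod
    def read(cls, path) -> "TruthRecord":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(**obj)


# ---------------------------------------------------------------------------
# Seascape generation


def _point_in_ring(x: float, y: float, ring: np.ndarray) -> bool:
    # even-odd rule; ring is (n, 2), closed or open
    inside = False
    n = len(ring)
    j = n - 1
    for i in range(n):
        xi, yi = ring[i]
        xj, yj = ring[j]
        if (yi > y) != (yj > y) and x < (xj - xi) * (y - yi) / (yj - yi) + xi:
            inside = not inside
        j = i
    return inside


def _default_land_ring_xy(radius_km: float) -> np.ndarray:
    # a coastal block occupying the eastern sector of the study disc
    r = radius_km * 1000.0
    return np.array(
        [
            (0.35 * r, -0.9 * r),
            (0.95 * r, -0.9 * r),
            (0.95 * r, 0.9 * r),
            (0.35 * r, 0.9 * r),
            (0.35 * r, -0.9 * r),
        ]
    )


def simulate_seascape(config: SimConfig) -> Seascape:
    """Lay out colonies, glacier fronts and a land ring.

    Colonies go in the inner half of the study disc, fronts anywhere within
    the study radius; both avoid the land block and keep minimum mutual
    separations.  Explicit ``colony_positions`` / ``front_polylines`` /
    ``land_polygon`` in the config override generation.
    """
    rng = np.random.default_rng(config.seed)
    proj = LocalProjection(*config.centre)
    r_m = config.study_radius_km * 1000.0

    if config.land_polygon is not None:
        ring_ll = np.asarray(config.land_polygon, dtype=float)
        lx, ly = proj.forward(ring_ll[:, 0], ring_ll[:, 1])
        land_xy = np.column_stack([lx, ly])
        land_ll = [tuple(p) for p in ring_ll]
    else:
        land_xy = _default_land_ring_xy(config.study_radius_km)
        lon, lat = proj.inverse(land_xy[:, 0], land_xy[:, 1])
        land_ll = [(float(a), float(b)) for a, b in zip(lon, lat)]

    def place(n, rmax, min_sep, avoid, avoid_sep, budget=2000):
        pts: list[tuple[float, float]] = []
        tries = 0
        while len(pts) < n:
            tries += 1
            if tries > budget:
                raise PlacementError(
                    f"could not place {n} points (min_sep={min_sep} m) "
                    f"within {budget} attempts"
                )
            ang = rng.uniform(0, 2 * np.pi)
            rad = rmax * np.sqrt(rng.uniform())
            x, y = rad * np.cos(ang), rad * np.sin(ang)
            if _point_in_ring(x, y, land_xy):
                continue
            if any(np.hypot(x - px, y - py) < min_sep for px, py in pts):
                continue
            if any(np.hypot(x - px, y - py) < avoid_sep for px, py in avoid):
                continue
            pts.append((x, y))
        return pts

    if config.colony_positions is not None:
        cx, cy = proj.forward(
            np.asarray(config.colony_positions)[:, 0],
            np.asarray(config.colony_positions)[:, 1],
        )
        colony_xy = list(zip(cx.tolist(), cy.tolist()))
        colony_ll = [tuple(map(float, p)) for p in config.colony_positions]
    else:
        colony_xy = place(config.n_colonies, 0.5 * r_m, 3000.0, [], 0.0)
        lon, lat = proj.inverse(
            np.array([p[0] for p in colony_xy]), np.array([p[1] for p in colony_xy])
        )
        colony_ll = [(float(a), float(b)) for a, b in zip(lon, lat)]
    colony_ids = [f"C{i+1:02d}" for i in range(len(colony_xy))]

    if config.colony_sizes is not None:
        sizes = [int(s) for s in config.colony_sizes]
    else:
        sizes = [int(round(10 ** rng.uniform(2.0, 3.6))) for _ in colony_xy]

    if config.front_polylines is not None:
        front_ll = [[tuple(map(float, p)) for p in line] for line in config.front_polylines]
    else:
        # glacier fronts cluster in the inner fjord where the colonies sit,
        # with the remainder spread across the wider study disc
        n_inner = int(round(config.fjord_front_fraction * config.n_fronts))
        inner = place(
            n_inner, config.fjord_radius_km * 1000.0, 2500.0, colony_xy, 2000.0
        )
        outer = place(
            config.n_fronts - n_inner, 0.95 * r_m, 2500.0, colony_xy + inner, 2000.0
        )
        centres = inner + outer
        front_ll = []
        for x, y in centres:
            theta = rng.uniform(0, 2 * np.pi)
            length = rng.uniform(1200.0, 2500.0)
            ux, uy = np.cos(theta), np.sin(theta)
            # 3-vertex, gently kinked front line
            mid_off = rng.normal(0.0, 120.0)
            verts_xy = np.array(
                [
                    (x - ux * length / 2, y - uy * length / 2),
                    (x - uy * mid_off, y + ux * mid_off),
                    (x + ux * length / 2, y + uy * length / 2),
                ]
            )
            lon, lat = proj.inverse(verts_xy[:, 0], verts_xy[:, 1])
            front_ll.append([(float(a), float(b)) for a, b in zip(lon, lat)])
    front_ids = [f"F{i+1:02d}" for i in range(len(front_ll))]

    return Seascape(
        centre=config.centre,
        colony_ids=colony_ids,
        colony_positions=colony_ll,
        colony_sizes=sizes,
        front_ids=front_ids,
        front_polylines=front_ll,
        land_polygon=land_ll,
    )


# ---------------------------------------------------------------------------
# Track generation


def _draw_trip_count(rng: np.random.Generator, bounds: tuple[int, int]) -> int:
    # 1 + Poisson(3.3) clipped into bounds: mean ~4.3 within the 1-10 range
    lo, hi = bounds
    return int(np.clip(1 + rng.poisson(3.3), lo, hi))


def _ou_dwell(rng, n, dt, tau_pos, tau_vel, sigma, centre):
    """Sample n dwell positions at spacing dt around ``centre`` (2-vector).

    Plain OU when tau_vel == 0; otherwise an OUF path via its 2-D
    (position, velocity) state-space representation.  Started at the patch
    centre with stationary velocity.
    """
    out = np.empty((n, 2))
    if tau_vel <= 0.0:
        rho = np.exp(-dt / tau_pos)
        innov_sd = sigma * np.sqrt(max(1.0 - rho * rho, 0.0))
        x = np.zeros(2)
        for i in range(n):
            x = rho * x + rng.normal(0.0, innov_sd, size=2)
            out[i] = x
        return out + centre
    l1, l2 = -1.0 / tau_pos, -1.0 / tau_vel
    if abs(l1 - l2) < 1e-8:
        l2 *= 1.0 + 1e-6
    A = np.array([[0.0, 1.0], [-(1.0 / (tau_pos * tau_vel)), l1 + l2]])
    I2 = np.eye(2)
    Phi = (np.exp(l1 * dt) * (A - l2 * I2) - np.exp(l2 * dt) * (A - l1 * I2)) / (
        l1 - l2
    )
    Pinf = np.diag([sigma**2, sigma**2 / (tau_pos * tau_vel)])
    Q = Pinf - Phi @ Pinf @ Phi.T
    Q = 0.5 * (Q + Q.T)
    w, V = np.linalg.eigh(Q)
    Qh = V @ np.diag(np.sqrt(np.clip(w, 0.0, None))) @ V.T
    state = np.zeros((2, 2))  # rows: (pos, vel), cols: x/y coordinate
    state[1] = rng.normal(0.0, sigma / np.sqrt(tau_pos * tau_vel), size=2)
    for i in range(n):
        state = Phi @ state + Qh @ rng.normal(size=(2, 2))
        out[i] = state[0]
    return out + centre


def simulate_tracks(
    config: SimConfig, seascape: Seascape
) -> tuple[pd.DataFrame, TruthRecord]:
    """Simulate GPS fixes for every individual and record the ground truth.

    Returns a fix table with columns ``individual_id, colony_id,
    timestamp_iso8601_utc (as pandas UTC Timestamp), lon_wgs84, lat_wgs84``
    and the matching :class:`TruthRecord`.
    """
    rng = np.random.default_rng(config.seed + 1_000_003)
    proj = seascape.projection
    dt = config.fix_interval
    t0 = pd.Timestamp(config.start_time)

    cxy = np.column_stack(
        proj.forward(
            np.asarray(seascape.colony_positions)[:, 0],
            np.asarray(seascape.colony_positions)[:, 1],
        )
    )
    fronts_ll = np.asarray(seascape.front_centroids(), dtype=float) if seascape.front_ids else np.empty((0, 2))
    if len(fronts_ll):
        fxy = np.column_stack(proj.forward(fronts_ll[:, 0], fronts_ll[:, 1]))
    else:
        fxy = np.empty((0, 2))
    land_xy = None
    if seascape.land_polygon:
        arr = np.asarray(seascape.land_polygon, dtype=float)
        lx, ly = proj.forward(arr[:, 0], arr[:, 1])
        land_xy = np.column_stack([lx, ly])

    # colony-to-front great-circle distances (km) drive the choice logit
    if len(fronts_ll):
        d_cf = np.array(
            [
                [great_circle_km(c, f) for f in fronts_ll]
                for c in seascape.colony_positions
            ]
        )
    else:
        d_cf = np.empty((len(cxy), 0))

    truth = TruthRecord(beta_distance=config.beta_distance)
    rows_id, rows_col, rows_t, rows_x, rows_y = [], [], [], [], []

    for ci, colony_id in enumerate(seascape.colony_ids):
        if d_cf.shape[1]:
            logits = config.alpha + config.beta_distance * d_cf[ci]
            logits = logits - logits.max()
            probs = np.exp(logits)
            probs /= probs.sum()
        else:
            probs = None
        for bi in range(config.individuals_per_colony):
            ind = f"{colony_id}_B{bi+1:02d}"
            n_trips = _draw_trip_count(rng, config.trips_per_individual)
            front_counts: dict[str, int] = {}
            # itinerary: list of (t_start_min, t_end_min, kind, payload)
            itinerary = []
            t_cursor = float(rng.integers(2, 7)) * dt  # initial colony stint
            itinerary.append((0.0, t_cursor, "colony", None))
            trip_meta = []
            for k in range(n_trips):
                u = rng.uniform()
                if config.p_overland_trip > 0 and rng.uniform() < config.p_overland_trip and land_xy is not None:
                    kind = "overland"
                    lc = land_xy.mean(axis=0)
                    dest = lc + rng.normal(0.0, 2000.0, size=2)
                    front_id = None
                elif probs is not None and u >= config.p_pelagic:
                    kind = "front"
                    fk = int(rng.choice(len(probs), p=probs))
                    dest = fxy[fk].copy()
                    front_id = seascape.front_ids[fk]
                    front_counts[front_id] = front_counts.get(front_id, 0) + 1
                else:
                    kind = "pelagic"
                    front_id = None
                    for _ in range(200):
                        ang = rng.uniform(0, 2 * np.pi)
                        dist = rng.uniform(5000.0, 35000.0)
                        dest = cxy[ci] + dist * np.array([np.cos(ang), np.sin(ang)])
                        if land_xy is None or not _point_in_ring(dest[0], dest[1], land_xy):
                            break
                d = float(np.hypot(*(dest - cxy[ci])))
                commute = max(d / (config.commute_speed_kmh * 1000.0 / 60.0), 1e-9)
                t_dep = t_cursor
                itinerary.append((t_dep, t_dep + commute, "out", dest))
                itinerary.append(
                    (t_dep + commute, t_dep + commute + config.dwell_time, "dwell", dest)
                )
                itinerary.append(
                    (
                        t_dep + commute + config.dwell_time,
                        t_dep + 2 * commute + config.dwell_time,
                        "back",
                        dest,
                    )
                )
                t_cursor = t_dep + 2 * commute + config.dwell_time
                trip_meta.append(
                    (kind, front_id, dest.copy(), t_dep + commute,
                     t_dep + commute + config.dwell_time)
                )
                stint = float(rng.integers(3, 9)) * dt
                itinerary.append((t_cursor, t_cursor + stint, "colony", None))
                t_cursor += stint
            # sample fixes on the regular grid
            n_fix = int(np.floor(t_cursor / dt)) + 1
            times = np.arange(n_fix) * dt
            pos = np.empty((n_fix, 2))
            seg_iter = iter(itinerary)
            seg = next(seg_iter)
            dwell_cache: dict[int, np.ndarray] = {}
            for i, t in enumerate(times):
                while t >= seg[1] and seg is not itinerary[-1]:
                    try:
                        seg = next(seg_iter)
                    except StopIteration:
                        break
                t_a, t_b, kind, payload = seg
                if kind == "colony" or payload is None:
                    pos[i] = cxy[ci]
                elif kind == "out":
                    f = (t - t_a) / (t_b - t_a)
                    pos[i] = cxy[ci] + np.clip(f, 0, 1) * (payload - cxy[ci])
                elif kind == "back":
                    f = (t - t_a) / (t_b - t_a)
                    pos[i] = payload + np.clip(f, 0, 1) * (cxy[ci] - payload)
                else:  # dwell: lazily sample the OU path for this segment
                    key = id(seg)
                    if key not in dwell_cache:
                        n_in = int(np.sum((times >= t_a) & (times < t_b)))
                        dwell_cache[key] = _ou_dwell(
                            rng,
                            n_in,
                            dt,
                            config.ou_tau_pos,
                            max(config.ou_tau_vel, 0.0),
                            config.ou_sigma,
                            payload,
                        )
                        dwell_cache[key + 1] = 0  # consumed counter
                    j = dwell_cache[key + 1]
                    pos[i] = dwell_cache[key][min(j, len(dwell_cache[key]) - 1)]
                    dwell_cache[key + 1] = j + 1
            noisy = pos + rng.normal(0.0, config.gps_noise_sd, size=pos.shape)
            # truth trip boundaries from noise-free positions
            away = np.hypot(pos[:, 0] - cxy[ci, 0], pos[:, 1] - cxy[ci, 1]) > 200.0
            # occasional logger failure mid-way through the last trip
            if config.p_truncate > 0 and rng.uniform() < config.p_truncate:
                runs_all = _runs(away)
                if runs_all:
                    a_last, b_last = runs_all[-1]
                    if b_last - a_last >= 3:
                        cut = int(rng.integers(a_last + 2, b_last)) + 1
                        pos, noisy, times = pos[:cut], noisy[:cut], times[:cut]
                        away = away[:cut]
                        n_fix = cut
            runs = _runs(away)
            for ti, (a, b) in enumerate(runs):
                kind, front_id, dest, dwell_a, dwell_b = trip_meta[
                    min(ti, len(trip_meta) - 1)
                ]
                truth.trips.append(
                    {
                        "individual_id": ind,
                        "trip_index": ti,
                        "t_start": str(t0 + pd.Timedelta(minutes=float(times[a]))),
                        "t_end": str(t0 + pd.Timedelta(minutes=float(times[b]))),
                        "t_dwell_start": str(t0 + pd.Timedelta(minutes=dwell_a)),
                        "t_dwell_end": str(t0 + pd.Timedelta(minutes=dwell_b)),
                        "kind": kind,
                        "front_id": front_id,
                        "dest_x": float(dest[0]),
                        "dest_y": float(dest[1]),
                        "complete": bool(b + 1 < n_fix),
                    }
                )
            total = sum(front_counts.values())
            truth.p_ik[ind] = (
                {k: v / total for k, v in sorted(front_counts.items())} if total else {}
            )
            lon, lat = proj.inverse(noisy[:, 0], noisy[:, 1])
            rows_id.extend([ind] * n_fix)
            rows_col.extend([colony_id] * n_fix)
            rows_t.extend(t0 + pd.to_timedelta(times, unit="m"))
            rows_x.extend(np.round(lon, 7))
            rows_y.extend(np.round(lat, 7))

    fixes = pd.DataFrame(
        {
            "individual_id": rows_id,
            "colony_id": rows_col,
            "timestamp": pd.DatetimeIndex(rows_t),
            "lon": rows_x,
            "lat": rows_y,
        }
    )
    return fixes, truth


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """(start, end) index pairs (inclusive) of True runs."""
    out = []
    in_run = False
    start = 0
    for i, m in enumerate(mask):
        if m and not in_run:
            in_run, start = True, i
        elif not m and in_run:
            out.append((start, i - 1))
            in_run = False
    if in_run:
        out.append((start, len(mask) - 1))
    return out


def write_fixes(fixes: pd.DataFrame, path) -> None:
    """Write the canonical delimited fix table (UTC ISO-8601 timestamps)."""
    out = pd.DataFrame(
        {
            "individual_id": fixes["individual_id"],
            "colony_id": fixes["colony_id"],
            "timestamp_iso8601_utc": fixes["timestamp"].dt.strftime(
                "%Y-%m-%dT%H:%M:%SZ"
            ),
            "lon_wgs84": fixes["lon"].map(lambda v: f"{v:.7f}"),
            "lat_wgs84": fixes["lat"].map(lambda v: f"{v:.7f}"),
        }
    )
    out.to_csv(path, index=False)
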