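"""Glacier-front use scoring and per-individual use profiles.

A front is "used" on a trip when at least two consecutive 10-min fixes fall
inside its 400-m buffer.  Trip-level binaries are summed per individual to
counts, converted to proportions p_ik, and compared across individuals with
the proportional-similarity overlap H = sum_k min(p_ik, p_jk); its
complement DH = 1 - H is the use-dissimilarity fed to the distance-matrix
regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely

from .geo import LocalProjection, great_circle_km
from .synthetic import Seascape
from .trajectory import Trip


@dataclass
class GlacierFront:
    id: str
    polyline_lonlat: list[tuple[float, float]]
    line_xy: shapely.LineString  # in the local projection
    buffer_xy: shapely.Polygon  # 400-m round-capped Euclidean buffer
    centroid_lonlat: tuple[float, float]  # arc-length midpoint of the line


def buffer_front(line_xy: shapely.LineString, radius_m: float = 400.0) -> shapely.Polygon:
    """Euclidean round-capped buffer of a front polyline (local projection)."""
    if len(line_xy.coords) < 2:
        raise ValueError("front polyline needs at least 2 vertices")
    return line_xy.buffer(radius_m, quad_segs=32)


def build_fronts(
    seascape: Seascape, radius_m: float = 400.0
) -> list[GlacierFront]:
    proj = seascape.projection
    centroids = seascape.front_centroids()
    fronts = []
    for fid, line, cen in zip(seascape.front_ids, seascape.front_polylines, centroids):
        arr = np.asarray(line, dtype=float)
        x, y = proj.forward(arr[:, 0], arr[:, 1])
        ls = shapely.LineString(np.column_stack([x, y]))
        fronts.append(
            GlacierFront(
                id=fid,
                polyline_lonlat=[tuple(p) for p in line],
                line_xy=ls,
                buffer_xy=buffer_front(ls, radius_m),
                centroid_lonlat=cen,
            )
        )
    return fronts


def trip_front_use(
    trip: Trip, fronts: list[GlacierFront], projection: LocalProjection
) -> np.ndarray:
    """Binary use vector: 1 iff >= 2 consecutive fixes lie in the buffer.

    Boundary points count as inside (closed containment).
    """
    x, y = projection.forward(
        trip.fixes["lon"].to_numpy(), trip.fixes["lat"].to_numpy()
    )
    pts = shapely.points(np.atleast_1d(x), np.atleast_1d(y))
    out = np.zeros(len(fronts), dtype=int)
    for k, fr in enumerate(fronts):
        inside = shapely.covers(fr.buffer_xy, pts)
        if np.any(inside[:-1] & inside[1:]):
            out[k] = 1
    return out


@dataclass
class FrontUseProfile:
    individual_id: str
    counts: dict[str, int] = field(default_factory=dict)  # front id -> trips used
    excluded: bool = True  # True when the bird used no front at all

    @property
    def proportions(self) -> dict[str, float]:
        total = sum(self.counts.values())
        if total == 0:
            return {}
        return {k: v / total for k, v in self.counts.items()}


def use_profile(
    individual_id: str,
    use_rows: np.ndarray,
    front_ids: list[str],
) -> FrontUseProfile:
    """Per-individual profile from a (trips x fronts) binary use array."""
    use_rows = np.atleast_2d(np.asarray(use_rows, dtype=int))
    counts = {
        fid: int(use_rows[:, k].sum())
        for k, fid in enumerate(front_ids)
        if use_rows[:, k].sum() > 0
    }
    return FrontUseProfile(
        individual_id=individual_id, counts=counts, excluded=not counts
    )


def bolnick_dissimilarity(pi: FrontUseProfile, pj: FrontUseProfile) -> float:
    """DH = 1 - sum_k min(p_ik, p_jk) over the union of fronts used."""
    for p in (pi, pj):
        if p.excluded:
            raise ValueError(
                f"individual {p.individual_id} used no front; excluded from DH"
            )
    a, b = pi.proportions, pj.proportions
    h = sum(min(a.get(k, 0.0), b.get(k, 0.0)) for k in set(a) | set(b))
    return float(np.clip(1.0 - h, 0.0, 1.0))


def dh_matrix(profiles: dict[str, FrontUseProfile]) -> tuple[list[str], np.ndarray]:
    """Pairwise DH among all non-excluded individuals (sorted ids)."""
    ids = sorted(i for i, p in profiles.items() if not p.excluded)
    n = len(ids)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = bolnick_dissimilarity(
                profiles[ids[i]], profiles[ids[j]]
            )
    return ids, m


def colony_front_distances(
    colony_positions: list[tuple[float, float]], fronts: list[GlacierFront]
) -> np.ndarray:
    """Great-circle km from each colony to each front-line centroid."""
    out = np.empty((len(colony_positions), len(fronts)))
    for i, c in enumerate(colony_positions):
        for k, fr in enumerate(fronts):
            out[i, k] = great_circle_km(c, fr.centroid_lonlat)
    return out


def front_use_table(
    trips: list[Trip],
    fronts: list[GlacierFront],
    projection: LocalProjection,
    colony_of_individual: dict[str, str],
    colony_front_km: np.ndarray,
    colony_index: dict[str, int],
) -> pd.DataFrame:
    """Tidy trip x front table: individual_id, trip_id, front_id, used,
    distance_km (colony-to-front centroid)."""
    rows = []
    for tr in trips:
        used = trip_front_use(tr, fronts, projection)
        ci = colony_index[colony_of_individual[tr.individual_id]]
        for k, fr in enumerate(fronts):
            rows.append(
                (
                    tr.individual_id,
                    tr.trip_id,
                    fr.id,
                    int(used[k]),
                    float(colony_front_km[ci, k]),
                )
            )
    return pd.DataFrame(
        rows, columns=["individual_id", "trip_id", "front_id", "used", "distance_km"]
    )
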