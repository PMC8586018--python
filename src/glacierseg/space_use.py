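"""Pairwise space-use overlap and colony-level utilization summaries.

All UDs live on one global 500-m lattice anchored at the projection origin,
so pairwise operations align cells by integer index — no interpolation.
The segregation index between two individuals is SI = 1 - BA, where BA is
the Bhattacharyya coefficient of their utilization distributions: 0 means
complete overlap, 1 full segregation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .movement import UD


def _union_frame(ud1: UD, ud2: UD) -> tuple[np.ndarray, np.ndarray]:
    """Paste two lattice-aligned UDs onto their common bounding grid."""
    if ud1.cell != ud2.cell:
        raise ValueError("UDs must share the lattice cell size")
    ix0 = min(ud1.ix0, ud2.ix0)
    iy0 = min(ud1.iy0, ud2.iy0)
    ix1 = max(ud1.ix0 + ud1.nx, ud2.ix0 + ud2.nx)
    iy1 = max(ud1.iy0 + ud1.ny, ud2.iy0 + ud2.ny)
    a = np.zeros((iy1 - iy0, ix1 - ix0))
    b = np.zeros_like(a)
    a[ud1.iy0 - iy0 : ud1.iy0 - iy0 + ud1.ny, ud1.ix0 - ix0 : ud1.ix0 - ix0 + ud1.nx] = ud1.masses
    b[ud2.iy0 - iy0 : ud2.iy0 - iy0 + ud2.ny, ud2.ix0 - ix0 : ud2.ix0 - ix0 + ud2.nx] = ud2.masses
    return a, b


def bhattacharyya(ud1: UD, ud2: UD) -> float:
    """BA = sum over cells of sqrt(p*q), in [0, 1] (raw, no debiasing)."""
    ud1.check_normalized()
    ud2.check_normalized()
    a, b = _union_frame(ud1, ud2)
    return float(np.clip(np.sqrt(a * b).sum(), 0.0, 1.0))


def segregation_index(ud1: UD, ud2: UD) -> float:
    return 1.0 - bhattacharyya(ud1, ud2)


@dataclass
class SegregationMatrix:
    ids: list[str]
    si: np.ndarray  # symmetric, zero diagonal, entries in [0, 1]
    colony: dict[str, str]  # individual -> colony label

    def labels(self) -> list[str]:
        return [self.colony[i] for i in self.ids]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.si, index=self.ids, columns=self.ids)

    def write(self, path) -> None:
        self.to_frame().to_csv(path)


def segregation_matrix(uds: dict[str, UD], colony_of: dict[str, str]) -> SegregationMatrix:
    """Pairwise SI = 1 - BA among all individuals (>= 2 required)."""
    ids = sorted(uds)
    if len(ids) < 2:
        raise ValueError("need at least 2 individuals")
    n = len(ids)
    si = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            v = segregation_index(uds[ids[i]], uds[ids[j]])
            si[i, j] = si[j, i] = v
    return SegregationMatrix(ids=ids, si=si, colony=dict(colony_of))


def isopleth(ud: UD, level: float) -> np.ndarray:
    """Boolean mask of the smallest cell set holding >= ``level`` of the mass.

    Cells enter in order of decreasing mass with a stable (deterministic)
    order among equal-mass cells, stopping as soon as the cumulative mass
    reaches the level.
    """
    if not (0.0 < level < 1.0):
        raise ValueError("level must be in (0, 1)")
    flat = ud.masses.ravel()
    order = np.argsort(-flat, kind="stable")
    cum = np.cumsum(flat[order])
    k = int(np.searchsorted(cum, level - 1e-12)) + 1
    k = min(k, len(flat))
    mask = np.zeros(flat.shape, dtype=bool)
    mask[order[:k]] = True
    return mask.reshape(ud.masses.shape)


def isopleth_area_km2(ud: UD, level: float) -> float:
    return float(isopleth(ud, level).sum()) * (ud.cell / 1000.0) ** 2


def colony_ud(uds: list[UD], weights=None) -> UD:
    """Trip-count-weighted mixture of member UDs, renormalized."""
    if not uds:
        raise ValueError("need at least one UD")
    if weights is None:
        weights = np.ones(len(uds))
    weights = np.asarray(weights, dtype=float)
    if weights.sum() <= 0:
        raise ValueError("total weight must be positive")
    cell = uds[0].cell
    ix0 = min(u.ix0 for u in uds)
    iy0 = min(u.iy0 for u in uds)
    ix1 = max(u.ix0 + u.nx for u in uds)
    iy1 = max(u.iy0 + u.ny for u in uds)
    acc = np.zeros((iy1 - iy0, ix1 - ix0))
    for u, w in zip(uds, weights):
        if u.cell != cell:
            raise ValueError("UDs must share the lattice cell size")
        acc[u.iy0 - iy0 : u.iy0 - iy0 + u.ny, u.ix0 - ix0 : u.ix0 - ix0 + u.nx] += (
            w * u.masses
        )
    acc /= acc.sum()
    return UD(ix0=ix0, iy0=iy0, masses=acc, cell=cell)


def _points_in_isopleth(ud: UD, mask: np.ndarray, xy: np.ndarray) -> np.ndarray:
    ix, iy = ud.cell_index_of(xy[:, 0], xy[:, 1])
    ok = (ix >= 0) & (ix < ud.nx) & (iy >= 0) & (iy < ud.ny)
    out = np.zeros(len(xy), dtype=bool)
    out[ok] = mask[iy[ok], ix[ok]]
    return out


@dataclass
class RepresentativenessResult:
    percent: float | None  # 100 * predicted(N) / asymptote, None if fit failed
    subset_sizes: np.ndarray
    mean_inclusion: np.ndarray
    fit_ok: bool


def representativeness(
    uds: dict[str, UD],
    fixes_xy: dict[str, np.ndarray],
    weights: dict[str, float] | None = None,
    n_boot: int = 50,
    level: float = 0.95,
    seed: int = 0,
) -> RepresentativenessResult:
    """Colony-level sample-size representativeness by bootstrap.

    For each subset size i = 1..N-1, ``n_boot`` random individual subsets
    are pooled into a colony UD; the inclusion rate is the fraction of the
    withheld individuals' fixes inside that UD's 95% isopleth.  A saturating
    Michaelis-Menten curve y = a*x/(b+x) is fitted to mean inclusion vs i
    and representativeness = 100 * y(N) / a.
    """
    ids = sorted(uds)
    N = len(ids)
    if N < 3:
        raise ValueError("need at least 3 individuals")
    rng = np.random.default_rng(seed)
    w = {i: (weights or {}).get(i, 1.0) for i in ids}
    sizes = np.arange(1, N)
    mean_inc = np.empty(len(sizes))
    for si, m in enumerate(sizes):
        vals = []
        for _ in range(n_boot):
            subset = list(rng.choice(ids, size=m, replace=False))
            rest = [i for i in ids if i not in subset]
            pooled = colony_ud([uds[i] for i in subset], [w[i] for i in subset])
            mask = isopleth(pooled, level)
            pts = np.vstack([fixes_xy[i] for i in rest])
            vals.append(float(np.mean(_points_in_isopleth(pooled, mask, pts))))
        mean_inc[si] = np.mean(vals)
    try:
        popt, _ = curve_fit(
            lambda x, a, b: a * x / (b + x),
            sizes.astype(float),
            mean_inc,
            p0=[max(mean_inc.max(), 0.5), 1.0],
            maxfev=10000,
        )
        a, b = popt
        pct = float(100.0 * (a * N / (b + N)) / a)
        return RepresentativenessResult(pct, sizes, mean_inc, True)
    except RuntimeError:
        return RepresentativenessResult(None, sizes, mean_inc, False)
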