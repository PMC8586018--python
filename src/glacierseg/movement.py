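"""Continuous-time position models and autocorrelation-aware kernel UDs.

Three stationary Gaussian position processes are fitted per individual to
its projected track (metres): IID (independent fixes), OU (position
autocorrelation, timescale tau_pos) and OUF (position + velocity
autocorrelation, tau_vel < tau_pos).  Likelihoods are exact and tolerant of
irregular gaps: the process is whitened by sequential conditioning (OU is
Markov in position; OUF is Markov in the position-velocity state, handled
by a Kalman recursion), and the mean and spatial variance are profiled out
analytically so only timescales are optimized numerically.

The utilization distribution is a Gaussian-reference kernel density on a
fixed 500-m lattice whose bandwidth uses the model's effective sample size
N_area (duration / tau_pos for autocorrelated models) in place of the
nominal number of fixes — wide bandwidths for strongly autocorrelated,
poorly-mixed tracks.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .geo import LocalProjection

NAREA_THRESHOLD = 4.5


class DegenerateTrackError(ValueError):
    """Track has (near-)zero spatial variance; no model is identifiable."""


class ModelFitError(RuntimeError):
    pass


class NAreaError(ValueError):
    """Effective sample size below the reliability threshold."""


@dataclass
class MovementModel:
    kind: str  # IID | OU | OUF
    mu: tuple[float, float]
    sigma2: float  # isotropic spatial variance (m^2)
    tau_pos: float | None  # minutes
    tau_vel: float | None  # minutes
    loglik: float
    n_params: int
    n_obs: int
    duration_min: float
    converged: bool = True
    message: str = ""

    @property
    def aicc(self) -> float:
        k, n = self.n_params, self.n_obs
        if n - k - 1 <= 0:
            return math.inf
        return -2.0 * self.loglik + 2 * k + 2 * k * (k + 1) / (n - k - 1)

    @property
    def n_area(self) -> float:
        return effective_sample_size(self, self.duration_min)


def to_local_xy(lon, lat, projection_centre) -> np.ndarray:
    """Project lon/lat degrees to local planar metres, shape (n, 2)."""
    proj = (
        projection_centre
        if isinstance(projection_centre, LocalProjection)
        else LocalProjection(*projection_centre)
    )
    x, y = proj.forward(np.asarray(lon, dtype=float), np.asarray(lat, dtype=float))
    return np.column_stack([np.atleast_1d(x), np.atleast_1d(y)])


# ---------------------------------------------------------------------------
# Whitening recursions: return innovations of (x, y, 1) and their variances
# under the unit-variance correlation structure of each process.


def _whiten_iid(z: np.ndarray, dts: np.ndarray):
    n = len(z)
    ones = np.ones(n)
    return z[:, 0], z[:, 1], ones, np.ones(n)


def _whiten_ou(z: np.ndarray, dts: np.ndarray, tau: float):
    n = len(z)
    ex = np.empty(n)
    ey = np.empty(n)
    e1 = np.empty(n)
    v = np.empty(n)
    ex[0], ey[0], e1[0], v[0] = z[0, 0], z[0, 1], 1.0, 1.0
    rho = np.exp(-dts / tau)
    ex[1:] = z[1:, 0] - rho * z[:-1, 0]
    ey[1:] = z[1:, 1] - rho * z[:-1, 1]
    e1[1:] = 1.0 - rho
    v[1:] = 1.0 - rho * rho
    return ex, ey, e1, v


def _whiten_ouf(z: np.ndarray, dts: np.ndarray, tau_pos: float, tau_vel: float):
    """Kalman innovations of the OUF process (unit position variance).

    The position is observed exactly, so after each update the filter state
    reduces to the conditional velocity mean and variance — a fast scalar
    recursion.  Innovation coefficients are data-independent, so the
    constant-mean column is filtered alongside the data columns.
    """
    n = len(z)
    l1, l2 = -1.0 / tau_pos, -1.0 / tau_vel
    if abs(l1 - l2) < 1e-10 * abs(l1):
        l2 = l1 * (1.0 + 1e-6)
    kappa = 1.0 / (tau_pos * tau_vel)  # stationary velocity variance
    a21 = -kappa
    a22 = l1 + l2
    ex = np.empty(n)
    ey = np.empty(n)
    e1 = np.empty(n)
    v = np.empty(n)
    # first observation: stationary prior
    ex[0], ey[0], e1[0], v[0] = z[0, 0], z[0, 1], 1.0, 1.0
    # velocity posterior after exact position observation
    m1x = m1y = m11 = 0.0
    p11 = kappa
    zx, zy = z[:, 0], z[:, 1]
    # cache transition/noise entries per unique gap
    cache: dict[float, tuple] = {}
    denom = l1 - l2
    for i in range(1, n):
        dt = float(dts[i - 1])
        ent = cache.get(dt)
        if ent is None:
            E1, E2 = math.exp(l1 * dt), math.exp(l2 * dt)
            # Phi = (E1 (A - l2 I) - E2 (A - l1 I)) / (l1 - l2)
            f00 = (E1 * (0.0 - l2) - E2 * (0.0 - l1)) / denom
            f01 = (E1 - E2) / denom
            f10 = (E1 * a21 - E2 * a21) / denom
            f11 = (E1 * (a22 - l2) - E2 * (a22 - l1)) / denom
            # Q = Pinf - Phi Pinf Phi', Pinf = diag(1, kappa)
            q00 = 1.0 - (f00 * f00 + kappa * f01 * f01)
            q01 = -(f10 * f00 + kappa * f11 * f01)
            q11 = kappa - (f10 * f10 + kappa * f11 * f11)
            ent = (f00, f01, f10, f11, q00, q01, q11)
            cache[dt] = ent
        f00, f01, f10, f11, q00, q01, q11 = ent
        # predict: previous position known exactly (z_prev / 1), velocity ~ (m1, p11)
        p00p = f01 * f01 * p11 + q00
        p01p = f01 * f11 * p11 + q01
        p11p = f11 * f11 * p11 + q11
        m0x = f00 * zx[i - 1] + f01 * m1x
        m0y = f00 * zy[i - 1] + f01 * m1y
        m01 = f00 * 1.0 + f01 * m11
        exi = zx[i] - m0x
        eyi = zy[i] - m0y
        e1i = 1.0 - m01
        g = p01p / p00p
        m1x = f10 * zx[i - 1] + f11 * m1x + g * exi
        m1y = f10 * zy[i - 1] + f11 * m1y + g * eyi
        m11 = f10 * 1.0 + f11 * m11 + g * e1i
        p11 = p11p - p01p * g
        ex[i], ey[i], e1[i], v[i] = exi, eyi, e1i, p00p
    return ex, ey, e1, v


def _profile_loglik(ex, ey, e1, v):
    """Profile mu (per coordinate) and the common isotropic sigma^2 out of
    the whitened Gaussian likelihood; returns (loglik, mu, sigma2)."""
    n = len(v)
    if np.any(v <= 0):
        return -math.inf, (0.0, 0.0), 0.0
    w11 = float(np.sum(e1 * e1 / v))
    mux = float(np.sum(ex * e1 / v)) / w11
    muy = float(np.sum(ey * e1 / v)) / w11
    qx = float(np.sum((ex - mux * e1) ** 2 / v))
    qy = float(np.sum((ey - muy * e1) ** 2 / v))
    sigma2 = (qx + qy) / (2 * n)
    if sigma2 <= 0:
        return -math.inf, (mux, muy), 0.0
    ll = -n * math.log(2 * math.pi * sigma2) - float(np.sum(np.log(v))) - n
    return ll, (mux, muy), sigma2


def fit_movement_model(positions, times_min, kind: str) -> MovementModel:
    """Maximum-likelihood fit of one process kind to a projected track.

    ``positions``: (n, 2) metres; ``times_min``: strictly increasing minutes
    (gaps allowed).  Timescale optimization restarts from several
    initializations; a fit that fails to converge is returned flagged
    (``converged=False``) so model selection can skip it.
    """
    z = np.asarray(positions, dtype=float)
    t = np.asarray(times_min, dtype=float)
    if z.ndim != 2 or z.shape[1] != 2:
        raise ValueError("positions must be (n, 2)")
    n = len(z)
    if n < 10:
        raise ValueError("need at least 10 positions")
    dts = np.diff(t)
    if np.any(dts <= 0):
        raise ValueError("times must be strictly increasing")
    if float(np.var(z[:, 0]) + np.var(z[:, 1])) < 1e-12:
        raise DegenerateTrackError("all positions coincide; variance is zero")
    duration = float(t[-1] - t[0])
    kind = kind.upper()

    if kind == "IID":
        ll, mu, s2 = _profile_loglik(*_whiten_iid(z, dts))
        return MovementModel("IID", mu, s2, None, None, ll, 3, n, duration)

    dt_med = float(np.median(dts))
    inits = [
        max(dt_med, duration / 50.0),
        duration / 10.0,
        duration / 3.0,
    ]

    if kind == "OU":
        def nll(logtau):
            ll, _, _ = _profile_loglik(*_whiten_ou(z, dts, math.exp(float(logtau[0]))))
            return -ll

        best = None
        for tau0 in inits:
            res = minimize(nll, [math.log(tau0)], method="Nelder-Mead",
                           options={"xatol": 1e-4, "fatol": 1e-8, "maxiter": 200})
            if best is None or res.fun < best.fun:
                best = res
        tau = math.exp(float(best.x[0]))
        ll, mu, s2 = _profile_loglik(*_whiten_ou(z, dts, tau))
        ok = bool(best.success) and math.isfinite(ll)
        return MovementModel("OU", mu, s2, tau, None, ll, 4, n, duration,
                             converged=ok, message="" if ok else str(best.message))

    if kind == "OUF":
        def nll(p):
            ta, tb = math.exp(float(p[0])), math.exp(float(p[1]))
            ll, _, _ = _profile_loglik(*_whiten_ouf(z, dts, max(ta, tb), min(ta, tb)))
            return -ll

        best = None
        for tp0, tv0 in [(inits[1], dt_med / 2), (inits[2], dt_med),
                         (inits[0], dt_med / 4)]:
            res = minimize(nll, [math.log(tp0), math.log(tv0)], method="Nelder-Mead",
                           options={"xatol": 1e-4, "fatol": 1e-8, "maxiter": 400})
            if best is None or res.fun < best.fun:
                best = res
        ta, tb = math.exp(float(best.x[0])), math.exp(float(best.x[1]))
        tau_pos, tau_vel = max(ta, tb), min(ta, tb)
        ll, mu, s2 = _profile_loglik(*_whiten_ouf(z, dts, tau_pos, tau_vel))
        ok = bool(best.success) and math.isfinite(ll)
        return MovementModel("OUF", mu, s2, tau_pos, tau_vel, ll, 5, n, duration,
                             converged=ok, message="" if ok else str(best.message))

    raise ValueError(f"unknown model kind {kind!r}")


def fit_all_models(positions, times_min, kinds=("IID", "OU", "OUF")) -> list[MovementModel]:
    out = []
    for k in kinds:
        try:
            out.append(fit_movement_model(positions, times_min, k))
        except (ModelFitError, ValueError):
            continue
    return out


def select_model(candidates: list[MovementModel]) -> MovementModel:
    """Lowest AICc among converged candidates; ties favour fewer parameters."""
    ok = [m for m in candidates if m.converged and math.isfinite(m.aicc)]
    if not ok:
        raise ModelFitError("no converged candidate models")
    return min(ok, key=lambda m: (round(m.aicc, 9), m.n_params))


def effective_sample_size(model: MovementModel, duration_min: float) -> float:
    """N_area: nominal n for IID; sampled duration / tau_pos otherwise
    (roughly the number of home-range crossings)."""
    if model.kind == "IID":
        return float(model.n_obs)
    return float(duration_min) / float(model.tau_pos)


# ---------------------------------------------------------------------------
# Utilization distribution on a fixed global lattice


@dataclass
class UD:
    """Gridded utilization distribution on the global ``cell``-m lattice.

    Cell (iy, ix) covers the half-open square
    [ix0+ix, ix0+ix+1) x [iy0+iy, iy0+iy+1) in lattice units; ``masses``
    sum to 1.
    """

    ix0: int
    iy0: int
    masses: np.ndarray  # (ny, nx)
    cell: float = 500.0

    @property
    def nx(self) -> int:
        return self.masses.shape[1]

    @property
    def ny(self) -> int:
        return self.masses.shape[0]

    def x_centres(self) -> np.ndarray:
        return (self.ix0 + np.arange(self.nx) + 0.5) * self.cell

    def y_centres(self) -> np.ndarray:
        return (self.iy0 + np.arange(self.ny) + 0.5) * self.cell

    def check_normalized(self, tol: float = 1e-9) -> None:
        s = float(self.masses.sum())
        if abs(s - 1.0) > tol or np.any(self.masses < 0):
            raise ValueError(f"UD not a normalized density (sum={s})")

    def cell_index_of(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Lattice indices (relative to this grid) of planar points."""
        ix = np.floor(np.asarray(x, dtype=float) / self.cell).astype(int) - self.ix0
        iy = np.floor(np.asarray(y, dtype=float) / self.cell).astype(int) - self.iy0
        return ix, iy

    def write_ascii_grid(self, path, metadata: dict | None = None) -> None:
        """ESRI-ASCII-style text grid plus a JSON sidecar."""
        with open(path, "w") as fh:
            fh.write(f"ncols {self.nx}\n")
            fh.write(f"nrows {self.ny}\n")
            fh.write(f"xllcorner {self.ix0 * self.cell}\n")
            fh.write(f"yllcorner {self.iy0 * self.cell}\n")
            fh.write(f"cellsize {self.cell}\n")
            fh.write("NODATA_value -1\n")
            for row in self.masses[::-1]:  # north-up raster order
                fh.write(" ".join(f"{v:.8e}" for v in row) + "\n")
        if metadata is not None:
            with open(str(path) + ".json", "w") as fh:
                json.dump(metadata, fh, indent=1)


def akde(positions, model: MovementModel, cell: float = 500.0,
         narea_threshold: float = NAREA_THRESHOLD) -> UD:
    """Autocorrelation-aware kernel UD on the global ``cell``-m lattice.

    Gaussian-reference bandwidth matrix H = Sigma_hat * N_area^(-1/3) with
    the model's effective (not nominal) sample size; the grid is padded at
    least four bandwidth SDs beyond the data extent and renormalized.
    """
    z = np.asarray(positions, dtype=float)
    if not model.converged:
        raise ModelFitError("refusing to build a UD from a non-converged model")
    n_area = model.n_area
    if n_area < narea_threshold:
        raise NAreaError(
            f"effective sample size {n_area:.2f} below threshold "
            f"{narea_threshold}; UD unreliable"
        )
    cov = np.cov(z.T)
    if z.shape[0] < 2 or not np.all(np.isfinite(cov)):
        raise ValueError("cannot estimate a bandwidth from these positions")
    H = cov * n_area ** (-1.0 / 3.0)
    # regularize to at least one-tenth of a cell in each direction
    w, V = np.linalg.eigh(H)
    w = np.maximum(w, (cell / 10.0) ** 2)
    H = V @ np.diag(w) @ V.T
    sd_max = math.sqrt(float(w.max()))
    pad = 4.0 * sd_max
    ix0 = int(math.floor((z[:, 0].min() - pad) / cell))
    ix1 = int(math.floor((z[:, 0].max() + pad) / cell))
    iy0 = int(math.floor((z[:, 1].min() - pad) / cell))
    iy1 = int(math.floor((z[:, 1].max() + pad) / cell))
    nx, ny = ix1 - ix0 + 1, iy1 - iy0 + 1
    xc = (ix0 + np.arange(nx) + 0.5) * cell
    yc = (iy0 + np.arange(ny) + 0.5) * cell
    Hinv = np.linalg.inv(H)
    dens = np.zeros((ny, nx))
    # each point contributes on a local window of ~4.5 SD
    win = 4.5 * sd_max
    a, b, c = Hinv[0, 0], Hinv[0, 1], Hinv[1, 1]
    for px, py in z:
        jx0 = max(int((px - win - xc[0]) // cell), 0)
        jx1 = min(int((px + win - xc[0]) // cell) + 1, nx)
        jy0 = max(int((py - win - yc[0]) // cell), 0)
        jy1 = min(int((py + win - yc[0]) // cell) + 1, ny)
        if jx1 <= jx0 or jy1 <= jy0:
            continue
        dx = xc[jx0:jx1] - px
        dy = yc[jy0:jy1] - py
        quad = (
            a * dx[None, :] ** 2
            + 2.0 * b * dy[:, None] * dx[None, :]
            + c * dy[:, None] ** 2
        )
        dens[jy0:jy1, jx0:jx1] += np.exp(-0.5 * quad)
    total = dens.sum()
    if total <= 0:
        raise ValueError("empty density; check positions and bandwidth")
    return UD(ix0=ix0, iy0=iy0, masses=dens / total, cell=cell)
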