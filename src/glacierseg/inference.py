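"""Permutation and mixed-model inference for colony segregation analyses.

Implements the analysis battery applied to the pairwise matrices and the
trip-level front-use data: rank-based ANOSIM (global and per colony dyad
with Benjamini–Hochberg control), a multivariate dispersion-homogeneity
test in principal-coordinate space, a binomial random-intercept GLMM fitted
by Laplace-approximate maximum likelihood with likelihood-ratio tests and
Nakagawa's conditional R², a simulation-based overdispersion check, and
multiple regression on distance matrices (MRM) with response-permutation
p-values.

Every permutation engine takes an explicit seed and reports
p = (1 + #{null >= observed}) / (1 + n_perm), so the smallest attainable
p at 999 permutations is 0.001.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import chi2 as chi2_dist
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

from .trajectory import Colony


class SeparationError(RuntimeError):
    """Outcome is degenerate or separated; the GLMM cannot be fitted."""


# ---------------------------------------------------------------------------
# ANOSIM


@dataclass
class AnosimResult:
    r: float
    p: float
    n_perm: int
    groups: list[str]
    seed: int


def _check_square(d: np.ndarray) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    return d


def anosim(dist, groups, n_perm: int = 999, seed: int = 0) -> AnosimResult:
    """Rank-based analysis of similarities.

    R = (mean between-group rank - mean within-group rank) / (n(n-1)/4),
    computed on midranks of all off-diagonal distances; p by permuting
    group labels.
    """
    d = _check_square(dist)
    g = np.asarray(groups)
    n = len(g)
    labels, counts = np.unique(g, return_counts=True)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    if np.any(counts < 2):
        bad = labels[counts < 2]
        raise ValueError(f"every group needs >= 2 members; offending: {list(bad)}")
    iu, ju = np.triu_indices(n, k=1)
    ranks = rankdata(d[iu, ju])
    denom = n * (n - 1) / 4.0

    def r_stat(glab):
        within = glab[iu] == glab[ju]
        return (ranks[~within].mean() - ranks[within].mean()) / denom

    r_obs = float(r_stat(g))
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if r_stat(g[perm]) >= r_obs:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return AnosimResult(r=r_obs, p=float(p), n_perm=n_perm,
                        groups=[str(x) for x in labels], seed=seed)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotonicity enforced)."""
    return multipletests(np.asarray(pvals, dtype=float), method="fdr_bh")[1]


def pairwise_anosim(dist, groups, n_perm: int = 999, seed: int = 0) -> pd.DataFrame:
    """One ANOSIM per group dyad with BH-adjusted p over all dyads.

    Meant to follow a significant global test.  Dyads whose test cannot run
    (e.g. a single-member group) are reported with NaN and excluded from
    the adjustment.
    """
    d = _check_square(dist)
    g = np.asarray(groups)
    labels = np.unique(g)
    rows = []
    for a in range(len(labels)):
        for b in range(a + 1, len(labels)):
            sel = np.isin(g, [labels[a], labels[b]])
            idx = np.flatnonzero(sel)
            sub = d[np.ix_(idx, idx)]
            try:
                res = anosim(sub, g[idx], n_perm=n_perm, seed=seed + 7919 * (a * len(labels) + b))
                rows.append((labels[a], labels[b], res.r, res.p))
            except ValueError:
                rows.append((labels[a], labels[b], np.nan, np.nan))
    out = pd.DataFrame(rows, columns=["group1", "group2", "r", "p"])
    ok = out["p"].notna()
    adj = np.full(len(out), np.nan)
    if ok.any():
        adj[ok.to_numpy()] = bh_adjust(out.loc[ok, "p"])
    out["p_adj"] = adj
    return out


# ---------------------------------------------------------------------------
# Multivariate dispersion homogeneity (betadisper-style)


def dispersion_homogeneity(dist, groups, n_perm: int = 999, seed: int = 0):
    """Permutation test of homogeneous group dispersion in PCoA space.

    The distance matrix is embedded by principal coordinates; negative
    eigenvalues contribute imaginary axes whose squared distances subtract
    (the standard real/imaginary split).  The statistic is the one-way F of
    point-to-group-centroid distances; p permutes group labels in the fixed
    embedding.  Returns (F, p).
    """
    d = _check_square(dist)
    g = np.asarray(groups)
    n = len(g)
    labels, counts = np.unique(g, return_counts=True)
    if len(labels) < 2 or np.any(counts < 2):
        raise ValueError("need >= 2 groups with >= 2 members each")
    A = -0.5 * d**2
    J = np.eye(n) - np.ones((n, n)) / n
    G = J @ A @ J
    w, V = np.linalg.eigh(0.5 * (G + G.T))
    tol = 1e-8 * max(abs(w).max(), 1.0)
    pos = w > tol
    neg = w < -tol
    Xp = V[:, pos] * np.sqrt(w[pos])
    Xn = V[:, neg] * np.sqrt(-w[neg])

    def centroid_distances(glab):
        z = np.empty(n)
        for lab in np.unique(glab):
            m = glab == lab
            cp = Xp[m].mean(axis=0) if Xp.size else np.zeros(0)
            cn = Xn[m].mean(axis=0) if Xn.size else np.zeros(0)
            d2 = np.zeros(int(m.sum()))
            if Xp.size:
                d2 += ((Xp[m] - cp) ** 2).sum(axis=1)
            if Xn.size:
                d2 -= ((Xn[m] - cn) ** 2).sum(axis=1)
            z[m] = np.sqrt(np.clip(d2, 0.0, None))
        return z

    def f_stat(glab):
        z = centroid_distances(glab)
        grand = z.mean()
        ss_b = ss_w = 0.0
        k = 0
        for lab in np.unique(glab):
            m = glab == lab
            k += 1
            ss_b += m.sum() * (z[m].mean() - grand) ** 2
            ss_w += ((z[m] - z[m].mean()) ** 2).sum()
        df1, df2 = k - 1, n - k
        if ss_w <= 1e-9 * max(ss_b, 1.0):
            raise ValueError("zero within-group dispersion; F undefined")
        return (ss_b / df1) / (ss_w / df2)

    f_obs = float(f_stat(g))
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        if f_stat(g[rng.permutation(n)]) >= f_obs:
            count += 1
    return f_obs, float((1 + count) / (1 + n_perm))


# ---------------------------------------------------------------------------
# Binomial GLMM with individual random intercepts (Laplace ML)


@dataclass
class GlmmResult:
    params: pd.Series  # fixed effects on the logit scale
    se: pd.Series
    sigma2_re: float  # random-intercept variance
    loglik: float
    n_obs: int
    n_groups: int
    converged: bool
    formula_terms: tuple[str, ...]
    vcov: np.ndarray = field(repr=False, default=None)
    # internals for simulation-based diagnostics
    _eta_fixed: np.ndarray = field(repr=False, default=None)
    _cluster_idx: np.ndarray = field(repr=False, default=None)
    _y: np.ndarray = field(repr=False, default=None)
    _bhat: np.ndarray = field(repr=False, default=None)
    _m: np.ndarray = field(repr=False, default=None)  # binomial totals

    def ci(self, name: str, level: float = 0.95) -> tuple[float, float]:
        from scipy.stats import norm

        z = norm.ppf(0.5 + level / 2.0)
        est, se = self.params[name], self.se[name]
        return est - z * se, est + z * se


def _design_matrix(data: pd.DataFrame, terms: tuple[str, ...]):
    """Treatment-coded design matrix: female and the alphabetically first
    colony are reference levels."""
    cols = {"(Intercept)": np.ones(len(data))}
    if "distance" in terms:
        cols["distance_km"] = data["distance_km"].to_numpy(dtype=float)
    if "sex" in terms:
        cols["sex[male]"] = (data["sex"].astype(str) == "male").astype(float).to_numpy()
    if "colony" in terms:
        levels = sorted(data["colony"].astype(str).unique())
        for lev in levels[1:]:
            cols[f"colony[{lev}]"] = (
                (data["colony"].astype(str) == lev).astype(float).to_numpy()
            )
    if "distance:sex" in terms:
        cols["distance_km:sex[male]"] = (
            data["distance_km"].to_numpy(dtype=float)
            * (data["sex"].astype(str) == "male").to_numpy(dtype=float)
        )
    names = list(cols)
    X = np.column_stack([cols[c] for c in names])
    return X, names


def _laplace_nll(theta, X, y, m, cluster_idx, n_groups, return_bhat=False):
    """Negative Laplace-approximate marginal log-likelihood.

    theta = (beta..., log_sigma); ``m`` is the vector of binomial totals
    (all ones for a Bernoulli response).  The random-intercept modes are
    found by a vectorized per-cluster Newton iteration.
    """
    beta = theta[:-1]
    sigma = math.exp(min(theta[-1], 10.0))
    s2 = sigma * sigma
    eta0 = X @ beta
    b = np.zeros(n_groups)
    inv_s2 = 1.0 / max(s2, 1e-12)
    for _ in range(50):
        eta = eta0 + b[cluster_idx]
        p = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
        g = np.bincount(cluster_idx, weights=y - m * p, minlength=n_groups) - b * inv_s2
        W = np.bincount(cluster_idx, weights=m * p * (1 - p), minlength=n_groups)
        step = g / (W + inv_s2)
        b += step
        if np.max(np.abs(step)) < 1e-10:
            break
    eta = eta0 + b[cluster_idx]
    p = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
    W = np.bincount(cluster_idx, weights=m * p * (1 - p), minlength=n_groups)
    ll_data = float(np.sum(y * eta - m * np.logaddexp(0.0, eta)))
    ll = ll_data - float(np.sum(b * b)) * inv_s2 / 2.0 - 0.5 * float(
        np.sum(np.log1p(s2 * W))
    )
    if return_bhat:
        return -ll, b
    return -ll


def fit_binomial_glmm(
    data: pd.DataFrame,
    terms: tuple[str, ...] = ("distance", "sex", "colony"),
    interaction: bool = False,
    fix_sigma2: float | None = None,
) -> GlmmResult:
    """Binomial (logit) GLMM of trip-level front use with an individual
    random intercept, fitted by Laplace-approximate maximum likelihood.

    ``data`` needs columns used, distance_km, sex, colony, individual_id;
    an optional ``trials`` column turns the response into binomial counts
    (default Bernoulli).  With ``fix_sigma2=0`` (or when the variance
    estimate hits its boundary) the fit reproduces a plain logistic
    regression exactly.
    """
    terms = tuple(terms) + (("distance:sex",) if interaction else ())
    y = data["used"].to_numpy(dtype=float)
    m = (
        data["trials"].to_numpy(dtype=float)
        if "trials" in data.columns
        else np.ones(len(y))
    )
    if np.all(y == 0) or np.all(y == m):
        raise SeparationError("outcome is constant; model is separated/degenerate")
    X, names = _design_matrix(data, terms)
    groups, cluster_idx = np.unique(data["individual_id"], return_inverse=True)
    n_groups = len(groups)

    import statsmodels.api as sm

    glm = sm.GLM(
        np.column_stack([y, m - y]), X, family=sm.families.Binomial()
    ).fit(maxiter=200)
    glm_params = np.asarray(glm.params)

    at_boundary = False
    if fix_sigma2 is not None and fix_sigma2 <= 0:
        theta = np.concatenate([glm_params, [-15.0]])
        at_boundary = True
        success = True
    else:
        if fix_sigma2 is not None:
            logsig = 0.5 * math.log(fix_sigma2)

            def obj(b):
                return _laplace_nll(
                    np.concatenate([b, [logsig]]), X, y, m, cluster_idx, n_groups
                )

            res = minimize(obj, glm_params, method="BFGS",
                           options={"gtol": 1e-6, "maxiter": 500})
            theta = np.concatenate([res.x, [logsig]])
            success = bool(res.success)
        else:
            theta0 = np.concatenate([glm_params, [math.log(0.5)]])
            res = minimize(
                _laplace_nll,
                theta0,
                args=(X, y, m, cluster_idx, n_groups),
                method="BFGS",
                options={"gtol": 1e-6, "maxiter": 500},
            )
            theta = res.x
            success = bool(res.success)
            # the variance may sit on its boundary: compare against the
            # sigma -> 0 limit, which is exactly the plain logistic fit
            theta_glm = np.concatenate([glm_params, [-15.0]])
            if _laplace_nll(theta_glm, X, y, m, cluster_idx, n_groups) <= res.fun + 1e-8:
                theta = theta_glm
                at_boundary = True
                success = True

    nll, bhat = _laplace_nll(theta, X, y, m, cluster_idx, n_groups, return_bhat=True)
    beta = theta[:-1]
    sigma2 = 0.0 if at_boundary else math.exp(2.0 * theta[-1])
    if np.max(np.abs(beta)) > 30:
        raise SeparationError("diverging fixed effects; data appear separated")

    if at_boundary or fix_sigma2 is not None:
        vcov = np.asarray(glm.cov_params()) if at_boundary else None
        se = (
            np.sqrt(np.diag(vcov))
            if vcov is not None
            else np.full(len(beta), np.nan)
        )
    else:
        # observed-information vcov by central finite differences
        k = len(theta)
        h = 1e-4 * np.maximum(np.abs(theta), 1.0)
        H = np.zeros((k, k))
        for i in range(k):
            for j in range(i, k):
                tpp = theta.copy(); tpp[i] += h[i]; tpp[j] += h[j]
                tpm = theta.copy(); tpm[i] += h[i]; tpm[j] -= h[j]
                tmp = theta.copy(); tmp[i] -= h[i]; tmp[j] += h[j]
                tmm = theta.copy(); tmm[i] -= h[i]; tmm[j] -= h[j]
                H[i, j] = H[j, i] = (
                    _laplace_nll(tpp, X, y, m, cluster_idx, n_groups)
                    - _laplace_nll(tpm, X, y, m, cluster_idx, n_groups)
                    - _laplace_nll(tmp, X, y, m, cluster_idx, n_groups)
                    + _laplace_nll(tmm, X, y, m, cluster_idx, n_groups)
                ) / (4 * h[i] * h[j])
        try:
            vcov = np.linalg.inv(H)[: k - 1, : k - 1]
            se = np.sqrt(np.clip(np.diag(vcov), 0.0, None))
        except np.linalg.LinAlgError:
            vcov = np.full((k - 1, k - 1), np.nan)
            se = np.full(k - 1, np.nan)

    return GlmmResult(
        params=pd.Series(beta, index=names),
        se=pd.Series(se, index=names),
        sigma2_re=sigma2,
        loglik=-nll,
        n_obs=len(y),
        n_groups=n_groups,
        converged=success,
        formula_terms=terms,
        vcov=vcov,
        _eta_fixed=X @ beta,
        _cluster_idx=cluster_idx,
        _y=y,
        _bhat=bhat,
        _m=m,
    )


def lrt(model_h0: GlmmResult, model_h1: GlmmResult) -> tuple[float, int, float]:
    """Likelihood-ratio test of nested fits: chi2 = 2(ll1 - ll0)."""
    chi2 = 2.0 * (model_h1.loglik - model_h0.loglik)
    df = len(model_h1.params) - len(model_h0.params)
    if df <= 0:
        raise ValueError("H0 must be nested in H1 (fewer parameters)")
    if chi2 < -1e-4 * max(1.0, abs(model_h1.loglik)):
        raise RuntimeError(
            f"H1 log-likelihood below H0 ({chi2:.4g}); optimization failed"
        )
    chi2 = max(chi2, 0.0)
    return chi2, df, float(chi2_dist.sf(chi2, df))


def conditional_r2(glmm: GlmmResult) -> float:
    """Nakagawa's conditional R2 for a logit GLMM: variance explained by
    fixed + random effects over total latent variance (pi^2/3 residual)."""
    s2f = float(np.var(glmm._eta_fixed))
    s2r = glmm.sigma2_re
    return (s2f + s2r) / (s2f + s2r + math.pi**2 / 3.0)


def overdispersion_check(
    glmm: GlmmResult, n_sim: int = 200, seed: int = 0
) -> float:
    """Simulation-based dispersion check.

    The statistic is the variance of Pearson residuals taken against
    cluster-conditional fitted probabilities (random-intercept modes
    re-solved per dataset with the fixed effects held at their estimates).
    Response sets are simulated from the fitted model and the two-sided p
    is the rank of the observed statistic among them.
    """
    if n_sim <= 0:
        raise ValueError("n_sim must be positive")
    rng = np.random.default_rng(seed)
    eta0 = glmm._eta_fixed
    idx = glmm._cluster_idx
    n_groups = glmm.n_groups
    s2 = glmm.sigma2_re
    inv_s2 = 1.0 / max(s2, 1e-12)
    m = glmm._m if glmm._m is not None else np.ones(len(glmm._y))

    def solve_modes(yv):
        b = np.zeros(n_groups)
        for _ in range(50):
            eta = eta0 + b[idx]
            p = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
            g = np.bincount(idx, weights=yv - m * p, minlength=n_groups) - b * inv_s2
            W = np.bincount(idx, weights=m * p * (1 - p), minlength=n_groups)
            step = g / (W + inv_s2)
            b += step
            if np.max(np.abs(step)) < 1e-9:
                break
        return b

    def stat(yv):
        b = solve_modes(yv)
        p = 1.0 / (1.0 + np.exp(-np.clip(eta0 + b[idx], -35, 35)))
        r = (yv - m * p) / np.sqrt(np.clip(m * p * (1 - p), 1e-12, None))
        return float(np.var(r))

    s_obs = stat(glmm._y)
    sims = np.empty(n_sim)
    sd = math.sqrt(max(s2, 0.0))
    for s in range(n_sim):
        b_true = rng.normal(0.0, sd, size=n_groups)
        p_true = 1.0 / (1.0 + np.exp(-np.clip(eta0 + b_true[idx], -35, 35)))
        ysim = rng.binomial(m.astype(int), p_true).astype(float)
        sims[s] = stat(ysim)
    p_hi = (1 + int(np.sum(sims >= s_obs))) / (1 + n_sim)
    p_lo = (1 + int(np.sum(sims <= s_obs))) / (1 + n_sim)
    return float(min(1.0, 2.0 * min(p_hi, p_lo)))


# ---------------------------------------------------------------------------
# Multiple regression on distance matrices


@dataclass
class MrmResult:
    coefficients: pd.Series
    p_values: pd.Series  # permutation p per coefficient
    r2: float
    f: float
    p_f: float
    n_perm: int
    seed: int


def mrm(
    response: np.ndarray,
    predictors: dict[str, np.ndarray],
    n_perm: int = 999,
    seed: int = 0,
) -> MrmResult:
    """OLS on the vectorized lower triangles of distance matrices.

    Coefficient and overall-F significance come from simultaneously
    permuting rows and columns of the response matrix (predictors fixed)
    and refitting.
    """
    yM = _check_square(response)
    n = yM.shape[0]
    for name, m in predictors.items():
        m = _check_square(m)
        if m.shape[0] != n:
            raise ValueError(f"predictor matrix {name!r} has mismatched size")
        predictors[name] = m
    il, jl = np.tril_indices(n, k=-1)
    names = ["(Intercept)"] + list(predictors)
    X = np.column_stack(
        [np.ones(len(il))] + [predictors[k][il, jl] for k in predictors]
    )
    k = X.shape[1] - 1
    XtX_inv_Xt = np.linalg.pinv(X)

    def fit(yv):
        b = XtX_inv_Xt @ yv
        resid = yv - X @ b
        ss_res = float(resid @ resid)
        ss_tot = float(((yv - yv.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
        dfe = len(yv) - k - 1
        f = (r2 / k) / ((1.0 - r2) / dfe) if (1.0 - r2) > 1e-15 else math.inf
        return b, r2, f

    y = yM[il, jl]
    b_obs, r2_obs, f_obs = fit(y)
    rng = np.random.default_rng(seed)
    count_b = np.zeros(len(names), dtype=int)
    count_f = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        yp = yM[np.ix_(perm, perm)][il, jl]
        b_p, _, f_p = fit(yp)
        count_b += np.abs(b_p) >= np.abs(b_obs)
        if f_p >= f_obs:
            count_f += 1
    p_b = (1 + count_b) / (1 + n_perm)
    return MrmResult(
        coefficients=pd.Series(b_obs, index=names),
        p_values=pd.Series(p_b, index=names),
        r2=r2_obs,
        f=f_obs,
        p_f=float((1 + count_f) / (1 + n_perm)),
        n_perm=n_perm,
        seed=seed,
    )


def build_predictor_matrices(
    individual_ids: list[str],
    colony_of: dict[str, str],
    colonies: dict[str, Colony],
    projection,
) -> tuple[np.ndarray, np.ndarray]:
    """Colony-size (Manhattan, |size_i - size_j| breeding pairs) and
    colony-separation (Euclidean metres between projected centroids)
    matrices over individuals."""
    for ind in individual_ids:
        cid = colony_of.get(ind)
        if cid is None or cid not in colonies:
            raise KeyError(f"unknown colony for individual {ind!r}")
    sizes = np.array(
        [colonies[colony_of[i]].size for i in individual_ids], dtype=float
    )
    xy = {
        cid: np.array(projection.forward(c.lon, c.lat), dtype=float).ravel()
        for cid, c in colonies.items()
    }
    pts = np.vstack([xy[colony_of[i]] for i in individual_ids])
    size_mat = np.abs(sizes[:, None] - sizes[None, :])
    sep_mat = np.hypot(
        pts[:, 0][:, None] - pts[:, 0][None, :],
        pts[:, 1][:, None] - pts[:, 1][None, :],
    )
    return size_mat, sep_mat
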