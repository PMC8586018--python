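import itertools
import math

import numpy as np
import pandas as pd
import pytest

from glacierseg.geo import LocalProjection, great_circle_km
from glacierseg.inference import (
    GlmmResult,
    SeparationError,
    anosim,
    bh_adjust,
    build_predictor_matrices,
    conditional_r2,
    dispersion_homogeneity,
    fit_binomial_glmm,
    lrt,
    mrm,
    overdispersion_check,
    pairwise_anosim,
)
from glacierseg.trajectory import Colony


def euclidean_matrix(pts):
    pts = np.asarray(pts, dtype=float)
    return np.hypot(
        pts[:, 0][:, None] - pts[:, 0][None, :],
        pts[:, 1][:, None] - pts[:, 1][None, :],
    )


class TestAnosim:
    def test_perfect_separation_r_one(self):
        # all between distances exceed all within distances
        d = np.array(
            [
                [0, 1, 1, 9, 9, 9],
                [1, 0, 1, 9, 9, 9],
                [1, 1, 0, 9, 9, 9],
                [9, 9, 9, 0, 1, 1],
                [9, 9, 9, 1, 0, 1],
                [9, 9, 9, 1, 1, 0],
            ],
            dtype=float,
        )
        g = ["a"] * 3 + ["b"] * 3
        res = anosim(d, g, n_perm=99, seed=0)
        assert res.r == pytest.approx(1.0)

    def test_all_equal_distances_r_zero(self):
        d = np.ones((6, 6)) - np.eye(6)
        res = anosim(d, ["a"] * 3 + ["b"] * 3, n_perm=99, seed=0)
        assert res.r == pytest.approx(0.0)

    def test_sampled_p_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(5)
        pts = np.vstack([rng.normal(0, 1, (3, 2)), rng.normal(1.5, 1, (3, 2))])
        d = euclidean_matrix(pts)
        g = np.array(["a"] * 3 + ["b"] * 3)
        from scipy.stats import rankdata

        iu, ju = np.triu_indices(6, k=1)
        ranks = rankdata(d[iu, ju])
        denom = 6 * 5 / 4

        def r_of(lab):
            lab = np.asarray(lab)
            within = lab[iu] == lab[ju]
            return (ranks[~within].mean() - ranks[within].mean()) / denom

        r_obs = r_of(g)
        null = [r_of(g[list(p)]) for p in itertools.permutations(range(6))]
        exact = np.mean([r >= r_obs for r in null])
        res = anosim(d, g, n_perm=4999, seed=1)
        assert res.r == pytest.approx(r_obs)
        assert res.p == pytest.approx(exact, abs=3 * math.sqrt(exact * (1 - exact) / 4999) + 1e-3)

    def test_matches_skbio_statistic(self):
        from skbio import DistanceMatrix
        from skbio.stats.distance import anosim as sk_anosim

        rng = np.random.default_rng(6)
        pts = np.vstack([rng.normal(0, 1, (5, 2)), rng.normal(2, 1, (5, 2))])
        d = euclidean_matrix(pts)
        g = ["a"] * 5 + ["b"] * 5
        ref = sk_anosim(DistanceMatrix(d), g, permutations=999)
        res = anosim(d, g, n_perm=999, seed=2)
        assert res.r == pytest.approx(ref["test statistic"], abs=1e-12)

    def test_rank_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(0, 1, (8, 2))
        d = euclidean_matrix(pts)
        g = ["a"] * 4 + ["b"] * 4
        r1 = anosim(d, g, n_perm=9, seed=0).r
        r2 = anosim(np.expm1(d), g, n_perm=9, seed=0).r  # strictly monotone
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_seed_determinism_and_p_floor(self):
        d = euclidean_matrix(np.random.default_rng(8).normal(0, 1, (8, 2)))
        g = ["a"] * 4 + ["b"] * 4
        p1 = anosim(d, g, n_perm=99, seed=5).p
        p2 = anosim(d, g, n_perm=99, seed=5).p
        assert p1 == p2
        assert p1 >= 1 / 100

    def test_single_member_group_rejected(self):
        d = np.zeros((3, 3))
        with pytest.raises(ValueError):
            anosim(d, ["a", "a", "b"])


class TestPairwiseAnosim:
    def test_five_groups_ten_dyads(self):
        rng = np.random.default_rng(9)
        pts = np.vstack([rng.normal(3 * i, 1, (3, 2)) for i in range(5)])
        d = euclidean_matrix(pts)
        g = np.repeat([f"g{i}" for i in range(5)], 3)
        out = pairwise_anosim(d, g, n_perm=49, seed=0)
        assert len(out) == 10
        assert out["p_adj"].notna().all()

    def test_single_dyad_adjusted_equals_raw(self):
        rng = np.random.default_rng(10)
        pts = np.vstack([rng.normal(0, 1, (4, 2)), rng.normal(2, 1, (4, 2))])
        d = euclidean_matrix(pts)
        out = pairwise_anosim(d, ["a"] * 4 + ["b"] * 4, n_perm=99, seed=0)
        assert len(out) == 1
        assert out["p_adj"].iloc[0] == out["p"].iloc[0]


def test_bh_step_up_worked_example():
    # raw (0.01, 0.02, 0.03, 0.04) with m = 4 all adjust to 0.04
    np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)
    # monotonicity enforcement across a non-monotone raw sequence
    adj = bh_adjust([0.005, 0.049, 0.05])
    assert np.all(np.diff(adj[np.argsort([0.005, 0.049, 0.05])]) >= -1e-12)


class TestDispersion:
    def test_inflated_group_detected(self):
        rng = np.random.default_rng(11)
        a = rng.normal(0, 1, (15, 2))
        b = rng.normal(0, 4, (15, 2))  # much more dispersed
        d = euclidean_matrix(np.vstack([a, b]))
        f, p = dispersion_homogeneity(d, ["a"] * 15 + ["b"] * 15, n_perm=999, seed=0)
        assert p < 0.01

    def test_zero_dispersion_degenerate(self):
        pts = np.array([[0, 0]] * 3 + [[5, 5]] * 3, dtype=float)
        d = euclidean_matrix(pts)
        with pytest.raises(ValueError):
            dispersion_homogeneity(d, ["a"] * 3 + ["b"] * 3, n_perm=9, seed=0)

    def test_handles_non_euclidean_matrix(self):
        # a DH-style bounded dissimilarity generally has negative PCoA axes
        rng = np.random.default_rng(12)
        d = rng.uniform(0.2, 1.0, (10, 10))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        f, p = dispersion_homogeneity(d, ["a"] * 5 + ["b"] * 5, n_perm=99, seed=0)
        assert np.isfinite(f)
        assert 0 < p <= 1


def simulate_logistic(rng, n_ind=25, per_ind=30, beta=(-0.5, 0.15), sigma_re=0.0):
    rows = []
    for i in range(n_ind):
        b = rng.normal(0, sigma_re) if sigma_re > 0 else 0.0
        x = rng.uniform(0, 20, per_ind)
        eta = beta[0] + beta[1] * x + b
        y = (rng.uniform(size=per_ind) < 1 / (1 + np.exp(-eta))).astype(int)
        for xv, yv in zip(x, y):
            rows.append((f"I{i:02d}", yv, xv, "female", "C1"))
    return pd.DataFrame(
        rows, columns=["individual_id", "used", "distance_km", "sex", "colony"]
    )


class TestGlmm:
    def test_matches_irls_logistic_when_variance_profiled_to_zero(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(13)
        data = simulate_logistic(rng, sigma_re=0.0)
        fit = fit_binomial_glmm(data, terms=("distance",), fix_sigma2=0.0)
        X = np.column_stack([np.ones(len(data)), data["distance_km"]])
        ref = sm.GLM(data["used"], X, family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(fit.params.to_numpy(), ref.params, atol=1e-3)
        assert fit.sigma2_re == 0.0
        assert fit.loglik == pytest.approx(ref.llf, abs=1e-4)

    def test_recovers_random_intercept_variance(self):
        rng = np.random.default_rng(14)
        data = simulate_logistic(rng, n_ind=60, per_ind=40, sigma_re=1.0)
        fit = fit_binomial_glmm(data, terms=("distance",))
        assert 0.4 < fit.sigma2_re < 2.2

    def test_constant_outcome_raises_separation(self):
        data = simulate_logistic(np.random.default_rng(15))
        data["used"] = 0
        with pytest.raises(SeparationError):
            fit_binomial_glmm(data, terms=("distance",))

    def test_matches_lme4_glmer_on_identical_data(self, tmp_path):
        # independent oracle: R lme4 Laplace fit of the same model
        import subprocess

        rng = np.random.default_rng(27)
        data = simulate_logistic(rng, n_ind=30, per_ind=40, sigma_re=0.8)
        fit = fit_binomial_glmm(data, terms=("distance",))
        csv = tmp_path / "glmm.csv"
        data.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(
            "suppressMessages(library(lme4))\n"
            f"d <- read.csv('{csv}')\n"
            "f <- glmer(used ~ distance_km + (1|individual_id), data=d,"
            " family=binomial)\n"
            "s <- summary(f)\n"
            "cat(s$coefficients['distance_km',1], s$coefficients['distance_km',2],"
            " as.numeric(VarCorr(f)$individual_id[1]), as.numeric(logLik(f)),"
            " sep=',')\n"
        )
        res = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, check=True
        )
        slope, se, s2, ll = map(float, res.stdout.strip().split(","))
        assert fit.params["distance_km"] == pytest.approx(slope, abs=2e-4)
        assert fit.se["distance_km"] == pytest.approx(se, rel=0.02)
        assert fit.sigma2_re == pytest.approx(s2, rel=0.02, abs=1e-3)
        assert fit.loglik == pytest.approx(ll, abs=1e-2)

    def test_reference_levels(self):
        rng = np.random.default_rng(16)
        data = simulate_logistic(rng)
        data.loc[::2, "sex"] = "male"
        data.loc[::3, "colony"] = "C0"  # alphabetically first -> reference
        fit = fit_binomial_glmm(data, terms=("distance", "sex", "colony"))
        assert "sex[male]" in fit.params.index
        assert "colony[C1]" in fit.params.index
        assert "colony[C0]" not in fit.params.index


class TestLrt:
    def test_identical_models_chi2_zero_p_one(self):
        rng = np.random.default_rng(17)
        data = simulate_logistic(rng)
        m = fit_binomial_glmm(data, terms=("distance",))
        m2 = GlmmResult(
            params=pd.Series([0.0, 0.0, 0.0], index=["a", "b", "c"]),
            se=m.se, sigma2_re=0.0, loglik=m.loglik, n_obs=m.n_obs,
            n_groups=m.n_groups, converged=True, formula_terms=("x",),
        )
        chi2, df, p = lrt(m, m2)
        assert chi2 == 0.0
        assert p == 1.0

    def test_strong_effect_detected(self):
        rng = np.random.default_rng(18)
        data = simulate_logistic(rng, beta=(-0.5, 0.3))
        m1 = fit_binomial_glmm(data, terms=("distance",))
        m0 = fit_binomial_glmm(data, terms=())
        chi2, df, p = lrt(m0, m1)
        assert df == 1
        assert p < 1e-3

    def test_non_nested_rejected(self):
        rng = np.random.default_rng(19)
        data = simulate_logistic(rng)
        m = fit_binomial_glmm(data, terms=("distance",))
        with pytest.raises(ValueError):
            lrt(m, m)


class TestConditionalR2:
    def _mock(self, s2f, s2r, n=100):
        eta = np.sqrt(s2f) * np.concatenate([-np.ones(n // 2), np.ones(n // 2)])
        return GlmmResult(
            params=pd.Series([0.0]), se=pd.Series([0.0]), sigma2_re=s2r,
            loglik=0.0, n_obs=n, n_groups=2, converged=True,
            formula_terms=(), _eta_fixed=eta,
        )

    def test_zero_variances_zero(self):
        assert conditional_r2(self._mock(0.0, 0.0)) == 0.0

    def test_unit_variances_formula(self):
        # (1+1) / (1+1+pi^2/3)
        assert conditional_r2(self._mock(1.0, 1.0)) == pytest.approx(
            2.0 / (2.0 + math.pi**2 / 3.0), rel=1e-12
        )

    def test_monotone_in_random_variance(self):
        vals = [conditional_r2(self._mock(1.0, s)) for s in (0.0, 0.5, 1.0, 2.0)]
        assert np.all(np.diff(vals) > 0)


class TestOverdispersion:
    def test_zero_sims_rejected(self):
        rng = np.random.default_rng(20)
        fit = fit_binomial_glmm(simulate_logistic(rng), terms=("distance",))
        with pytest.raises(ValueError):
            overdispersion_check(fit, n_sim=0)

    def test_well_specified_model_not_flagged(self):
        rng = np.random.default_rng(21)
        data = simulate_logistic(rng, n_ind=30, per_ind=40, sigma_re=0.6)
        fit = fit_binomial_glmm(data, terms=("distance",))
        p = overdispersion_check(fit, n_sim=100, seed=0)
        assert p > 0.05

    def test_beta_binomial_counts_flagged(self):
        # binomial totals with beta-varying success probability carry
        # extra-binomial dispersion the random intercept cannot absorb
        rng = np.random.default_rng(22)
        rows = []
        trials = 20
        for i in range(30):
            for _ in range(10):
                q = rng.beta(2.0, 4.0)  # mean 1/3, strongly overdispersed
                rows.append(
                    (f"I{i:02d}", int(rng.binomial(trials, q)), trials,
                     0.0, "female", "C1")
                )
        data = pd.DataFrame(
            rows,
            columns=["individual_id", "used", "trials", "distance_km", "sex", "colony"],
        )
        fit = fit_binomial_glmm(data, terms=())
        p = overdispersion_check(fit, n_sim=100, seed=0)
        assert p < 0.05


class TestMrm:
    def test_noiseless_linear_response_exact(self):
        rng = np.random.default_rng(23)
        x = euclidean_matrix(rng.normal(0, 1, (12, 2)))
        y = 0.3 + 2.0 * x
        res = mrm(y, {"x": x}, n_perm=199, seed=0)
        assert res.r2 == pytest.approx(1.0)
        assert res.coefficients["x"] == pytest.approx(2.0)
        assert res.p_values["x"] == pytest.approx(1 / 200)
        assert res.p_f == pytest.approx(1 / 200)

    def test_dimension_mismatch_named(self):
        y = np.zeros((5, 5))
        with pytest.raises(ValueError, match="bad"):
            mrm(y, {"bad": np.zeros((4, 4))}, n_perm=9)

    def test_seed_determinism(self):
        rng = np.random.default_rng(24)
        x = euclidean_matrix(rng.normal(0, 1, (10, 2)))
        y = x + euclidean_matrix(rng.normal(0, 1, (10, 2)))
        r1 = mrm(y, {"x": x}, n_perm=99, seed=7)
        r2 = mrm(y, {"x": x}, n_perm=99, seed=7)
        assert r1.p_values.equals(r2.p_values)
        assert r1.p_f == r2.p_f

    def test_known_coefficients_recovered_with_noise(self):
        # response built from DH-like and separation-like matrices with
        # matched noise: strong predictors significant, null one not
        rng = np.random.default_rng(25)
        n = 30
        dh = rng.uniform(0, 1, (n, n)); dh = (dh + dh.T) / 2; np.fill_diagonal(dh, 0)
        sep = euclidean_matrix(rng.normal(0, 10000, (n, 2)))
        s = rng.integers(100, 2000, n).astype(float)
        size = np.abs(s[:, None] - s[None, :])
        noise = rng.normal(0, 0.05, (n, n)); noise = (noise + noise.T) / 2; np.fill_diagonal(noise, 0)
        y = 0.1 + 0.4 * dh + 2e-5 * sep + 0.0 * size + noise
        res = mrm(y, {"size": size, "separation": sep, "dh": dh}, n_perm=199, seed=0)
        assert res.coefficients["dh"] == pytest.approx(0.4, abs=0.1)
        assert res.p_values["dh"] <= 0.01
        assert res.p_values["separation"] <= 0.01
        assert res.p_values["size"] > 0.05


class TestPredictorMatrices:
    COLS = {
        "A": Colony("A", 12.11, 78.99, 908),
        "B": Colony("B", 12.28, 78.93, 141),
    }
    PROJ = LocalProjection(12.3, 78.95)

    def test_same_colony_pair_zero(self):
        size, sep = build_predictor_matrices(
            ["i1", "i2"], {"i1": "A", "i2": "A"}, self.COLS, self.PROJ
        )
        assert size[0, 1] == 0.0
        assert sep[0, 1] == 0.0

    def test_size_difference_manhattan(self):
        size, _ = build_predictor_matrices(
            ["i1", "i2"], {"i1": "A", "i2": "B"}, self.COLS, self.PROJ
        )
        assert size[0, 1] == 767.0  # |908 - 141|

    def test_separation_close_to_great_circle(self):
        _, sep = build_predictor_matrices(
            ["i1", "i2"], {"i1": "A", "i2": "B"}, self.COLS, self.PROJ
        )
        gc = great_circle_km((12.11, 78.99), (12.28, 78.93)) * 1000.0
        assert sep[0, 1] == pytest.approx(gc, rel=0.005)

    def test_unknown_colony_rejected(self):
        with pytest.raises(KeyError):
            build_predictor_matrices(["i1"], {"i1": "Z"}, self.COLS, self.PROJ)
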