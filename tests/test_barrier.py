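import numpy as np
import pandas as pd
import pytest

from riverhap.barrier import (RiverineBarrierModel, ks_normality,
                              make_pair_table, pearson_correlation,
                              significance_stars)
from riverhap.distances import DistanceMatrix
from riverhap.errors import InputError, InsufficientDataError


# oracle values for the 6-point fit below, computed once with R:
#   glm(y ~ x, family = gaussian) and glm(y ~ x + z, family = gaussian)
R_FIT = {
    "x": [10, 25, 43, 61, 78, 95],
    "z": [0, 1, 0, 2, 1, 3],
    "y": [0.05, 0.12, 0.18, 0.34, 0.35, 0.51],
    "intercept": -0.0140141570,
    "slope": 0.0052374517,
    "t": 10.671107,
    "p": 0.00043682,
    "aic1": -19.523687,
    "aic2": -28.664385,
}


def pair_frame(x, y, z=None):
    n = len(x)
    rows = []
    # synthesise pair labels from a star design: enough for fitting tests
    for k in range(n):
        rows.append({"pop_a": f"p{k}", "pop_b": f"q{k}", "fst": y[k],
                     "straight_km": x[k],
                     "detoured_km": x[k] * 1.1,
                     "crossings": (z[k] if z is not None else 0)})
    return pd.DataFrame(rows)


class TestPearson:
    def test_perfect_line(self):
        x = np.arange(5.0)
        res = pearson_correlation(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)
        assert res.p == pytest.approx(0.0, abs=1e-12)

    def test_hand_dataset_closed_form(self):
        x = np.array([1, 2, 3, 4, 5.0])
        y = np.array([2, 1, 4, 3, 6.0])
        n = 5
        sxy = (x * y).sum() - x.sum() * y.sum() / n
        sxx = (x * x).sum() - x.sum() ** 2 / n
        syy = (y * y).sum() - y.sum() ** 2 / n
        r_oracle = sxy / np.sqrt(sxx * syy)
        res = pearson_correlation(x, y)
        assert res.r == pytest.approx(r_oracle, abs=1e-12)
        assert res.n == 5

    def test_zero_variance_rejected(self):
        with pytest.raises(InputError):
            pearson_correlation([1, 1, 1], [1, 2, 3])

    def test_stars_formatting(self):
        assert significance_stars(0.0001) == "***"
        assert significance_stars(0.005) == "**"
        assert significance_stars(0.03) == "*"
        assert significance_stars(0.2) == "ns"


class TestKs:
    def test_fitted_quantiles_fit_well(self):
        from scipy.stats import norm
        q = norm.ppf((np.arange(1, 22) - 0.5) / 21, loc=0.3, scale=0.1)
        d, p = ks_normality(q)
        assert d < 0.1
        assert p > 0.95

    def test_hand_ecdf_enumeration(self):
        from scipy.stats import norm
        vals = np.array([0.1, 0.2, 0.25, 0.4, 0.9])
        mu, sd = vals.mean(), vals.std(ddof=1)
        cdf = norm.cdf(np.sort(vals), mu, sd)
        n = 5
        d_oracle = max(max(abs((i + 1) / n - cdf[i]), abs(i / n - cdf[i]))
                       for i in range(n))
        d, _ = ks_normality(vals)
        assert d == pytest.approx(d_oracle, abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(InputError):
            ks_normality([1.0] * 6)

    def test_lilliefors_variant_available(self):
        rng = np.random.default_rng(7)
        d, p = ks_normality(rng.normal(size=30), lilliefors=True)
        assert 0 <= d <= 1 and 0 <= p <= 1


class TestGlmFit:
    def test_matches_R_gaussian_glm(self):
        tab = pair_frame(R_FIT["x"], R_FIT["y"], R_FIT["z"])
        model = RiverineBarrierModel(tab)
        fit = model.fit(("straight",))
        assert fit.params["const"] == pytest.approx(R_FIT["intercept"],
                                                    abs=1e-8)
        assert fit.params["straight"] == pytest.approx(R_FIT["slope"],
                                                       abs=1e-8)
        assert fit.tvalues["straight"] == pytest.approx(R_FIT["t"], abs=1e-4)
        assert fit.pvalues["straight"] == pytest.approx(R_FIT["p"], abs=1e-6)
        assert fit.aic == pytest.approx(R_FIT["aic1"], abs=1e-4)
        assert fit.signs["straight"] == "+"
        fit2 = model.fit(("straight", "crossings"))
        assert fit2.aic == pytest.approx(R_FIT["aic2"], abs=1e-4)

    def test_normal_equation_oracle(self, rng):
        x = rng.uniform(0, 100, 8)
        y = 0.002 * x + rng.normal(0, 0.02, 8)
        tab = pair_frame(x, y)
        fit = RiverineBarrierModel(tab).fit(("straight",))
        X = np.column_stack([np.ones(8), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        rss = float(((y - X @ beta) ** 2).sum())
        aic = 8 * np.log(2 * np.pi * rss / 8) + 8 + 2 * 3
        assert fit.params["const"] == pytest.approx(beta[0], abs=1e-10)
        assert fit.params["straight"] == pytest.approx(beta[1], abs=1e-10)
        assert fit.aic == pytest.approx(aic, abs=1e-8)

    def test_pearson_t_equals_slope_t(self, rng):
        x = rng.uniform(0, 50, 9)
        y = 0.01 * x + rng.normal(0, 0.1, 9)
        fit = RiverineBarrierModel(pair_frame(x, y)).fit(("straight",))
        corr = pearson_correlation(x, y)
        assert fit.tvalues["straight"] == pytest.approx(corr.t, abs=1e-9)
        assert fit.pvalues["straight"] == pytest.approx(corr.p, abs=1e-9)

    def test_aic_two_unit_penalty(self, rng):
        # a pure-noise extra predictor must not beat the 2-unit penalty
        x = np.linspace(0, 100, 12)
        y = 0.004 * x + rng.normal(0, 0.01, 12)
        tab = pair_frame(x, y, z=list(rng.normal(0, 1, 12)))
        model = RiverineBarrierModel(tab)
        f1 = model.fit(("straight",))
        f2 = model.fit(("straight", "crossings"))
        n, k = 12, 1
        # AIC improves iff n*ln(RSS1/RSS2) > 2
        gain = n * np.log(f1.rss / f2.rss)
        assert (f2.aic < f1.aic) == (gain > 2.0)

    def test_collinear_predictors_rejected(self):
        x = [10, 25, 43, 61, 78, 95.0]
        tab = pair_frame(x, [0.1] * 6, z=x)  # crossings == straight
        with pytest.raises(InputError, match="ollinear"):
            RiverineBarrierModel(tab).fit(("straight", "crossings"))

    def test_row_order_invariance(self, rng):
        x = rng.uniform(0, 100, 10)
        y = 0.003 * x + rng.normal(0, 0.05, 10)
        tab = pair_frame(x, y, z=list(rng.integers(0, 3, 10)))
        f1 = RiverineBarrierModel(tab).fit(("straight", "crossings"))
        f2 = RiverineBarrierModel(
            tab.sample(frac=1, random_state=0)).fit(("straight", "crossings"))
        assert f1.aic == pytest.approx(f2.aic, abs=1e-10)
        assert f1.params["straight"] == pytest.approx(f2.params["straight"],
                                                      abs=1e-10)


def star_table(rng, n_pops=7):
    """A full pairwise table over n_pops populations with an IBD signal."""
    lat = rng.uniform(-3, 3, n_pops)
    lon = rng.uniform(15, 26, n_pops)
    pops = [f"P{k}" for k in range(n_pops)]
    rows = []
    for i in range(n_pops):
        for j in range(i + 1, n_pops):
            d = float(np.hypot(lat[i] - lat[j], lon[i] - lon[j])) * 111
            rows.append({"pop_a": pops[i], "pop_b": pops[j],
                         "fst": 0.0004 * d + rng.normal(0, 0.02),
                         "straight_km": d, "detoured_km": d * 1.2,
                         "crossings": int(rng.integers(0, 4))})
    return pd.DataFrame(rows)


class TestModelComparisonAndProfiles:
    def test_ranking_contains_four_models(self, rng):
        model = RiverineBarrierModel(star_table(rng))
        res = model.model_comparison()
        assert len(res.fits) == 4
        aics = [f.aic for f in res.fits]
        assert aics == sorted(aics)
        assert "AIC" in res.summary()

    def test_exclusion_row_counts(self, rng):
        model = RiverineBarrierModel(star_table(rng))
        assert len(model._subset(None)) == 21
        assert len(model._subset("P0")) == 15
        fit = model.fit(("straight",), exclude="P0")
        assert fit.n == 15

    def test_site_profile_has_six_pairs(self, rng):
        model = RiverineBarrierModel(star_table(rng))
        prof = model.site_correlation_profile("P3")
        assert prof["straight"].n == 6
        with pytest.raises(InputError):
            model.site_correlation_profile("P3", exclude="P3")

    def test_correlation_table_shape(self, rng):
        model = RiverineBarrierModel(star_table(rng))
        tab = model.correlation_table()
        assert len(tab) == 7
        assert set(["r_straight", "r_detoured", "r_crossings"]) <= \
            set(tab.columns)

    def test_make_pair_table_joins_fst_and_geo(self):
        fst = DistanceMatrix(["A", "B", "C"],
                             np.array([[0, .1, .2], [.1, 0, .3],
                                       [.2, .3, 0]]), "fst")
        geo = pd.DataFrame([
            {"pop_a": "A", "pop_b": "B", "straight_km": 10.0,
             "detoured_km": 12.0, "crossings": 1},
            {"pop_a": "A", "pop_b": "C", "straight_km": 20.0,
             "detoured_km": 20.0, "crossings": 0},
            {"pop_a": "B", "pop_b": "C", "straight_km": 30.0,
             "detoured_km": 45.0, "crossings": 2},
        ])
        tab = make_pair_table(fst, geo, cohorts={"A": "w", "B": "w",
                                                 "C": "e"})
        assert len(tab) == 3
        assert tab.loc[tab.pop_b == "C", "cohort_pair"].tolist() == \
            ["e-w", "e-w"]

    def test_mantel_detects_strong_signal(self, rng):
        model = RiverineBarrierModel(star_table(rng))
        r, p = model.mantel_test("straight", n_perm=99, seed=1)
        assert -1 <= r <= 1
        assert 0 < p <= 1

    def test_too_few_pairs_rejected(self):
        tab = pair_frame([1, 2], [0.1, 0.2])
        with pytest.raises(InsufficientDataError):
            RiverineBarrierModel(tab).fit(("straight",))
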