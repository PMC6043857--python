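"""Growth model: likelihood oracles, priors, sampler, summaries."""

import numpy as np
import pandas as pd
import pytest
from numpy.polynomial.hermite import hermgauss
from scipy import stats

import eduslope as es
from eduslope.model import _MarginalGrowthPosterior
from eduslope.names import FIXED_EFFECT_LABELS, VARIANCE_LABELS


def gauss_hermite_loglik(prepared, params, n_nodes=201):
    """Independent oracle: integrate the random effects by 2-D quadrature."""
    g = params[list(FIXED_EFFECT_LABELS)].to_numpy()
    s0, s1, rho, se = (params[k] for k in VARIANCE_LABELS)
    cov = np.array([[s0**2, rho * s0 * s1], [rho * s0 * s1, s1**2]])
    L = np.linalg.cholesky(cov)
    nodes, weights = hermgauss(n_nodes)
    U = np.sqrt(2) * (
        L @ np.stack(np.meshgrid(nodes, nodes, indexing="ij"), 0).reshape(2, -1)
    )
    W = (weights[:, None] * weights[None, :]).reshape(-1)
    X = prepared.X.to_numpy()
    y = prepared.y
    zlin = prepared.X["Linear slope (LS)"].to_numpy()
    total = 0.0
    for pid in pd.unique(prepared.person_ids):
        m = prepared.person_ids == pid
        Z = np.column_stack([np.ones(m.sum()), zlin[m]])
        r0 = y[m] - X[m] @ g
        R = r0[:, None] - Z @ U
        vals = np.exp(-0.5 * (R**2).sum(0) / se**2)
        like = (W * vals).sum() / np.pi * (2 * np.pi * se**2) ** (-m.sum() / 2)
        total += np.log(like)
    return total


@pytest.fixture(scope="module")
def tiny_prepared():
    d = es.StudyDesign(
        cohort_birth_years=(1919, 1939, 1949), persons_per_cell=1,
        dropout_hazard=0.0, education_min=6,
        sample_entry_waves={"S1": 0}, wave_years=(1989, 1994, 1999),
        wave_spacing=5,
    )
    data = es.generate(d, es.betula_like_truth("em"), seed=9)
    return es.prepare(data, "em",
                      es.PrepConfig(recompute_centers_from_data=True))


class TestLogLikelihood:
    def params(self, **kw):
        base = dict(sd_u0=2.0, sd_u1=0.2, rho=-0.4, sd_resid=2.0)
        base.update(kw)
        gamma = base.pop("gamma", {"g00": 50.0, "g10": -0.2, "g02": 0.5})
        return es.truth_table(es.TrueParameters(gamma=gamma, **base))

    def test_matches_quadrature_oracle(self, tiny_prepared):
        p = self.params()
        ours = es.log_likelihood(p, tiny_prepared)
        oracle = gauss_hermite_loglik(tiny_prepared, p)
        assert abs(ours - oracle) <= 1e-6

    def test_no_random_effects_limit(self, tiny_prepared):
        # sd_u -> 0 reduces to a sum of independent univariate normals
        p = self.params(sd_u0=0.0, sd_u1=0.0, rho=0.0)
        g = p[list(FIXED_EFFECT_LABELS)].to_numpy()
        mu = tiny_prepared.X.to_numpy() @ g
        direct = stats.norm.logpdf(tiny_prepared.y, mu, 2.0).sum()
        assert es.log_likelihood(p, tiny_prepared) == pytest.approx(direct)

    def test_single_standard_normal_observation(self, tiny_prepared):
        # one person, one observation, zero residual, sd_resid = 1 and no
        # random effects: the log density is the standard normal at 0
        single = es.PreparedDataset(
            frame=tiny_prepared.frame.iloc[[0]],
            X=tiny_prepared.X.iloc[[0]],
            y=np.array([tiny_prepared.y[0]]),
            person_ids=np.array([1]), outcome="em",
            baseline_mean=tiny_prepared.baseline_mean,
            baseline_sd=tiny_prepared.baseline_sd,
            centers=tiny_prepared.centers,
            quad_coefficients=tiny_prepared.quad_coefficients,
            exclusion_report={}, config=tiny_prepared.config,
        )
        p = es.truth_table(es.TrueParameters(
            gamma={}, sd_u0=0.0, sd_u1=0.0, rho=0.0, sd_resid=1.0,
        ))
        x0 = single.X.iloc[0].to_numpy()
        # choose the intercept so the linear predictor equals y exactly
        p["Intercept"] = (single.y[0]
                          - x0 @ p[list(FIXED_EFFECT_LABELS)].to_numpy())
        ll = es.log_likelihood(p, single)
        assert ll == pytest.approx(-0.5 * np.log(2 * np.pi))

    def test_row_permutation_invariance(self, tiny_prepared):
        p = self.params()
        base = es.log_likelihood(p, tiny_prepared)
        rng = np.random.default_rng(3)
        perm = rng.permutation(len(tiny_prepared.y))
        shuffled = es.PreparedDataset(
            frame=tiny_prepared.frame.iloc[perm],
            X=tiny_prepared.X.iloc[perm],
            y=tiny_prepared.y[perm],
            person_ids=tiny_prepared.person_ids[perm],
            outcome="em", baseline_mean=tiny_prepared.baseline_mean,
            baseline_sd=tiny_prepared.baseline_sd,
            centers=tiny_prepared.centers,
            quad_coefficients=tiny_prepared.quad_coefficients,
            exclusion_report={}, config=tiny_prepared.config,
        )
        assert abs(es.log_likelihood(p, shuffled) - base) < 1e-10

    def test_fast_path_matches_dense(self, recovery_world):
        # the batched Woodbury path used by the sampler equals the dense
        # per-person reference on dropout-patterned data
        prep = recovery_world["prepared"]
        p = self.params(sd_u0=1.5, sd_u1=0.03, rho=0.2, sd_resid=1.9)
        post = _MarginalGrowthPosterior(
            prep.X.to_numpy(), prep.y,
            prep.X["Linear slope (LS)"].to_numpy(), prep.person_ids,
            es.PriorSpec(), list(prep.X.columns),
        )
        g = p[list(FIXED_EFFECT_LABELS)].to_numpy()
        fast = post.loglik(g, 1.5, 0.03, 0.2, 1.9)
        dense = es.log_likelihood(p, prep)
        assert fast == pytest.approx(dense, abs=1e-8)


class TestLogPrior:
    def test_focal_prior_at_zero(self):
        sigma = 0.068
        prior = es.PriorSpec(sigma_focal=sigma)
        p0 = es.truth_table(es.TrueParameters(sd_u0=1, sd_u1=1, rho=0.0,
                                              sd_resid=1))
        base = es.log_prior(p0, prior)
        p1 = p0.copy()
        p1["LS x education"] = 0.01
        shifted = es.log_prior(p1, prior)
        # Normal(0, sigma) log-density difference
        expected = stats.norm.logpdf(0.01, 0, sigma) - stats.norm.logpdf(0, 0, sigma)
        assert shifted - base == pytest.approx(expected)

    def test_lkj_flat_in_rho(self):
        prior = es.PriorSpec()
        p = es.truth_table(es.TrueParameters(sd_u0=1, sd_u1=1, rho=0.0,
                                             sd_resid=1))
        vals = []
        for r in (-0.9, -0.2, 0.5, 0.95):
            q = p.copy()
            q["Correlation (intercept, slope)"] = r
            vals.append(es.log_prior(q, prior))
        assert np.allclose(vals, vals[0])

    def test_negative_sd_gives_log_zero(self):
        p = es.truth_table(es.TrueParameters(sd_u0=1, sd_u1=1, rho=0.0,
                                             sd_resid=1))
        p["Residual error"] = -1.0
        assert es.log_prior(p, es.PriorSpec()) == -np.inf

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            es.PriorSpec(sigma_focal=-1.0)


class TestRhat:
    def make(self, arr):
        arr = np.asarray(arr, dtype=float)
        return es.PosteriorDraws(draws=arr[:, :, None], names=["x0"])

    def test_identical_stationary_chains_give_one(self):
        # identical chains whose two halves repeat the same pattern: the
        # between-sequence variance vanishes and R-hat sits at its floor
        base = np.tile([0.0, 1.0, 0.5, 2.0, -1.0] * 10, 2)
        r = es.rhat(self.make([base] * 4))
        assert r["x0"] == pytest.approx(1.0, abs=0.02)
        assert r["x0"] < 1.01

    def test_constant_draws_guarded(self):
        r = es.rhat(self.make(np.full((4, 50), 3.0)))
        assert r["x0"] == 1.0

    def test_separated_chains_blow_up(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 500)
        b = rng.normal(10, 1, 500)
        r = es.rhat(self.make([a, b]))
        assert r["x0"] > 3.0

    def test_iid_chains_converge(self):
        rng = np.random.default_rng(1)
        chains = rng.normal(0, 1, (4, 2000))
        r = es.rhat(self.make(chains))
        assert r["x0"] < 1.01

    def test_matches_arviz_split_rhat(self):
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(2)
        chains = rng.normal(0, 1, (4, 500)) + rng.normal(0, 0.3, (4, 1))
        ours = es.rhat(self.make(chains))["x0"]
        theirs = float(az.rhat(chains[None].transpose(1, 2, 0)[:, :, 0],
                               method="split"))
        assert ours == pytest.approx(theirs, rel=1e-6)

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            es.rhat(self.make(np.zeros((1, 100))))


class TestSummaries:
    def test_degenerate_draws(self):
        d = es.PosteriorDraws(draws=np.full((2, 100, 1), 4.2), names=["x0"])
        s = es.summarize(d)
        assert s.loc["x0", "map"] == 4.2
        assert s.loc["x0", "hdi_low"] == s.loc["x0", "hdi_high"] == 4.2

    def test_normal_hdi(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, (4, 2500, 1))
        s = es.summarize(es.PosteriorDraws(draws=x, names=["x0"]))
        assert s.loc["x0", "hdi_low"] == pytest.approx(-1.96, abs=0.08)
        assert s.loc["x0", "hdi_high"] == pytest.approx(1.96, abs=0.08)
        assert abs(s.loc["x0", "map"]) < 0.15

    def test_exponential_hdi_left_anchored(self):
        rng = np.random.default_rng(4)
        x = rng.exponential(1.0, 20000)
        lo, hi = es.hdi(x, 0.95)
        eq_lo, eq_hi = np.quantile(x, [0.025, 0.975])
        assert lo < 0.01
        assert (hi - lo) < (eq_hi - eq_lo)

    def test_hdi_matches_arviz(self):
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(5)
        x = rng.gamma(2.0, 1.0, 5000)
        lo, hi = es.hdi(x, 0.95)
        ref = az.hdi(x, hdi_prob=0.95)
        # conventions differ by one draw in the window size, so agreement
        # is to the local draw spacing rather than exact
        assert lo == pytest.approx(float(ref[0]), abs=0.02)
        assert hi == pytest.approx(float(ref[1]), abs=0.02)

    def test_map_inside_hdi(self, small_fit):
        s = small_fit.summary_
        inside = (s["map"] >= s["hdi_low"]) & (s["map"] <= s["hdi_high"])
        assert inside.all()

    def test_invalid_mass(self):
        with pytest.raises(ValueError):
            es.hdi([1.0, 2.0], 1.5)


class TestSampler:
    def test_no_data_posterior_equals_prior(self):
        # with zero rows the sampler must reproduce the prior marginals
        X = pd.DataFrame(np.empty((0, 25)), columns=FIXED_EFFECT_LABELS)
        prior = es.PriorSpec(sigma_focal=0.068)
        model = es.BayesianGrowthModel(prior=prior, n_chains=4, n_draws=1500,
                                       n_warmup=500, random_state=12)
        model.fit(X, np.empty(0), groups=np.empty(0, dtype=int))
        focal = model.draws_.pooled("LS x education")
        ks = stats.kstest(focal, stats.norm(0, 0.068).cdf).statistic
        assert ks < 0.03  # exact conjugate draws: iid from the prior
        inter = model.draws_.pooled("Intercept")
        ks_i = stats.kstest(inter, stats.norm(50, 20).cdf).statistic
        assert ks_i < 0.03
        # MH-sampled scale parameter against the half-Cauchy(0, 10) prior
        sd0 = model.draws_.pooled("SD intercept")
        ks_s = stats.kstest(sd0, stats.halfcauchy(scale=10).cdf).statistic
        assert ks_s < 0.1
        rho = model.draws_.pooled("Correlation (intercept, slope)")
        ks_r = stats.kstest(rho, stats.uniform(-1, 2).cdf).statistic
        assert ks_r < 0.1

    def test_posterior_means_near_truth(self, main_fit, recovery_world):
        s = main_fit.summary_
        truth = recovery_world["truth_vector"]
        for name in ["Intercept", "Linear slope (LS)",
                     "Quadratic slope (QS)", "Education"]:
            z = (s.loc[name, "mean"] - truth[name]) / s.loc[name, "sd"]
            assert abs(z) < 3.0, name

    def test_information_scaling_on_duplicated_data(self, small_world):
        # duplicating every person shrinks posterior SDs by about 1/sqrt(2)
        prep = small_world["prepared"]
        model1 = es.BayesianGrowthModel(n_chains=4, n_draws=500,
                                        n_warmup=500, random_state=21)
        model1.fit_prepared(prep)
        X2 = pd.concat([prep.X, prep.X], ignore_index=True)
        y2 = np.concatenate([prep.y, prep.y])
        ids2 = np.concatenate([prep.person_ids, prep.person_ids + 10_000])
        model2 = es.BayesianGrowthModel(n_chains=4, n_draws=500,
                                        n_warmup=500, random_state=22)
        model2.fit(X2, y2, groups=ids2)
        ratio = (model2.summary_.loc["Linear slope (LS)", "sd"]
                 / model1.summary_.loc["Linear slope (LS)", "sd"])
        assert ratio == pytest.approx(1 / np.sqrt(2), abs=0.12)

    def test_determinism(self, small_world):
        prep = small_world["prepared"]
        kw = dict(n_chains=2, n_draws=100, n_warmup=100, random_state=33)
        a = es.BayesianGrowthModel(**kw).fit_prepared(prep).draws_
        b = es.BayesianGrowthModel(**kw).fit_prepared(prep).draws_
        assert np.array_equal(a.draws, b.draws)

    def test_sd_draws_positive_rho_bounded(self, small_fit):
        d = small_fit.draws_
        for name in ("SD intercept", "SD linear slope", "Residual error"):
            assert (d.pooled(name) > 0).all()
        assert (np.abs(d.pooled("Correlation (intercept, slope)")) <= 1).all()

    def test_parameter_names_match_truth_table(self, small_fit):
        table = es.truth_table(es.TrueParameters())
        assert small_fit.param_names_ == list(table.index)

    def test_get_set_params_roundtrip(self):
        m = es.BayesianGrowthModel(n_draws=10)
        m.set_params(n_chains=2)
        assert m.get_params()["n_chains"] == 2
        with pytest.raises(ValueError):
            m.set_params(bogus=1)

    def test_draws_csv_roundtrip(self, small_fit, tmp_path):
        small_fit.draws_.save(tmp_path / "fit")
        df = pd.read_csv(tmp_path / "fit_draws.csv")
        assert len(df) == small_fit.draws_.n_chains * small_fit.draws_.n_draws
        assert "LS x education" in df.columns
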