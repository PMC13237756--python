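"""Bayesian LMM machinery: design building, Gibbs sampler, summaries, slopes."""

import numpy as np
import pandas as pd
import pytest

from restalpha.bayes import (
    DesignMatrices,
    ModelSpec,
    PosteriorDraws,
    build_design,
    delta_over_range,
    diagnostics,
    effective_sample_size,
    evidence_stratum,
    gibbs_sample,
    marginal_slopes,
    posterior_predictive_check,
    sleep_slope_draws,
    split_rhat,
    summarize,
)
from restalpha.geometry import build_default_layout
from restalpha.simulate import GenerativeParams, generate_alpha_table, generate_cohort


@pytest.fixture(scope="module")
def small_table():
    layout = build_default_layout()
    params = GenerativeParams(seed=42, sigma_noise=0.2, sigma_participant=0.3)
    cohort = generate_cohort(6, 6, params)
    return generate_alpha_table(cohort, layout, params)


@pytest.fixture(scope="module")
def model3_fit(small_table):
    spec = ModelSpec.for_model(3)
    design = build_design(small_table, spec)
    draws = gibbs_sample(design, spec, chains=2, iterations=600, warmup=300, seed=11)
    return spec, design, draws


class TestBuildDesign:
    @pytest.mark.parametrize(
        "model_id,n_cols",
        [(1, 10), (2, 10), (3, 12), (4, 15), (5, 15), (6, 15), (7, 15)],
    )
    def test_column_counts(self, small_table, model_id, n_cols):
        design = build_design(small_table, ModelSpec.for_model(model_id))
        assert len(design.columns) == n_cols
        assert len(set(design.columns)) == n_cols

    def test_model3_columns_exact(self, small_table):
        design = build_design(small_table, ModelSpec.for_model(3))
        assert design.columns == (
            "Intercept", "Sleep", "Group", "Sleep:Group", "Eyes",
            "ML", "AP", "IS", "ML:AP", "ML:IS", "AP:IS", "ML:AP:IS",
        )

    def test_unknown_term_rejected(self, small_table):
        with pytest.raises(ValueError, match="Weather"):
            build_design(small_table, ModelSpec(terms=("Sleep x Weather",)))

    def test_reference_coding(self, small_table):
        design = build_design(small_table, ModelSpec.for_model(3))
        g = design.feature_values["Group"]
        e = design.feature_values["Eyes"]
        abst = small_table["group"] == "abstinent"
        assert np.all(g[abst.to_numpy()] == 0.0)
        assert np.all(e[(small_table["condition"] == "closed").to_numpy()] == 0.0)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            build_design(pd.DataFrame(), ModelSpec.for_model(1))


def ridge_design(rng, n=400, p=3):
    X = np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))])
    beta = np.array([1.0, -0.5, 0.25])
    y = X @ beta + rng.normal(0, 0.7, size=n)
    feats = {k: np.zeros(n) for k in ("Sleep", "Group", "Eyes", "ML", "AP", "IS")}
    return DesignMatrices(
        y=y, X=X, columns=("Intercept", "Sleep", "Group"),
        participant_index=np.zeros(n, dtype=int), participants=("p0",),
        feature_values=feats,
    )


class TestGibbsSampler:
    def test_matches_closed_form_ridge_posterior(self, rng):
        design = ridge_design(rng)
        spec = ModelSpec(terms=())
        sigma = 0.7
        draws = gibbs_sample(
            design, spec, chains=2, iterations=2500, warmup=500,
            seed=3, fix_sigma=sigma, no_random_effects=True,
        )
        prec = design.X.T @ design.X / sigma**2 + np.eye(3) / 100.0
        cov = np.linalg.inv(prec)
        mean = cov @ design.X.T @ design.y / sigma**2
        flat = draws.flat_beta()
        n_draws = flat.shape[0]
        for j in range(3):
            mc_se = np.sqrt(cov[j, j]) / np.sqrt(n_draws)
            assert abs(flat[:, j].mean() - mean[j]) < 3 * mc_se
            assert flat[:, j].std() == pytest.approx(np.sqrt(cov[j, j]), rel=0.10)

    def test_prior_only_recovers_prior(self, rng):
        design = ridge_design(rng, n=50)
        spec = ModelSpec(terms=())
        draws = gibbs_sample(
            design, spec, chains=2, iterations=3000, warmup=100, seed=5, prior_only=True
        )
        flat = draws.flat_beta()
        n = flat.shape[0]
        assert abs(flat[:, 0].mean()) < 3 * 10 / np.sqrt(n)
        assert flat[:, 0].std() == pytest.approx(10.0, rel=0.05)

    def test_same_seed_identical_draws(self, small_table):
        spec = ModelSpec.for_model(2)
        design = build_design(small_table, spec)
        kw = dict(chains=2, iterations=60, warmup=30, seed=7)
        a = gibbs_sample(design, spec, **kw)
        b = gibbs_sample(design, spec, **kw)
        np.testing.assert_array_equal(a.beta, b.beta)
        np.testing.assert_array_equal(a.sigma, b.sigma)

    def test_single_chain_rejected(self, small_table):
        spec = ModelSpec.for_model(1)
        design = build_design(small_table, spec)
        with pytest.raises(ValueError, match="chains"):
            gibbs_sample(design, spec, chains=1)

    def test_nonfinite_response_rejected(self, small_table):
        spec = ModelSpec.for_model(1)
        design = build_design(small_table, spec)
        bad = DesignMatrices(
            y=np.where(np.arange(len(design.y)) == 0, np.nan, design.y),
            X=design.X, columns=design.columns,
            participant_index=design.participant_index,
            participants=design.participants, feature_values=design.feature_values,
        )
        with pytest.raises(ValueError, match="finite"):
            gibbs_sample(bad, spec)

    def test_variance_draws_positive(self, model3_fit):
        _, _, draws = model3_fit
        assert np.all(draws.sigma > 0)
        assert np.all(draws.sigma_u > 0)


class TestDiagnostics:
    def test_iid_chains_near_one(self, rng):
        chains = rng.normal(size=(4, 1000))
        assert 0.99 <= split_rhat(chains) <= 1.01
        ess = effective_sample_size(chains)
        assert abs(ess - 4000) / 4000 < 0.2

    def test_ar1_ess_matches_closed_form(self, rng):
        rho, n, m = 0.5, 20000, 4
        chains = np.empty((m, n))
        for c in range(m):
            e = rng.normal(size=n)
            x = np.empty(n)
            x[0] = e[0]
            for t in range(1, n):
                x[t] = rho * x[t - 1] + np.sqrt(1 - rho**2) * e[t]
            chains[c] = x
        ess = effective_sample_size(chains)
        expected = m * n * (1 - rho) / (1 + rho)
        assert abs(ess - expected) / expected < 0.25

    def test_shifted_chains_flagged(self, rng):
        chains = rng.normal(size=(4, 500))
        chains[0] += 3.0
        assert split_rhat(chains) > 1.1

    def test_agrees_with_arviz(self, rng):
        az = pytest.importorskip("arviz")
        rho, n = 0.6, 2000
        e = rng.normal(size=(4, n))
        chains = np.empty((4, n))
        chains[:, 0] = e[:, 0]
        for t in range(1, n):
            chains[:, t] = rho * chains[:, t - 1] + np.sqrt(1 - rho**2) * e[:, t]
        ours_rhat = split_rhat(chains)
        ours_ess = effective_sample_size(chains)
        ref_rhat = float(az.rhat(chains[None].transpose(1, 2, 0)[..., 0]))
        ref_ess = float(az.ess(chains[None].transpose(1, 2, 0)[..., 0]))
        assert ours_rhat == pytest.approx(ref_rhat, abs=0.02)
        assert ours_ess == pytest.approx(ref_ess, rel=0.2)

    def test_too_few_chains_rejected(self):
        with pytest.raises(ValueError):
            split_rhat(np.zeros((1, 100)))


class TestEvidenceStrata:
    @pytest.mark.parametrize(
        "pp,label",
        [
            (50.0, "none"), (50.4, "none"), (51.0, "anecdotal"), (74.0, "anecdotal"),
            (75.0, "moderate"), (90.0, "moderate"), (91.0, "strong"), (93.0, "strong"),
            (96.0, "strong"), (97.0, "very strong"), (99.0, "very strong"),
            (99.5, "extreme"), (100.0, "extreme"),
        ],
    )
    def test_strata_table(self, pp, label):
        assert evidence_stratum(pp) == label

    def test_below_half_rejected(self):
        with pytest.raises(ValueError, match="50"):
            evidence_stratum(49.0)

    def test_monotone_in_pp(self):
        order = ["none", "anecdotal", "moderate", "strong", "very strong", "extreme"]
        ranks = [order.index(evidence_stratum(pp)) for pp in np.linspace(50, 100, 401)]
        assert all(a <= b for a, b in zip(ranks, ranks[1:]))


class TestSummarize:
    def draws_from(self, values):
        v = np.asarray(values, dtype=float).reshape(2, -1, 1)
        n = v.shape[1]
        return PosteriorDraws(
            beta=v,
            sigma=np.ones((2, n)),
            sigma_u=np.ones((2, n)),
            u=np.zeros((2, n, 1)),
            columns=("Sleep",),
        )

    def test_all_positive_pp_100(self):
        s = summarize(self.draws_from([1, 2, 3, 4, 5, 6, 7, 8]))
        assert s.row("Sleep")["pp"] == 100.0
        assert s.row("Sleep")["stratum"] == "extreme"

    def test_balanced_signs_pp_50(self):
        s = summarize(self.draws_from([-1, -1, 1, 1, -2, -2, 2, 2]))
        row = s.row("Sleep")
        assert row["pp"] == 50.0
        assert row["stratum"] == "none"

    def test_three_quarters_positive(self):
        s = summarize(self.draws_from([-1, 1, 1, 1, -1, 1, 1, 1]))
        assert s.row("Sleep")["pp"] == 75.0

    def test_cri_brackets_median(self, model3_fit):
        _, _, draws = model3_fit
        t = summarize(draws).table
        assert (t["cri_lower"] <= t["median"]).all()
        assert (t["median"] <= t["cri_upper"]).all()
        assert t["pp"].between(50, 100).all()


def predict_eta(columns, beta, at):
    """Linear predictor from named interaction columns at a covariate point."""
    eta = 0.0
    for j, name in enumerate(columns):
        prod = 1.0
        if name != "Intercept":
            for f in name.split(":"):
                prod *= at[f]
        eta += beta[j] * prod
    return eta


class TestMarginalSlopes:
    def test_no_moderation_equals_sleep_coefficient(self, small_table):
        spec = ModelSpec.for_model(2)
        design = build_design(small_table, spec)
        draws = gibbs_sample(design, spec, chains=2, iterations=200, warmup=100, seed=2)
        tab = marginal_slopes(draws, design, moderator="Eyes")
        sleep_med = np.median(draws.flat_beta()[:, list(draws.columns).index("Sleep")])
        assert tab["slope_median"].nunique() == 1
        assert tab["slope_median"].iloc[0] == pytest.approx(sleep_med)

    def test_nonabstinent_slope_is_sum_of_draws(self, model3_fit):
        _, design, draws = model3_fit
        flat = draws.flat_beta()
        cols = list(draws.columns)
        expected = flat[:, cols.index("Sleep")] + flat[:, cols.index("Sleep:Group")]
        got = sleep_slope_draws(draws, {"Group": 1.0})
        np.testing.assert_allclose(got, expected, atol=1e-12)

    @pytest.mark.parametrize("model_id", [2, 3, 4, 5, 6, 7])
    def test_finite_difference_oracle(self, small_table, model_id):
        spec = ModelSpec.for_model(model_id)
        design = build_design(small_table, spec)
        draws = gibbs_sample(design, spec, chains=2, iterations=120, warmup=60, seed=4)
        beta_mean = draws.flat_beta().mean(axis=0)
        base = {"Sleep": 5.0, "Group": 1.0, "Eyes": 1.0, "ML": 0.3, "AP": -0.2, "IS": 0.8}
        slope = sleep_slope_draws(draws, base).mean()
        up = dict(base, Sleep=base["Sleep"] + 1.0)
        fd = predict_eta(draws.columns, beta_mean, up) - predict_eta(
            draws.columns, beta_mean, base
        )
        assert slope == pytest.approx(fd, abs=1e-8)

    def test_sleep_free_model_rejected(self, small_table):
        spec = ModelSpec.for_model(1)
        design = build_design(small_table, spec)
        draws = gibbs_sample(design, spec, chains=2, iterations=40, warmup=20, seed=1)
        with pytest.raises(ValueError, match="Sleep"):
            marginal_slopes(draws, design)

    def test_axis_strata_structure(self, model3_fit):
        _, design, draws = model3_fit
        tab = marginal_slopes(draws, design, moderator="AP")
        assert list(tab["moderator"].unique()) == ["Posterior", "Central", "Anterior"]
        assert set(tab["group"]) == {"Abstinent", "Non-Abstinent"}
        assert len(tab) == 6


class TestDeltaOverRange:
    def test_known_slope_and_range(self):
        out = delta_over_range(np.full(100, -0.2), np.array([3.0, 7.0, 10.0]))
        assert out["delta_median"] == pytest.approx(-1.4)

    def test_zero_slope(self):
        out = delta_over_range(np.zeros(50), np.array([0.0, 10.0]))
        assert out["delta_median"] == 0.0

    def test_symmetric_draws_scale(self, rng):
        slopes = -0.15 + 0.01 * rng.normal(size=4000)
        out = delta_over_range(slopes, np.array([0.0, 10.0]))
        assert out["delta_median"] == pytest.approx(-1.5, abs=0.02)

    def test_constant_sleep_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            delta_over_range(np.ones(10), np.full(5, 6.0))


class TestPosteriorPredictiveCheck:
    def test_self_consistent_fit_calibrated(self, model3_fit):
        _, design, draws = model3_fit
        report = posterior_predictive_check(draws, design, n_reps=200, seed=1)
        for _, row in report.iterrows():
            assert 0.05 <= row["p_upper"] <= 0.95

    def test_shifted_response_flagged(self, model3_fit):
        _, design, draws = model3_fit
        shifted = DesignMatrices(
            y=design.y + 10.0, X=design.X, columns=design.columns,
            participant_index=design.participant_index,
            participants=design.participants, feature_values=design.feature_values,
        )
        report = posterior_predictive_check(draws, shifted, n_reps=200, seed=1)
        mean_row = report[report["statistic"] == "mean"].iloc[0]
        assert mean_row["p_upper"] < 0.01

    def test_zero_reps_empty(self, model3_fit):
        _, design, draws = model3_fit
        assert posterior_predictive_check(draws, design, n_reps=0).empty


def test_diagnostics_frame_covers_all_fixed_effects(model3_fit):
    _, _, draws = model3_fit
    d = diagnostics(draws)
    assert list(d["parameter"]) == list(draws.columns)
    assert (d["ess"] > 0).all()
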