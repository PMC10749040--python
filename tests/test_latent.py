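import math

import numpy as np
import pandas as pd
import pytest

from racemix import latent, names, synth
from racemix.exceptions import SingularDesignError
from racemix.latent import (
    effect_size_pct,
    fit_latent_model,
    fit_result_to_frame,
    latent_covariates,
    model_spec,
    monte_carlo_pvalues,
    residual_qq,
    significance_stars,
)
from conftest import make_degenerate


class TestLatentCovariates:
    @pytest.mark.parametrize(
        "gender,natal,expected",
        [
            ("non-binary", "male", (1, 1, 0, 1)),
            ("non-binary", "female", (-1, 0, 1, 1)),
            ("female", "female", (0, 0, 0, 0)),
            ("male", "male", (0, 0, 0, 0)),
            ("male", "female", (0, 0, 0, 0)),
        ],
    )
    def test_values(self, gender, natal, expected):
        assert latent_covariates(gender, natal) == expected

    def test_is_nb_is_sum(self):
        for g in ("male", "female", "non-binary"):
            for s in ("male", "female"):
                nbp, nbm, nbf, nb = latent_covariates(g, s)
                assert nb == nbm + nbf
                assert nbp in (-1, 0, 1)

    def test_invalid_rejected(self):
        with pytest.raises(ValueError):
            latent_covariates("other", "male")
        with pytest.raises(ValueError):
            latent_covariates("male", "intersex")


class TestModelSpec:
    def test_four_models(self):
        assert model_spec(1).nb_terms == ("nb_predictor",)
        assert model_spec(2).sex_term == "gender_id"
        assert model_spec(3).nb_terms == ("is_nbm", "is_nbf")
        assert model_spec(4).nb_terms == ("is_nb",)

    def test_unknown_rejected(self):
        with pytest.raises(ValueError):
            model_spec(5)


def _ols_oracle(df: pd.DataFrame, spec) -> dict[str, float]:
    """Brute-force least squares on the completed data (independent path).

    Builds the design by hand with pandas/numpy and solves via lstsq; natal
    sex is taken from the degenerate prob_male.
    """
    natal_female = (df["prob_male"] == 0.0).astype(float)
    nb = (df["gender_id"] == "non-binary").astype(float)
    age_c = df["age"].astype(float) - 40.0
    cols = {"intercept": np.ones(len(df))}
    events = sorted(df["event"].unique())
    for e in events[1:]:
        cols[f"event[{e}]"] = (df["event"] == e).astype(float).to_numpy()
    if spec.sex_term == "natal_sex":
        cols["natal_female"] = natal_female.to_numpy()
    else:
        cols["gender_female"] = (df["gender_id"] == "female").astype(float).to_numpy()
        cols["gender_nonbinary"] = nb.to_numpy()
    cols["age_c"] = age_c.to_numpy()
    cols["age_c2"] = (age_c**2).to_numpy()
    for term in spec.nb_terms:
        if term == "nb_predictor":
            cols[term] = (nb * (1 - 2 * natal_female)).to_numpy()
        elif term == "is_nbm":
            cols[term] = (nb * (1 - natal_female)).to_numpy()
        elif term == "is_nbf":
            cols[term] = (nb * natal_female).to_numpy()
        elif term == "is_nb":
            cols[term] = nb.to_numpy()
    x = np.column_stack(list(cols.values()))
    y = np.log(df["time_seconds"].to_numpy())
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    return dict(zip(cols.keys(), beta))


class TestFitLatentModel:
    @pytest.mark.parametrize("model_id", [1, 2, 3, 4])
    def test_degenerate_probs_match_ols_oracle(self, assigned, model_id):
        df = make_degenerate(assigned)
        spec = model_spec(model_id)
        fit = fit_latent_model(df, spec)
        oracle = _ols_oracle(df, spec)
        for term, value in oracle.items():
            assert fit.coefficients[term] == pytest.approx(value, abs=1e-8), term

    def test_no_nonbinary_reduces_to_plain_ols(self, assigned):
        df = make_degenerate(assigned)
        df = df[df["gender_id"] != "non-binary"].reset_index(drop=True)
        with pytest.warns(UserWarning, match="structurally zero"):
            fit = fit_latent_model(df, model_spec(1))
        assert fit.dropped_terms == ("nb_predictor",)
        assert math.isnan(fit.coefficients["nb_predictor"])
        oracle = _ols_oracle(df, model_spec(4))
        oracle.pop("is_nb", None)
        for term, value in oracle.items():
            assert fit.coefficients[term] == pytest.approx(value, abs=1e-8)

    def test_loglik_nondecreasing(self, assigned):
        fit = fit_latent_model(assigned, model_spec(1))
        trace = np.asarray(fit.loglik_trace)
        assert np.all(np.diff(trace) >= -1e-8)

    def test_fractional_probs_near_degenerate_truth(self, assigned):
        # blurring a few probabilities should barely move the estimates
        fit_frac = fit_latent_model(assigned, model_spec(4))
        fit_deg = fit_latent_model(make_degenerate(assigned), model_spec(4))
        assert fit_frac.coefficients["natal_female"] == pytest.approx(
            fit_deg.coefficients["natal_female"], abs=0.02
        )

    def test_missing_prob_rejected(self, assigned):
        df = assigned.copy()
        df.loc[df.index[0], "prob_male"] = np.nan
        with pytest.raises(ValueError):
            fit_latent_model(df, model_spec(1))

    def test_rank_deficient_rejected(self, assigned):
        df = assigned.copy()
        df["age"] = 50  # age_c constant -> collinear with the intercept
        with pytest.raises(SingularDesignError):
            fit_latent_model(df, model_spec(1))

    def test_residual_sd_positive_and_close_to_truth(self, assigned, small_truth):
        fit = fit_latent_model(assigned, model_spec(4))
        assert fit.residual_sd > 0
        assert fit.residual_sd == pytest.approx(small_truth.sigma, rel=0.15)


class TestEffectSize:
    @pytest.mark.parametrize(
        "coef,pct,digits",
        [
            (0.12221, 13.00, 2),
            (0.03225, 3.278, 3),
            (-0.06803, -6.58, 2),
            (0.0, 0.0, 6),
        ],
    )
    def test_reference_values(self, coef, pct, digits):
        assert round(effect_size_pct(coef), digits) == pct

    def test_sd_context(self):
        # residual SD 0.20 on the log scale corresponds to a 22% change
        assert round(effect_size_pct(0.20)) == 22

    def test_stars(self):
        assert significance_stars(0.0005) == "***"
        assert significance_stars(0.005) == "**"
        assert significance_stars(0.02) == "*"
        assert significance_stars(0.07) == "(.)"
        assert significance_stars(0.5) == ""


class TestMonteCarloPvalues:
    def test_determinism(self, assigned):
        spec = model_spec(4)
        fit = fit_latent_model(assigned, spec)
        a = monte_carlo_pvalues(fit, assigned, spec, "is_nb", n_sims=50, seed=42)
        b = monte_carlo_pvalues(fit, assigned, spec, "is_nb", n_sims=50, seed=42)
        assert a == b

    def test_absent_term_rejected(self, assigned):
        spec = model_spec(4)
        fit = fit_latent_model(assigned, spec)
        with pytest.raises(ValueError):
            monte_carlo_pvalues(fit, assigned, spec, "nb_predictor", 10, 0)

    def test_overwhelming_effect_hits_add_one_bound(self, name_table):
        # enormous true sex effect + tiny noise: no null draw can beat it
        truth = synth.SyntheticTruth(
            n_athletes=150, frac_nonbinary=0.0, beta_female=2.0, sigma=0.01,
            event_log_means={"marathon": 9.7},
        )
        ath = synth.generate_athletes(truth, name_table, seed=1)
        res = synth.generate_race_results(ath, truth, races_per_athlete=1,
                                          seed=2, marathon_frac=1.0)
        df, _ = names.assign_probabilities(res, None, name_table)
        df = df[df["prob_source"] != "none"].reset_index(drop=True)
        spec = model_spec(4)
        with pytest.warns(UserWarning):
            fit = fit_latent_model(df, spec)
        p1, p2 = monte_carlo_pvalues(fit, df, spec, "natal_female", n_sims=19, seed=3)
        assert p2 == pytest.approx(1 / 20)
        assert p1 == pytest.approx(1 / 20)

    def test_pvalues_in_unit_interval(self, assigned):
        spec = model_spec(1)
        fit = fit_latent_model(assigned, spec)
        p1, p2 = monte_carlo_pvalues(fit, assigned, spec, "nb_predictor",
                                     n_sims=30, seed=5)
        for p in (p1, p2):
            assert 0 < p <= 1


class TestResidualQq:
    def test_single_point_at_zero_quantile(self):
        df = pd.DataFrame([
            {"name": "a", "event": "marathon", "date": "2022-01-01", "age": 40,
             "gender_id": "male", "time_seconds": 10000.0, "prob_male": 1.0},
            {"name": "b", "event": "marathon", "date": "2022-01-01", "age": 41,
             "gender_id": "female", "time_seconds": 11000.0, "prob_male": 0.0},
            {"name": "c", "event": "marathon", "date": "2022-01-01", "age": 42,
             "gender_id": "male", "time_seconds": 10500.0, "prob_male": 1.0},
            {"name": "d", "event": "marathon", "date": "2022-01-01", "age": 43,
             "gender_id": "non-binary", "time_seconds": 10200.0, "prob_male": 0.7},
        ])
        fit = fit_latent_model(df, latent.model_spec(4))
        qq = residual_qq(fit, df, known_sex_only=True)
        assert qq.shape == (3, 2)
        qq1 = residual_qq(fit, df.iloc[:1], known_sex_only=True)
        assert qq1.shape == (1, 2)
        assert qq1[0, 0] == pytest.approx(0.0)

    def test_quantiles_antisymmetric(self, assigned):
        fit = fit_latent_model(assigned, model_spec(4))
        qq = residual_qq(fit, assigned, known_sex_only=True)
        q = qq[:, 0]
        assert np.allclose(q, -q[::-1], atol=1e-12)

    def test_known_sex_only_filters(self, assigned):
        fit = fit_latent_model(assigned, model_spec(4))
        qq_known = residual_qq(fit, assigned, known_sex_only=True)
        qq_all = residual_qq(fit, assigned, known_sex_only=False)
        n_known = int(((assigned["prob_male"] == 0) | (assigned["prob_male"] == 1)).sum())
        assert qq_known.shape[0] == n_known
        assert qq_all.shape[0] == len(assigned)

    def test_normal_residuals_track_quantiles(self, name_table):
        truth = synth.SyntheticTruth(n_athletes=4000, frac_nonbinary=0.0,
                                     event_log_means={"marathon": 9.7})
        ath = synth.generate_athletes(truth, name_table, seed=8)
        res = synth.generate_race_results(ath, truth, races_per_athlete=1,
                                          seed=9, marathon_frac=1.0)
        df, _ = names.assign_probabilities(res, None, name_table)
        df = df[df["prob_source"] != "none"].reset_index(drop=True)
        with pytest.warns(UserWarning):
            fit = fit_latent_model(df, model_spec(4))
        qq = residual_qq(fit, df, known_sex_only=True)
        scaled = qq[:, 1] / fit.residual_sd
        inner = np.abs(qq[:, 0]) < 2.0  # tails of a finite sample are noisy
        assert np.max(np.abs(scaled[inner] - qq[inner, 0])) < 0.15


class TestSerialization:
    def test_frame_layout(self, assigned):
        spec = model_spec(4)
        fit = fit_latent_model(assigned, spec)
        fit.p_one_tailed["is_nb"], fit.p_two_tailed["is_nb"] = 0.03, 0.06
        frame = fit_result_to_frame(fit)
        assert list(frame.columns) == [
            "Parameter", "Coefficient", "Effect size",
            "P(one-tailed)", "P(two-tailed)", "Stars",
        ]
        assert not frame["Parameter"].str.startswith("event[").any()
        row = frame.set_index("Parameter").loc["is_nb"]
        assert row["Stars"] == "(.)"
        # effect column is always the exponential transform of the coefficient
        for _, r in frame.iterrows():
            assert r["Effect size"] == pytest.approx(
                effect_size_pct(r["Coefficient"])
            )
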