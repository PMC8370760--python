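"""Mixed-model fitting, bootstrap machinery, slopes, FDR, between-subject."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from mvreact.inference import (ModelSpec, attach_lure_accuracy,
                               between_subject_model, bootstrap_inference,
                               calcarine_spec, ci_from_draws, fdr_correct,
                               feature_hc_spec, fit_glmm, image_hc_spec,
                               level_average, paired_difference,
                               pvalue_from_draws, simple_slopes)


def _logistic_data(rng, n_subj=12, per_subj=40, beta=(0.4, 0.8, -0.5, 0.6),
                   subj_sd=0.0, pair_sd=0.0, n_pair=15):
    """Trial table from a known logistic model (optionally with intercepts)."""
    b0, b_x, b_int, b_probe = beta
    subj_u = rng.normal(0, subj_sd, n_subj)
    pair_u = rng.normal(0, pair_sd, n_pair)
    rows = []
    for s in range(n_subj):
        mod = rng.standard_normal()
        for t in range(per_subj):
            x = rng.standard_normal()
            pair = rng.integers(n_pair)
            probe = t % 2
            eta = (b0 + b_x * x + b_int * x * mod + b_probe * probe
                   + subj_u[s] + pair_u[pair])
            y = int(rng.random() < 1 / (1 + np.exp(-eta)))
            rows.append({"subject": s, "trial": t, "pair": int(pair),
                         "m": x, "lure_acc": mod, "is_lure": probe,
                         "accuracy": y})
    return pd.DataFrame(rows)


SPEC_1M = ModelSpec(name="one_measure", measures=("m",))


class TestDesign:
    def test_feature_hc_term_count(self):
        # 1 intercept + 8 main + 8 interactions + probe control
        assert len(feature_hc_spec().term_names()) == 18

    def test_image_hc_term_count(self):
        assert len(image_hc_spec().term_names()) == 6

    def test_calcarine_three_way_term_count(self):
        # intercept + 8 HC + calcarine + 8 HCxCal + (8+1) xlure
        # + 8 three-way + probe
        assert len(calcarine_spec().term_names()) == 36

    def test_design_columns_are_products(self, rng):
        data = _logistic_data(rng, n_subj=3, per_subj=5)
        X = SPEC_1M.design(data)
        assert np.allclose(X["m:lure_acc"],
                           data["m"] * data["lure_acc"])
        assert np.allclose(X["intercept"], 1.0)


class TestGlmmFit:
    def test_forced_fixed_matches_statsmodels_logit(self, rng):
        import statsmodels.api as sm
        data = _logistic_data(rng)
        fit = fit_glmm(SPEC_1M, data, force_fixed=True)
        X = SPEC_1M.design(data).to_numpy()
        oracle = sm.Logit(data["accuracy"].to_numpy(), X).fit(disp=0)
        assert np.allclose(fit.coefficients.to_numpy(), oracle.params,
                           atol=1e-4)

    def test_recovers_planted_coefficients(self, rng):
        data = _logistic_data(rng, n_subj=30, per_subj=60, subj_sd=0.4,
                              pair_sd=0.3)
        fit = fit_glmm(SPEC_1M, data)
        assert fit.coefficients["m"] == pytest.approx(0.8, abs=0.25)
        assert fit.coefficients["m:lure_acc"] == pytest.approx(-0.5, abs=0.25)
        assert 0.0 < fit.var_subject < 1.0

    def test_binary_response_required(self, rng):
        data = _logistic_data(rng, n_subj=3, per_subj=5)
        data.loc[0, "accuracy"] = 0.5
        with pytest.raises(ValueError):
            fit_glmm(SPEC_1M, data)

    @pytest.mark.skipif(shutil.which("Rscript") is None,
                        reason="R not available")
    def test_matches_lme4_glmer_on_crossed_design(self, rng, tmp_path):
        """Independent cross-check of the Laplace fit against lme4."""
        data = _logistic_data(np.random.default_rng(7), n_subj=20,
                              per_subj=30, subj_sd=0.5, pair_sd=0.3)
        fit = fit_glmm(SPEC_1M, data)
        csv = tmp_path / "d.csv"
        data.to_csv(csv, index=False)
        script = (
            'suppressMessages(library(lme4));'
            f'd <- read.csv("{csv}");'
            'm <- glmer(accuracy ~ m + m:lure_acc + is_lure + (1|subject)'
            ' + (1|pair), data=d, family=binomial);'
            'cat(fixef(m)[c("(Intercept)","m","m:lure_acc","is_lure")], "\\n")'
        )
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, timeout=300)
        assert out.returncode == 0, out.stderr
        ref = np.array([float(x) for x in out.stdout.split()])
        mine = fit.coefficients[["intercept", "m", "m:lure_acc",
                                 "is_lure"]].to_numpy()
        assert np.allclose(mine, ref, atol=0.05)


class TestBootstrapMachinery:
    def _fit_with_draws(self, draws):
        fit = fit_glmm(SPEC_1M, _logistic_data(np.random.default_rng(0),
                                               n_subj=4, per_subj=10),
                       force_fixed=True)
        fit.draws = draws
        fit.B = len(draws)
        return fit

    def test_pvalues_match_counting_oracle(self):
        d = np.array([-0.2, 0.1, 0.3, 0.5, 0.7, 0.9, 1.1, 1.3, -0.1, 0.0])
        B = len(d)
        lo = np.sum(d <= 0) / B   # 3/10
        hi = np.sum(d >= 0) / B   # 8/10
        assert pvalue_from_draws(d, tail="greater") == pytest.approx(lo)
        assert pvalue_from_draws(d, tail="less") == pytest.approx(hi)
        assert pvalue_from_draws(d, tail="two") == pytest.approx(2 * lo)

    def test_empty_tail_floors_at_one_over_B(self):
        d = np.full(200, 0.4)
        assert pvalue_from_draws(d, tail="greater") == 1.0 / 200

    def test_symmetric_draws_give_p_near_one(self, rng):
        d = np.concatenate([rng.standard_normal(500),
                            -rng.standard_normal(500)])
        assert pvalue_from_draws(d, tail="two") > 0.9

    def test_ci_quantiles_match_percentile_oracle(self, rng):
        draws = pd.DataFrame({"a": rng.standard_normal(1000)})
        ci = ci_from_draws(draws, 0.90)
        assert ci.loc["a", "lower"] == pytest.approx(
            np.quantile(draws["a"], 0.05, method="linear"), abs=1e-6)
        assert ci.loc["a", "upper"] == pytest.approx(
            np.quantile(draws["a"], 0.95, method="linear"), abs=1e-6)

    def test_parametric_bootstrap_centers_on_fit(self, rng):
        data = _logistic_data(rng, n_subj=10, per_subj=40)
        fit = fit_glmm(SPEC_1M, data, force_fixed=True)
        fit = bootstrap_inference(fit, B=150, rng=rng)
        assert fit.n_failed == 0
        assert fit.draws.shape == (150, len(fit.terms))
        assert fit.draws["m"].mean() == pytest.approx(
            fit.coefficients["m"], abs=3 * fit.draws["m"].std())

    def test_subject_resampling_scheme_runs(self, rng):
        data = _logistic_data(rng, n_subj=10, per_subj=30, subj_sd=0.4)
        fit = fit_glmm(SPEC_1M, data)
        fit = bootstrap_inference(fit, B=40, scheme="subjects", rng=rng)
        assert len(fit.draws) >= 36

    def test_unknown_scheme_rejected(self, rng):
        data = _logistic_data(rng, n_subj=4, per_subj=10)
        fit = fit_glmm(SPEC_1M, data, force_fixed=True)
        with pytest.raises(ValueError):
            bootstrap_inference(fit, B=10, scheme="banana", rng=rng)

    def test_paired_difference(self, rng):
        draws = pd.DataFrame({"a": rng.standard_normal(100) + 5.0,
                              "b": rng.standard_normal(100)})
        fit = self._fit_with_draws(draws)
        fit.coefficients = pd.Series({"a": 5.0, "b": 0.0})
        d, p = paired_difference(fit, "a", "b", tail="greater")
        assert np.allclose(d, draws["a"] - draws["b"])
        assert p == 1.0 / 100
        d_same, p_same = paired_difference(fit, "a", "a")
        assert np.all(d_same == 0) and p_same == 1.0
        with pytest.raises(KeyError):
            paired_difference(fit, "a", "zzz")


class TestSlopesAveragesFdr:
    def _fit(self, rng, coef, draws=None):
        data = _logistic_data(rng, n_subj=4, per_subj=10)
        fit = fit_glmm(SPEC_1M, data, force_fixed=True)
        fit.coefficients = pd.Series(coef)
        fit.draws = draws
        if draws is not None:
            fit.B = len(draws)
        return fit

    def test_zero_interaction_gives_flat_slopes(self, rng):
        fit = self._fit(rng, {"m": 0.4, "m:lure_acc": 0.0})
        out = simple_slopes(fit, terms=["m"])
        assert np.allclose(out["slope"], 0.4)

    def test_stated_linear_combination(self, rng):
        fit = self._fit(rng, {"m": 0.1, "m:lure_acc": 0.2})
        out = simple_slopes(fit, terms=["m"]).set_index("moderator_value")
        assert out.loc[1.0, "slope"] == pytest.approx(0.3)
        assert out.loc[-1.0, "slope"] == pytest.approx(-0.1)

    def test_drawwise_slopes_match_linear_combination_oracle(self, rng):
        draws = pd.DataFrame({"m": rng.standard_normal(200),
                              "m:lure_acc": rng.standard_normal(200)})
        fit = self._fit(rng, {"m": 0.0, "m:lure_acc": 0.0}, draws)
        out = simple_slopes(fit, terms=["m"]).set_index("moderator_value")
        oracle = (draws["m"] + draws["m:lure_acc"]).to_numpy()
        assert out.loc[1.0, "lower"] == pytest.approx(
            np.quantile(oracle, 0.05))
        assert out.loc[1.0, "p_two"] == pytest.approx(
            pvalue_from_draws(oracle, tail="two"))

    def test_level_average_point_and_drawwise(self, rng):
        terms = {f"phc_{lvl}:lure_acc": c for lvl, c in
                 zip(("low", "mid", "high", "semantic"),
                     (0.2, -0.2, 0.1, -0.1))}
        draws = pd.DataFrame({t: rng.standard_normal(100) for t in terms})
        fit = self._fit(rng, terms, draws)
        out = level_average(fit, "phc")
        assert out["estimate"] == pytest.approx(0.0)
        assert np.allclose(out["draws"], draws.mean(axis=1))
        with pytest.raises(KeyError):
            level_average(fit, "ahc")

    def test_bh_by_hand(self):
        p = pd.Series({"a": 0.01, "b": 0.02, "c": 0.03})
        adj = fdr_correct(p, family=["a", "b", "c"])
        assert np.allclose(adj, [0.03, 0.03, 0.03])

    def test_equal_pvalues_unchanged(self):
        p = pd.Series({"a": 0.2, "b": 0.2, "c": 0.2})
        assert np.allclose(fdr_correct(p, family=list(p.index)), 0.2)

    def test_adjusted_at_least_raw_and_excluded_pass_through(self, rng):
        p = pd.Series({"low": 0.001, "mid": 0.04, "high": 0.02,
                       "semantic": 0.9})
        adj = fdr_correct(p, family=list(p.index), exclude=("low",))
        assert adj["low"] == 0.001            # prioritized, unadjusted
        assert (adj[["mid", "high", "semantic"]]
                >= p[["mid", "high", "semantic"]] - 1e-12).all()

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            fdr_correct(pd.Series({"a": 1.5}), family=["a"])


class TestBetweenSubject:
    def _trials(self, rng, n_subj=20, per=40, slope=0.0):
        rows = []
        skills = rng.standard_normal(n_subj)
        for s in range(n_subj):
            for t in range(per):
                lure = t % 2
                react = rng.standard_normal() + slope * skills[s]
                p = 1 / (1 + np.exp(-(1.0 + 0.8 * skills[s] * lure)))
                rows.append({"subject": s, "trial": t, "is_lure": lure,
                             "accuracy": int(rng.random() < p),
                             "m1": react,
                             "m2": rng.standard_normal()})
        return pd.DataFrame(rows)

    def test_correctness_filter_changes_means_by_known_amount(self, rng):
        trials = self._trials(rng, n_subj=12)
        fit = between_subject_model(trials, measures=("m1", "m2"), B=10,
                                    rng=rng)
        sub = fit.subject_means
        g = trials[trials["subject"] == 0]
        assert sub.loc[sub["subject"] == 0, "m1"].iloc[0] == pytest.approx(
            g[g["accuracy"] == 1]["m1"].mean())
        # unfiltered mean differs exactly by the incorrect trials' pull
        assert not np.isclose(g["m1"].mean(),
                              g[g["accuracy"] == 1]["m1"].mean()) \
            or (g["accuracy"] == 1).all()

    def test_planted_between_subject_slope_recovered(self):
        rng = np.random.default_rng(5)
        trials = self._trials(rng, n_subj=25, per=60, slope=1.0)
        fit = between_subject_model(trials, measures=("m1", "m2"), B=200,
                                    rng=rng)
        assert fit.coefficients["m1"] > 0
        assert fit.pvalues("two")["m1"] < 0.05

    def test_null_coefficients_cover_zero(self):
        rng = np.random.default_rng(9)
        cover = 0
        for rep in range(10):
            trials = self._trials(np.random.default_rng(100 + rep),
                                  n_subj=20, per=40, slope=0.0)
            fit = between_subject_model(trials, measures=("m1", "m2"), B=100,
                                        rng=rng)
            ci = fit.ci(0.90)
            cover += ci.loc["m1", "lower"] <= 0 <= ci.loc["m1", "upper"]
        assert cover >= 8

    def test_too_few_subjects_raise(self, rng):
        trials = self._trials(rng, n_subj=3)
        with pytest.raises(ValueError):
            between_subject_model(trials, measures=("m1", "m2"), B=10,
                                  rng=rng)


def test_attach_lure_accuracy_anchors(rng):
    trials = pd.DataFrame({
        "subject": np.repeat([0, 1], 4),
        "is_lure": [1, 1, 0, 0] * 2,
        "accuracy": [1, 1, 0, 1, 1, 0, 1, 1],
    })
    out, mu, sd = attach_lure_accuracy(trials)
    assert mu == pytest.approx(0.75)         # subject means 1.0 and 0.5
    assert sd == pytest.approx(0.25)
    assert np.allclose(sorted(out["lure_acc"].unique()), [-1.0, 1.0])
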