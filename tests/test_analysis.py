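"""Tests of the statistical pipeline: McNemar, agreement, mixed logit."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.special import comb

from treatthresh import (
    SimulationConfig,
    build_agreement_table,
    compare_models,
    fit_random_intercept_logit,
    main_effects,
    mcnemar_exact,
    mcnemar_from_counts,
    simulate_cohort,
    threshold_table,
    treat_proportions,
)
from treatthresh.demo import demo_cohort


def enumeration_p_value(b, c):
    """Brute-force two-sided exact McNemar p: under the null the discordant
    count is Binomial(b+c, 1/2); sum the probability of every outcome no
    more probable than the observed one."""
    n = b + c
    if n == 0:
        return 1.0
    observed = comb(n, b, exact=True)
    total = sum(comb(n, k, exact=True) for k in range(n + 1) if comb(n, k, exact=True) <= observed)
    return min(1.0, total / 2**n)


class TestMcNemar:
    def test_matches_enumeration_for_all_small_tables(self):
        for n in range(0, 13):
            for b in range(n + 1):
                c = n - b
                result = mcnemar_from_counts(b, c)
                assert result.p_value == pytest.approx(
                    enumeration_p_value(b, c), abs=1e-12
                ), (b, c)

    def test_one_sided_discordance_example(self):
        assert mcnemar_from_counts(10, 0).p_value == pytest.approx(2 * 0.5**10)

    def test_balanced_discordance_gives_p_one(self):
        assert mcnemar_from_counts(1, 1).p_value == 1.0

    def test_no_discordance_is_degenerate(self):
        result = mcnemar_from_counts(0, 0)
        assert result.p_value == 1.0
        assert result.degenerate

    def test_symmetric_in_b_and_c(self):
        assert mcnemar_from_counts(3, 8).p_value == mcnemar_from_counts(8, 3).p_value

    def test_paired_vectors(self):
        first = pd.Series([1, 1, 1, 0, 0], index=list("abcde"))
        second = pd.Series([0, 1, 1, 0, 1], index=list("abcde"))
        result = mcnemar_exact(first, second)
        assert (result.b, result.c) == (1, 1)

    def test_mismatched_participants_is_a_pairing_error(self):
        first = pd.Series([1, 0], index=["a", "b"])
        second = pd.Series([1, 0], index=["a", "c"])
        with pytest.raises(ValueError, match="pairing"):
            mcnemar_exact(first, second)


class TestTreatProportions:
    def test_demo_cohort_reproduces_expected_margins(self):
        props = treat_proportions(demo_cohort()).set_index(["condition", "risk_level"])
        assert props.loc[("PE", "base"), "pct_treat"] == 98
        assert props.loc[("PE", "high_threshold"), "pct_treat"] == 39
        assert props.loc[("PE", "low_threshold"), "pct_treat"] == 100
        assert props.loc[("AML", "base"), "pct_treat"] == 66
        assert props.loc[("AML", "high_threshold"), "pct_treat"] == 20
        assert props.loc[("AML", "low_threshold"), "pct_treat"] == 88

    def test_all_treat_table(self):
        table = demo_cohort()
        table["decision"] = 1
        props = treat_proportions(table)
        assert (props["pct_treat"] == 100).all()

    def test_main_effects_pairs_on_participant(self):
        effects = main_effects(demo_cohort())
        assert set(effects["condition"]) == {"PE", "AML"}
        assert effects["p_value"].between(0, 1).all()

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            treat_proportions(demo_cohort().iloc[0:0])


class TestAgreementTable:
    def test_three_rows_per_response(self, vignettes, noise_free_eut_cohort):
        responses, _ = noise_free_eut_cohort
        agreement = build_agreement_table(
            responses, threshold_table(responses, vignettes)
        )
        assert len(agreement) == 3 * len(responses)
        per_key = agreement.groupby(["participant_id", "vignette_id"]).size()
        assert (per_key == 3).all()

    def test_single_response_flags(self, vignettes):
        responses = demo_cohort().iloc[[0]].copy()
        thresholds = pd.DataFrame(
            {
                "participant_id": responses["participant_id"].values,
                "vignette_id": responses["vignette_id"].values,
                "p": [0.5],
                "t_eut": [0.1],
                "t_rg": [0.6],
                "gamma": [0.0],
                "t_dp": [0.1],
            }
        )
        responses["decision"] = 1
        agreement = build_agreement_table(responses, thresholds)
        flags = agreement.set_index("model")["agree"]
        assert flags["EUT"] and not flags["regret"]

    def test_missing_threshold_names_the_row(self, vignettes, noise_free_eut_cohort):
        responses, _ = noise_free_eut_cohort
        thresholds = threshold_table(responses, vignettes).iloc[1:]
        with pytest.raises(KeyError, match="P001"):
            build_agreement_table(responses, thresholds)


@pytest.fixture(scope="module")
def dual_agreement(vignettes, dual_cohort):
    responses, _ = dual_cohort
    return build_agreement_table(responses, threshold_table(responses, vignettes))


class TestMixedLogit:
    def test_zero_variance_matches_pooled_logistic(self, dual_agreement):
        """With the random-intercept variance pinned at zero the fit must
        coincide with the ordinary pooled logistic regression."""
        reduced = fit_random_intercept_logit(
            dual_agreement, var_fixed=0.0, compute_null=False
        )
        X = np.column_stack(
            [
                np.ones(len(dual_agreement)),
                (dual_agreement["model"] == "regret").to_numpy(float),
                (dual_agreement["model"] == "dual").to_numpy(float),
            ]
        )
        pooled = sm.Logit(dual_agreement["agree"].astype(float), X).fit(disp=0)
        np.testing.assert_allclose(
            reduced.fit.params, pooled.params.values, atol=1e-3
        )

    def test_matches_lme4_glmer_oracle(self, dual_agreement, tmp_path):
        """Independent cross-check of the adaptive-quadrature fit against
        R's lme4::glmer with the same quadrature order."""
        csv = tmp_path / "agreement.csv"
        out = tmp_path / "glmer.txt"
        df = dual_agreement.copy()
        df["agree"] = df["agree"].astype(int)
        df.to_csv(csv, index=False)
        script = textwrap.dedent(
            f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            d$model <- factor(d$model, levels = c("EUT", "regret", "dual"))
            fit <- glmer(agree ~ model + (1 | participant_id), data = d,
                         family = binomial, nAGQ = 15)
            writeLines(c(format(fixef(fit), digits = 10),
                         format(sqrt(unlist(VarCorr(fit))), digits = 10),
                         format(as.numeric(logLik(fit)), digits = 10)),
                       "{out}")
            """
        )
        subprocess.run(["Rscript", "-e", script], check=True, capture_output=True)
        values = [float(x) for x in out.read_text().split()]
        ours = fit_random_intercept_logit(dual_agreement, compute_null=False)
        np.testing.assert_allclose(ours.fit.params, values[:3], atol=5e-3)
        assert ours.sigma == pytest.approx(values[3], abs=5e-3)
        assert ours.loglik == pytest.approx(values[4], abs=1e-2)

    def test_identical_agreement_patterns_give_unit_odds_ratios(self, vignettes):
        responses, _ = simulate_cohort(
            SimulationConfig(n_participants=25, generating_model="EUT", seed=21)
        )
        agreement = build_agreement_table(
            responses, threshold_table(responses, vignettes)
        )
        flat = agreement.copy()
        eut_flags = (
            flat[flat["model"] == "EUT"]
            .set_index(["participant_id", "vignette_id"])["agree"]
        )
        flat["agree"] = flat.apply(
            lambda r: eut_flags.loc[(r["participant_id"], r["vignette_id"])], axis=1
        )
        result = fit_random_intercept_logit(flat, compute_null=False)
        assert np.allclose(result.or_table["odds_ratio"], 1.0, atol=1e-4)

    def test_loglik_dominates_null(self, dual_agreement):
        result = fit_random_intercept_logit(dual_agreement)
        assert result.loglik >= result.null_loglik - 1e-6
        assert result.converged

    def test_needs_at_least_two_participants(self, dual_agreement):
        one = dual_agreement[dual_agreement["participant_id"] == "P001"]
        with pytest.raises(ValueError):
            fit_random_intercept_logit(one)


class TestCompareModels:
    def test_eut_generated_cohort_not_beaten_by_other_models(self, vignettes):
        responses, _ = simulate_cohort(
            SimulationConfig(
                n_participants=80, generating_model="EUT", decision_noise=0.0, seed=17
            )
        )
        agreement = build_agreement_table(
            responses, threshold_table(responses, vignettes)
        )
        comparison = compare_models(agreement)
        ors = comparison.pooled.or_table.set_index("contrast")["odds_ratio"]
        assert ors["regret_vs_EUT"] <= 1.0
        assert ors["dual_vs_EUT"] <= 1.0

    def test_one_sided_extra_agreement_enumeration(self):
        """If one model agrees on 10 extra responses with none reversed, the
        exact paired p-value is 2 * (1/2)^10."""
        rows = []
        for i in range(40):
            for model in ("EUT", "regret", "dual"):
                agree = True if model != "regret" else i >= 10
                rows.append(
                    {
                        "participant_id": f"P{i:03d}",
                        "vignette_id": "PE_base",
                        "model": model,
                        "agree": agree,
                    }
                )
        agreement = pd.DataFrame(rows)
        comparison_rows = compare_models(agreement).per_vignette
        row = comparison_rows.set_index("contrast").loc["regret_vs_EUT"]
        assert (row["b"], row["c"]) == (0, 10)
        assert row["p_value"] == pytest.approx(2 * 0.5**10)
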