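"""Statistical pipeline: treat proportions, paired tests, model agreement.

Given a validated response table and the vignette set, the pipeline

1. tabulates treat / no-treat proportions per vignette and compares risk
   levels within condition by exact McNemar tests on the paired decisions;
2. computes, per response, the thresholds of the three models and whether
   the observed decision agrees with each;
3. compares the models by per-vignette exact paired tests on the agreement
   flags and by a pooled random-intercept logistic regression of agreement
   on model indicators, clustered by participant.

The exact (binomial) McNemar test is used throughout because the paired
samples are small (dozens of pairs) with few discordant pairs, where the
chi-square approximation is unreliable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar

from .design import RISK_LEVELS, Vignette
from .mixedlogit import MixedLogitFit, fit_mixed_logit
from .thresholds import (
    AssessmentSource,
    BenefitHarmAssessment,
    Decision,
    classify_agreement,
    compute_gamma,
    compute_t_dp,
    compute_t_eut,
    compute_t_rg,
)

__all__ = [
    "MODELS",
    "McNemarResult",
    "MixedLogitResult",
    "ModelComparison",
    "mcnemar_exact",
    "mcnemar_from_counts",
    "treat_proportions",
    "main_effects",
    "threshold_table",
    "build_agreement_table",
    "agreement_summary",
    "fit_random_intercept_logit",
    "compare_models",
]

MODELS = ("EUT", "regret", "dual")
CONTRASTS = (("regret", "EUT"), ("dual", "EUT"), ("dual", "regret"))


# ---------------------------------------------------------------------------
# McNemar
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class McNemarResult:
    """Exact McNemar test on the discordant pairs of a paired binary design."""

    b: int  # pairs positive under the first condition only
    c: int  # pairs positive under the second condition only
    p_value: float
    method: str = "exact-binomial"
    degenerate: bool = False  # no discordant pairs at all


def mcnemar_from_counts(b: int, c: int) -> McNemarResult:
    """Exact two-sided McNemar p-value from the discordant counts alone.

    Under the null the ``b`` out of ``b + c`` discordant pairs are
    Binomial(b + c, 1/2); the two-sided p-value doubles the smaller tail
    (capped at 1).  With no discordant pairs the test is degenerate and
    p = 1 by convention.
    """
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be non-negative")
    n = b + c
    if n == 0:
        return McNemarResult(b=b, c=c, p_value=1.0, degenerate=True)
    table = [[0, b], [c, 0]]
    p = float(_sm_mcnemar(table, exact=True).pvalue)
    return McNemarResult(b=int(b), c=int(c), p_value=min(1.0, p))


def mcnemar_exact(first, second) -> McNemarResult:
    """Exact McNemar test for two paired binary outcome vectors.

    ``first`` and ``second`` must be aligned element-wise (same participants
    in the same order); pandas Series are aligned on their index first and a
    pairing error is raised if the index sets differ.
    """
    if isinstance(first, pd.Series) and isinstance(second, pd.Series):
        if not first.index.sort_values().equals(second.index.sort_values()):
            raise ValueError("pairing error: participant sets differ")
        second = second.reindex(first.index)
    a = np.asarray(first, dtype=float)
    b_arr = np.asarray(second, dtype=float)
    if a.shape != b_arr.shape:
        raise ValueError("pairing error: unequal lengths")
    if np.isnan(a).any() or np.isnan(b_arr).any():
        raise ValueError("pairing error: missing values in paired outcomes")
    b = int(np.sum((a == 1) & (b_arr == 0)))
    c = int(np.sum((a == 0) & (b_arr == 1)))
    return mcnemar_from_counts(b, c)


# ---------------------------------------------------------------------------
# Treat proportions (main analysis)
# ---------------------------------------------------------------------------


def treat_proportions(responses: pd.DataFrame) -> pd.DataFrame:
    """Counts and percentages of treat / no-treat per condition x risk level."""
    if responses.empty:
        raise ValueError("response table is empty")
    records = []
    for (condition, level), grp in responses.groupby(
        ["condition", "risk_level"], sort=False
    ):
        n = len(grp)
        n_treat = int((grp["decision"] == 1).sum())
        records.append(
            {
                "condition": condition,
                "risk_level": level,
                "n": n,
                "n_treat": n_treat,
                "n_no_treat": n - n_treat,
                "pct_treat": round(100.0 * n_treat / n),
                "pct_no_treat": round(100.0 * (n - n_treat) / n),
            }
        )
    out = pd.DataFrame.from_records(records)
    order = {level: i for i, level in enumerate(RISK_LEVELS)}
    return (
        out.sort_values(
            ["condition", "risk_level"],
            key=lambda s: s.map(order) if s.name == "risk_level" else s,
        ).reset_index(drop=True)
    )


def main_effects(responses: pd.DataFrame) -> pd.DataFrame:
    """Paired comparisons of the base case against each shifted-threshold case.

    Within each condition, the decisions in the high-threshold and
    low-threshold vignettes are compared with the base case by the exact
    McNemar test, pairing on participant.
    """
    records = []
    for condition, grp in responses.groupby("condition", sort=False):
        wide = grp.pivot(
            index="participant_id", columns="risk_level", values="decision"
        )
        for level in ("high_threshold", "low_threshold"):
            result = mcnemar_exact(wide["base"], wide[level])
            records.append(
                {
                    "condition": condition,
                    "comparison": f"base vs {level}",
                    "b": result.b,
                    "c": result.c,
                    "p_value": result.p_value,
                    "degenerate": result.degenerate,
                }
            )
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# Thresholds and agreement
# ---------------------------------------------------------------------------


def threshold_table(
    responses: pd.DataFrame,
    vignettes: list[Vignette],
    variant: str = "product",
) -> pd.DataFrame:
    """Per-response thresholds of the three models (plus gamma).

    Expects a validated response table (uninformative all-zero DVAS rows
    already excluded).  Returns one row per response with the disease
    probability and ``t_eut``, ``t_rg``, ``gamma``, ``t_dp``.
    """
    by_id = {v.id: v for v in vignettes}
    records = []
    for _, row in responses.iterrows():
        vignette = by_id.get(row["vignette_id"])
        if vignette is None:
            raise KeyError(f"unknown vignette_id {row['vignette_id']!r}")
        elicited = BenefitHarmAssessment(
            benefit=float(row["regret_omission"]),
            harm=float(row["regret_commission"]),
            source=AssessmentSource.TYPE1_ELICITED,
        )
        t_eut = compute_t_eut(vignette.objective_bh)
        t_rg = compute_t_rg(elicited)
        gamma = compute_gamma(t_eut, t_rg)
        t_dp = compute_t_dp(t_eut, gamma, elicited, vignette.objective_bh, variant)
        records.append(
            {
                "participant_id": row["participant_id"],
                "vignette_id": row["vignette_id"],
                "p": vignette.disease_probability.p,
                "t_eut": t_eut,
                "t_rg": t_rg,
                "gamma": gamma,
                "t_dp": t_dp,
            }
        )
    return pd.DataFrame.from_records(records)


def build_agreement_table(
    responses: pd.DataFrame, thresholds: pd.DataFrame
) -> pd.DataFrame:
    """Long-format agreement flags: one row per response per model.

    A response agrees with a model when the observed decision matches the
    decision implied by that model's threshold at the vignette's disease
    probability (boundary inclusive).
    """
    keyed = thresholds.set_index(["participant_id", "vignette_id"])
    records = []
    for _, row in responses.iterrows():
        key = (row["participant_id"], row["vignette_id"])
        if key not in keyed.index:
            raise KeyError(
                f"missing thresholds for participant {key[0]!r} vignette {key[1]!r}"
            )
        thr = keyed.loc[key]
        observed = Decision.TREAT if row["decision"] == 1 else Decision.NO_TREAT
        p = float(thr["p"])
        for model, column in (("EUT", "t_eut"), ("regret", "t_rg"), ("dual", "t_dp")):
            records.append(
                {
                    "participant_id": row["participant_id"],
                    "vignette_id": row["vignette_id"],
                    "model": model,
                    "agree": classify_agreement(p, float(thr[column]), observed),
                }
            )
    return pd.DataFrame.from_records(records)


def agreement_summary(agreement: pd.DataFrame) -> pd.DataFrame:
    """Agreement counts and percentages per vignette and model."""
    records = []
    for (vignette_id, model), grp in agreement.groupby(
        ["vignette_id", "model"], sort=False
    ):
        n = len(grp)
        n_agree = int(grp["agree"].sum())
        records.append(
            {
                "vignette_id": vignette_id,
                "model": model,
                "n": n,
                "n_agree": n_agree,
                "n_disagree": n - n_agree,
                "pct_agree": round(100.0 * n_agree / n),
                "pct_disagree": round(100.0 * (n - n_agree) / n),
            }
        )
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# Pooled mixed-model comparison
# ---------------------------------------------------------------------------


@dataclass
class MixedLogitResult:
    """Pooled comparison of the three models' agreement rates.

    Odds ratios contrast each model's odds of agreeing with the observed
    decision; the participant-level random intercept absorbs the correlation
    among one participant's eighteen agreement flags (six vignettes times
    three models).
    """

    or_table: pd.DataFrame  # contrast, odds_ratio, ci_low, ci_high, p_value
    sigma: float
    loglik: float
    null_loglik: float
    converged: bool
    quadrature_order: int
    separation: bool
    penalized: bool
    fit: MixedLogitFit = field(repr=False, default=None)
    diagnostics: dict = field(default_factory=dict)

    def odds_ratio(self, contrast: str) -> float:
        row = self.or_table.set_index("contrast").loc[contrast]
        return float(row["odds_ratio"])

    def p_value(self, contrast: str) -> float:
        row = self.or_table.set_index("contrast").loc[contrast]
        return float(row["p_value"])


def fit_random_intercept_logit(
    agreement: pd.DataFrame,
    quadrature_order: int = 15,
    var_fixed: float | None = None,
    compute_null: bool = True,
) -> MixedLogitResult:
    """Random-intercept logistic regression of agreement on model indicators.

    The fixed effects are an intercept (reference: expected-utility model)
    and indicators for the regret and dual-processing models; the random
    intercept is at the participant level.  Reports the three pairwise odds
    ratios with Wald 95% confidence intervals on the log-odds scale.

    ``var_fixed=0`` collapses the model to the ordinary pooled logistic fit
    (used as a reduction check); ``compute_null=False`` skips the
    intercept-only reference fit.
    """
    participants = agreement["participant_id"].unique()
    if len(participants) < 2:
        raise ValueError("need at least 2 participants")
    if agreement["model"].nunique() < 2:
        raise ValueError("need at least 2 models to contrast")

    y = agreement["agree"].astype(float).to_numpy()
    X = np.column_stack(
        [
            np.ones(len(agreement)),
            (agreement["model"] == "regret").to_numpy(dtype=float),
            (agreement["model"] == "dual").to_numpy(dtype=float),
        ]
    )
    groups = agreement["participant_id"].to_numpy()
    fit = fit_mixed_logit(
        y,
        X,
        groups,
        exog_names=["intercept", "regret", "dual"],
        quadrature_order=quadrature_order,
        var_fixed=var_fixed,
    )

    contrast_weights = {
        "regret_vs_EUT": np.array([0.0, 1.0, 0.0]),
        "dual_vs_EUT": np.array([0.0, 0.0, 1.0]),
        "dual_vs_regret": np.array([0.0, -1.0, 1.0]),
    }
    z975 = stats.norm.ppf(0.975)
    rows = []
    for name, w in contrast_weights.items():
        est, se = fit.contrast(w)
        z = est / se if se > 0 else np.inf * np.sign(est)
        rows.append(
            {
                "contrast": name,
                "log_odds": est,
                "se": se,
                "odds_ratio": float(np.exp(est)),
                "ci_low": float(np.exp(est - z975 * se)),
                "ci_high": float(np.exp(est + z975 * se)),
                "p_value": float(2.0 * stats.norm.sf(abs(z))),
            }
        )

    null_loglik = np.nan
    if compute_null:
        null_fit = fit_mixed_logit(
            y,
            np.ones((len(y), 1)),
            groups,
            exog_names=["intercept"],
            quadrature_order=quadrature_order,
            var_fixed=var_fixed,
        )
        null_loglik = null_fit.loglik

    return MixedLogitResult(
        or_table=pd.DataFrame(rows),
        sigma=fit.sigma,
        loglik=fit.loglik,
        null_loglik=null_loglik,
        converged=fit.converged,
        quadrature_order=quadrature_order,
        separation=fit.separation,
        penalized=fit.penalized,
        fit=fit,
        diagnostics=dict(fit.diagnostics),
    )


@dataclass
class ModelComparison:
    """Per-vignette exact paired tests plus the pooled mixed-model summary."""

    per_vignette: pd.DataFrame
    pooled: MixedLogitResult
    agreement_by_model: pd.DataFrame


def compare_models(
    agreement: pd.DataFrame,
    quadrature_order: int = 15,
) -> ModelComparison:
    """Pairwise model comparison on agreement flags.

    For each vignette, each pair of models is compared by an exact McNemar
    test on the paired agreement flags (paired on participant).  The pooled
    comparison is the random-intercept logit over all vignettes.
    """
    wide = agreement.pivot_table(
        index=["participant_id", "vignette_id"], columns="model", values="agree"
    ).reset_index()
    records = []
    for vignette_id, grp in wide.groupby("vignette_id", sort=False):
        for model_a, model_b in CONTRASTS:
            result = mcnemar_exact(
                grp[model_a].astype(int), grp[model_b].astype(int)
            )
            records.append(
                {
                    "vignette_id": vignette_id,
                    "contrast": f"{model_a}_vs_{model_b}",
                    "b": result.b,
                    "c": result.c,
                    "p_value": result.p_value,
                    "degenerate": result.degenerate,
                }
            )
    pooled = fit_random_intercept_logit(agreement, quadrature_order=quadrature_order)
    totals = (
        agreement.groupby("model", sort=False)["agree"]
        .agg(n="size", n_agree="sum")
        .reset_index()
    )
    totals["prop_agree"] = totals["n_agree"] / totals["n"]
    return ModelComparison(
        per_vignette=pd.DataFrame.from_records(records),
        pooled=pooled,
        agreement_by_model=totals,
    )
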