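"""Synthetic physician cohorts with the structure the analysis assumes.

No response data for this vignette design are publicly deposited, so the
simulator stands in: it emits a tidy response table in the elicitation CSV schema
plus a latent truth table, generated by running the threshold equations
forward.  Each simulated participant carries a latent decision model
(expected-utility, regret, or dual-processing; or a mixture over
participants), produces DVAS regret marks from per-vignette scaled Beta
distributions, and decides to treat when the vignette's disease probability
reaches the threshold implied by their latent model — with an optional
symmetric Bernoulli flip as decision noise.

DVAS marks are generated by drawing the omission share
``u = omission / (omission + commission)`` from a Beta distribution whose
mean is set by the vignette's target median regret ratio, then scaling by a
total mark intensity.  Within a condition the three vignettes share a
participant's Beta quantile, so a respondent who leans toward omission
regret does so consistently across that condition's cases; this comonotone
coupling is what makes the low-threshold / base / high-threshold treatment
gradient deterministic in noise-free cohorts and induces the within-subject
correlation the mixed model is meant to absorb.
"""

from __future__ import annotations

from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy import stats
from scipy.special import ndtr

from .design import (
    CONDITIONS,
    RISK_LEVELS,
    Vignette,
    build_default_vignettes,
    randomize_presentation,
)
from .elicitation import RESPONSE_COLUMNS
from .thresholds import (
    AssessmentSource,
    BenefitHarmAssessment,
    compute_gamma,
    compute_t_dp,
    compute_t_eut,
)

__all__ = [
    "GammaDistribution",
    "DvasNoiseModel",
    "SimulationConfig",
    "simulate_cohort",
    "target_bh_calibration",
]

MODELS = ("EUT", "regret", "dual")


class GammaDistribution(BaseModel):
    """Optional latent distribution of the type-1 mixing parameter gamma.

    When set, dual-processing participants draw a personal gamma from
    ``Beta(mean * concentration, (1 - mean) * concentration)`` (a point mass
    at ``mean`` when ``concentration`` is None) instead of deriving gamma
    from the distance between their expected-utility and regret thresholds.
    """

    mean: float = Field(ge=0.0, le=1.0)
    concentration: float | None = Field(default=None, gt=0.0)


class DvasNoiseModel(BaseModel):
    """Distributional model of the DVAS marks.

    ``target_median_ratio`` gives, per condition and risk level, the regret
    ratio around which the omission share is centred; the defaults are the
    published per-vignette medians of elicited benefit/harm ratios from a
    physician cohort of this design.  ``concentration`` controls the spread of the
    omission share around its target, ``participant_rho`` the share of
    quantile variance attributable to the participant (within-subject
    consistency across conditions), and ``scale_range`` the range of total
    mark intensity (omission + commission) on the 0-100 sliders.
    """

    target_median_ratio: dict[str, dict[str, float]] = {
        "PE": {"base": 3.18, "low_threshold": 5.26, "high_threshold": 0.98},
        "AML": {"base": 1.00, "low_threshold": 1.94, "high_threshold": 0.50},
    }
    concentration: float = Field(default=5.0, gt=0.0)
    participant_rho: float = Field(default=0.3, ge=0.0, le=1.0)
    scale_range: tuple[float, float] = (40.0, 100.0)
    automatic_median_ratio: dict[str, float] = {"PE": 3.0, "AML": 2.0}
    automatic_sigma: float = Field(default=0.5, ge=0.0)

    @model_validator(mode="after")
    def _check(self) -> "DvasNoiseModel":
        lo, hi = self.scale_range
        if not (0.0 < lo <= hi <= 100.0):
            raise ValueError("scale_range must satisfy 0 < lo <= hi <= 100")
        for condition in CONDITIONS:
            levels = self.target_median_ratio.get(condition, {})
            if set(levels) != set(RISK_LEVELS):
                raise ValueError(f"{condition}: need a target ratio per risk level")
            if any(v <= 0 for v in levels.values()):
                raise ValueError("target median ratios must be positive")
        return self


class SimulationConfig(BaseModel):
    """Full specification of one simulated survey run."""

    n_participants: int = Field(default=41, ge=1)
    generating_model: Literal["EUT", "regret", "dual", "mixture"] = "dual"
    mixture_weights: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    gamma_distribution: GammaDistribution | None = None
    dvas_noise: DvasNoiseModel = DvasNoiseModel()
    decision_noise: float = Field(default=0.05, ge=0.0, lt=0.5)
    dp_variant: Literal["product", "ratio"] = "product"
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SimulationConfig":
        if self.generating_model == "mixture":
            w = np.asarray(self.mixture_weights, dtype=float)
            if (w < 0).any() or not np.isclose(w.sum(), 1.0):
                raise ValueError("mixture_weights must be non-negative and sum to 1")
        return self


def _model_threshold(
    model: str,
    t_eut: float,
    t_rg: float,
    gamma: float,
    elicited: BenefitHarmAssessment,
    objective: BenefitHarmAssessment,
    variant: str,
) -> float:
    if model == "EUT":
        return t_eut
    if model == "regret":
        return t_rg
    if model == "dual":
        return compute_t_dp(t_eut, gamma, elicited, objective, variant=variant)
    raise ValueError(f"unknown latent model {model!r}")


def simulate_cohort(
    config: SimulationConfig, vignettes: list[Vignette] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one cohort; returns (response table, latent truth table).

    The response table follows the elicitation CSV schema; the truth table
    records each participant's latent model and mean gamma for recovery
    tests.  Byte-identical across runs with the same config.
    """
    vignettes = vignettes if vignettes is not None else build_default_vignettes()
    by_id = {v.id: v for v in vignettes}
    if len(by_id) != 6:
        raise ValueError("expected the six-vignette factorial set")

    noise = config.dvas_noise
    n = config.n_participants
    streams = np.random.SeedSequence(config.seed).spawn(6)
    rng_plan, rng_marks, rng_scale, rng_aut, rng_flip, rng_latent = (
        np.random.default_rng(s) for s in streams
    )

    plans = randomize_presentation(n, rng_plan)

    # latent model labels
    if config.generating_model == "mixture":
        labels = rng_latent.choice(MODELS, size=n, p=config.mixture_weights)
    else:
        labels = np.repeat(config.generating_model, n)
    if config.gamma_distribution is not None:
        gd = config.gamma_distribution
        if gd.concentration is None:
            gamma_override = np.full(n, gd.mean)
        else:
            a = gd.mean * gd.concentration
            b = (1.0 - gd.mean) * gd.concentration
            gamma_override = rng_latent.beta(max(a, 1e-9), max(b, 1e-9), size=n)
    else:
        gamma_override = None

    # participant- and condition-level quantiles of the omission share
    rho = noise.participant_rho
    z_part = rng_marks.standard_normal(n)
    z_cond = rng_marks.standard_normal((n, len(CONDITIONS)))
    q = ndtr(np.sqrt(rho) * z_part[:, None] + np.sqrt(1.0 - rho) * z_cond)

    # automatic (pre-context) assessments, one per participant x condition
    h_aut = rng_aut.uniform(10.0, 40.0, size=(n, len(CONDITIONS)))
    aut_ratio = np.exp(
        rng_aut.normal(
            np.log([noise.automatic_median_ratio[c] for c in CONDITIONS]),
            noise.automatic_sigma,
            size=(n, len(CONDITIONS)),
        )
    )
    b_aut = aut_ratio * h_aut

    lo, hi = noise.scale_range
    rows: list[dict] = []
    gammas_used: dict[str, list[float]] = {}
    for ci, condition in enumerate(CONDITIONS):
        for level in RISK_LEVELS:
            vignette = by_id[f"{condition}_{level}"]
            mu = 1.0 / (1.0 + 1.0 / noise.target_median_ratio[condition][level])
            a = mu * noise.concentration
            b = (1.0 - mu) * noise.concentration
            u = stats.beta.ppf(q[:, ci], a, b)
            u = np.clip(u, 1e-6, 1.0 - 1e-6)
            scale = rng_scale.uniform(lo, hi, size=n)
            omission = u * scale
            commission = (1.0 - u) * scale
            flips = rng_flip.random(n) < config.decision_noise

            t_eut = compute_t_eut(vignette.objective_bh)
            p = vignette.disease_probability.p
            for i, plan in enumerate(plans):
                elicited = BenefitHarmAssessment(
                    benefit=float(omission[i]),
                    harm=float(commission[i]),
                    source=AssessmentSource.TYPE1_ELICITED,
                )
                t_rg = 1.0 - float(u[i])
                gamma = compute_gamma(t_eut, t_rg)
                if gamma_override is not None and labels[i] == "dual":
                    gamma = float(gamma_override[i])
                threshold = _model_threshold(
                    str(labels[i]),
                    t_eut,
                    t_rg,
                    gamma,
                    elicited,
                    vignette.objective_bh,
                    config.dp_variant,
                )
                treat = p >= threshold
                if flips[i]:
                    treat = not treat
                gammas_used.setdefault(plan.participant_id, []).append(gamma)
                rows.append(
                    {
                        "participant_id": plan.participant_id,
                        "vignette_id": vignette.id,
                        "condition": condition,
                        "risk_level": level,
                        "decision": int(treat),
                        "regret_omission": round(float(omission[i]), 4),
                        "regret_commission": round(float(commission[i]), 4),
                        "anchor_start": plan.dvas_anchor.value,
                        "b_aut": round(float(b_aut[i, ci]), 4),
                        "h_aut": round(float(h_aut[i, ci]), 4),
                        "presentation_rank": plan.vignette_sequence().index(vignette.id)
                        + 1,
                    }
                )

    responses = pd.DataFrame(rows, columns=RESPONSE_COLUMNS)
    responses = responses.sort_values(
        ["participant_id", "presentation_rank"], kind="stable"
    ).reset_index(drop=True)
    truth = pd.DataFrame(
        {
            "participant_id": [p.participant_id for p in plans],
            "latent_model": labels,
            "latent_gamma": [
                round(float(np.mean(gammas_used[p.participant_id])), 6) for p in plans
            ],
        }
    )
    return responses, truth


def target_bh_calibration(responses: pd.DataFrame) -> pd.DataFrame:
    """Summarize simulated benefit/harm ratios per condition and risk level.

    Returns the count, mean, min, median and max of the elicited regret
    ratio B1/H1 for each vignette, plus one row per condition for the
    automatic (pre-context) ratio B_aut/H_aut — the shape of the published
    type-1 summary table.  Intended as calibration guidance against the
    published medians, not as a hard test.
    """
    if responses.empty:
        raise ValueError("response table is empty")
    df = responses.copy()
    with np.errstate(divide="ignore"):
        df["ratio"] = np.where(
            df["regret_commission"] > 0,
            df["regret_omission"] / df["regret_commission"],
            np.inf,
        )
    records = []
    for condition in CONDITIONS:
        sub = df[df["condition"] == condition]
        aut = (
            sub.groupby("participant_id")[["b_aut", "h_aut"]].first().eval(
                "b_aut / h_aut"
            )
        )
        records.append(
            {
                "condition": condition,
                "risk_level": "(pre-context)",
                "variable": "B_aut/H_aut",
                "n": int(aut.size),
                "mean": aut.mean(),
                "min": aut.min(),
                "median": aut.median(),
                "max": aut.max(),
            }
        )
        for level in RISK_LEVELS:
            ratios = sub.loc[sub["risk_level"] == level, "ratio"]
            records.append(
                {
                    "condition": condition,
                    "risk_level": level,
                    "variable": "B1/H1",
                    "n": int(ratios.size),
                    "mean": ratios.mean(),
                    "min": ratios.min(),
                    "median": ratios.median(),
                    "max": ratios.max(),
                }
            )
    return pd.DataFrame.from_records(records)
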