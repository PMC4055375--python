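"""The six-vignette within-subject design and its randomization plan.

Two clinical conditions — pulmonary embolism (PE, familiar to most
physicians) and acute myeloid leukemia relapse (AML, requiring specialist
knowledge) — are each presented at three benefit/harm levels: a base case
with an intermediate objective benefit/harm ratio, a low-threshold case
(high ratio, treatment easily justified) and a high-threshold case (low
ratio, treatment hard to justify).  Every participant answers all six
vignettes; only the order of conditions, the order of the high- versus
low-threshold cases, and the DVAS slider anchor are randomized.

There is no canonical set of objective benefit/harm magnitudes for these
cases; the defaults here are config-driven choices that
satisfy the design's qualitative constraints: the threshold ordering
high > base > low within each condition, an explicit 50% disease probability
for every PE vignette (with the base and low-threshold PE thresholds well
below 50%, and the high-threshold PE threshold just above it), and
qualitative-only relapse probabilities for AML.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .elicitation import AnchorStart
from .thresholds import (
    AssessmentSource,
    BenefitHarmAssessment,
    DiseaseProbability,
    compute_t_eut,
)

__all__ = [
    "Vignette",
    "VignetteSpec",
    "VignetteConfig",
    "PresentationPlan",
    "RISK_LEVELS",
    "CONDITIONS",
    "build_default_vignettes",
    "randomize_presentation",
]

CONDITIONS = ("PE", "AML")
RISK_LEVELS = ("base", "high_threshold", "low_threshold")


@dataclass(frozen=True)
class Vignette:
    """One clinical case: condition, benefit/harm level and disease probability.

    ``normative_statement_threshold`` is the probability X of the prescriptive
    statement "treatment should be given if the probability of disease
    exceeds X", derived from the objective benefit/harm ratio.
    """

    id: str
    condition: str
    risk_level: str
    disease_probability: DiseaseProbability
    objective_bh: BenefitHarmAssessment
    normative_statement_threshold: float

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        if self.risk_level not in RISK_LEVELS:
            raise ValueError(f"risk_level must be one of {RISK_LEVELS}")
        expected = compute_t_eut(self.objective_bh)
        if abs(self.normative_statement_threshold - expected) > 1e-12:
            raise ValueError(
                "normative_statement_threshold must equal the expected-utility "
                f"threshold {expected!r} of the objective assessment"
            )


class VignetteSpec(BaseModel):
    """Configurable parameters of a single vignette."""

    benefit: float = Field(gt=0)
    harm: float = Field(gt=0)
    disease_probability: float = Field(ge=0.0, le=1.0)
    explicit_probability: bool

    @property
    def bh_ratio(self) -> float:
        return self.benefit / self.harm


class VignetteConfig(BaseModel):
    """The 2 x 3 factorial vignette set as a round-trippable document.

    Defaults: PE vignettes state a 50% disease probability explicitly and use
    objective ratios 9 (base), 20 (low-threshold) and 0.8 (high-threshold),
    so the normative thresholds are 10%, 4.8% and 55.6% — the base and
    low-threshold cases sit far below the stated 50% probability while the
    high-threshold case sits just above it.  AML relapse probabilities are
    never told to the respondent (``explicit_probability = False``); the
    values here are latent simulation parameters chosen per risk level.
    Benefit/harm magnitudes are expressed on the same 0-100 severity scale
    as the DVAS marks so that elicited-to-objective harm ratios are
    dimensionless and of order one.
    """

    PE: dict[str, VignetteSpec] = {
        "base": VignetteSpec(
            benefit=45, harm=5, disease_probability=0.50, explicit_probability=True
        ),
        "low_threshold": VignetteSpec(
            benefit=80, harm=4, disease_probability=0.50, explicit_probability=True
        ),
        "high_threshold": VignetteSpec(
            benefit=20, harm=25, disease_probability=0.50, explicit_probability=True
        ),
    }
    AML: dict[str, VignetteSpec] = {
        "base": VignetteSpec(
            benefit=50, harm=25, disease_probability=0.70, explicit_probability=False
        ),
        "low_threshold": VignetteSpec(
            benefit=80, harm=20, disease_probability=0.90, explicit_probability=False
        ),
        "high_threshold": VignetteSpec(
            benefit=15, harm=30, disease_probability=0.50, explicit_probability=False
        ),
    }

    @model_validator(mode="after")
    def _check_design(self) -> "VignetteConfig":
        for condition in CONDITIONS:
            specs = getattr(self, condition)
            missing = set(RISK_LEVELS) - set(specs)
            if missing:
                raise ValueError(f"{condition}: missing risk levels {missing}")
            if not (
                specs["low_threshold"].bh_ratio
                > specs["base"].bh_ratio
                > specs["high_threshold"].bh_ratio
            ):
                raise ValueError(
                    f"{condition}: benefit/harm ratios must be ordered "
                    "low_threshold > base > high_threshold"
                )
        for level, spec in self.PE.items():
            if not spec.explicit_probability:
                raise ValueError(f"PE {level}: probability must be explicit")
            if spec.disease_probability != 0.50:
                raise ValueError(f"PE {level}: disease probability must be 0.50")
        for level, spec in self.AML.items():
            if spec.explicit_probability:
                raise ValueError(f"AML {level}: probability must not be explicit")
        return self


def build_default_vignettes(config: VignetteConfig | None = None) -> list[Vignette]:
    """Construct the 2 x 3 factorial vignette set from a (default) config."""
    config = config or VignetteConfig()
    vignettes = []
    for condition in CONDITIONS:
        for level in RISK_LEVELS:
            spec = getattr(config, condition)[level]
            bh = BenefitHarmAssessment(
                benefit=spec.benefit, harm=spec.harm, source=AssessmentSource.OBJECTIVE
            )
            vignettes.append(
                Vignette(
                    id=f"{condition}_{level}",
                    condition=condition,
                    risk_level=level,
                    disease_probability=DiseaseProbability(
                        p=spec.disease_probability, explicit=spec.explicit_probability
                    ),
                    objective_bh=bh,
                    normative_statement_threshold=compute_t_eut(bh),
                )
            )
    return vignettes


@dataclass(frozen=True)
class PresentationPlan:
    """Per-participant randomization: orderings and DVAS anchor.

    Each participant sees all six vignettes exactly once; only the order of
    conditions, the order of the high- versus low-threshold cases (the base
    case always leads its condition block) and the slider anchor vary.
    """

    participant_id: str
    condition_order: tuple[str, str]
    threshold_case_order: tuple[str, str]
    dvas_anchor: AnchorStart

    def vignette_sequence(self) -> list[str]:
        """Vignette ids in presentation order (base case first per block)."""
        return [
            f"{condition}_{level}"
            for condition in self.condition_order
            for level in ("base", *self.threshold_case_order)
        ]


def randomize_presentation(
    n_participants: int, seed: int | np.random.Generator
) -> list[PresentationPlan]:
    """Draw independent fair randomizations for each participant.

    Condition order (PE-first vs AML-first), high- vs low-threshold case
    order and the DVAS anchor are each a fair coin per participant,
    reproducible under a fixed seed.
    """
    if n_participants < 1:
        raise ValueError("n_participants must be at least 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    plans = []
    for i in range(1, n_participants + 1):
        pe_first, high_first, anchor_low = rng.random(3) < 0.5
        plans.append(
            PresentationPlan(
                participant_id=f"P{i:03d}",
                condition_order=("PE", "AML") if pe_first else ("AML", "PE"),
                threshold_case_order=(
                    ("high_threshold", "low_threshold")
                    if high_first
                    else ("low_threshold", "high_threshold")
                ),
                dvas_anchor=AnchorStart.AT_0 if anchor_low else AnchorStart.AT_100,
            )
        )
    return plans
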