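"""Treatment-threshold models for decisions under diagnostic uncertainty.

A clinician facing a patient who may or may not have a disease should treat
when the probability of disease exceeds a threshold probability and withhold
treatment otherwise.  Three threshold models are implemented:

* the expected-utility threshold ``T_EUT = 1 / (1 + B2/H2)``, computed from
  the objective benefit/harm ratio of the treatment;
* the regret threshold ``T_RG = 1 / (1 + B1/H1)``, computed from the
  subjectively elicited ratio of regret of omission (foregone benefit) to
  regret of commission (inflicted harm);
* the dual-processing threshold ``T_DP``, which blends the analytic
  (type-2) expected-utility threshold with intuitive (type-1) regret-driven
  adjustment through a mixing parameter ``gamma`` in [0, 1].

All thresholds are probabilities in the closed unit interval; the decision
rule treats the boundary ``p == threshold`` as treatment-indicated.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass

__all__ = [
    "AssessmentSource",
    "BenefitHarmAssessment",
    "DiseaseProbability",
    "Decision",
    "ThresholdSet",
    "UndefinedInputError",
    "compute_t_eut",
    "compute_t_rg",
    "compute_gamma",
    "compute_t_dp",
    "decide",
    "classify_agreement",
    "threshold_from_ratio",
]

#: Cap on the ``gamma / (2 (1 - gamma))`` multiplier of the "ratio" variant
#: of the dual-processing formula, which diverges as gamma -> 1.  The capped
#: value is far beyond anything that survives the final clamp to [0, 1].
RATIO_VARIANT_CAP = 1e6


class UndefinedInputError(ValueError):
    """Raised when a threshold is mathematically undefined for the input."""


class AssessmentSource(str, enum.Enum):
    """Provenance of a benefit/harm assessment.

    ``objective`` is the literature-based evidence (B2/H2), ``type1_elicited``
    the contextual regret-based judgment (B1/H1), and ``automatic`` the
    pre-context anchor (B_aut/H_aut).
    """

    AUTOMATIC = "automatic"
    TYPE1_ELICITED = "type1_elicited"
    OBJECTIVE = "objective"


class Decision(str, enum.Enum):
    TREAT = "treat"
    NO_TREAT = "no_treat"


@dataclass(frozen=True)
class BenefitHarmAssessment:
    """A non-negative benefit magnitude and harm magnitude with provenance.

    ``benefit`` and ``harm`` are dimensionless magnitudes; only their ratio
    enters the threshold formulas, so the absolute scale is arbitrary as long
    as the two are commensurable.
    """

    benefit: float
    harm: float
    source: AssessmentSource = AssessmentSource.OBJECTIVE

    def __post_init__(self) -> None:
        if not (self.benefit >= 0.0) or not (self.harm >= 0.0):
            raise ValueError(
                f"benefit and harm must be non-negative, got "
                f"benefit={self.benefit!r} harm={self.harm!r}"
            )

    def ratio(self) -> float:
        """Benefit-to-harm ratio; defined only for strictly positive harm."""
        if self.harm <= 0.0:
            raise UndefinedInputError("benefit/harm ratio undefined for harm = 0")
        return self.benefit / self.harm


@dataclass(frozen=True)
class DiseaseProbability:
    """Probability that the patient has the disease.

    ``explicit`` records whether the probability was stated numerically to
    the respondent (as for the pulmonary-embolism vignettes) or only conveyed
    qualitatively (as for the leukemia-relapse vignettes).
    """

    p: float
    explicit: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"disease probability must be in [0, 1], got {self.p!r}")


@dataclass(frozen=True)
class ThresholdSet:
    """Per participant-vignette thresholds of the three models plus gamma."""

    t_eut: float
    t_rg: float
    gamma: float
    t_dp: float

    def __post_init__(self) -> None:
        for name in ("t_eut", "t_rg", "gamma", "t_dp"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value!r}")


def _threshold_from_assessment(assessment: BenefitHarmAssessment) -> float:
    if assessment.harm == 0.0:
        if assessment.benefit == 0.0:
            raise UndefinedInputError(
                "threshold undefined when benefit and harm are both zero"
            )
        warnings.warn(
            "harm = 0 with positive benefit: benefit/harm ratio is infinite, "
            "returning threshold 0",
            RuntimeWarning,
            stacklevel=3,
        )
        return 0.0
    ratio = assessment.benefit / assessment.harm
    return 1.0 / (1.0 + ratio)


def threshold_from_ratio(bh_ratio: float) -> float:
    """Threshold probability ``1 / (1 + B/H)`` for a benefit/harm ratio.

    Accepts ``math.inf`` (threshold 0).  Strictly decreasing in the ratio.
    """
    if bh_ratio < 0:
        raise ValueError(f"benefit/harm ratio must be non-negative, got {bh_ratio!r}")
    if math.isinf(bh_ratio):
        return 0.0
    return 1.0 / (1.0 + bh_ratio)


def compute_t_eut(objective: BenefitHarmAssessment) -> float:
    """Expected-utility threshold ``1 / (1 + B2/H2)`` from objective evidence.

    Equivalently the probability at which the expected benefit ``p * B2``
    equals the expected harm ``(1 - p) * H2``.  For B2/H2 = 9 the threshold
    is 0.10: treatment is already justified at a 10% disease probability.
    """
    return _threshold_from_assessment(objective)


def compute_t_rg(elicited: BenefitHarmAssessment) -> float:
    """Regret threshold ``1 / (1 + B1/H1)`` from elicited regret magnitudes.

    ``B1/H1`` is the ratio of regret of omission (failure to provide a
    beneficial treatment) to regret of commission (administering an
    unnecessary, harmful one).  A zero ratio (no perceived benefit) yields a
    threshold of 1 — never treat; an infinite ratio yields 0 — always treat.
    """
    return _threshold_from_assessment(elicited)


def compute_gamma(t_eut: float, t_rg: float) -> float:
    """Type-1 involvement ``gamma = (T_EUT - T_RG) / T_EUT``, kept in [0, 1].

    gamma measures the relative distance between the analytically derived
    expected-utility threshold and the regret-based threshold.  Values at or
    above 1 are capped at 1; negative values (regret threshold above the
    expected-utility threshold) are clamped to 0.
    """
    if not 0.0 <= t_eut <= 1.0 or not 0.0 <= t_rg <= 1.0:
        raise ValueError("thresholds must be probabilities in [0, 1]")
    if t_eut == 0.0:
        raise UndefinedInputError("gamma undefined for T_EUT = 0")
    raw = (t_eut - t_rg) / t_eut
    return min(1.0, max(0.0, raw))


def compute_t_dp(
    t_eut: float,
    gamma: float,
    elicited: BenefitHarmAssessment,
    objective: BenefitHarmAssessment,
    variant: str = "product",
) -> float:
    """Dual-processing threshold blending analytic and intuitive processing.

    The default ``"product"`` variant evaluates::

        T_DP = T_EUT * [1 + (gamma/2) * (1 - gamma) * (H1/H2) * (1 - B1/H1)]

    which is finite on all of gamma in [0, 1] and reduces exactly to
    ``T_EUT`` at both gamma = 0 (pure type-2 processing) and gamma = 1.
    The ``"ratio"`` variant reads the gamma factor as a quotient::

        T_DP = T_EUT * [1 + gamma / (2 * (1 - gamma)) * (H1/H2) * (1 - B1/H1)]

    whose multiplier diverges as gamma -> 1 and is therefore capped at
    ``RATIO_VARIANT_CAP``.  Both variants clamp the result into [0, 1],
    since a large elicited regret ratio can push the raw value outside the
    probability scale.
    """
    if not 0.0 <= gamma <= 1.0:
        raise ValueError(f"gamma must be in [0, 1], got {gamma!r}")
    if objective.harm == 0.0:
        raise UndefinedInputError("H2 = 0: harm ratio H1/H2 undefined")
    if gamma == 0.0:
        # exact reduction to the expected-utility threshold, both variants
        return t_eut
    h_ratio = elicited.harm / objective.harm
    if elicited.harm == 0.0:
        if elicited.benefit == 0.0:
            raise UndefinedInputError("elicited benefit and harm both zero")
        # H1 = 0, B1 > 0: the correction term H1*(1 - B1/H1) -> -B1
        bh_term = -elicited.benefit / objective.harm
    else:
        bh_term = h_ratio * (1.0 - elicited.benefit / elicited.harm)
    if variant == "product":
        factor = (gamma / 2.0) * (1.0 - gamma)
    elif variant == "ratio":
        if gamma >= 1.0:
            factor = RATIO_VARIANT_CAP
        else:
            factor = min(gamma / (2.0 * (1.0 - gamma)), RATIO_VARIANT_CAP)
    else:
        raise ValueError(f"unknown dual-processing variant {variant!r}")
    raw = t_eut * (1.0 + factor * bh_term)
    return min(1.0, max(0.0, raw))


def decide(p: DiseaseProbability | float, threshold: float) -> Decision:
    """Treat when the disease probability is at or above the threshold.

    The boundary ``p == threshold`` counts as treatment-indicated, matching
    the agreement rule's "greater than or equal to".
    """
    prob = p.p if isinstance(p, DiseaseProbability) else float(p)
    if not 0.0 <= prob <= 1.0 or not 0.0 <= threshold <= 1.0:
        raise ValueError("probability and threshold must be in [0, 1]")
    return Decision.TREAT if prob >= threshold else Decision.NO_TREAT


def classify_agreement(
    p: DiseaseProbability | float, threshold: float, observed: Decision | str
) -> bool:
    """Whether an observed decision agrees with a model's threshold.

    Agreement holds when the disease probability is at or above the threshold
    and the participant treated, or below the threshold and the participant
    withheld treatment.  Identical to ``decide(p, threshold) == observed``.
    """
    observed = Decision(observed)
    return decide(p, threshold) == observed
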