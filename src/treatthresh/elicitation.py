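"""Conversion of raw DVAS regret marks into benefit/harm assessments.

The dual visual analog scale (DVAS) asks a respondent to mark, on two 0-100
sliders, the anticipated regret of *omission* (failing to provide a
beneficial treatment) and of *commission* (administering an unnecessary,
potentially harmful one).  The elicited benefit/harm ratio is taken as the
ratio of the two marks, ``B1/H1 = omission / commission``; only this ratio
enters the regret threshold, so the mapping is scale-invariant.

The slider's randomized starting anchor (at 0 or at 100) is carried as
metadata only; no anchoring correction is applied.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import pandas as pd

from .thresholds import AssessmentSource, BenefitHarmAssessment

__all__ = [
    "AnchorStart",
    "DvasResponse",
    "AutomaticAssessment",
    "UninformativeResponseError",
    "ValidationReport",
    "RESPONSE_COLUMNS",
    "dvas_to_bh_ratio",
    "validate_response_table",
]

#: Required columns of the tidy response table, one row per
#: participant x vignette.
RESPONSE_COLUMNS = [
    "participant_id",
    "vignette_id",
    "condition",
    "risk_level",
    "decision",
    "regret_omission",
    "regret_commission",
    "anchor_start",
    "b_aut",
    "h_aut",
    "presentation_rank",
]


class UninformativeResponseError(ValueError):
    """Both DVAS marks are zero: no defensible regret ratio exists."""


class AnchorStart(str, enum.Enum):
    AT_0 = "at_0"
    AT_100 = "at_100"


@dataclass(frozen=True)
class DvasResponse:
    """One dual visual analog scale response (two marks on 0-100 sliders)."""

    regret_omission: float
    regret_commission: float
    anchor_start: AnchorStart = AnchorStart.AT_0

    def __post_init__(self) -> None:
        for name in ("regret_omission", "regret_commission"):
            value = getattr(self, name)
            if not 0.0 <= value <= 100.0 or math.isnan(value):
                raise ValueError(f"{name} must be a mark in [0, 100], got {value!r}")


@dataclass(frozen=True)
class AutomaticAssessment:
    """Pre-context ("automatic") benefit and harm judgment for a condition.

    Elicited before any case-specific detail is shown; serves only as an
    anchor and never enters the threshold calculations.
    """

    b_aut: float
    h_aut: float

    def __post_init__(self) -> None:
        if self.b_aut < 0 or self.h_aut < 0:
            raise ValueError("automatic assessments must be non-negative")


def dvas_to_bh_ratio(r: DvasResponse) -> BenefitHarmAssessment:
    """Map DVAS marks to a type-1 elicited benefit/harm assessment.

    The omission mark plays the role of the perceived benefit B1 and the
    commission mark that of the perceived harm H1, so that
    ``B1/H1 = omission / commission``.  A zero commission mark with a
    positive omission mark carries infinite-ratio semantics (regret
    threshold 0); both marks zero is uninformative and raises.
    """
    if r.regret_omission == 0.0 and r.regret_commission == 0.0:
        raise UninformativeResponseError(
            "both DVAS marks are zero: regret ratio undefined"
        )
    return BenefitHarmAssessment(
        benefit=r.regret_omission,
        harm=r.regret_commission,
        source=AssessmentSource.TYPE1_ELICITED,
    )


@dataclass
class ValidationReport:
    """Outcome of validating a tidy response table.

    ``clean`` holds the rows retained for analysis; ``excluded`` the rows
    dropped (currently: uninformative all-zero DVAS responses); ``violations``
    human-readable descriptions of structural problems.  A table is usable
    when ``violations`` is empty.
    """

    clean: pd.DataFrame
    excluded: pd.DataFrame
    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    @property
    def n_excluded(self) -> int:
        return len(self.excluded)


def validate_response_table(rows: pd.DataFrame) -> ValidationReport:
    """Validate a tidy per-participant-per-vignette response table.

    Checks for missing columns, out-of-range DVAS marks, invalid or missing
    decisions, and duplicate participant x vignette keys.  Rows whose two
    DVAS marks are both zero are excluded (logged, not imputed) rather than
    reported as violations: they are valid survey output with no usable
    regret ratio.
    """
    if not isinstance(rows, pd.DataFrame):
        raise TypeError("response table must be a pandas DataFrame")
    violations: list[str] = []

    missing = [c for c in RESPONSE_COLUMNS if c not in rows.columns]
    if missing:
        violations.append(f"missing required columns: {', '.join(missing)}")
        return ValidationReport(rows.iloc[0:0], rows.iloc[0:0], violations)

    df = rows.copy()

    dup = df.duplicated(subset=["participant_id", "vignette_id"], keep=False)
    if dup.any():
        for _, row in df.loc[dup, ["participant_id", "vignette_id"]].iterrows():
            violations.append(
                f"duplicate key: participant {row['participant_id']!r} "
                f"vignette {row['vignette_id']!r}"
            )

    for col in ("regret_omission", "regret_commission"):
        marks = pd.to_numeric(df[col], errors="coerce")
        bad = marks.isna() | (marks < 0) | (marks > 100)
        for idx in df.index[bad]:
            violations.append(
                f"row {idx}: {col} = {df.at[idx, col]!r} outside [0, 100]"
            )

    decision = pd.to_numeric(df["decision"], errors="coerce")
    bad_decision = ~decision.isin([0, 1])
    for idx in df.index[bad_decision]:
        violations.append(
            f"row {idx}: decision = {df.at[idx, 'decision']!r} is not 0/1"
        )

    uninformative = (df["regret_omission"] == 0) & (df["regret_commission"] == 0)
    clean = df.loc[~uninformative].reset_index(drop=True)
    excluded = df.loc[uninformative].reset_index(drop=True)
    return ValidationReport(clean=clean, excluded=excluded, violations=violations)
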