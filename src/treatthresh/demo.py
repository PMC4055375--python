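"""A small deterministic demonstration cohort.

``demo_cohort`` builds a synthetic 41-respondent response table whose
per-vignette treat / no-treat margins follow the characteristic pattern of
the vignette design — near-ceiling treatment uptake in the low-threshold
and base pulmonary-embolism cases, a sharp drop in the high-threshold
cases — so that examples and table-rendering code have a stable, readable
input that does not depend on the stochastic simulator.
"""

from __future__ import annotations

import pandas as pd

from .design import CONDITIONS, RISK_LEVELS, randomize_presentation
from .elicitation import RESPONSE_COLUMNS

#: Number of respondents treating, out of 41, per condition and risk level.
DEMO_TREAT_COUNTS = {
    ("PE", "base"): 40,
    ("PE", "high_threshold"): 16,
    ("PE", "low_threshold"): 41,
    ("AML", "base"): 27,
    ("AML", "high_threshold"): 8,
    ("AML", "low_threshold"): 36,
}

#: Fixed DVAS mark pairs (omission, commission) cycled over respondents,
#: spanning ratios from 0.25 to 4 so every derived quantity is exercised.
_MARK_CYCLE = [(80, 20), (60, 30), (50, 50), (30, 60), (20, 80), (75, 25), (40, 40)]


def demo_cohort(n_participants: int = 41) -> pd.DataFrame:
    """Deterministic synthetic response table with fixed treat margins.

    The first ``k`` respondents (in id order) treat in each vignette, where
    ``k`` scales the margin in :data:`DEMO_TREAT_COUNTS`; DVAS marks, anchor
    assignments and presentation ranks are filled deterministically.
    """
    plans = randomize_presentation(n_participants, seed=20140605)
    rows = []
    for idx, plan in enumerate(plans):
        sequence = plan.vignette_sequence()
        for condition in CONDITIONS:
            for level in RISK_LEVELS:
                vignette_id = f"{condition}_{level}"
                k = round(DEMO_TREAT_COUNTS[(condition, level)] * n_participants / 41)
                omission, commission = _MARK_CYCLE[
                    (idx + len(vignette_id)) % len(_MARK_CYCLE)
                ]
                rows.append(
                    {
                        "participant_id": plan.participant_id,
                        "vignette_id": vignette_id,
                        "condition": condition,
                        "risk_level": level,
                        "decision": int(idx < k),
                        "regret_omission": float(omission),
                        "regret_commission": float(commission),
                        "anchor_start": plan.dvas_anchor.value,
                        "b_aut": 30.0,
                        "h_aut": 15.0,
                        "presentation_rank": sequence.index(vignette_id) + 1,
                    }
                )
    return pd.DataFrame(rows, columns=RESPONSE_COLUMNS)
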