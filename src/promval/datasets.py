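"""Deterministic demonstration cohorts built from summary counts.

These builders construct small synthetic cohort tables whose marginal
counts match user-supplied flow figures exactly (enrolment, inclusion,
per-period transition respondents, recoveries). They are useful for
exercising the flow-accounting code against published-style summary
tables when no participant-level data exist; scores are filled with
arbitrary valid values and carry no signal.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import (
    CohortTable,
    cohort_from_frame,
    expected_columns,
    score_column,
    submitted_column,
    transition_column,
)
from .instruments import DEFAULT_INSTRUMENTS, FOLLOWUPS


def make_flow_cohort(
    n_enrolled: int,
    n_low_back_pain: int,
    transition_respondents: dict[str, int],
    recovered: dict[str, int],
) -> CohortTable:
    """Cohort whose inclusion and recovery counts equal the arguments.

    ``transition_respondents`` and ``recovered`` are keyed by follow-up
    period; recovered participants get transition category 2 (much
    improved), the rest of the respondents category 4 (no change).
    Respondents are assigned from the top of the included block, so
    every transition respondent is an included participant.
    """
    if n_low_back_pain > n_enrolled:
        raise ValueError("n_low_back_pain cannot exceed n_enrolled")
    for p in FOLLOWUPS:
        n_resp = transition_respondents.get(p, 0)
        if recovered.get(p, 0) > n_resp:
            raise ValueError(f"recovered[{p}] cannot exceed respondents")
        if n_resp > n_low_back_pain:
            raise ValueError(f"respondents[{p}] cannot exceed included")

    n = n_enrolled
    data: dict[str, object] = {
        "participant_id": [f"F{i:04d}" for i in range(n)],
        "has_low_back_pain": (np.arange(n) < n_low_back_pain).astype(int),
        "chronicity": ["chronic"] * n,
        "none_box_available": np.ones(n, dtype=int),
        submitted_column("t0"): np.ones(n, dtype=int),
    }
    for s in DEFAULT_INSTRUMENTS:
        mid = (s.min_score + s.max_score) // 2
        data[score_column(s.name, "t0")] = np.full(n, float(mid))
    for p in FOLLOWUPS:
        n_resp = transition_respondents.get(p, 0)
        n_rec = recovered.get(p, 0)
        responds = np.arange(n) < n_resp
        trans = np.full(n, np.nan)
        trans[:n_rec] = 2.0
        trans[n_rec:n_resp] = 4.0
        data[submitted_column(p)] = responds.astype(int)
        data[transition_column(p)] = trans
        for s in DEFAULT_INSTRUMENTS:
            mid = float((s.min_score + s.max_score) // 2)
            col = np.where(responds, mid, np.nan)
            data[score_column(s.name, p)] = col
    df = pd.DataFrame(data)[expected_columns(DEFAULT_INSTRUMENTS)]
    return cohort_from_frame(df, DEFAULT_INSTRUMENTS, "flow demo cohort")
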