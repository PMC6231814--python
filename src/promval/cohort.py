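"""Cohort table I/O, inclusion filtering, zero-imputation, and flow accounting.

The cohort file is a wide CSV: one row per participant, one column per
instrument x timepoint score, a 1..7 transition rating per follow-up
period, and explicit per-timepoint submission markers. The submission
markers exist because the disability-questionnaire zero-imputation rules
are conditional on "a submission was made", which an empty cell alone
cannot encode.

Missingness is a first-class state distinct from 0; every imputation is
logged, never silent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._utils import round_half_up
from .instruments import (
    DEFAULT_INSTRUMENTS,
    FOLLOWUPS,
    TIMEPOINTS,
    InstrumentSpec,
)

#: Transition (global rating of change) categories, 1 best to 7 worst.
TRANSITION_CATEGORIES = tuple(range(1, 8))

META_COLUMNS = (
    "participant_id",
    "has_low_back_pain",
    "chronicity",
    "none_box_available",
)
CHRONICITY_LEVELS = ("acute_subacute", "chronic")


class CohortValidationError(ValueError):
    """Raised when a cohort file violates the schema or score bounds."""

    def __init__(self, problems: Sequence[str]):
        self.problems = list(problems)
        super().__init__(
            "cohort validation failed:\n  " + "\n  ".join(self.problems)
        )


def score_column(instrument: str, timepoint: str) -> str:
    return f"{instrument}_{timepoint}"


def transition_column(period: str) -> str:
    return f"transition_{period}"


def submitted_column(timepoint: str) -> str:
    return f"submitted_{timepoint}"


def expected_columns(specs: Sequence[InstrumentSpec]) -> list[str]:
    cols = list(META_COLUMNS)
    cols += [submitted_column(t) for t in TIMEPOINTS]
    cols += [score_column(s.name, t) for s in specs for t in TIMEPOINTS]
    cols += [transition_column(p) for p in FOLLOWUPS]
    return cols


@dataclass
class CohortTable:
    """Participant-level cohort with provenance.

    ``data`` is a wide DataFrame following :func:`expected_columns`;
    score and transition columns are float dtype with NaN for missing.
    """

    data: pd.DataFrame
    specs: tuple[InstrumentSpec, ...] = DEFAULT_INSTRUMENTS
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = self.data["participant_id"]
        if ids.duplicated().any():
            dups = ids[ids.duplicated()].tolist()
            raise CohortValidationError(
                [f"duplicate participant_id {d!r}" for d in dups]
            )

    def __len__(self) -> int:
        return len(self.data)

    def copy(self) -> "CohortTable":
        return CohortTable(self.data.copy(), self.specs, list(self.provenance))

    def instrument(self, name: str) -> InstrumentSpec:
        for spec in self.specs:
            if spec.name == name:
                return spec
        raise KeyError(f"unknown instrument {name!r}")


@dataclass
class FlowFragment:
    """Enrolment-to-inclusion accounting."""

    n_enrolled: int
    n_included: int

    @property
    def n_excluded(self) -> int:
        return self.n_enrolled - self.n_included

    @property
    def pct_included(self) -> float:
        if self.n_enrolled == 0:
            return float("nan")
        return round_half_up(100.0 * self.n_included / self.n_enrolled, 1)


@dataclass
class CohortFlow:
    """Respondent and recovery accounting per follow-up period.

    Percent recovered is among period transition respondents; cumulative
    percent uses all included baseline participants as the denominator.
    Percentages are displayed at 0 decimals (half-up), matching the
    summary-table convention; missing denominators report NaN.
    """

    n_enrolled: int
    n_included: int
    n_respondents: dict[str, dict[str, int]]  # timepoint -> instrument -> n
    n_transition_respondents: dict[str, int]  # period -> n
    n_recovered: dict[str, int]  # period -> n improved
    n_cumulative_recovered: dict[str, int]  # period -> running total

    def pct_recovered(self, period: str) -> float:
        n = self.n_transition_respondents[period]
        if n == 0:
            return float("nan")
        return round_half_up(100.0 * self.n_recovered[period] / n, 0)

    def pct_cumulative_recovered(self, period: str) -> float:
        if self.n_included == 0:
            return float("nan")
        return round_half_up(
            100.0 * self.n_cumulative_recovered[period] / self.n_included, 0
        )

    def to_dict(self) -> dict:
        return {
            "n_enrolled": self.n_enrolled,
            "n_included": self.n_included,
            "n_respondents": self.n_respondents,
            "n_transition_respondents": self.n_transition_respondents,
            "n_recovered": self.n_recovered,
            "n_cumulative_recovered": self.n_cumulative_recovered,
            "pct_recovered": {
                p: self.pct_recovered(p) for p in self.n_recovered
            },
            "pct_cumulative_recovered": {
                p: self.pct_cumulative_recovered(p)
                for p in self.n_cumulative_recovered
            },
        }

    def summary_text(self) -> str:
        """Plain-text recovery table (periods x counts/percentages)."""
        lines = [
            "Recoveries and cumulative recoveries (transition question)",
            f"{'period':<8}{'n':>6}{'recovered n (%)':>20}"
            f"{'cumulative n (%)':>20}",
        ]
        for p in self.n_recovered:
            rec = f"{self.n_recovered[p]} ({self.pct_recovered(p):.0f})"
            cum = (
                f"{self.n_cumulative_recovered[p]} "
                f"({self.pct_cumulative_recovered(p):.0f})"
            )
            lines.append(
                f"{p:<8}{self.n_transition_respondents[p]:>6}{rec:>20}{cum:>20}"
            )
        return "\n".join(lines)


def _validate_frame(
    df: pd.DataFrame, specs: Sequence[InstrumentSpec]
) -> list[str]:
    problems: list[str] = []
    missing_cols = [c for c in expected_columns(specs) if c not in df.columns]
    if missing_cols:
        return [f"missing column {c!r}" for c in missing_cols]

    pid = df["participant_id"].astype(str)
    for spec in specs:
        for t in TIMEPOINTS:
            col = score_column(spec.name, t)
            vals = df[col]
            bad = vals.notna() & ~vals.between(spec.min_score, spec.max_score)
            for p, v in zip(pid[bad], vals[bad]):
                problems.append(
                    f"participant {p}: {col}={v} outside "
                    f"[{spec.min_score}, {spec.max_score}]"
                )
            on_grid = vals.notna() & (
                np.mod(vals - spec.min_score, spec.resolution) != 0
            )
            for p, v in zip(pid[on_grid], vals[on_grid]):
                problems.append(
                    f"participant {p}: {col}={v} not on the score grid"
                )
    for period in FOLLOWUPS:
        col = transition_column(period)
        vals = df[col]
        bad = vals.notna() & ~vals.isin(TRANSITION_CATEGORIES)
        for p, v in zip(pid[bad], vals[bad]):
            problems.append(f"participant {p}: {col}={v} not in 1..7")
    for col in ("has_low_back_pain", "none_box_available") + tuple(
        submitted_column(t) for t in TIMEPOINTS
    ):
        vals = df[col]
        bad = vals.notna() & ~vals.isin((0, 1))
        for p, v in zip(pid[bad], vals[bad]):
            problems.append(f"participant {p}: {col}={v} is not 0/1")
    bad = df["chronicity"].notna() & ~df["chronicity"].isin(CHRONICITY_LEVELS)
    for p, v in zip(pid[bad], df["chronicity"][bad]):
        problems.append(f"participant {p}: chronicity={v!r} unknown")
    return problems


def _coerce_types(
    df: pd.DataFrame, specs: Sequence[InstrumentSpec]
) -> pd.DataFrame:
    df = df.copy()
    num_cols = (
        [submitted_column(t) for t in TIMEPOINTS]
        + [score_column(s.name, t) for s in specs for t in TIMEPOINTS]
        + [transition_column(p) for p in FOLLOWUPS]
        + ["has_low_back_pain", "none_box_available"]
    )
    for col in num_cols:
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="raise")
    return df


def read_cohort(
    path: str | Path,
    specs: Sequence[InstrumentSpec] = DEFAULT_INSTRUMENTS,
) -> CohortTable:
    """Read and validate a wide cohort CSV.

    Raises
    ------
    CohortValidationError
        On schema violations, out-of-range/off-grid scores, or invalid
        transition categories; the message names each offending
        participant and field.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:  # line number is in the message
        raise CohortValidationError([f"malformed CSV {path}: {exc}"]) from exc
    try:
        df = _coerce_types(df, specs)
    except (ValueError, TypeError) as exc:
        raise CohortValidationError(
            [f"non-numeric value in {path}: {exc}"]
        ) from exc
    problems = _validate_frame(df, specs)
    if problems:
        raise CohortValidationError(problems)
    return CohortTable(df, tuple(specs), [f"read from {path}"])


def write_cohort(cohort: CohortTable, path: str | Path) -> None:
    """Write the cohort back to CSV (empty cell = missing).

    Round-trips bit-exact through :func:`read_cohort` for valid tables.
    """
    cohort.data.to_csv(path, index=False)


def cohort_from_frame(
    df: pd.DataFrame,
    specs: Sequence[InstrumentSpec] = DEFAULT_INSTRUMENTS,
    provenance: str = "in-memory frame",
) -> CohortTable:
    """Validate an in-memory DataFrame into a :class:`CohortTable`."""
    df = _coerce_types(df, specs)
    problems = _validate_frame(df, specs)
    if problems:
        raise CohortValidationError(problems)
    return CohortTable(df.reset_index(drop=True), tuple(specs), [provenance])


def apply_inclusion_filter(
    cohort: CohortTable,
) -> tuple[CohortTable, FlowFragment]:
    """Keep participants whose main complaint is low back pain.

    Returns the filtered table plus an enrolment/inclusion fragment with
    the inclusion percentage at one decimal (half-up).
    """
    df = cohort.data
    if df["has_low_back_pain"].isna().any():
        raise CohortValidationError(
            ["has_low_back_pain must be populated for all records"]
        )
    kept = df[df["has_low_back_pain"] == 1].reset_index(drop=True)
    frag = FlowFragment(n_enrolled=len(df), n_included=len(kept))
    out = CohortTable(
        kept,
        cohort.specs,
        cohort.provenance
        + [
            f"inclusion filter: {frag.n_included}/{frag.n_enrolled} "
            f"({frag.pct_included}%) kept"
        ],
    )
    return out, frag


@dataclass(frozen=True)
class ImputationEvent:
    participant_id: str
    field: str
    rule: str
    value: float


def impute_zero_scores(
    cohort: CohortTable,
) -> tuple[CohortTable, list[ImputationEvent]]:
    """Apply the disability-questionnaire zero-imputation rules.

    Before the "none of the above" confirmation box existed, a submitted
    questionnaire with no items ticked arrived as a blank score. Two
    rules recover the intended zeros for those records only:

    (a) baseline blank with a baseline submission -> 0;
    (b) follow-up blank with a follow-up submission, provided the
        baseline score was greater than 0 -> 0.

    An untouched pain slider submits an explicit 0, which is retained as
    valid data (nothing to impute); the 0-10 rating is a required field
    and is never imputed — a missing value despite a submission is
    recorded as a data anomaly in the log, not an error.

    Idempotent: a second application changes nothing.
    """
    df = cohort.data.copy()
    log: list[ImputationEvent] = []
    pre_era = df["none_box_available"] == 0

    base_col = score_column("ermdq", "t0")
    mask_a = pre_era & (df[submitted_column("t0")] == 1) & df[base_col].isna()
    for idx in df.index[mask_a]:
        df.loc[idx, base_col] = 0.0
        log.append(
            ImputationEvent(
                str(df.loc[idx, "participant_id"]), base_col, "a", 0.0
            )
        )

    for period in FOLLOWUPS:
        col = score_column("ermdq", period)
        mask_b = (
            pre_era
            & (df[submitted_column(period)] == 1)
            & df[col].isna()
            & (df[base_col] > 0)
        )
        for idx in df.index[mask_b]:
            df.loc[idx, col] = 0.0
            log.append(
                ImputationEvent(
                    str(df.loc[idx, "participant_id"]), col, "b", 0.0
                )
            )

    # required-field anomaly: submitted but blank 0-10 rating
    for t in TIMEPOINTS:
        col = score_column("enrs", t)
        anomaly = (df[submitted_column(t)] == 1) & df[col].isna()
        for idx in df.index[anomaly]:
            log.append(
                ImputationEvent(
                    str(df.loc[idx, "participant_id"]),
                    col,
                    "anomaly:required-missing",
                    float("nan"),
                )
            )

    n_imputed = sum(1 for e in log if not e.rule.startswith("anomaly"))
    out = CohortTable(
        df,
        cohort.specs,
        cohort.provenance + [f"zero-imputation: {n_imputed} values set"],
    )
    return out, log


def compute_flow(cohort: CohortTable) -> CohortFlow:
    """Respondent counts and (cumulative) recovery accounting.

    "Recovered" means the transition rating dichotomizes to improved
    (categories 1-2). Cumulative recoveries sum the per-period recovery
    counts; their percentage is of all included baseline participants.
    """
    from .responsiveness import dichotomize_transition

    df = cohort.data
    n_resp = {
        t: {
            s.name: int(df[score_column(s.name, t)].notna().sum())
            for s in cohort.specs
        }
        for t in TIMEPOINTS
    }
    n_trans: dict[str, int] = {}
    n_rec: dict[str, int] = {}
    n_cum: dict[str, int] = {}
    running = 0
    for period in FOLLOWUPS:
        ratings = df[transition_column(period)].dropna()
        n_trans[period] = int(len(ratings))
        improved = sum(dichotomize_transition(int(r)) for r in ratings)
        n_rec[period] = int(improved)
        running += int(improved)
        n_cum[period] = running
    return CohortFlow(
        n_enrolled=len(df),
        n_included=len(df),
        n_respondents=n_resp,
        n_transition_respondents=n_trans,
        n_recovered=n_rec,
        n_cumulative_recovered=n_cum,
    )
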