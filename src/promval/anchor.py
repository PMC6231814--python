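"""Transition-anchor validity diagnostics.

A global rating of change is only a trustworthy external criterion if it
actually measures change. If it does, its correlation with the baseline
score and with the follow-up score should be present, equal, and
opposite; and in a regression of the rating on follow-up score, adding
the baseline score should explain a significant share of the residual
variance. A rating that correlates with follow-up status but not with
baseline is tracking how the patient feels now, not how much they have
changed.

The transition rating (1 best .. 7 worst) is treated as numeric, and the
nested models are ordinary least squares compared by a likelihood-ratio
chi-square on 1 degree of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .cohort import CohortTable, score_column, transition_column


class UndefinedCorrelationError(ValueError):
    """Raised when a variable has zero variance."""


@dataclass
class TransitionValidityResult:
    instrument: str
    period: str
    r_baseline: float
    r_followup: float
    lr_statistic: float
    lr_p: float
    coef_followup: float
    coef_baseline: float
    n: int
    collinear: bool = False

    def to_dict(self) -> dict:
        return {
            "instrument": self.instrument,
            "period": self.period,
            "r_baseline": self.r_baseline,
            "r_followup": self.r_followup,
            "lr_statistic": self.lr_statistic,
            "lr_p": self.lr_p,
            "coef_followup": self.coef_followup,
            "coef_baseline": self.coef_baseline,
            "n": self.n,
            "collinear": self.collinear,
        }


def _complete_triples(
    cohort: CohortTable, instrument: str, period: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    df = cohort.data
    base = df[score_column(instrument, "t0")]
    fup = df[score_column(instrument, period)]
    trans = df[transition_column(period)]
    ok = base.notna() & fup.notna() & trans.notna()
    return (
        base[ok].to_numpy(dtype=float),
        fup[ok].to_numpy(dtype=float),
        trans[ok].to_numpy(dtype=float),
    )


def anchor_correlations(
    cohort: CohortTable, instrument: str, period: str
) -> tuple[float, float]:
    """Pearson r of the transition rating with baseline and follow-up.

    Returns ``(r_baseline, r_followup)``. Under an anchor that truly
    measures change these are equal and opposite; an anchor driven by
    follow-up status shows r_baseline near zero.
    """
    base, fup, trans = _complete_triples(cohort, instrument, period)
    if len(trans) < 3:
        raise ValueError("need at least 3 complete (t0, follow-up, "
                         "transition) triples")
    for name, v in (("transition", trans), ("baseline", base),
                    ("follow-up", fup)):
        if np.ptp(v) == 0:
            raise UndefinedCorrelationError(
                f"{name} has zero variance; correlation undefined"
            )
    r_b = float(stats.pearsonr(trans, base).statistic)
    r_f = float(stats.pearsonr(trans, fup).statistic)
    return r_b, r_f


def nested_anchor_regression(
    cohort: CohortTable, instrument: str, period: str
) -> TransitionValidityResult:
    """Does baseline score add to follow-up score in explaining the anchor?

    Fits ``transition ~ followup`` then ``transition ~ followup +
    baseline`` by OLS and compares them with the likelihood-ratio
    statistic ``n * ln(RSS0 / RSS1)`` (chi-square, 1 df). A significant
    statistic is the behavior expected of a change-measuring anchor.
    """
    base, fup, trans = _complete_triples(cohort, instrument, period)
    n = len(trans)
    if n < 5:
        raise ValueError("need at least 5 complete triples")
    x0 = sm.add_constant(fup)
    x1 = sm.add_constant(np.column_stack([fup, base]))
    m0 = sm.OLS(trans, x0).fit()
    m1 = sm.OLS(trans, x1).fit()
    collinear = bool(np.linalg.matrix_rank(x1) < x1.shape[1]) or (
        np.linalg.cond(x1) > 1e10
    )
    lr = float(2.0 * (m1.llf - m0.llf))
    lr = max(lr, 0.0)
    p = float(stats.chi2.sf(lr, df=1))
    r_b, r_f = anchor_correlations(cohort, instrument, period)
    return TransitionValidityResult(
        instrument=instrument,
        period=period,
        r_baseline=r_b,
        r_followup=r_f,
        lr_statistic=lr,
        lr_p=p,
        coef_followup=float(m1.params[1]),
        coef_baseline=float(m1.params[2]),
        n=n,
        collinear=collinear,
    )
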