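import numpy as np
import pandas as pd
import pytest

from promval.cohort import (
    apply_inclusion_filter,
    cohort_from_frame,
    expected_columns,
)
from promval.instruments import DEFAULT_INSTRUMENTS
from promval.simulate import SyntheticConfig, generate_cohort


def blank_row(pid="P0", **overrides):
    """One schema-complete wide row; everything submitted, scores missing."""
    row = {c: np.nan for c in expected_columns(DEFAULT_INSTRUMENTS)}
    row.update(
        participant_id=pid,
        has_low_back_pain=1,
        chronicity="chronic",
        none_box_available=1,
        submitted_t0=1,
        submitted_t1w=0,
        submitted_t6w=0,
    )
    row.update(overrides)
    return row


def make_cohort(rows):
    return cohort_from_frame(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def default_cohort():
    """One included, imputed, paper-scale synthetic cohort (seed 7)."""
    gen = generate_cohort(SyntheticConfig(seed=7))
    cohort, _ = apply_inclusion_filter(gen.cohort)
    return cohort


@pytest.fixture(scope="session")
def default_truth():
    return generate_cohort(SyntheticConfig(seed=7)).truth
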