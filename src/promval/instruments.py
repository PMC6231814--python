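"""Bounded-instrument descriptions.

The three built-in instruments are electronic migrations of the classic
low back pain outcome measures: a 24-item disability questionnaire
(0-24), a pain-intensity slider with 101 positions (0-100 units), and an
11-point pain-intensity rating (0-10). Higher scores are worse on all
three, and all three live on an integer grid.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class InstrumentSpec:
    """A bounded, gridded score scale.

    Parameters
    ----------
    name
        Short identifier used in column names (``"<name>_<timepoint>"``).
    min_score, max_score
        Inclusive scale bounds.
    resolution
        Grid step; must divide ``max_score - min_score``.
    higher_is_worse
        Direction of the scale. True for all built-ins, so the
        improvement-positive change score is baseline minus follow-up.
    required_on_submit
        Whether the platform refuses a submission with this field blank
        (true only for the 0-10 rating, whose response set is exhaustive).
    """

    name: str
    min_score: int
    max_score: int
    resolution: int = 1
    higher_is_worse: bool = True
    required_on_submit: bool = False

    def __post_init__(self) -> None:
        if self.min_score >= self.max_score:
            raise ValueError(f"{self.name}: min_score must be < max_score")
        if self.resolution <= 0 or (self.max_score - self.min_score) % self.resolution:
            raise ValueError(f"{self.name}: resolution must divide the range")

    @property
    def span(self) -> int:
        return self.max_score - self.min_score

    def in_range(self, value: float) -> bool:
        return self.min_score <= value <= self.max_score

    def snap(self, value: float) -> float:
        """Clip to the bounds and round to the nearest grid point."""
        import numpy as np

        v = np.clip(value, self.min_score, self.max_score)
        steps = np.rint((v - self.min_score) / self.resolution)
        return self.min_score + steps * self.resolution


#: 24-item disability questionnaire, summed yes/no items.
ERMDQ = InstrumentSpec("ermdq", 0, 24)
#: Pain-intensity slider reported in scale units (101 positions).
EVAS = InstrumentSpec("evas", 0, 100)
#: 11-point pain-intensity numerical rating; completion required.
ENRS = InstrumentSpec("enrs", 0, 10, required_on_submit=True)

DEFAULT_INSTRUMENTS: tuple[InstrumentSpec, ...] = (ERMDQ, EVAS, ENRS)

TIMEPOINTS: tuple[str, ...] = ("t0", "t1w", "t6w")
FOLLOWUPS: tuple[str, ...] = ("t1w", "t6w")


def get_instrument(name: str) -> InstrumentSpec:
    for spec in DEFAULT_INSTRUMENTS:
        if spec.name == name:
            return spec
    raise KeyError(f"unknown instrument {name!r}")
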