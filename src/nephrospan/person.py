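"""Shared person-level record types.

A :class:`Person` carries the index measurements, comorbidity flags and the
follow-up outcome for one individual.  It is produced by the synthetic cohort
generator or read from a delimited file, and consumed by the classifier and
the exposure-splitting stage.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"


class Dipstick(str, enum.Enum):
    """Semi-quantitative urine dipstick reading, ordinal scale 0..4."""

    NEGATIVE = "negative"
    TRACE = "trace"
    PLUS1 = "1+"
    PLUS2 = "2+"
    PLUS3 = "3+"

    @property
    def ordinal(self) -> int:
        return _DIPSTICK_ORDER[self]


_DIPSTICK_ORDER = {
    Dipstick.NEGATIVE: 0,
    Dipstick.TRACE: 1,
    Dipstick.PLUS1: 2,
    Dipstick.PLUS2: 3,
    Dipstick.PLUS3: 4,
}


@dataclass
class Person:
    """One individual's index measurements and follow-up outcome.

    Ages are continuous years.  ``serum_creatinine`` is mg/dL, ``acr_values``
    are mg/g.  ``exit_age`` is the age at death or censoring; ``died`` marks
    which.
    """

    id: str
    sex: Sex
    index_age: float
    serum_creatinine: float
    acr_values: list[float] = field(default_factory=list)
    dipstick_values: list[Dipstick] = field(default_factory=list)
    has_diabetes: bool = False
    has_hypertension: bool = False
    has_cvd: bool = False
    exit_age: float = 0.0
    died: bool = False
    on_dialysis_or_transplant: bool = False

    def __post_init__(self) -> None:
        if self.exit_age < self.index_age:
            raise ValueError(
                f"exit_age {self.exit_age} < index_age {self.index_age} "
                f"for person {self.id}"
            )

    @property
    def followup_years(self) -> float:
        return self.exit_age - self.index_age

    @property
    def has_comorbidity(self) -> bool:
        return self.has_diabetes or self.has_hypertension or self.has_cvd
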