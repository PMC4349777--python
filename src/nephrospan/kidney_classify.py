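"""Kidney-function classification.

Computes eGFR from serum creatinine (2009 CKD-EPI creatinine equation),
categorizes eGFR and albuminuria, applies cohort exclusions, and assigns the
KDIGO 2012 prognosis class.

Creatinine is mg/dL internally; readers may convert from µmol/L by dividing
by 88.4 (:data:`UMOL_PER_MGDL`).
"""
from __future__ import annotations

import enum
import statistics
from dataclasses import dataclass

from .person import Dipstick, Person, Sex

UMOL_PER_MGDL = 88.4

#: half-open eGFR category edges (mL/min/1.73m²), descending
_EGFR_EDGES = (60.0, 45.0, 30.0, 15.0)

#: ACR thresholds (mg/g): <30 normal, 30–300 inclusive mild, >300 heavy
ACR_MILD_LOWER = 30.0
ACR_HEAVY_LOWER = 300.0


class EgfrCategory(enum.Enum):
    """Baseline eGFR category; intervals are half-open and exhaustive."""

    GE60 = "GE60"            # [60, inf)
    C45_59 = "C45_59"        # [45, 60)
    C30_44 = "C30_44"        # [30, 45)
    C15_29 = "C15_29"        # [15, 30)
    EXCLUDED_LT15 = "EXCLUDED_LT15"  # [0, 15): not cohort-eligible

    @property
    def severity(self) -> int:
        """0 = best kidney function, increasing with severity."""
        return list(EgfrCategory).index(self)


class AlbuminuriaCategory(enum.Enum):
    NORMAL = "NORMAL"
    MILD = "MILD"
    HEAVY = "HEAVY"

    @property
    def severity(self) -> int:
        return list(AlbuminuriaCategory).index(self)


class KdigoRisk(enum.Enum):
    LOW = "LOW"
    MODERATE = "MODERATE"
    HIGH = "HIGH"
    VERY_HIGH = "VERY_HIGH"

    @property
    def severity(self) -> int:
        return list(KdigoRisk).index(self)


class AlbuminuriaSource(str, enum.Enum):
    ACR = "ACR"
    DIPSTICK = "DIPSTICK"


class IneligiblePersonError(ValueError):
    """Raised when a record does not meet the cohort eligibility rules."""


@dataclass(frozen=True)
class CkdEpiParams:
    """Constants of the 2009 CKD-EPI creatinine equation.

    Parameters are data rather than code so they can be inspected and tested.
    The ethnicity factor is carried but applied only when
    ``apply_ethnicity_factor`` is set.
    """

    kappa_female: float = 0.7
    kappa_male: float = 0.9
    alpha_female: float = -0.329
    alpha_male: float = -0.411
    slope_exponent: float = -1.209
    age_base: float = 0.993
    female_factor: float = 1.018
    intercept: float = 141.0
    ethnicity_factor: float = 1.159
    apply_ethnicity_factor: bool = False

    def kappa(self, sex: Sex) -> float:
        return self.kappa_female if sex is Sex.FEMALE else self.kappa_male

    def alpha(self, sex: Sex) -> float:
        return self.alpha_female if sex is Sex.FEMALE else self.alpha_male


DEFAULT_CKDEPI = CkdEpiParams()


def compute_egfr(
    scr: float,
    age: float,
    sex: Sex,
    params: CkdEpiParams = DEFAULT_CKDEPI,
) -> float:
    """eGFR in mL/min/1.73m² from serum creatinine (mg/dL), age and sex.

    Strictly decreasing in both creatinine and age.
    """
    if scr <= 0:
        raise ValueError(f"serum creatinine must be positive, got {scr}")
    if age < 18:
        raise ValueError(f"equation not validated below age 18, got {age}")
    sex = Sex(sex)
    kappa = params.kappa(sex)
    alpha = params.alpha(sex)
    ratio = scr / kappa
    egfr = (
        params.intercept
        * min(ratio, 1.0) ** alpha
        * max(ratio, 1.0) ** params.slope_exponent
        * params.age_base ** age
    )
    if sex is Sex.FEMALE:
        egfr *= params.female_factor
    if params.apply_ethnicity_factor:
        egfr *= params.ethnicity_factor
    return egfr


def categorize_egfr(egfr: float) -> EgfrCategory:
    """Map an eGFR value onto the study categories (half-open intervals)."""
    if egfr < 0:
        raise ValueError(f"eGFR must be non-negative, got {egfr}")
    if egfr >= 60.0:
        return EgfrCategory.GE60
    if egfr >= 45.0:
        return EgfrCategory.C45_59
    if egfr >= 30.0:
        return EgfrCategory.C30_44
    if egfr >= 15.0:
        return EgfrCategory.C15_29
    return EgfrCategory.EXCLUDED_LT15


def categorize_acr(acr: float) -> AlbuminuriaCategory:
    # boundary values 30 and 300 mg/g are MILD (inclusive range)
    if acr < ACR_MILD_LOWER:
        return AlbuminuriaCategory.NORMAL
    if acr <= ACR_HEAVY_LOWER:
        return AlbuminuriaCategory.MILD
    return AlbuminuriaCategory.HEAVY


def categorize_dipstick(reading: Dipstick) -> AlbuminuriaCategory:
    # negative -> normal; trace/1+ -> mild; 2+ and above -> heavy
    if reading.ordinal == 0:
        return AlbuminuriaCategory.NORMAL
    if reading.ordinal <= 2:
        return AlbuminuriaCategory.MILD
    return AlbuminuriaCategory.HEAVY


def summarize_albuminuria(
    acr_values: list[float],
    dipstick_values: list[Dipstick],
    window_ok: bool = True,
) -> tuple[AlbuminuriaCategory, AlbuminuriaSource]:
    """Baseline albuminuria category from repeated measurements.

    ACR takes precedence over dipstick when both are present.  The baseline
    is the median of all respective measurements: arithmetic midpoint for the
    continuous ACR scale, lower-middle value for the ordinal dipstick scale
    (a category cannot be interpolated).

    ``window_ok=False`` marks a person whose only albuminuria measures fall
    outside the ±6-month window around the index creatinine; such records are
    not cohort-eligible.
    """
    if not window_ok:
        raise IneligiblePersonError(
            "albuminuria measurements outside the index window"
        )
    if acr_values:
        med = statistics.median(acr_values)
        return categorize_acr(med), AlbuminuriaSource.ACR
    if dipstick_values:
        ranked = sorted(dipstick_values, key=lambda d: d.ordinal)
        med_reading = ranked[(len(ranked) - 1) // 2]  # lower middle
        return categorize_dipstick(med_reading), AlbuminuriaSource.DIPSTICK
    raise IneligiblePersonError("no albuminuria measurements")


#: KDIGO 2012 prognosis matrix: (eGFR category, albuminuria category) -> risk
_KDIGO_MATRIX = {
    (EgfrCategory.GE60, AlbuminuriaCategory.NORMAL): KdigoRisk.LOW,
    (EgfrCategory.GE60, AlbuminuriaCategory.MILD): KdigoRisk.MODERATE,
    (EgfrCategory.GE60, AlbuminuriaCategory.HEAVY): KdigoRisk.HIGH,
    (EgfrCategory.C45_59, AlbuminuriaCategory.NORMAL): KdigoRisk.MODERATE,
    (EgfrCategory.C45_59, AlbuminuriaCategory.MILD): KdigoRisk.HIGH,
    (EgfrCategory.C45_59, AlbuminuriaCategory.HEAVY): KdigoRisk.VERY_HIGH,
    (EgfrCategory.C30_44, AlbuminuriaCategory.NORMAL): KdigoRisk.HIGH,
    (EgfrCategory.C30_44, AlbuminuriaCategory.MILD): KdigoRisk.VERY_HIGH,
    (EgfrCategory.C30_44, AlbuminuriaCategory.HEAVY): KdigoRisk.VERY_HIGH,
    (EgfrCategory.C15_29, AlbuminuriaCategory.NORMAL): KdigoRisk.VERY_HIGH,
    (EgfrCategory.C15_29, AlbuminuriaCategory.MILD): KdigoRisk.VERY_HIGH,
    (EgfrCategory.C15_29, AlbuminuriaCategory.HEAVY): KdigoRisk.VERY_HIGH,
}


def kdigo_risk(
    egfr_cat: EgfrCategory, alb_cat: AlbuminuriaCategory
) -> KdigoRisk:
    """KDIGO 2012 prognosis class for an eligible eGFR/albuminuria pair."""
    if egfr_cat is EgfrCategory.EXCLUDED_LT15:
        raise ValueError("eGFR <15 is excluded from the risk matrix")
    return _KDIGO_MATRIX[(egfr_cat, AlbuminuriaCategory(alb_cat))]


@dataclass(frozen=True)
class KidneyProfile:
    """Derived classification for one person."""

    egfr_value: float
    egfr_category: EgfrCategory
    albuminuria_category: AlbuminuriaCategory | None
    albuminuria_source: AlbuminuriaSource | None
    kdigo_risk: KdigoRisk | None
    excluded: bool = False
    exclusion_reason: str | None = None


def classify_person(
    person: Person, params: CkdEpiParams = DEFAULT_CKDEPI
) -> KidneyProfile:
    """Full baseline classification with cohort exclusions.

    Excluded persons (dialysis/transplant at entry, or eGFR <15) carry a
    reason and are dropped from downstream strata by the pipeline.
    """
    egfr = compute_egfr(
        person.serum_creatinine, person.index_age, person.sex, params
    )
    egfr_cat = categorize_egfr(egfr)
    if person.on_dialysis_or_transplant:
        return KidneyProfile(
            egfr_value=egfr,
            egfr_category=egfr_cat,
            albuminuria_category=None,
            albuminuria_source=None,
            kdigo_risk=None,
            excluded=True,
            exclusion_reason="dialysis_or_transplant",
        )
    if egfr_cat is EgfrCategory.EXCLUDED_LT15:
        return KidneyProfile(
            egfr_value=egfr,
            egfr_category=egfr_cat,
            albuminuria_category=None,
            albuminuria_source=None,
            kdigo_risk=None,
            excluded=True,
            exclusion_reason="egfr_lt15",
        )
    alb_cat, source = summarize_albuminuria(
        person.acr_values, person.dipstick_values
    )
    return KidneyProfile(
        egfr_value=egfr,
        egfr_category=egfr_cat,
        albuminuria_category=alb_cat,
        albuminuria_source=source,
        kdigo_risk=kdigo_risk(egfr_cat, alb_cat),
    )
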