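"""Synthetic cohorts with known piecewise-constant mortality hazards.

Stands in for the inaccessible registry data: every stratum
(sex × eGFR category × albuminuria category) gets a vector of band-specific
hazards, death times are drawn exactly by inverse-CDF sampling on the
piecewise-exponential survival function, and measurement values (creatinine,
ACR, dipstick) are generated to be consistent with the stratum's categories.
The closed-form expectancy of the generating model
(:func:`analytic_life_expectancy`) is the oracle against which the life-table
estimator is validated.

Ages below the band scheme's start use the first band's hazard; this only
affects survival up to the scheme start (left truncation), never the rates
within tabulated bands.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import brentq

from .kidney_classify import (
    DEFAULT_CKDEPI,
    AlbuminuriaCategory,
    CkdEpiParams,
    EgfrCategory,
    compute_egfr,
)
from .person import Dipstick, Person, Sex
from .persontime import DEFAULT_SCHEME, AgeBandScheme

StratumKey = tuple[Sex, EgfrCategory, AlbuminuriaCategory]

#: target-eGFR sampling interval per category (top category capped at 150)
EGFR_INTERVALS: dict[EgfrCategory, tuple[float, float]] = {
    EgfrCategory.GE60: (60.0, 150.0),
    EgfrCategory.C45_59: (45.0, 60.0),
    EgfrCategory.C30_44: (30.0, 45.0),
    EgfrCategory.C15_29: (15.0, 30.0),
}

#: ACR sampling bounds (mg/g) per category, shrunk 5% inside the thresholds
#: so that medians of noisy repeats stay in-category
ACR_INTERVALS: dict[AlbuminuriaCategory, tuple[float, float]] = {
    AlbuminuriaCategory.NORMAL: (1.0, 30.0 * 0.95),
    AlbuminuriaCategory.MILD: (30.0 * 1.05, 300.0 * 0.95),
    AlbuminuriaCategory.HEAVY: (300.0 * 1.05, 5000.0),
}

_DIPSTICK_CHOICES: dict[AlbuminuriaCategory, list[Dipstick]] = {
    AlbuminuriaCategory.NORMAL: [Dipstick.NEGATIVE],
    AlbuminuriaCategory.MILD: [Dipstick.TRACE, Dipstick.PLUS1],
    AlbuminuriaCategory.HEAVY: [Dipstick.PLUS2, Dipstick.PLUS3],
}


@dataclass(frozen=True)
class HazardSpec:
    """Ground-truth hazards (deaths per person-year) per stratum and band."""

    strata: Mapping[StratumKey, np.ndarray]
    scheme: AgeBandScheme = DEFAULT_SCHEME

    def __post_init__(self) -> None:
        n = self.scheme.n_bands
        normalized = {}
        for key, hazards in self.strata.items():
            h = np.asarray(hazards, dtype=float)
            if h.shape != (n,):
                raise ValueError(
                    f"stratum {key}: expected {n} hazards, got {h.shape}"
                )
            if np.any(h < 0):
                raise ValueError(f"stratum {key}: negative hazard")
            if h[-1] <= 0:
                raise ValueError(
                    f"stratum {key}: terminal-band hazard must be positive "
                    "(expectancy diverges otherwise)"
                )
            normalized[key] = h
        object.__setattr__(self, "strata", normalized)

    def hazards_for(self, stratum: StratumKey) -> np.ndarray:
        try:
            return self.strata[stratum]
        except KeyError:
            raise KeyError(f"unknown stratum {stratum!r}") from None


def constant_hazard_spec(
    rate: float,
    strata: Sequence[StratumKey],
    scheme: AgeBandScheme = DEFAULT_SCHEME,
) -> HazardSpec:
    """Convenience: the same constant hazard in every band of each stratum."""
    h = np.full(scheme.n_bands, rate)
    return HazardSpec({k: h.copy() for k in strata}, scheme)


@dataclass(frozen=True)
class CohortConfig:
    n_per_stratum: int = 1000
    index_age_range: tuple[float, float] = (30.0, 90.0)
    admin_followup_years: float = 7.0
    min_followup_years: float = 1.0
    acr_log_spread: float = 0.15
    dipstick_probability: float = 0.3
    n_measurements: int = 3
    comorbidity_prevalence: Mapping[str, float] = field(
        default_factory=lambda: {
            "diabetes": 0.12, "hypertension": 0.38, "cvd": 0.08,
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_stratum <= 0:
            raise ValueError("n_per_stratum must be positive")
        if self.admin_followup_years <= 0:
            raise ValueError("admin_followup_years must be positive")
        if not 0 < self.min_followup_years <= self.admin_followup_years:
            raise ValueError("need 0 < min_followup_years <= admin horizon")
        lo, hi = self.index_age_range
        if not (30.0 <= lo < hi):
            raise ValueError("index ages must lie in [30, inf) with lo < hi")
        if not 0.0 <= self.dipstick_probability <= 1.0:
            raise ValueError("dipstick_probability must be in [0, 1]")
        if self.n_measurements < 1:
            raise ValueError("need at least one measurement per person")
        for name, p in self.comorbidity_prevalence.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence {name}={p} outside [0, 1]")


# ---------------------------------------------------------------------------
# hazard machinery

def _age_grid(spec_hazards: np.ndarray, scheme: AgeBandScheme):
    """Piecewise-constant hazard over [0, inf).

    Grid nodes 0, start, start+w, …, open_start; rate before the scheme start
    equals the first band's rate; the last rate applies forever.
    """
    nodes = np.concatenate(([0.0], scheme.edges))
    rates = np.concatenate(([spec_hazards[0]], spec_hazards))
    return nodes, rates


def _cumulative_hazard_nodes(nodes: np.ndarray, rates: np.ndarray):
    seg = np.diff(nodes) * rates[:-1]
    return np.concatenate(([0.0], np.cumsum(seg)))


def sample_death_ages(
    hazards: np.ndarray,
    entry_ages: np.ndarray,
    rng: np.random.Generator,
    scheme: AgeBandScheme = DEFAULT_SCHEME,
) -> np.ndarray:
    """Exact inverse-CDF death ages under the piecewise-exponential model.

    Conditional on being alive at ``entry_ages``; returns inf where the
    hazard mass never reaches the drawn exponential quantile (only possible
    with a zero terminal rate, which :class:`HazardSpec` forbids but plain
    arrays may carry in tests).
    """
    nodes, rates = _age_grid(np.asarray(hazards, float), scheme)
    cum = _cumulative_hazard_nodes(nodes, rates)
    entry_ages = np.asarray(entry_ages, float)
    h_entry = np.interp(entry_ages, nodes, cum) + np.where(
        entry_ages > nodes[-1], (entry_ages - nodes[-1]) * rates[-1], 0.0
    )
    target = h_entry + rng.exponential(size=entry_ages.shape)

    death = np.empty_like(entry_ages)
    seg = np.searchsorted(cum[1:], target, side="left")
    inside = seg < len(rates) - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        t_inside = nodes[seg[inside]] + (
            target[inside] - cum[seg[inside]]
        ) / rates[seg[inside]]
    death[inside] = t_inside
    tail = ~inside
    if rates[-1] > 0:
        death[tail] = nodes[-1] + (target[tail] - cum[-1]) / rates[-1]
    else:
        death[tail] = np.inf
    return np.maximum(death, entry_ages)


def analytic_life_expectancy(
    spec: HazardSpec, stratum: StratumKey, start_age: float
) -> float:
    """Exact residual life expectancy under the generating hazards.

    Sums S_j·(1 − exp(−λ_j n_j))/λ_j over closed bands at or above
    ``start_age`` (S_j·n_j when λ_j = 0) plus S_w/λ_w for the open band.
    ``start_age`` must sit on a band boundary of the scheme.
    """
    hazards = spec.hazards_for(stratum)
    scheme = spec.scheme
    starts = scheme.band_starts
    match = np.flatnonzero(np.abs(starts - start_age) < 1e-9)
    if match.size == 0:
        raise ValueError(
            f"start_age {start_age} is not a band boundary of the scheme"
        )
    k = int(match[0])
    w = scheme.n_bands - 1
    if hazards[w] <= 0:
        raise ValueError("terminal hazard is zero: expectancy diverges")
    surv = 1.0
    total = 0.0
    width = scheme.band_width
    for j in range(k, w):
        lam = hazards[j]
        if lam == 0.0:
            total += surv * width
        else:
            total += surv * (1.0 - np.exp(-lam * width)) / lam
            surv *= np.exp(-lam * width)
            continue
        surv *= 1.0  # zero hazard: no attrition
    total += surv / hazards[w]
    return float(total)


# ---------------------------------------------------------------------------
# measurement generation

def invert_egfr(
    target_egfr: float,
    age: float,
    sex: Sex,
    params: CkdEpiParams = DEFAULT_CKDEPI,
) -> float:
    """Serum creatinine (mg/dL) whose eGFR equals ``target_egfr`` (±0.1).

    Solved by monotone root-finding over the physiological range
    [0.2, 20] mg/dL; the equation is strictly decreasing in creatinine.
    """
    if not 5.0 < target_egfr < 200.0:
        raise ValueError(f"target eGFR {target_egfr} outside (5, 200)")
    if age < 18:
        raise ValueError("equation not validated below age 18")
    lo, hi = 0.2, 20.0

    def f(scr: float) -> float:
        return compute_egfr(scr, age, sex, params) - target_egfr

    if f(lo) < 0 or f(hi) > 0:
        raise ValueError(
            f"no creatinine in [{lo}, {hi}] mg/dL yields eGFR {target_egfr} "
            f"at age {age}"
        )
    return float(brentq(f, lo, hi, xtol=1e-10))


def _creatinine_for_egfr(
    target: np.ndarray,
    age: np.ndarray,
    sex: Sex,
    params: CkdEpiParams = DEFAULT_CKDEPI,
) -> np.ndarray:
    """Closed-form vectorized inverse of the eGFR equation (one sex)."""
    target = np.asarray(target, float)
    kappa = params.kappa(sex)
    alpha = params.alpha(sex)
    base = params.intercept * params.age_base ** np.asarray(age, float)
    if sex is Sex.FEMALE:
        base = base * params.female_factor
    if params.apply_ethnicity_factor:
        base = base * params.ethnicity_factor
    ratio = target / base  # value of the creatinine spline at scr
    # ratio > 1 iff scr < kappa (low-creatinine branch, exponent alpha)
    exponent = np.where(ratio > 1.0, alpha, params.slope_exponent)
    return kappa * ratio ** (1.0 / exponent)


def _log_uniform(
    rng: np.random.Generator, lo: float, hi: float, size: int
) -> np.ndarray:
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size=size))


# ---------------------------------------------------------------------------
# cohort sampling

def _sorted_strata(spec: HazardSpec) -> list[StratumKey]:
    return sorted(
        spec.strata.keys(),
        key=lambda k: (k[0].value, k[1].severity, k[2].severity),
    )


def sample_cohort(config: CohortConfig, spec: HazardSpec) -> list[Person]:
    """Draw a full synthetic cohort; deterministic given ``config.seed``.

    Per stratum: index ages uniform over ``index_age_range``; an exact death
    age from the stratum hazards; administrative censoring at a follow-up
    horizon drawn uniform on [min_followup_years, admin_followup_years]
    (emulating staggered entry with a fixed study end); creatinine obtained
    by inverting the eGFR equation at a target drawn uniform within the
    category interval; ACR log-uniform strictly inside the category bounds
    (or dipstick readings from the category's set); comorbidity flags by
    prevalence.
    """
    rng = np.random.default_rng(config.seed)
    persons: list[Person] = []
    n = config.n_per_stratum
    lo_age, hi_age = config.index_age_range

    for s_idx, key in enumerate(_sorted_strata(spec)):
        sex, egfr_cat, alb_cat = key
        hazards = spec.hazards_for(key)

        index_age = rng.uniform(lo_age, hi_age, size=n)
        death_age = sample_death_ages(hazards, index_age, rng, spec.scheme)
        horizon = rng.uniform(
            config.min_followup_years, config.admin_followup_years, size=n
        )
        censor_age = index_age + horizon
        died = death_age <= censor_age
        exit_age = np.where(died, death_age, censor_age)

        g_lo, g_hi = EGFR_INTERVALS[egfr_cat]
        target_egfr = rng.uniform(g_lo, g_hi, size=n)
        creatinine = _creatinine_for_egfr(target_egfr, index_age, sex)

        use_dipstick = rng.uniform(size=n) < config.dipstick_probability
        a_lo, a_hi = ACR_INTERVALS[alb_cat]
        acr_draws = np.exp(
            rng.normal(
                np.log(_log_uniform(rng, a_lo, a_hi, n))[:, None],
                config.acr_log_spread,
                size=(n, config.n_measurements),
            )
        )
        acr_draws = np.clip(acr_draws, a_lo, a_hi)
        stick_pool = _DIPSTICK_CHOICES[alb_cat]
        stick_idx = rng.integers(
            0, len(stick_pool), size=(n, config.n_measurements)
        )

        prev = config.comorbidity_prevalence
        diabetes = rng.uniform(size=n) < prev.get("diabetes", 0.0)
        hypertension = rng.uniform(size=n) < prev.get("hypertension", 0.0)
        cvd = rng.uniform(size=n) < prev.get("cvd", 0.0)

        for i in range(n):
            if use_dipstick[i]:
                acr: list[float] = []
                sticks = [stick_pool[j] for j in stick_idx[i]]
            else:
                acr = [round(float(v), 4) for v in acr_draws[i]]
                sticks = []
            persons.append(
                Person(
                    id=f"s{s_idx:02d}-{i:06d}",
                    sex=sex,
                    index_age=float(index_age[i]),
                    serum_creatinine=round(float(creatinine[i]), 6),
                    acr_values=acr,
                    dipstick_values=sticks,
                    has_diabetes=bool(diabetes[i]),
                    has_hypertension=bool(hypertension[i]),
                    has_cvd=bool(cvd[i]),
                    exit_age=float(exit_age[i]),
                    died=bool(died[i]),
                )
            )
    return persons


def calibrate_hazard_scale(
    shape: np.ndarray,
    target_e: float,
    start_age: float,
    scheme: AgeBandScheme = DEFAULT_SCHEME,
) -> np.ndarray:
    """Scale a hazard shape so the analytic expectancy at ``start_age``
    equals ``target_e``."""
    shape = np.asarray(shape, float)
    key = (Sex.MALE, EgfrCategory.GE60, AlbuminuriaCategory.NORMAL)

    def gap(c: float) -> float:
        spec = HazardSpec({key: c * shape}, scheme)
        return analytic_life_expectancy(spec, key, start_age) - target_e

    c = brentq(gap, 1e-6, 50.0, xtol=1e-12)
    return c * shape
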