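"""Chiang abridged life tables with variances and confidence intervals.

Closed bands use the standard rate→probability conversion
``q = n·m / (1 + n·(1−a)·m)`` with ``a = 0.5`` by default; the terminal band
is closed with ``q = 1`` and ``L = l/m``.  The variance of the expectancy
follows Chiang's estimator, augmented with a delta-method term
``1/(m_w²·D_w)`` for the open interval so that confidence intervals exist at
the last tabulated age.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .persontime import AgeBandScheme, StratumCounts

Z_95 = 1.959963984540054  # standard-normal 97.5% quantile


def mortality_rates(counts: StratumCounts) -> np.ndarray:
    """Age-specific death rates m_i = D_i / PY_i (per person-year)."""
    empty = np.flatnonzero(counts.person_years <= 0)
    if empty.size:
        labels = [counts.scheme.labels()[j] for j in empty]
        raise ValueError(
            f"stratum {counts.key}: zero person-years in bands {labels}; "
            "too sparse for a life table"
        )
    return counts.deaths / counts.person_years


@dataclass(frozen=True)
class LifeTableRow:
    band_start: float
    band_width: float
    a: float
    deaths: float
    person_years: float
    m: float
    q: float
    l: float
    d: float
    L: float
    T: float
    e: float
    var_q: float
    se_e: float
    ci_low: float
    ci_high: float


@dataclass
class LifeTable:
    """Abridged life table for one stratum."""

    stratum: str
    radix: float
    rows: list[LifeTableRow]
    scheme: AgeBandScheme
    confidence: float = 0.95

    def row_at(self, index_age: float) -> LifeTableRow:
        for row in self.rows:
            if abs(row.band_start - index_age) < 1e-9:
                return row
        starts = [r.band_start for r in self.rows]
        raise ValueError(
            f"index age {index_age} is not a band start (bands: {starts}); "
            "no interpolation is performed"
        )


def build_life_table(
    counts: StratumCounts,
    radix: float = 100_000.0,
    a_default: float = 0.5,
) -> LifeTable:
    """Abridged life table from band-level deaths and person-years.

    Requires positive exposure in every band and at least one death in the
    terminal band (otherwise the terminal rate/variance are undefined and the
    stratum is unreportable).
    """
    if radix <= 0:
        raise ValueError("radix must be positive")
    scheme = counts.scheme
    m = mortality_rates(counts)
    w = scheme.n_bands - 1
    if counts.deaths[w] <= 0:
        raise ValueError(
            f"stratum {counts.key}: no deaths in the terminal band; "
            "terminal rate and variance undefined"
        )

    n = np.full(scheme.n_bands, scheme.band_width)
    a = np.full(scheme.n_bands, a_default)

    q = np.empty(scheme.n_bands)
    q[:w] = (n[:w] * m[:w]) / (1.0 + n[:w] * (1.0 - a[:w]) * m[:w])
    q[w] = 1.0
    q = np.clip(q, 0.0, 1.0)

    l = np.empty(scheme.n_bands)
    l[0] = radix
    for j in range(w):
        l[j + 1] = l[j] * (1.0 - q[j])
    d = l * q
    L = np.empty(scheme.n_bands)
    L[:w] = n[:w] * (l[1:] * 1.0 + a[:w] * d[:w])
    # closed L_j = n (l_{j+1} + a d_j); terminal L_w = l_w / m_w
    L[w] = l[w] / m[w]
    T = np.cumsum(L[::-1])[::-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.where(l > 0, T / l, np.nan)

    # Chiang sampling variance of q; zero when no deaths observed
    var_q = np.zeros(scheme.n_bands)
    nz = counts.deaths > 0
    var_q[nz] = q[nz] ** 2 * (1.0 - q[nz]) / counts.deaths[nz]
    var_q[w] = 0.0  # terminal q is 1 by construction

    # variance of e_x: closed-band propagation plus the open-interval term;
    # bands with var_q = 0 contribute nothing even when the table has
    # collapsed (l = 0, e undefined) further down
    terminal_term = l[w] ** 2 / (m[w] ** 2 * counts.deaths[w])
    weights = np.zeros(scheme.n_bands)
    active = var_q[:w] > 0
    factor = np.where(active, (1.0 - a[:w]) * n[:w] + e[1:], 0.0)
    weights[:w] = np.where(
        active, l[:w] ** 2 * factor**2 * var_q[:w], 0.0
    )
    tail = np.cumsum(weights[::-1])[::-1]  # tail[j] = sum_{k>=j} weights[k]
    with np.errstate(divide="ignore", invalid="ignore"):
        var_e = np.where(l > 0, (tail + terminal_term) / l**2, np.nan)
    se_e = np.sqrt(var_e)

    rows = [
        LifeTableRow(
            band_start=float(scheme.band_starts[j]),
            band_width=float(scheme.widths[j]),
            a=float(a[j]),
            deaths=float(counts.deaths[j]),
            person_years=float(counts.person_years[j]),
            m=float(m[j]),
            q=float(q[j]),
            l=float(l[j]),
            d=float(d[j]),
            L=float(L[j]),
            T=float(T[j]),
            e=float(e[j]),
            var_q=float(var_q[j]),
            se_e=float(se_e[j]),
            ci_low=float(e[j] - Z_95 * se_e[j]),
            ci_high=float(e[j] + Z_95 * se_e[j]),
        )
        for j in range(scheme.n_bands)
    ]
    return LifeTable(
        stratum=counts.key, radix=radix, rows=rows, scheme=scheme
    )


def expectancy_at(
    table: LifeTable, index_age: float
) -> tuple[float, float, tuple[float, float]]:
    """(e, se, 95% CI) at a band start; no interpolation between bands."""
    row = table.row_at(index_age)
    return row.e, row.se_e, (row.ci_low, row.ci_high)


@dataclass(frozen=True)
class LEDifference:
    reference: str
    comparison: str
    index_age: float
    difference: float
    se: float
    ci_low: float
    ci_high: float


def expectancy_difference(
    e_ref: float,
    se_ref: float,
    e_cmp: float,
    se_cmp: float,
    index_age: float = float("nan"),
    reference: str = "reference",
    comparison: str = "comparison",
) -> LEDifference:
    """Difference of two independent expectancies with a normal 95% CI."""
    diff = e_ref - e_cmp
    se = float(np.hypot(se_ref, se_cmp))
    return LEDifference(
        reference=reference,
        comparison=comparison,
        index_age=index_age,
        difference=diff,
        se=se,
        ci_low=diff - Z_95 * se,
        ci_high=diff + Z_95 * se,
    )


def le_difference(
    t_ref: LifeTable, t_cmp: LifeTable, index_age: float
) -> LEDifference:
    """Expectancy difference (reference − comparison) between two strata.

    Strata are treated as independent.  Comparing a table with itself yields
    exactly 0 with CI [0, 0].
    """
    if t_ref.scheme != t_cmp.scheme:
        raise ValueError(
            f"mismatched band schemes: {t_ref.scheme} vs {t_cmp.scheme}"
        )
    e_ref, se_ref, _ = expectancy_at(t_ref, index_age)
    e_cmp, se_cmp, _ = expectancy_at(t_cmp, index_age)
    if t_ref.stratum == t_cmp.stratum and t_ref.rows == t_cmp.rows:
        return LEDifference(
            reference=t_ref.stratum,
            comparison=t_cmp.stratum,
            index_age=index_age,
            difference=0.0,
            se=0.0,
            ci_low=0.0,
            ci_high=0.0,
        )
    return expectancy_difference(
        e_ref,
        se_ref,
        e_cmp,
        se_cmp,
        index_age=index_age,
        reference=t_ref.stratum,
        comparison=t_cmp.stratum,
    )
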