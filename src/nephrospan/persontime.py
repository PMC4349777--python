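"""Person-years exposure splitting on an age time scale.

Follow-up is split into 5-year age bands left-truncated at 40 with an open
terminal band at 80+; deaths and person-years are accumulated per
stratum × sex.  Ages are continuous (no rounding).  Deaths at an exact band
boundary go to the higher band, consistent with half-open [a, b) intervals.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

from .kidney_classify import KidneyProfile
from .person import Person, Sex

Grouping = Literal["egfr_x_albuminuria", "kdigo"]


@dataclass(frozen=True)
class AgeBandScheme:
    """5-year bands [start, start+w), …, plus one open terminal band.

    Default: [40,45), [45,50), …, [75,80), [80,∞).
    """

    start_age: float = 40.0
    band_width: float = 5.0
    open_band_start: float = 80.0

    def __post_init__(self) -> None:
        span = self.open_band_start - self.start_age
        if span <= 0 or self.band_width <= 0:
            raise ValueError("degenerate age band scheme")
        if abs(span / self.band_width - round(span / self.band_width)) > 1e-9:
            raise ValueError("open_band_start must align with band_width")

    @property
    def n_closed(self) -> int:
        return round((self.open_band_start - self.start_age) / self.band_width)

    @property
    def n_bands(self) -> int:
        return self.n_closed + 1

    @property
    def edges(self) -> np.ndarray:
        """Closed-band edges: start, start+w, …, open_band_start."""
        return self.start_age + self.band_width * np.arange(self.n_closed + 1)

    @property
    def band_starts(self) -> np.ndarray:
        return np.append(self.edges[:-1], self.open_band_start)

    @property
    def widths(self) -> np.ndarray:
        """Band widths; the terminal band is unbounded (inf)."""
        return np.append(np.full(self.n_closed, self.band_width), np.inf)

    def band_index(self, age: float) -> int:
        """Index of the band containing ``age`` (>= start_age)."""
        if age < self.start_age:
            raise ValueError(f"age {age} below scheme start {self.start_age}")
        return min(int((age - self.start_age) // self.band_width), self.n_closed)

    def labels(self) -> list[str]:
        out = [
            f"{s:g}-{s + self.band_width:g}" for s in self.edges[:-1]
        ]
        out.append(f"{self.open_band_start:g}+")
        return out


DEFAULT_SCHEME = AgeBandScheme()


def split_exposure(
    entry_age: float,
    exit_age: float,
    died: bool,
    scheme: AgeBandScheme = DEFAULT_SCHEME,
) -> tuple[np.ndarray, int | None]:
    """Per-band person-years and the death band for one person.

    Exposure before ``scheme.start_age`` contributes nothing; the death
    indicator lands in the band containing ``exit_age`` when the person died
    at or after the scheme start.
    """
    if exit_age < entry_age:
        raise ValueError(f"exit_age {exit_age} < entry_age {entry_age}")
    lo = np.append(scheme.edges[:-1], scheme.open_band_start)
    hi = np.append(scheme.edges[1:], np.inf)
    py = np.clip(
        np.minimum(exit_age, hi) - np.maximum(entry_age, lo), 0.0, None
    )
    death_band: int | None = None
    if died and exit_age >= scheme.start_age:
        death_band = scheme.band_index(exit_age)
    return py, death_band


def exposure_matrix(
    entry_ages: np.ndarray,
    exit_ages: np.ndarray,
    died: np.ndarray,
    scheme: AgeBandScheme = DEFAULT_SCHEME,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized :func:`split_exposure` for n persons.

    Returns an (n, n_bands) person-years matrix and an int array of death
    band indices (−1 for censored or death before the scheme start).
    """
    entry_ages = np.asarray(entry_ages, dtype=float)
    exit_ages = np.asarray(exit_ages, dtype=float)
    died = np.asarray(died, dtype=bool)
    if np.any(exit_ages < entry_ages):
        raise ValueError("exit_age < entry_age")
    lo = np.append(scheme.edges[:-1], scheme.open_band_start)
    hi = np.append(scheme.edges[1:], np.inf)
    py = np.clip(
        np.minimum(exit_ages[:, None], hi[None, :])
        - np.maximum(entry_ages[:, None], lo[None, :]),
        0.0,
        None,
    )
    idx = np.minimum(
        ((exit_ages - scheme.start_age) // scheme.band_width).astype(int),
        scheme.n_closed,
    )
    death_band = np.where(died & (exit_ages >= scheme.start_age), idx, -1)
    return py, death_band


@dataclass
class StratumCounts:
    """Deaths and person-years per age band for one stratum × sex."""

    stratum: str
    sex: Sex
    deaths: np.ndarray
    person_years: np.ndarray
    scheme: AgeBandScheme = field(default_factory=AgeBandScheme)

    def __post_init__(self) -> None:
        self.deaths = np.asarray(self.deaths, dtype=float)
        self.person_years = np.asarray(self.person_years, dtype=float)
        n = self.scheme.n_bands
        if len(self.deaths) != n or len(self.person_years) != n:
            raise ValueError(
                f"expected {n} bands, got {len(self.deaths)} deaths / "
                f"{len(self.person_years)} person-year entries"
            )
        if np.any(self.deaths < 0) or np.any(self.person_years < 0):
            raise ValueError("negative counts")
        if np.any((self.person_years == 0) & (self.deaths > 0)):
            raise ValueError("deaths recorded in a band with zero exposure")

    @property
    def key(self) -> str:
        return f"{self.sex.value}|{self.stratum}"


def _stratum_label(profile: KidneyProfile, grouping: Grouping) -> str:
    if grouping == "kdigo":
        assert profile.kdigo_risk is not None
        return profile.kdigo_risk.value
    assert profile.egfr_category is not None
    assert profile.albuminuria_category is not None
    return f"{profile.egfr_category.value}|{profile.albuminuria_category.value}"


def aggregate_counts(
    classified: Iterable[tuple[Person, KidneyProfile]],
    grouping: Grouping = "egfr_x_albuminuria",
    scheme: AgeBandScheme = DEFAULT_SCHEME,
) -> list[StratumCounts]:
    """Sum per-person exposure splits within each sex × grouping cell.

    All persons must be classified and non-excluded.  Total person-years
    across the result equals the summed post-truncation follow-up
    (conservation, exact up to float rounding).
    """
    groups: dict[tuple[Sex, str], list[tuple[Person, KidneyProfile]]] = {}
    for person, profile in classified:
        if profile is None:
            raise ValueError(f"person {person.id} lacks a profile")
        if profile.excluded:
            raise ValueError(
                f"excluded person {person.id} "
                f"({profile.exclusion_reason}) passed to aggregation"
            )
        label = _stratum_label(profile, grouping)
        groups.setdefault((person.sex, label), []).append((person, profile))

    out: list[StratumCounts] = []
    for (sex, label), members in sorted(
        groups.items(), key=lambda kv: (kv[0][0].value, kv[0][1])
    ):
        entry = np.array([p.index_age for p, _ in members])
        exit_ = np.array([p.exit_age for p, _ in members])
        died = np.array([p.died for p, _ in members])
        py, death_band = exposure_matrix(entry, exit_, died, scheme)
        deaths = np.bincount(
            death_band[death_band >= 0], minlength=scheme.n_bands
        ).astype(float)
        out.append(
            StratumCounts(
                stratum=label,
                sex=sex,
                deaths=deaths,
                person_years=py.sum(axis=0),
                scheme=scheme,
            )
        )
    return out


# ---------------------------------------------------------------------------
# CSV round-trip: stratum, sex, band_start, band_width, deaths, person_years

def write_counts_csv(counts: Sequence[StratumCounts], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["stratum", "sex", "band_start", "band_width", "deaths",
             "person_years"]
        )
        for sc in counts:
            starts = sc.scheme.band_starts
            widths = sc.scheme.widths
            for j in range(sc.scheme.n_bands):
                width = "inf" if np.isinf(widths[j]) else f"{widths[j]:g}"
                writer.writerow(
                    [sc.stratum, sc.sex.value, f"{starts[j]:g}", width,
                     f"{sc.deaths[j]:g}", f"{sc.person_years[j]:.10g}"]
                )


def read_counts_csv(path) -> list[StratumCounts]:
    rows: dict[tuple[str, str], list[tuple[float, float, float, float]]] = {}
    with open(path, newline="") as fh:
        for rec in csv.DictReader(fh):
            key = (rec["stratum"], rec["sex"])
            width = np.inf if rec["band_width"] == "inf" else float(
                rec["band_width"]
            )
            rows.setdefault(key, []).append(
                (float(rec["band_start"]), width, float(rec["deaths"]),
                 float(rec["person_years"]))
            )
    out = []
    for (stratum, sex), bands in rows.items():
        bands.sort(key=lambda b: b[0])
        starts = [b[0] for b in bands]
        closed_widths = [b[1] for b in bands if np.isfinite(b[1])]
        if not closed_widths:
            raise ValueError(f"stratum {stratum}: no closed bands")
        scheme = AgeBandScheme(
            start_age=starts[0],
            band_width=closed_widths[0],
            open_band_start=starts[-1],
        )
        out.append(
            StratumCounts(
                stratum=stratum,
                sex=Sex(sex),
                deaths=np.array([b[2] for b in bands]),
                person_years=np.array([b[3] for b in bands]),
                scheme=scheme,
            )
        )
    return out
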