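"""Delimited-text I/O for person-level records.

One row per person; list-valued fields (ACR, dipstick) are
semicolon-delimited within a cell and empty when absent; flags are 0/1.
Creatinine may be read in µmol/L (``creatinine_units="umol/L"``), converted
to mg/dL by dividing by 88.4.
"""
from __future__ import annotations

import csv
from typing import Iterable, Sequence

from .kidney_classify import UMOL_PER_MGDL
from .person import Dipstick, Person, Sex

PERSON_COLUMNS = [
    "id",
    "sex",
    "index_age",
    "serum_creatinine",
    "acr_values",
    "dipstick_values",
    "has_diabetes",
    "has_hypertension",
    "has_cvd",
    "exit_age",
    "died",
    "on_dialysis_or_transplant",
]

_LIST_SEP = ";"


def write_persons_csv(persons: Iterable[Person], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(PERSON_COLUMNS)
        for p in persons:
            writer.writerow(
                [
                    p.id,
                    p.sex.value,
                    f"{p.index_age:.6f}",
                    f"{p.serum_creatinine:.6f}",
                    _LIST_SEP.join(f"{v:g}" for v in p.acr_values),
                    _LIST_SEP.join(d.value for d in p.dipstick_values),
                    int(p.has_diabetes),
                    int(p.has_hypertension),
                    int(p.has_cvd),
                    f"{p.exit_age:.6f}",
                    int(p.died),
                    int(p.on_dialysis_or_transplant),
                ]
            )


def read_persons_csv(path, creatinine_units: str = "mg/dL") -> list[Person]:
    if creatinine_units not in ("mg/dL", "umol/L"):
        raise ValueError(f"unknown creatinine units {creatinine_units!r}")
    factor = 1.0 if creatinine_units == "mg/dL" else 1.0 / UMOL_PER_MGDL
    persons: list[Person] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(PERSON_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise ValueError(f"person CSV missing columns: {sorted(missing)}")
        for rec in reader:
            acr = [
                float(v) for v in rec["acr_values"].split(_LIST_SEP) if v
            ]
            sticks = [
                Dipstick(v)
                for v in rec["dipstick_values"].split(_LIST_SEP)
                if v
            ]
            persons.append(
                Person(
                    id=rec["id"],
                    sex=Sex(rec["sex"]),
                    index_age=float(rec["index_age"]),
                    serum_creatinine=float(rec["serum_creatinine"]) * factor,
                    acr_values=acr,
                    dipstick_values=sticks,
                    has_diabetes=_flag(rec["has_diabetes"]),
                    has_hypertension=_flag(rec["has_hypertension"]),
                    has_cvd=_flag(rec["has_cvd"]),
                    exit_age=float(rec["exit_age"]),
                    died=_flag(rec["died"]),
                    on_dialysis_or_transplant=_flag(
                        rec["on_dialysis_or_transplant"]
                    ),
                )
            )
    return persons


def _flag(value: str) -> bool:
    return value.strip().lower() in ("1", "true", "yes")
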