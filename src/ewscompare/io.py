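"""Readers and writers for the delimited-text study interfaces.

Four input files describe a study (empty cells are missing values):

* ``observations.csv`` — one row per observation set:
  ``admission_id, observed_at (ISO-8601), heart_rate, systolic_bp,
  respiratory_rate, temperature, spo2, on_oxygen (0/1), avpu (A/V/P/U),
  gcs (3-15)`` (one of ``avpu``/``gcs`` per row);
* ``admissions.csv`` — ``admission_id, hospital_id, admitted_at,
  discharged_at, age_years, discharge_status (alive/dead),
  oxygen_prescription_t2rf (0/1)``;
* ``diagnoses.csv`` — long format, ``admission_id, icd10_code``, pooled
  over concurrent and prior admissions upstream;
* ``events.csv`` — ``admission_id, event_type (death/icu_admission/
  cardiac_arrest), event_time, anticipated (0/1, ICU only)``.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .cohort import Admission

__all__ = ["read_observations", "read_admissions", "OBSERVATION_COLUMNS"]

OBSERVATION_COLUMNS = (
    "admission_id",
    "observed_at",
    "heart_rate",
    "systolic_bp",
    "respiratory_rate",
    "temperature",
    "spo2",
    "on_oxygen",
    "avpu",
    "gcs",
)


def read_observations(path: str | Path) -> pd.DataFrame:
    """Read an observation CSV, coercing types; missing stays missing."""
    df = pd.read_csv(path, dtype={"admission_id": str, "avpu": "string"})
    missing = set(OBSERVATION_COLUMNS[:8]) - set(df.columns)
    if missing:
        raise ValueError(f"observations file missing columns: {sorted(missing)}")
    df["observed_at"] = pd.to_datetime(df["observed_at"])
    for col in ("heart_rate", "systolic_bp", "respiratory_rate", "temperature",
                "spo2", "on_oxygen", "gcs"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    if "avpu" in df.columns:
        df["avpu"] = df["avpu"].str.strip().str.upper().replace("", pd.NA)
    return df


def read_admissions(
    admissions_path: str | Path,
    diagnoses_path: str | Path | None = None,
    events_path: str | Path | None = None,
) -> list[Admission]:
    """Assemble :class:`Admission` records from the three administrative CSVs."""
    adm = pd.read_csv(admissions_path, dtype={"admission_id": str, "hospital_id": str})
    adm["admitted_at"] = pd.to_datetime(adm["admitted_at"])
    adm["discharged_at"] = pd.to_datetime(adm["discharged_at"])

    codes: dict[str, set[str]] = {}
    if diagnoses_path is not None:
        diag = pd.read_csv(diagnoses_path, dtype=str)
        for aid, grp in diag.groupby("admission_id"):
            codes[aid] = set(grp["icd10_code"].dropna())

    deaths: dict[str, pd.Timestamp] = {}
    icus: dict[str, list] = {}
    arrests: dict[str, list] = {}
    if events_path is not None:
        ev = pd.read_csv(events_path, dtype={"admission_id": str, "event_type": str})
        ev["event_time"] = pd.to_datetime(ev["event_time"])
        for _, r in ev.iterrows():
            aid = r["admission_id"]
            t = r["event_time"].to_pydatetime()
            kind = r["event_type"]
            if kind == "death":
                deaths[aid] = t
            elif kind == "icu_admission":
                antic = bool(int(float(r.get("anticipated", 0) or 0)))
                icus.setdefault(aid, []).append((t, antic))
            elif kind == "cardiac_arrest":
                arrests.setdefault(aid, []).append(t)
            else:
                raise ValueError(f"unknown event_type {kind!r}")

    out = []
    for _, r in adm.iterrows():
        aid = r["admission_id"]
        out.append(
            Admission(
                admission_id=aid,
                hospital_id=r["hospital_id"],
                admitted_at=r["admitted_at"].to_pydatetime(),
                discharged_at=r["discharged_at"].to_pydatetime(),
                age_years=int(r["age_years"]),
                discharge_status=str(r["discharge_status"]).strip().lower(),
                icd10_codes=frozenset(codes.get(aid, set())),
                oxygen_prescription_t2rf=bool(int(float(r["oxygen_prescription_t2rf"]))),
                death_time=deaths.get(aid),
                icu_admissions=tuple(icus.get(aid, [])),
                cardiac_arrests=tuple(arrests.get(aid, [])),
            )
        )
    return out
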