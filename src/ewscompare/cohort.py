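"""Cohort construction and type-II-respiratory-failure (T2RF) risk groups.

The analysis cohort is built from completed adult admissions by applying, in
a fixed order, the exclusions used for track-and-trigger evaluation studies:

1. age under 16 years;
2. no complete vital-sign observation set during the stay;
3. discharged alive before midnight on the calendar day of admission
   (patients never sick enough to stay overnight);
4. no vital signs recorded in the 24 h before discharge (a proxy for
   patients on end-of-life care pathways, whose observations are typically
   discontinued deliberately).

Each admission is then classified into overlapping risk groups for
hypercapnic (type II) respiratory failure:

* **documented T2RF** — flagged on an oxygen-prescription form;
* **at risk of T2RF** — carrying qualifying ICD-10 diagnoses on the
  concurrent or a prior admission: COPD (J40-J44), bronchiectasis (J47),
  cystic fibrosis (E84), obesity / obesity-hypoventilation (E66), or a
  neuromuscular / chest-wall condition (G12, G47.3, G70, G71, M95.4, Q67.8)
  together with respiratory failure (J96);
* **not at risk** — in neither of the above.

Documented and at-risk may co-occur; "not at risk" is their complement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Admission",
    "RiskGroupFlags",
    "ExclusionTally",
    "apply_exclusions",
    "classify_risk_group",
    "normalise_icd10",
    "risk_flags_frame",
]


@dataclass(frozen=True)
class Admission:
    """Administrative record for one completed hospital admission."""

    admission_id: str
    hospital_id: str
    admitted_at: datetime
    discharged_at: datetime
    age_years: int
    discharge_status: str  # "alive" | "dead"
    icd10_codes: frozenset[str] = frozenset()
    oxygen_prescription_t2rf: bool = False
    death_time: datetime | None = None
    icu_admissions: tuple[tuple[datetime, bool], ...] = ()  # (time, anticipated)
    cardiac_arrests: tuple[datetime, ...] = ()

    def __post_init__(self) -> None:
        if self.discharged_at < self.admitted_at:
            raise ValueError(
                f"{self.admission_id}: discharged before admitted"
            )
        if self.discharge_status not in ("alive", "dead"):
            raise ValueError(
                f"{self.admission_id}: bad discharge_status {self.discharge_status!r}"
            )
        if self.discharge_status == "alive" and self.death_time is not None:
            raise ValueError(f"{self.admission_id}: alive but has death_time")
        if self.death_time is not None and self.death_time > self.discharged_at:
            raise ValueError(f"{self.admission_id}: death after discharge")

    def effective_death_time(self) -> datetime | None:
        """Death time, defaulting to discharge time when status is dead.

        Mortality is derived from discharge status; when no explicit death
        time is recorded the discharge instant is used as its proxy.
        """
        if self.discharge_status != "dead":
            return None
        return self.death_time if self.death_time is not None else self.discharged_at


@dataclass(frozen=True)
class RiskGroupFlags:
    documented_t2rf: bool
    at_risk_t2rf: bool

    @property
    def not_at_risk(self) -> bool:
        return not (self.documented_t2rf or self.at_risk_t2rf)


@dataclass
class ExclusionTally:
    """Flowchart stage counts; stages telescope to the final cohort size."""

    total: int
    removed_age: int
    removed_no_complete_obs: int
    removed_same_day_discharge: int
    removed_no_recent_vitals: int
    final: int

    def __post_init__(self) -> None:
        removed = (
            self.removed_age
            + self.removed_no_complete_obs
            + self.removed_same_day_discharge
            + self.removed_no_recent_vitals
        )
        if self.total - removed != self.final:
            raise ValueError("exclusion tally does not telescope")

    def as_tuple(self) -> tuple[int, int, int, int, int, int]:
        return (
            self.total,
            self.removed_age,
            self.removed_no_complete_obs,
            self.removed_same_day_discharge,
            self.removed_no_recent_vitals,
            self.final,
        )


def apply_exclusions(
    admissions: Sequence[Admission],
    observations: pd.DataFrame,
    *,
    window_hours: float = 24.0,
) -> tuple[list[Admission], ExclusionTally]:
    """Apply the exclusion flowchart and return (cohort, tally).

    ``observations`` is the observation frame (one row per observation set,
    with at least ``admission_id``, ``observed_at`` and the seven vital-sign
    columns).  Observations whose admission_id is unknown are ignored with a
    warning.  Stages are applied in the fixed order age -> completeness ->
    same-day live discharge -> no vitals in the final ``window_hours``.
    """
    from .scoring import complete_mask  # local import to avoid cycle

    ids = {a.admission_id for a in admissions}
    obs = observations
    orphan = ~obs["admission_id"].isin(ids)
    if orphan.any():
        warnings.warn(
            f"{int(orphan.sum())} observations reference unknown admissions; ignored",
            stacklevel=2,
        )
        obs = obs[~orphan]

    observed_at = pd.to_datetime(obs["observed_at"])
    complete = complete_mask(obs)
    has_complete = set(obs.loc[complete, "admission_id"])
    last_obs = observed_at.groupby(obs["admission_id"].to_numpy()).max()

    total = len(admissions)
    survivors = list(admissions)

    removed_age = [a for a in survivors if a.age_years < 16]
    survivors = [a for a in survivors if a.age_years >= 16]

    removed_incomplete = [a for a in survivors if a.admission_id not in has_complete]
    survivors = [a for a in survivors if a.admission_id in has_complete]

    def same_day_alive(a: Admission) -> bool:
        return (
            a.discharge_status == "alive"
            and a.discharged_at.date() == a.admitted_at.date()
        )

    removed_same_day = [a for a in survivors if same_day_alive(a)]
    survivors = [a for a in survivors if not same_day_alive(a)]

    window = timedelta(hours=window_hours)

    def has_recent_vitals(a: Admission) -> bool:
        if a.admission_id not in last_obs.index:
            return False
        return last_obs[a.admission_id] >= a.discharged_at - window

    removed_no_recent = [a for a in survivors if not has_recent_vitals(a)]
    survivors = [a for a in survivors if has_recent_vitals(a)]

    tally = ExclusionTally(
        total=total,
        removed_age=len(removed_age),
        removed_no_complete_obs=len(removed_incomplete),
        removed_same_day_discharge=len(removed_same_day),
        removed_no_recent_vitals=len(removed_no_recent),
        final=len(survivors),
    )
    return survivors, tally


# ---------------------------------------------------------------------------
# ICD-10 risk-group classification
# ---------------------------------------------------------------------------

# 3-character category ranges that qualify on their own.
_STANDALONE_RANGES = (("J40", "J44"), ("J47", "J47"), ("E84", "E84"), ("E66", "E66"))
# Codes qualifying only together with any respiratory-failure (J96) code.
_CONDITIONAL_CATEGORIES = ("G12", "G70", "G71")
_CONDITIONAL_4CHAR = ("G473", "M954", "Q678")


def normalise_icd10(code: str) -> str | None:
    """Uppercase, strip dots/whitespace; None for malformed codes.

    A well-formed code starts with a letter followed by two digits
    (the 3-character category), optionally with further characters.
    """
    if not isinstance(code, str):
        return None
    c = code.strip().upper().replace(".", "")
    if len(c) < 3 or not c[0].isalpha() or not c[1:3].isdigit():
        return None
    return c


def _category(code: str) -> str:
    return code[:3]


def classify_risk_group(
    adm: Admission | None = None,
    *,
    icd10_codes: Iterable[str] | None = None,
    oxygen_prescription_t2rf: bool | None = None,
) -> RiskGroupFlags:
    """Classify an admission (or a raw code set) into T2RF risk groups.

    Matching is prefix-based at ICD-10 category level: ``J44``, ``J440``,
    ``J44.1`` and ``J4409`` all fall in J40-J44; four-character rules
    (G47.3, M95.4, Q67.8) match on the first four significant characters.
    Malformed codes are ignored with a warning.
    """
    if adm is not None:
        icd10_codes = adm.icd10_codes
        oxygen_prescription_t2rf = adm.oxygen_prescription_t2rf
    codes = set()
    for raw in icd10_codes or ():
        norm = normalise_icd10(raw)
        if norm is None:
            warnings.warn(f"malformed ICD-10 code {raw!r} ignored", stacklevel=2)
            continue
        codes.add(norm)

    cats = {_category(c) for c in codes}
    at_risk = any(
        lo <= cat <= hi for cat in cats for lo, hi in _STANDALONE_RANGES
    )
    if not at_risk:
        has_j96 = "J96" in cats
        if has_j96:
            cond = any(cat in _CONDITIONAL_CATEGORIES for cat in cats) or any(
                c[:4] in _CONDITIONAL_4CHAR for c in codes if len(c) >= 4
            )
            at_risk = cond
    return RiskGroupFlags(
        documented_t2rf=bool(oxygen_prescription_t2rf),
        at_risk_t2rf=at_risk,
    )


def risk_flags_frame(admissions: Sequence[Admission]) -> pd.DataFrame:
    """Risk-group flags for a list of admissions, indexed by admission_id."""
    rows = []
    for a in admissions:
        f = classify_risk_group(a)
        rows.append(
            {
                "admission_id": a.admission_id,
                "documented_t2rf": f.documented_t2rf,
                "at_risk_t2rf": f.at_risk_t2rf,
                "not_at_risk": f.not_at_risk,
            }
        )
    return pd.DataFrame(rows).set_index("admission_id")
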