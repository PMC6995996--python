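"""24-hour outcome labelling and the observation-level analysis table.

Every complete observation set of a cohort admission is labelled with four
binary endpoints evaluated over the window ``(observed_at, observed_at + h]``
with horizon ``h`` = 24 h by default:

* ``death24`` — in-hospital death (primary endpoint);
* ``icu24`` — unanticipated ICU admission;
* ``arrest24`` — cardiac arrest;
* ``composite24`` — any of the above.

The window is half-open: an event at the observation instant does not count,
an event exactly ``h`` later does.  Observation sets are analysed as
independent rows, matching the standard design of aggregate-score validation
studies.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timedelta
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .cohort import Admission, RiskGroupFlags
from .scoring import complete_mask, score_frame

__all__ = [
    "OutcomeLabels",
    "label_observation",
    "label_frame",
    "build_analysis_table",
]

Scale2Policy = Literal["by_group", "always", "never"]


@dataclass(frozen=True)
class OutcomeLabels:
    death24: bool
    icu24: bool
    arrest24: bool

    @property
    def composite24(self) -> bool:
        return self.death24 or self.icu24 or self.arrest24


def _validate_event_times(adm: Admission) -> None:
    for t, _ in adm.icu_admissions:
        if t < adm.admitted_at or t > adm.discharged_at:
            raise ValueError(
                f"{adm.admission_id}: ICU admission outside stay window"
            )
    for t in adm.cardiac_arrests:
        if t < adm.admitted_at or t > adm.discharged_at:
            raise ValueError(
                f"{adm.admission_id}: cardiac arrest outside stay window"
            )


def label_observation(
    observed_at: datetime,
    adm: Admission,
    horizon: timedelta = timedelta(hours=24),
) -> OutcomeLabels:
    """Label one observation against the admission's timed events."""
    if observed_at < adm.admitted_at or observed_at > adm.discharged_at:
        raise ValueError(
            f"{adm.admission_id}: observation outside stay window"
        )
    _validate_event_times(adm)
    end = observed_at + horizon

    def in_window(t: datetime) -> bool:
        return observed_at < t <= end

    death = adm.effective_death_time()
    death24 = death is not None and in_window(death)
    icu24 = any(in_window(t) for t, anticipated in adm.icu_admissions if not anticipated)
    arrest24 = any(in_window(t) for t in adm.cardiac_arrests)
    return OutcomeLabels(death24, icu24, arrest24)


def _event_series(
    cohort: Sequence[Admission],
) -> tuple[dict, dict, dict]:
    deaths, icus, arrests = {}, {}, {}
    for a in cohort:
        _validate_event_times(a)
        deaths[a.admission_id] = a.effective_death_time()
        icus[a.admission_id] = [t for t, antic in a.icu_admissions if not antic]
        arrests[a.admission_id] = list(a.cardiac_arrests)
    return deaths, icus, arrests


def label_frame(
    cohort: Sequence[Admission],
    observations: pd.DataFrame,
    horizon_hours: float = 24.0,
    censor_after_icu: bool = False,
) -> pd.DataFrame:
    """Label every observation row (complete or not) of cohort admissions.

    Returns a frame aligned to the sorted observation rows with columns
    ``admission_id``, ``hospital_id``, ``observed_at``, the four labels and
    a ``keep`` mask (False for rows censored after a first unanticipated ICU
    admission, when that sensitivity option is on).
    """
    by_id = {a.admission_id: a for a in cohort}
    obs = observations[observations["admission_id"].isin(by_id)].copy()
    obs["observed_at"] = pd.to_datetime(obs["observed_at"])
    obs = obs.sort_values(["admission_id", "observed_at"], kind="mergesort")
    obs = obs.reset_index(drop=True)

    deaths, icus, arrests = _event_series(cohort)
    horizon = timedelta(hours=horizon_hours)

    n = len(obs)
    death24 = np.zeros(n, dtype=bool)
    icu24 = np.zeros(n, dtype=bool)
    arrest24 = np.zeros(n, dtype=bool)
    keep = np.ones(n, dtype=bool)
    hospital = np.empty(n, dtype=object)

    adm_ids = obs["admission_id"].to_numpy()
    times = obs["observed_at"].to_numpy()
    for i in range(n):
        aid = adm_ids[i]
        t = pd.Timestamp(times[i]).to_pydatetime()
        a = by_id[aid]
        hospital[i] = a.hospital_id
        end = t + horizon
        d = deaths[aid]
        death24[i] = d is not None and t < d <= end
        icu_times = icus[aid]
        icu24[i] = any(t < e <= end for e in icu_times)
        arrest24[i] = any(t < e <= end for e in arrests[aid])
        if censor_after_icu and icu_times and t > min(icu_times):
            keep[i] = False

    labels = obs.copy()
    labels["hospital_id"] = hospital
    labels["death24"] = death24
    labels["icu24"] = icu24
    labels["arrest24"] = arrest24
    labels["composite24"] = death24 | icu24 | arrest24
    labels["keep"] = keep
    return labels


def build_analysis_table(
    cohort: Sequence[Admission],
    observations: pd.DataFrame,
    risk_flags: pd.DataFrame,
    scale2_policy: Scale2Policy = "by_group",
    horizon_hours: float = 24.0,
    censor_after_icu: bool = False,
) -> pd.DataFrame:
    """One labelled row per complete observation set of each cohort admission.

    ``risk_flags`` is indexed by admission_id with boolean columns
    ``documented_t2rf``, ``at_risk_t2rf``, ``not_at_risk``.  The NEWS2 column
    uses SpO2 scale 2 according to ``scale2_policy``:

    * ``"by_group"`` — scale 2 for admissions documented or at risk of T2RF
      (the scale's intended use);
    * ``"always"`` — scale 2 for everyone, which in the not-at-risk group
      quantifies the effect of erroneous use of the scale;
    * ``"never"`` — scale 1 for everyone (NEWS2 then equals NEWS here, since
      the new-confusion item is not modelled).

    ``censor_after_icu`` drops observations recorded after an admission's
    first unanticipated ICU admission (sensitivity analysis; off by default).
    """
    labelled = label_frame(
        cohort, observations, horizon_hours=horizon_hours,
        censor_after_icu=censor_after_icu,
    )
    labelled = labelled[labelled["keep"] & complete_mask(labelled)]
    labelled = labelled.reset_index(drop=True)
    n = len(labelled)
    adm_ids = labelled["admission_id"].to_numpy()

    flags = risk_flags.reindex(adm_ids)
    documented = flags["documented_t2rf"].to_numpy(dtype=bool)
    at_risk = flags["at_risk_t2rf"].to_numpy(dtype=bool)
    not_at_risk = flags["not_at_risk"].to_numpy(dtype=bool)

    if scale2_policy == "always":
        scale2 = np.ones(n, dtype=bool)
    elif scale2_policy == "never":
        scale2 = np.zeros(n, dtype=bool)
    elif scale2_policy == "by_group":
        scale2 = documented | at_risk
    else:
        raise ValueError(f"unknown scale2_policy {scale2_policy!r}")

    out = pd.DataFrame(
        {
            "admission_id": adm_ids,
            "hospital_id": labelled["hospital_id"].to_numpy(),
            "observed_at": labelled["observed_at"].to_numpy(),
            "news": score_frame(labelled, "news"),
            "news2": score_frame(labelled, "news2", scale2=scale2),
            "documented_t2rf": documented,
            "at_risk_t2rf": at_risk,
            "not_at_risk": not_at_risk,
            "death24": labelled["death24"].to_numpy(),
            "icu24": labelled["icu24"].to_numpy(),
            "arrest24": labelled["arrest24"].to_numpy(),
            "composite24": labelled["composite24"].to_numpy(),
        }
    )
    return out
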