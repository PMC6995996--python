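"""Deterministic NEWS / NEWS2 aggregate scores for vital-sign observation sets.

A vital-sign observation set is one timestamped bedside recording of seven
inputs: heart rate, systolic blood pressure, respiratory rate, temperature,
SpO2, the inspired gas at the time of the SpO2 measurement (air or
supplemental oxygen), and conscious level (AVPU, or a GCS value that is first
converted to an AVPU equivalent).  Each input is assigned an integer weight
0-3 from its chart band; supplemental oxygen carries a flat weight; the
aggregate score is the sum of the weights.

NEWS and NEWS2 differ here only in the SpO2 item.  NEWS weights saturations
below 96%.  NEWS2 scale 1 is identical; NEWS2 scale 2 — intended for patients
with, or at risk of, hypercapnic (type II) respiratory failure — has its zero
band at 88-92%, weights values below 88%, and weights values above 92% only
when the patient is on supplemental oxygen.  The NEWS2 "new confusion"
consciousness item is not modelled (only AVPU is supported).

Scoring is complete-case: an observation missing any of the seven inputs is
rejected, mirroring the complete-observation-set rule of the analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime
from typing import Literal, Mapping

import numpy as np
import pandas as pd

from .tables import ScoringSystem, load_news2_tables, load_news_tables

__all__ = [
    "VitalSignSet",
    "AggregateScore",
    "ValidationError",
    "AVPU_LEVELS",
    "gcs_to_avpu",
    "is_complete",
    "score_news",
    "score_news2",
    "score_frame",
    "complete_mask",
]

AVPU_LEVELS = ("A", "V", "P", "U")
_AVPU_ORD = {c: i for i, c in enumerate(AVPU_LEVELS)}

#: GCS -> AVPU conversion: 15 Alert, 9-14 Voice, 4-8 Pain, 3 Unresponsive.
#: The mapping is a declared, configurable convention (several are in
#: clinical use); it is total over 3-15 and monotone.
GCS_TO_AVPU: Mapping[int, str] = {
    **{15: "A"},
    **{g: "V" for g in range(9, 15)},
    **{g: "P" for g in range(4, 9)},
    **{3: "U"},
}

_VITAL_FIELDS = (
    "heart_rate",
    "systolic_bp",
    "respiratory_rate",
    "temperature",
    "spo2",
    "on_oxygen",
    "consciousness",
)


class ValidationError(ValueError):
    """An observation violates the input contract."""


@dataclass(frozen=True)
class VitalSignSet:
    """One timestamped observation set for one admission.

    ``consciousness`` is an AVPU letter, a GCS integer in 3-15, or ``None``;
    any missing field makes the set incomplete and unscorable.
    """

    admission_id: str
    observed_at: datetime | None = None
    heart_rate: float | None = None
    systolic_bp: float | None = None
    respiratory_rate: float | None = None
    temperature: float | None = None
    spo2: float | None = None
    on_oxygen: bool | None = None
    consciousness: str | int | None = None

    def __post_init__(self) -> None:
        if self.spo2 is not None and not (0 <= self.spo2 <= 100):
            raise ValidationError(f"spo2 {self.spo2} outside [0, 100]")
        c = self.consciousness
        if c is not None and not isinstance(c, str):
            if not (3 <= int(c) <= 15):
                raise ValidationError(f"GCS {c} outside 3-15")
        if isinstance(c, str) and c not in _AVPU_ORD:
            raise ValidationError(f"unknown AVPU category {c!r}")

    def avpu(self) -> str | None:
        """Consciousness normalised to AVPU (converting GCS if needed)."""
        c = self.consciousness
        if c is None:
            return None
        if isinstance(c, str):
            return c
        return gcs_to_avpu(int(c))


@dataclass(frozen=True)
class AggregateScore:
    """An aggregate score with its per-component decomposition."""

    value: int
    system: Literal["NEWS", "NEWS2-scale1", "NEWS2-scale2"]
    components: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = sum(self.components.values())
        if total != self.value:
            raise ValidationError(
                f"aggregate {self.value} != component sum {total}"
            )
        if not (0 <= self.value <= 23):
            raise ValidationError(f"aggregate {self.value} outside 0-23")


def gcs_to_avpu(gcs: int) -> str:
    """Convert a Glasgow Coma Scale value (3-15) to its AVPU equivalent."""
    try:
        gcs = int(gcs)
    except (TypeError, ValueError):
        raise ValidationError(f"GCS {gcs!r} is not an integer") from None
    if not 3 <= gcs <= 15:
        raise ValidationError(f"GCS {gcs} outside 3-15")
    return GCS_TO_AVPU[gcs]


def is_complete(obs: VitalSignSet) -> bool:
    """True iff all seven inputs are present (incl. the inspired-gas flag)."""
    return all(getattr(obs, f) is not None for f in _VITAL_FIELDS)


def _score(obs: VitalSignSet, system: ScoringSystem, scale: int, label: str) -> AggregateScore:
    if not is_complete(obs):
        missing = [f for f in _VITAL_FIELDS if getattr(obs, f) is None]
        raise ValidationError(
            f"incomplete observation set (missing: {', '.join(missing)})"
        )
    on_oxygen = bool(obs.on_oxygen)
    components = {
        "respiratory_rate": system.tables["respiratory_rate"].weight(obs.respiratory_rate),
        "spo2": system.spo2_table(scale, on_oxygen).weight(obs.spo2),
        "supplemental_oxygen": system.oxygen_weight if on_oxygen else 0,
        "temperature": system.tables["temperature"].weight(obs.temperature),
        "systolic_bp": system.tables["systolic_bp"].weight(obs.systolic_bp),
        "heart_rate": system.tables["heart_rate"].weight(obs.heart_rate),
        "consciousness": system.consciousness.weight(_AVPU_ORD[obs.avpu()]),
    }
    return AggregateScore(sum(components.values()), label, components)


_DEFAULT_NEWS: ScoringSystem | None = None
_DEFAULT_NEWS2: ScoringSystem | None = None


def _news_system() -> ScoringSystem:
    global _DEFAULT_NEWS
    if _DEFAULT_NEWS is None:
        _DEFAULT_NEWS = load_news_tables()
    return _DEFAULT_NEWS


def _news2_system() -> ScoringSystem:
    global _DEFAULT_NEWS2
    if _DEFAULT_NEWS2 is None:
        _DEFAULT_NEWS2 = load_news2_tables()
    return _DEFAULT_NEWS2


def score_news(obs: VitalSignSet, system: ScoringSystem | None = None) -> AggregateScore:
    """NEWS aggregate score for a complete observation set."""
    return _score(obs, system or _news_system(), scale=1, label="NEWS")


def score_news2(
    obs: VitalSignSet,
    use_scale2: bool = False,
    system: ScoringSystem | None = None,
) -> AggregateScore:
    """NEWS2 aggregate score; ``use_scale2`` selects the SpO2 scale."""
    scale = 2 if use_scale2 else 1
    return _score(
        obs, system or _news2_system(), scale=scale,
        label=f"NEWS2-scale{scale}",
    )


# ---------------------------------------------------------------------------
# Vectorised scoring over observation frames
# ---------------------------------------------------------------------------

_NUMERIC_COLS = ("heart_rate", "systolic_bp", "respiratory_rate", "temperature", "spo2")


def consciousness_ordinal(df: pd.DataFrame) -> np.ndarray:
    """AVPU as ordinal 0-3 (A..U) per row, converting GCS where given.

    Expects ``avpu`` and/or ``gcs`` columns; returns NaN where neither is
    present.
    """
    n = len(df)
    out = np.full(n, np.nan)
    if "avpu" in df.columns:
        avpu = df["avpu"].astype("string")
        for cat, ordv in _AVPU_ORD.items():
            out[(avpu == cat).to_numpy(dtype=bool, na_value=False)] = ordv
    if "gcs" in df.columns:
        gcs = pd.to_numeric(df["gcs"], errors="coerce").to_numpy()
        has = np.isnan(out) & ~np.isnan(gcs)
        if np.any((gcs[has] < 3) | (gcs[has] > 15)):
            raise ValidationError("GCS outside 3-15 in observation frame")
        g = gcs[has]
        conv = np.where(g >= 15, 0.0, np.where(g >= 9, 1.0, np.where(g >= 4, 2.0, 3.0)))
        out[has] = conv
    return out


def complete_mask(df: pd.DataFrame) -> np.ndarray:
    """Row mask: all seven inputs present."""
    ok = np.ones(len(df), dtype=bool)
    for col in _NUMERIC_COLS:
        ok &= pd.to_numeric(df[col], errors="coerce").notna().to_numpy()
    ok &= pd.to_numeric(df["on_oxygen"], errors="coerce").notna().to_numpy()
    ok &= ~np.isnan(consciousness_ordinal(df))
    return ok


def score_frame(
    df: pd.DataFrame,
    system: Literal["news", "news2"] = "news",
    scale2: bool | np.ndarray = False,
) -> np.ndarray:
    """Aggregate scores for every row of a complete observation frame.

    ``scale2`` may be a scalar or a per-row boolean array (used when the
    SpO2 scale is chosen per admission by risk group).  Rows must already be
    complete; use :func:`complete_mask` to filter first.
    """
    sys_obj = _news_system() if system == "news" else _news2_system()
    n = len(df)
    if not np.all(complete_mask(df)):
        raise ValidationError("score_frame requires complete rows only")
    scale2_arr = np.broadcast_to(np.asarray(scale2, dtype=bool), (n,))
    if system == "news" and scale2_arr.any():
        raise ValidationError("NEWS has no SpO2 scale 2")

    on_oxy = pd.to_numeric(df["on_oxygen"]).to_numpy().astype(bool)
    total = np.zeros(n, dtype=np.int64)
    for col in ("respiratory_rate", "temperature", "systolic_bp", "heart_rate"):
        total += sys_obj.tables[col].weights(pd.to_numeric(df[col]).to_numpy())

    spo2 = pd.to_numeric(df["spo2"]).to_numpy()
    spo2_w = np.zeros(n, dtype=np.int64)
    for scale_flag in (False, True):
        sel_scale = scale2_arr == scale_flag
        if not sel_scale.any():
            continue
        scale = 2 if scale_flag else 1
        for state_flag in (False, True):
            sel = sel_scale & (on_oxy == state_flag)
            if sel.any():
                tab = sys_obj.spo2_table(scale, state_flag)
                spo2_w[sel] = tab.weights(spo2[sel])
    total += spo2_w
    total += np.where(on_oxy, sys_obj.oxygen_weight, 0)
    total += sys_obj.consciousness.weights(consciousness_ordinal(df))
    return total
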