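"""Weight-table engine for aggregate early-warning scores.

A :class:`ScoreTable` holds the ordered, non-overlapping weight bins for one
physiological parameter.  Bin edges are read from a human-editable CSV shipped
with the package (``data/news.csv`` and ``data/news2.csv``) so that any
discrepancy with a local chart can be corrected in configuration without a
code change.

All comparisons happen in integer "recording units": temperature is recorded
to 0.1 degC, every other parameter to the nearest integer.  Real-valued inputs
are rounded half-up to recording precision before lookup, which makes the
inclusive printed bounds of the charts (e.g. temperature 36.1-38.0) exact and
free of floating-point edge cases.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "ScoreTable",
    "ScoringSystem",
    "TableError",
    "load_system",
    "load_news_tables",
    "load_news2_tables",
    "PRECISION",
]

# Recording precision per parameter (size of one recording unit).
PRECISION: dict[str, float] = {
    "respiratory_rate": 1.0,
    "temperature": 0.1,
    "systolic_bp": 1.0,
    "heart_rate": 1.0,
    "spo2": 1.0,
    "supplemental_oxygen": 1.0,
    "consciousness": 1.0,
}

_OPEN = None  # sentinel for an open-ended bound


class TableError(ValueError):
    """A weight table violates its structural contract."""


#: guards decimal midpoints (e.g. 38.05 degC) against binary representation
_ROUND_EPS = 1e-6


def _to_units(value: float, precision: float) -> int:
    """Round half-up to recording precision, returning integer units."""
    return int(math.floor(value / precision + 0.5 + _ROUND_EPS))


@dataclass(frozen=True)
class ScoreTable:
    """Ordered, non-overlapping weight bins for one parameter.

    ``bins`` are ``(lower, upper, weight)`` triples in integer recording
    units; ``None`` bounds are open-ended.  On construction the bins are
    checked to partition the whole real line: every value maps to exactly
    one bin.
    """

    parameter: str
    bins: tuple[tuple[int | None, int | None, int], ...]
    precision: float = 1.0

    # Derived lookup arrays (integer units).
    _edges: np.ndarray = field(init=False, repr=False, compare=False)
    _weights: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        ordered = sorted(
            self.bins,
            key=lambda b: -np.inf if b[0] is None else b[0],
        )
        if not ordered:
            raise TableError(f"{self.parameter}: empty table")
        # Extreme bins may be open-ended (physiological charts) or closed
        # (categorical encodings); values beyond a closed extreme clamp to
        # the nearest extreme bin, since charts are open-ended at extremes.
        for (lo, up, w) in ordered:
            if w not in (0, 1, 2, 3):
                raise TableError(f"{self.parameter}: weight {w} outside 0-3")
        for (_, up, _), (lo, _, _) in zip(ordered, ordered[1:]):
            if up is None or lo is None or lo != up + 1:
                raise TableError(
                    f"{self.parameter}: bins do not partition the range "
                    f"(gap or overlap at {up}/{lo})"
                )
        # edges[i] = lower bound of bin i+1; searchsorted right gives the bin.
        edges = np.array([b[0] for b in ordered[1:]], dtype=np.int64)
        weights = np.array([b[2] for b in ordered], dtype=np.int64)
        object.__setattr__(self, "bins", tuple(ordered))
        object.__setattr__(self, "_edges", edges)
        object.__setattr__(self, "_weights", weights)

    def weight(self, value: float) -> int:
        """Weight of the unique bin containing ``value`` (scalar)."""
        return int(self.weights(np.asarray([value]))[0])

    def weights(self, values: np.ndarray) -> np.ndarray:
        """Vectorised bin lookup; values are rounded to recording units."""
        v = np.asarray(values, dtype=float)
        units = np.floor(v / self.precision + 0.5 + _ROUND_EPS).astype(np.int64)
        idx = np.searchsorted(self._edges, units, side="right")
        return self._weights[idx]


def component_weight(parameter: str, value: float, table: ScoreTable) -> int:
    """Weight assigned to ``value`` by ``table``.

    Thin named wrapper over :meth:`ScoreTable.weight`; ``parameter`` must
    match the table's own label (guards against passing the wrong table).
    """
    if table.parameter != parameter:
        raise TableError(
            f"table is for {table.parameter!r}, not {parameter!r}"
        )
    return table.weight(value)


@dataclass(frozen=True)
class ScoringSystem:
    """A full set of per-parameter tables for one scoring system.

    ``spo2`` tables are keyed by ``(scale, oxygen_state)``; scale-2 bands
    above 92% differ between air and supplemental oxygen, so the effective
    SpO2 table is resolved per observation.
    """

    name: str
    tables: dict[str, ScoreTable]
    spo2: dict[tuple[int, str], ScoreTable]
    oxygen_weight: int
    consciousness: ScoreTable

    def spo2_table(self, scale: int, on_oxygen: bool) -> ScoreTable:
        state = "oxygen" if on_oxygen else "air"
        try:
            return self.spo2[(scale, state)]
        except KeyError:
            raise TableError(
                f"{self.name}: no SpO2 scale {scale} for state {state!r}"
            ) from None


def _build_spo2_tables(rows: pd.DataFrame) -> dict[tuple[int, str], ScoreTable]:
    out: dict[tuple[int, str], ScoreTable] = {}
    for scale in sorted(rows["scale"].dropna().astype(int).unique()):
        sub = rows[rows["scale"] == scale]
        for state in ("air", "oxygen"):
            applicable = sub[sub["oxygen_state"].isin(["any", state])]
            bins = _rows_to_bins(applicable, PRECISION["spo2"])
            out[(scale, state)] = ScoreTable("spo2", bins, PRECISION["spo2"])
    return out


def _rows_to_bins(rows: pd.DataFrame, precision: float):
    bins = []
    for _, r in rows.iterrows():
        lo = None if pd.isna(r["lower"]) else _to_units(float(r["lower"]), precision)
        up = None if pd.isna(r["upper"]) else _to_units(float(r["upper"]), precision)
        bins.append((lo, up, int(r["weight"])))
    return tuple(bins)


def load_system(path: str | Path, name: str | None = None) -> ScoringSystem:
    """Load a scoring system from a weight-table CSV."""
    path = Path(path)
    df = pd.read_csv(path, comment="#", dtype={"oxygen_state": str})
    df["oxygen_state"] = df["oxygen_state"].fillna("any")
    name = name or path.stem

    tables: dict[str, ScoreTable] = {}
    for param in ("respiratory_rate", "temperature", "systolic_bp", "heart_rate"):
        rows = df[df["parameter"] == param]
        if rows.empty:
            raise TableError(f"{name}: missing table for {param}")
        tables[param] = ScoreTable(
            param, _rows_to_bins(rows, PRECISION[param]), PRECISION[param]
        )

    spo2 = _build_spo2_tables(df[df["parameter"] == "spo2"])
    if not spo2:
        raise TableError(f"{name}: missing SpO2 table")

    oxy_rows = df[df["parameter"] == "supplemental_oxygen"]
    oxy = ScoreTable("supplemental_oxygen", _rows_to_bins(oxy_rows, 1.0), 1.0)
    oxygen_weight = oxy.weight(1)

    consc_rows = df[df["parameter"] == "consciousness"]
    consciousness = ScoreTable("consciousness", _rows_to_bins(consc_rows, 1.0), 1.0)

    return ScoringSystem(
        name=name,
        tables=tables,
        spo2=spo2,
        oxygen_weight=oxygen_weight,
        consciousness=consciousness,
    )


def _data_path(filename: str) -> Path:
    return Path(str(resources.files("ewscompare").joinpath("data", filename)))


def load_news_tables() -> ScoringSystem:
    """The shipped NEWS weight tables."""
    return load_system(_data_path("news.csv"), name="NEWS")


def load_news2_tables() -> ScoringSystem:
    """The shipped NEWS2 weight tables (both SpO2 scales)."""
    return load_system(_data_path("news2.csv"), name="NEWS2")
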