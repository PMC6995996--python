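"""Discrimination analysis: ROC/AUROC, paired bootstrap, thresholds, efficiency.

The c-statistic (AUROC) is computed as tie-adjusted pairwise concordance —
the probability that a randomly chosen outcome-positive observation outscores
a randomly chosen negative one, counting ties as half — via the rank
(Mann-Whitney) identity, which equals the trapezoidal area under the ROC
curve.  Two scoring systems evaluated on the same observations are compared
with a paired bootstrap: each replicate resamples observation rows with
replacement and recomputes both AUROCs on the identical resample, giving
percentile confidence intervals for each AUROC and for their difference.

Triggering follows the "score >= threshold" convention throughout, matching
the recommended review thresholds of 5 and 7 points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "RocCurve",
    "AurocComparison",
    "ThresholdMetrics",
    "DegenerateLabelsError",
    "auroc",
    "roc_curve",
    "bootstrap_compare",
    "threshold_metrics",
    "efficiency_curve",
    "efficiency_delta",
    "stratified_report",
    "LOW_EVENT_THRESHOLD",
]

#: Strata with fewer outcome events than this are flagged as unreliable.
LOW_EVENT_THRESHOLD = 100


class DegenerateLabelsError(ValueError):
    """Labels contain only one class."""


def _check_labels(labels: np.ndarray) -> tuple[int, int]:
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0:
        raise DegenerateLabelsError("no positive labels")
    if n_neg == 0:
        raise DegenerateLabelsError("no negative labels")
    return n_pos, n_neg


def auroc(scores: Sequence[float], labels: Sequence[bool]) -> float:
    """Tie-adjusted concordance (wins + ties/2) / (n_pos * n_neg)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.shape != y.shape:
        raise ValueError("scores and labels must be aligned")
    n_pos, n_neg = _check_labels(y)
    ranks = rankdata(s)
    rank_sum = ranks[y].sum()
    return float((rank_sum - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def _auroc_rows(scores: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Row-wise AUROC for 2-D arrays (replicates in rows); NaN if degenerate."""
    n_pos = labels.sum(axis=1)
    n_neg = labels.shape[1] - n_pos
    ranks = rankdata(scores, axis=1)
    rank_sum = np.where(labels, ranks, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (rank_sum - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    out[(n_pos == 0) | (n_neg == 0)] = np.nan
    return out


@dataclass(frozen=True)
class RocCurve:
    """ROC curve over the attained integer score values.

    ``thresholds`` descend from a +inf sentinel (nothing triggers) through
    every attained score; positives are observations with score >= threshold.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auroc: float


def roc_curve(scores: Sequence[float], labels: Sequence[bool]) -> RocCurve:
    """ROC curve and trapezoidal area for integer-valued scores."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    n_pos, n_neg = _check_labels(y)
    values = np.unique(s)[::-1]
    thresholds = np.concatenate(([np.inf], values))
    sens = np.empty(thresholds.size)
    spec = np.empty(thresholds.size)
    for i, t in enumerate(thresholds):
        trigger = s >= t
        sens[i] = (trigger & y).sum() / n_pos
        spec[i] = (~trigger & ~y).sum() / n_neg
    area = float(np.trapezoid(sens, 1.0 - spec))
    return RocCurve(thresholds, sens, spec, area)


@dataclass(frozen=True)
class AurocComparison:
    """Paired AUROCs with bootstrap CIs and their difference (a - b)."""

    auroc_a: float
    auroc_b: float
    ci_a: tuple[float, float]
    ci_b: tuple[float, float]
    diff_mean: float
    diff_ci: tuple[float, float]
    p_value: float
    n_boot: int
    seed: int
    n_redraws: int

    @property
    def significant(self) -> bool:
        lo, hi = self.diff_ci
        return lo > 0 or hi < 0


def bootstrap_compare(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    labels: Sequence[bool],
    n_boot: int = 2000,
    seed: int = 0,
    cluster_ids: Sequence | None = None,
    max_redraw_rounds: int = 100,
) -> AurocComparison:
    """Paired bootstrap comparison of two scores on the same observations.

    Each replicate resamples rows with replacement (or whole clusters when
    ``cluster_ids`` is given, for a per-admission bootstrap) and computes
    both AUROCs on the same resample.  Replicates that draw a single label
    class are redrawn; after ``max_redraw_rounds`` rounds the comparison
    fails rather than report biased intervals.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if not (a.shape == b.shape == y.shape):
        raise ValueError("scores_a, scores_b, labels must be aligned")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    _check_labels(y)
    point_a = auroc(a, y)
    point_b = auroc(b, y)

    rng = np.random.default_rng(seed)
    n = y.size
    if cluster_ids is not None:
        clusters = pd.factorize(np.asarray(cluster_ids))[0]
        n_clusters = clusters.max() + 1
        members: list[np.ndarray] = [
            np.flatnonzero(clusters == c) for c in range(n_clusters)
        ]

    def draw(count: int) -> np.ndarray:
        if cluster_ids is None:
            return rng.integers(0, n, size=(count, n))
        picks = rng.integers(0, n_clusters, size=(count, n_clusters))
        return _ragged_cluster_indices(picks, members, n)

    boot_a = np.empty(n_boot)
    boot_b = np.empty(n_boot)
    pending = np.arange(n_boot)
    n_redraws = 0
    for _ in range(max_redraw_rounds):
        if pending.size == 0:
            break
        idx = draw(pending.size)
        ra = _auroc_rows(a[idx], y[idx])
        rb = _auroc_rows(b[idx], y[idx])
        ok = ~np.isnan(ra)
        boot_a[pending[ok]] = ra[ok]
        boot_b[pending[ok]] = rb[ok]
        n_redraws += int((~ok).sum())
        pending = pending[~ok]
    if pending.size:
        raise DegenerateLabelsError(
            f"{pending.size} bootstrap replicates degenerate after "
            f"{max_redraw_rounds} redraw rounds"
        )

    diff = boot_a - boot_b
    lo_a, hi_a = np.percentile(boot_a, [2.5, 97.5])
    lo_b, hi_b = np.percentile(boot_b, [2.5, 97.5])
    lo_d, hi_d = np.percentile(diff, [2.5, 97.5])
    if np.array_equal(a, b):
        diff_mean, lo_d, hi_d, p = 0.0, 0.0, 0.0, 1.0
    else:
        diff_mean = float(diff.mean())
        p_le = (diff <= 0).mean()
        p_ge = (diff >= 0).mean()
        p = float(min(1.0, 2 * min(p_le, p_ge)))
    return AurocComparison(
        auroc_a=point_a,
        auroc_b=point_b,
        ci_a=(float(lo_a), float(hi_a)),
        ci_b=(float(lo_b), float(hi_b)),
        diff_mean=float(diff_mean),
        diff_ci=(float(lo_d), float(hi_d)),
        p_value=p,
        n_boot=n_boot,
        seed=seed,
        n_redraws=n_redraws,
    )


def _ragged_cluster_indices(
    picks: np.ndarray, members: list[np.ndarray], n: int
) -> np.ndarray:
    """Cluster bootstrap index matrix, truncated/padded to n columns.

    Resampled clusters vary in total size; rows are truncated (or padded by
    cycling) to keep a rectangular index matrix of width n, which preserves
    the expected resample size.
    """
    rows = []
    for row in picks:
        flat = np.concatenate([members[c] for c in row])
        if flat.size >= n:
            rows.append(flat[:n])
        else:
            reps = int(np.ceil(n / flat.size))
            rows.append(np.tile(flat, reps)[:n])
    return np.stack(rows)


@dataclass(frozen=True)
class ThresholdMetrics:
    """Sensitivity / specificity / PPV (percent) at one trigger threshold."""

    threshold: int
    sensitivity: float
    specificity: float
    ppv: float  # NaN when no observation triggers


def threshold_metrics(
    scores: Sequence[float],
    labels: Sequence[bool],
    thresholds: Iterable[int] = (5, 7),
) -> list[ThresholdMetrics]:
    """2x2 metrics (in percent) at each trigger threshold (score >= t)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    n_pos, n_neg = _check_labels(y)
    out = []
    for t in thresholds:
        if t < 0:
            raise ValueError("thresholds must be nonnegative")
        trigger = s >= t
        tp = int((trigger & y).sum())
        fp = int((trigger & ~y).sum())
        sens = 100.0 * tp / n_pos
        spec = 100.0 * (n_neg - fp) / n_neg
        if tp + fp == 0:
            warnings.warn(
                f"threshold {t}: no predicted positives; PPV undefined",
                stacklevel=2,
            )
            ppv = float("nan")
        else:
            ppv = 100.0 * tp / (tp + fp)
        out.append(ThresholdMetrics(int(t), sens, spec, ppv))
    return out


def efficiency_curve(
    scores: Sequence[float], labels: Sequence[bool]
) -> pd.DataFrame:
    """Workload and sensitivity at every integer threshold 0..max+1.

    Workload is the proportion of all observation sets triggering
    (score >= threshold); sensitivity is the proportion of outcome-positive
    observations triggering.  Both equal 1 at threshold 0 and workload is 0
    above the maximal attained score.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    n_pos, _ = _check_labels(y)
    ts = np.arange(0, int(s.max()) + 2)
    workload = np.array([(s >= t).mean() for t in ts])
    sens = np.array([(y & (s >= t)).sum() / n_pos for t in ts])
    return pd.DataFrame({"threshold": ts, "workload": workload, "sensitivity": sens})


def efficiency_delta(
    curve_a: pd.DataFrame, curve_b: pd.DataFrame, thresholds: Iterable[int] = (5, 7)
) -> pd.DataFrame:
    """Workload / sensitivity differences (b - a) at nominated thresholds."""
    a = curve_a.set_index("threshold")
    b = curve_b.set_index("threshold")
    rows = []
    for t in thresholds:
        wa = a["workload"].get(t, 0.0)
        wb = b["workload"].get(t, 0.0)
        sa = a["sensitivity"].get(t, 0.0)
        sb = b["sensitivity"].get(t, 0.0)
        rows.append(
            {
                "threshold": t,
                "workload_delta": wb - wa,
                "sensitivity_delta": sb - sa,
            }
        )
    return pd.DataFrame(rows)


_ENDPOINTS = ("death24", "icu24", "arrest24", "composite24")
_RISK_STRATA = ("documented_t2rf", "at_risk_t2rf", "not_at_risk")


def stratified_report(
    table: pd.DataFrame,
    strata: str = "risk_group",
    endpoints: Sequence[str] = _ENDPOINTS,
    thresholds: Sequence[int] = (5, 7),
    n_boot: int = 2000,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """AUROC comparison and threshold metrics per stratum x endpoint.

    ``strata`` is ``"risk_group"`` (the three overlapping T2RF groups) or
    ``"hospital_id"`` (sub-analysis by institution).  Returns
    ``(auroc_table, threshold_table)``.  Strata or endpoints with a single
    label class are omitted with a warning; cells with fewer than
    ``LOW_EVENT_THRESHOLD`` outcome events are flagged ``low_events``.
    """
    if strata == "risk_group":
        groups = [(g, table[table[g]]) for g in _RISK_STRATA]
    elif strata == "hospital_id":
        groups = [(h, sub) for h, sub in table.groupby("hospital_id")]
    else:
        raise ValueError(f"unknown strata {strata!r}")

    seeds = np.random.SeedSequence(seed).generate_state(
        len(groups) * len(endpoints)
    )
    auroc_rows, thr_rows = [], []
    k = 0
    for name, sub in groups:
        if sub.empty:
            warnings.warn(f"stratum {name!r} is empty; omitted", stacklevel=2)
            k += len(endpoints)
            continue
        for ep in endpoints:
            cell_seed = int(seeds[k] % (2**31))
            k += 1
            y = sub[ep].to_numpy(dtype=bool)
            n_events = int(y.sum())
            if n_events == 0 or n_events == y.size:
                warnings.warn(
                    f"stratum {name!r}, endpoint {ep!r}: single-class labels; omitted",
                    stacklevel=2,
                )
                continue
            cmp = bootstrap_compare(
                sub["news"].to_numpy(),
                sub["news2"].to_numpy(),
                y,
                n_boot=n_boot,
                seed=cell_seed,
            )
            auroc_rows.append(
                {
                    "stratum": name,
                    "endpoint": ep,
                    "n_obs": len(sub),
                    "n_events": n_events,
                    "low_events": n_events < LOW_EVENT_THRESHOLD,
                    "auroc_news": cmp.auroc_a,
                    "auroc_news_lo": cmp.ci_a[0],
                    "auroc_news_hi": cmp.ci_a[1],
                    "auroc_news2": cmp.auroc_b,
                    "auroc_news2_lo": cmp.ci_b[0],
                    "auroc_news2_hi": cmp.ci_b[1],
                    "diff_mean": cmp.diff_mean,
                    "diff_lo": cmp.diff_ci[0],
                    "diff_hi": cmp.diff_ci[1],
                    "p_value": cmp.p_value,
                    "significant": cmp.significant,
                }
            )
            for system in ("news", "news2"):
                for m in threshold_metrics(
                    sub[system].to_numpy(), y, thresholds
                ):
                    thr_rows.append(
                        {
                            "stratum": name,
                            "endpoint": ep,
                            "system": system,
                            "threshold": m.threshold,
                            "sensitivity": m.sensitivity,
                            "specificity": m.specificity,
                            "ppv": m.ppv,
                        }
                    )
    return pd.DataFrame(auroc_rows), pd.DataFrame(thr_rows)
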