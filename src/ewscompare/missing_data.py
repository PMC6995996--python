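"""Multiple imputation of incomplete vital-sign sets and pooled AUROC.

Missing vitals are filled by chained equations with predictive-mean matching
(PMM): each incomplete variable is regressed (ordinary least squares) on the
other six inputs over the currently-completed data, predictions are made for
both observed and missing rows, and each missing cell receives the observed
value of one of the ``n_donors`` nearest donors by predicted mean.  Because
imputed values are always drawn from observed donors, categorical inputs
(AVPU ordinal, inspired-gas flag) remain valid categories and continuous
inputs stay in the observed range.  Observed cells are never altered.

Aggregate scores are recomputed on each completed dataset — scores are
deterministic functions of the vitals, so they are never imputed directly —
and the per-dataset AUROCs are pooled by Rubin's rules on the logit scale
(within-imputation variance from a row bootstrap, between-imputation
variance across the ``m`` datasets), then back-transformed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .discrimination import auroc
from .scoring import consciousness_ordinal, score_frame

__all__ = ["ImputationResult", "impute", "pooled_auroc", "pool_logit_aurocs"]

_CHAIN_VARS = (
    "heart_rate",
    "systolic_bp",
    "respiratory_rate",
    "temperature",
    "spo2",
    "on_oxygen",
    "consciousness_ord",
)
_INTEGER_VARS = {"heart_rate", "systolic_bp", "respiratory_rate", "spo2",
                 "on_oxygen", "consciousness_ord"}


@dataclass(frozen=True)
class ImputationResult:
    m: int
    aurocs: tuple[float, ...]
    pooled_auroc: float
    pooled_ci: tuple[float, float]
    seed: int


def _design(X: np.ndarray, j: int) -> np.ndarray:
    other = np.delete(X, j, axis=1)
    return np.column_stack([np.ones(len(other)), other])


def impute(
    observations: pd.DataFrame,
    m: int = 5,
    sweeps: int = 10,
    n_donors: int = 5,
    seed: int = 0,
) -> list[pd.DataFrame]:
    """Return ``m`` completed copies of the observation frame.

    The frame uses the standard observation schema (``avpu``/``gcs`` for
    consciousness).  A variable that is missing in every row cannot be
    imputed and raises ``ValueError``.  With no missing values the input is
    returned unchanged ``m`` times.
    """
    if m < 2:
        raise ValueError("m must be >= 2")
    df = observations.reset_index(drop=True)
    work = pd.DataFrame(index=df.index)
    for col in ("heart_rate", "systolic_bp", "respiratory_rate", "temperature",
                "spo2", "on_oxygen"):
        work[col] = pd.to_numeric(df[col], errors="coerce")
    work["consciousness_ord"] = consciousness_ordinal(df)

    X_obs = work[list(_CHAIN_VARS)].to_numpy(dtype=float)
    miss = np.isnan(X_obs)
    for j, var in enumerate(_CHAIN_VARS):
        if miss[:, j].all():
            raise ValueError(f"variable {var!r} missing in all rows; cannot impute")
    if not miss.any():
        return [df.copy() for _ in range(m)]

    rng_master = np.random.default_rng(seed)
    child_seeds = rng_master.integers(0, 2**31, size=m)
    out: list[pd.DataFrame] = []
    for k in range(m):
        rng = np.random.default_rng(int(child_seeds[k]))
        X = X_obs.copy()
        # Initialise missing cells with random observed donors.
        for j in range(X.shape[1]):
            mj = miss[:, j]
            if mj.any():
                donors = X[~mj, j]
                X[mj, j] = rng.choice(donors, size=mj.sum(), replace=True)
        for _ in range(sweeps):
            for j in range(X.shape[1]):
                mj = miss[:, j]
                if not mj.any():
                    continue
                D = _design(X, j)
                beta, *_ = np.linalg.lstsq(D[~mj], X[~mj, j], rcond=None)
                pred = D @ beta
                obs_pred = pred[~mj]
                obs_val = X[~mj, j]
                order = np.argsort(obs_pred, kind="mergesort")
                sorted_pred = obs_pred[order]
                sorted_val = obs_val[order]
                pos = np.searchsorted(sorted_pred, pred[mj])
                n_obs = sorted_val.size
                k_d = min(n_donors, n_obs)
                # Donor pool: window of the k_d nearest observed rows by
                # predicted mean; one donor drawn uniformly from the pool.
                start = np.clip(pos - k_d // 2, 0, n_obs - k_d)
                picks = start + rng.integers(0, k_d, size=pos.size)
                X[mj, j] = sorted_val[picks]
        comp = df.copy()
        for j, var in enumerate(_CHAIN_VARS[:-1]):
            vals = X[:, j]
            if var in _INTEGER_VARS:
                vals = np.round(vals).astype(float)
            col = comp[var].copy()
            col = pd.to_numeric(col, errors="coerce")
            col[miss[:, j]] = vals[miss[:, j]]
            comp[var] = col
        # Consciousness goes back through the AVPU column.
        c_ord = np.round(X[:, -1]).astype(int)
        avpu = comp["avpu"].astype("string") if "avpu" in comp else pd.Series(
            pd.NA, index=comp.index, dtype="string"
        )
        letters = np.array(["A", "V", "P", "U"])
        fill = miss[:, -1]
        avpu[fill] = letters[np.clip(c_ord[fill], 0, 3)]
        comp["avpu"] = avpu
        out.append(comp)
    return out


def pool_logit_aurocs(
    aurocs: np.ndarray, within_var: np.ndarray
) -> tuple[float, tuple[float, float]]:
    """Rubin's rules on logit-AUROCs; returns (pooled, (lo, hi)).

    ``within_var`` are per-imputation variances of the logit-AUROC.  The CI
    uses the Barnard-Rubin small-sample degrees of freedom.
    """
    a = np.asarray(aurocs, dtype=float)
    w = np.asarray(within_var, dtype=float)
    m = a.size
    theta = np.log(a / (1 - a))
    qbar = theta.mean()
    ubar = w.mean()
    b = theta.var(ddof=1) if m > 1 else 0.0
    total = ubar + (1 + 1 / m) * b
    if total == 0:
        lo = hi = qbar
    else:
        if b > 0:
            r = (1 + 1 / m) * b / ubar if ubar > 0 else np.inf
            df = (m - 1) * (1 + 1 / r) ** 2 if np.isfinite(r) else m - 1
        else:
            df = np.inf
        tcrit = stats.t.ppf(0.975, df) if np.isfinite(df) else stats.norm.ppf(0.975)
        half = tcrit * np.sqrt(total)
        lo, hi = qbar - half, qbar + half
    expit = lambda x: 1 / (1 + np.exp(-x))
    return float(expit(qbar)), (float(expit(lo)), float(expit(hi)))


def pooled_auroc(
    imputed: list[pd.DataFrame],
    labels: np.ndarray,
    system: str = "news",
    scale2: bool | np.ndarray = False,
    n_boot_within: int = 200,
    seed: int = 0,
) -> ImputationResult:
    """Score each completed dataset, compute AUROCs, pool by Rubin's rules."""
    if len(imputed) < 2:
        raise ValueError("need at least 2 imputed datasets")
    y = np.asarray(labels, dtype=bool)
    rng = np.random.default_rng(seed)
    aurocs, wvars = [], []
    for df in imputed:
        scores = score_frame(df, system=system, scale2=scale2)
        a = auroc(scores, y)
        aurocs.append(a)
        # Within-imputation variance of logit-AUROC via a row bootstrap.
        n = y.size
        idx = rng.integers(0, n, size=(n_boot_within, n))
        from .discrimination import _auroc_rows

        boot = _auroc_rows(scores[idx].astype(float), y[idx])
        boot = boot[~np.isnan(boot)]
        boot = np.clip(boot, 1e-6, 1 - 1e-6)
        wvars.append(np.log(boot / (1 - boot)).var(ddof=1))
    pooled, ci = pool_logit_aurocs(np.array(aurocs), np.array(wvars))
    return ImputationResult(
        m=len(imputed),
        aurocs=tuple(float(a) for a in aurocs),
        pooled_auroc=pooled,
        pooled_ci=ci,
        seed=seed,
    )
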