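"""Synthetic multi-hospital vital-signs cohorts with known ground truth.

The source data for early-warning-score evaluation — bedside observation
streams linked to admission records, diagnoses and timed adverse events —
cannot be shared, so this module generates cohorts with the statistical
structure the analysis assumes:

* admissions with stay windows, age, discharge status and hospital labels
  across five hospitals in two groups (one group contributes oxygen-
  prescription data, emulating the site-specific documented-T2RF flag);
* a latent per-admission severity trajectory (first-order autocorrelated
  Gaussian on a 4-hourly grid, plus an admission-level frailty offset);
* observation sets at jittered 4-hourly times whose vitals are monotone
  transforms of severity plus noise, with group-specific SpO2 behaviour:
  bell-shaped saturations centred near 91-92% for documented type-II-
  respiratory-failure (T2RF) admissions, and right-skewed saturations
  concentrated in 96-100% for admissions not at risk;
* ICD-10 code lists that place admissions in the at-risk group via the same
  clauses the classifier implements, plus benign distractor codes;
* death / unanticipated-ICU / cardiac-arrest events from a per-interval
  complementary-log-log hazard linear in current severity, with the
  intercept calibrated per risk group by bisection so that realised
  admission-level event rates hit the configured targets (defaults follow
  the published group rates: mortality 11.4% documented, 4.5% at-risk,
  2.3% not-at-risk).

Because events and vitals share the latent severity, any monotone severity
transform (such as the aggregate scores) discriminates events, and the
generator's ground-truth sidecar records everything needed for parameter-
recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_cohort",
    "simulate_binormal_scores",
    "inject_missingness",
    "write_cohort_csvs",
]

_EPOCH = datetime(2016, 1, 1)

_QUALIFYING_STANDALONE = (
    "J44.0", "J44.1", "J44.9", "J43.9", "J42", "J41.0", "J40",
    "J47", "E84.0", "E84.9", "E66.2", "E66.9",
)
_QUALIFYING_CONDITIONAL = ("G12.2", "G47.3", "G70.0", "G71.0", "M95.4", "Q67.8")
_J96 = ("J96.0", "J96.1", "J96.9")
_BENIGN = (
    "I10", "E11.9", "K21.9", "M54.5", "Z51.1", "N39.0", "I48.9",
    "K59.0", "D64.9", "R07.4",
)

_HOSPITALS = (  # (label, share, in OUH-like group with prescription data)
    ("PH", 0.55, False),
    ("JR", 0.25, True),
    ("CH", 0.08, True),
    ("HG", 0.08, True),
    ("NOC", 0.04, True),
)


class SimulationConfig(BaseModel):
    """Generator parameters; defaults emulate the published cohort marginals."""

    n_admissions: int = Field(default=20_000, ge=1)
    #: fraction of admissions with a documented-T2RF oxygen prescription
    prop_documented: float = Field(default=0.0055, ge=0, le=1)
    #: fraction of admissions at risk of T2RF by diagnosis
    prop_at_risk: float = Field(default=0.195, ge=0, le=1)
    #: fraction of documented admissions that also carry at-risk codes
    overlap_documented_at_risk: float = Field(default=0.803, ge=0, le=1)
    #: admission-level in-hospital mortality per group
    mortality: tuple[float, float, float] = (0.114, 0.045, 0.023)
    #: admission-level unanticipated-ICU rates per group
    icu_rate: tuple[float, float, float] = (0.032, 0.012, 0.008)
    #: admission-level cardiac-arrest rates per group
    arrest_rate: tuple[float, float, float] = (0.013, 0.006, 0.003)
    #: mean inter-observation interval (hours); observations sit on this grid
    cadence_hours: float = Field(default=4.0, gt=0)
    #: log-normal length of stay: log-median (days) and log-sd per group
    los_median_days: tuple[float, float, float] = (6.7, 4.0, 2.8)
    los_log_sd: float = 1.0
    #: AR(1) autocorrelation of the severity process per 4-h step
    severity_rho: float = Field(default=0.85, ge=0, lt=1)
    #: sd of the admission-level frailty offset
    frailty_sd: float = 0.7
    #: hazard slope on current severity (event link coefficient)
    event_beta: float = 1.5
    #: vitals-severity coupling multiplier (1 = defaults)
    vitals_coupling: float = 1.0
    #: SpO2 setpoint (mean, sd) for documented-T2RF admissions (bell-shaped)
    spo2_documented: tuple[float, float] = (91.5, 3.0)
    #: SpO2 setpoint (mean, sd) for at-risk admissions
    spo2_at_risk: tuple[float, float] = (94.5, 2.5)
    #: SpO2 right-skew for the not-at-risk group: 100 - offset - Exp(scale)
    spo2_not_at_risk: tuple[float, float] = (2.0, 1.3)
    #: probability of supplemental oxygen per group (baseline, at zero severity)
    oxygen_prob: tuple[float, float, float] = (0.45, 0.20, 0.08)
    #: fraction of observations reporting GCS instead of AVPU
    gcs_fraction: float = Field(default=0.10, ge=0, le=1)
    #: MCAR missingness rate applied to OUH-like hospitals' vitals
    missingness_rate: float = Field(default=0.0, ge=0, lt=1)
    #: fraction of admissions aged under 16 (exclusion-flowchart fodder)
    prop_minors: float = Field(default=0.01, ge=0, le=1)
    #: fraction with observations stopped >24 h before discharge
    prop_censored_tail: float = Field(default=0.01, ge=0, le=1)
    #: fraction of admissions with an anticipated (planned) ICU admission
    prop_anticipated_icu: float = Field(default=0.02, ge=0, le=1)
    seed: int = Field(default=0, ge=0)

    @model_validator(mode="after")
    def _check(self) -> "SimulationConfig":
        for rates in (self.mortality, self.icu_rate, self.arrest_rate):
            if any(not 0 <= r < 1 for r in rates):
                raise ValueError("event rates must lie in [0, 1)")
        if self.prop_documented + self.prop_at_risk > 1:
            raise ValueError("group proportions exceed 1")
        return self


@dataclass
class GroundTruth:
    """Latent state and calibration record for one simulated cohort."""

    config: SimulationConfig
    admission_class: pd.Series  # 'documented' | 'at_risk' | 'not_at_risk'
    severity: dict[str, np.ndarray] = field(repr=False, default_factory=dict)
    hazard_intercepts: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    spo2_setpoint: pd.Series | None = None

    def to_json(self) -> str:
        payload = {
            "config": json.loads(self.config.model_dump_json()),
            "hazard_intercepts": self.hazard_intercepts,
            "class_counts": self.admission_class.value_counts().to_dict(),
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def _calibrate_intercept(
    sev: list[np.ndarray],
    beta: float,
    target: float,
    uniforms: list[np.ndarray],
    alive_mask: list[np.ndarray] | None = None,
) -> float:
    """Bisection on the cloglog intercept so realised event rate hits target.

    ``sev``/``uniforms`` hold per-admission interval severities and the
    uniform draws that decide event firing; the realised rate is a monotone
    step function of the intercept, so bisection converges to within one
    admission of the target.  Raises if the target is unreachable.
    """
    n = len(sev)
    if target == 0 or n == 0:
        return -np.inf
    flat_s = np.concatenate(sev)
    flat_u = np.concatenate(uniforms)
    lengths = np.array([len(s) for s in sev])
    starts = np.concatenate([[0], np.cumsum(lengths)[:-1]])
    flat_m = np.concatenate(alive_mask) if alive_mask is not None else None

    def realised(alpha: float) -> float:
        p = -np.expm1(-np.exp(alpha + beta * flat_s))
        fired = flat_u < p
        if flat_m is not None:
            fired &= flat_m
        return float(np.logical_or.reduceat(fired, starts).mean())

    lo, hi = -20.0, 5.0
    r_hi = realised(hi)
    if r_hi < target:
        raise ValueError(
            f"target rate {target} infeasible; achievable at most {r_hi:.4f}"
        )
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if realised(mid) >= target:
            hi = mid
        else:
            lo = mid
    return hi


def _first_event_times(
    alpha: float, beta: float, sev: np.ndarray, uniforms: np.ndarray
) -> int | None:
    """Index of the first interval whose hazard draw fires, else None."""
    if not np.isfinite(alpha):
        return None
    p = -np.expm1(-np.exp(alpha + beta * sev))
    fired = np.flatnonzero(uniforms < p)
    return int(fired[0]) if fired.size else None


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate (admissions, observations, diagnoses, events, ground_truth).

    The four frames use exactly the CSV schemas consumed by the cohort and
    scoring readers; the run is fully reproducible from ``config.seed``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_admissions
    step_h = cfg.cadence_hours

    # --- group assignment ---------------------------------------------------
    u = rng.random(n)
    documented = u < cfg.prop_documented
    # at-risk codes: forced overlap among documented, plus enough others
    at_risk = np.zeros(n, dtype=bool)
    at_risk[documented] = rng.random(documented.sum()) < cfg.overlap_documented_at_risk
    remaining = cfg.prop_at_risk - (documented & at_risk).mean()
    pool = ~documented
    at_risk[pool] = rng.random(pool.sum()) < remaining / max(pool.mean(), 1e-12)
    # calibration classes: documented dominates, then at-risk, then neither
    cls = np.where(documented, 0, np.where(at_risk, 1, 2))
    class_names = np.array(["documented", "at_risk", "not_at_risk"])

    # --- administrative fields ----------------------------------------------
    hosp_labels = np.array([h[0] for h in _HOSPITALS])
    hosp_shares = np.array([h[1] for h in _HOSPITALS])
    ouh_like = {h[0] for h in _HOSPITALS if h[2]}
    hospital = rng.choice(hosp_labels, size=n, p=hosp_shares / hosp_shares.sum())
    # documented-T2RF prescriptions only exist at OUH-like sites
    documented &= np.isin(hospital, list(ouh_like))
    cls = np.where(documented, 0, np.where(at_risk, 1, 2))

    minors = rng.random(n) < cfg.prop_minors
    age = np.where(
        minors,
        rng.integers(1, 16, size=n),
        np.clip(rng.normal(66, 18, size=n), 16, 102).astype(int),
    )

    los_median = np.array(cfg.los_median_days)[cls]
    los_days = np.exp(np.log(los_median) + cfg.los_log_sd * rng.normal(size=n))
    los_days = np.clip(los_days, 0.15, 90.0)
    admit_offset_h = rng.uniform(0, 24 * 365, size=n)
    admitted = np.array([_EPOCH + timedelta(hours=float(h)) for h in admit_offset_h])

    # --- latent severity on the cadence grid --------------------------------
    n_steps = np.maximum(2, np.ceil(los_days * 24 / step_h).astype(int) + 1)
    rho = cfg.severity_rho
    frailty = rng.normal(0, cfg.frailty_sd, size=n)
    frailty[cls == 0] += 0.3  # documented patients are sicker on average
    sev_paths: list[np.ndarray] = []
    for i in range(n):
        k = n_steps[i]
        eps = rng.normal(size=k)
        z = np.empty(k)
        z[0] = eps[0]
        for t in range(1, k):
            z[t] = rho * z[t - 1] + np.sqrt(1 - rho * rho) * eps[t]
        sev_paths.append(frailty[i] + z)

    # --- event calibration and drawing --------------------------------------
    u_death = [rng.random(len(s)) for s in sev_paths]
    u_icu = [rng.random(len(s)) for s in sev_paths]
    u_arrest = [rng.random(len(s)) for s in sev_paths]
    beta = cfg.event_beta

    alpha_death, alpha_icu, alpha_arrest = {}, {}, {}
    death_step = [None] * n
    for g in range(3):
        idx = np.flatnonzero(cls == g)
        sev_g = [sev_paths[i] for i in idx]
        a_d = _calibrate_intercept(
            sev_g, beta, cfg.mortality[g], [u_death[i] for i in idx]
        )
        alpha_death[g] = a_d
        for i in idx:
            death_step[i] = _first_event_times(a_d, beta, sev_paths[i], u_death[i])

    # survival-truncated exposure for secondary events
    exposure_mask = []
    for i in range(n):
        k = len(sev_paths[i])
        mask = np.ones(k, dtype=bool)
        if death_step[i] is not None:
            mask[death_step[i] + 1:] = False
        exposure_mask.append(mask)

    icu_step = [None] * n
    arrest_step = [None] * n
    for g in range(3):
        idx = np.flatnonzero(cls == g)
        a_i = _calibrate_intercept(
            [sev_paths[i] for i in idx], beta, cfg.icu_rate[g],
            [u_icu[i] for i in idx], [exposure_mask[i] for i in idx],
        )
        a_a = _calibrate_intercept(
            [sev_paths[i] for i in idx], beta, cfg.arrest_rate[g],
            [u_arrest[i] for i in idx], [exposure_mask[i] for i in idx],
        )
        alpha_icu[g], alpha_arrest[g] = a_i, a_a
        for i in idx:
            icu_step[i] = _masked_first(a_i, beta, sev_paths[i], u_icu[i], exposure_mask[i])
            arrest_step[i] = _masked_first(a_a, beta, sev_paths[i], u_arrest[i], exposure_mask[i])

    # --- assemble admissions / events ---------------------------------------
    adm_rows, event_rows, diag_rows = [], [], []
    obs_frames = []
    censored_tail = rng.random(n) < cfg.prop_censored_tail
    anticipated_icu = rng.random(n) < cfg.prop_anticipated_icu
    spo2_setpoints = np.empty(n)

    for i in range(n):
        aid = f"A{i:06d}"
        adm_t = admitted[i]
        died = death_step[i] is not None
        if died:
            stay_h = (death_step[i] + rng.random()) * step_h
        else:
            stay_h = los_days[i] * 24
        stay_h = max(stay_h, 1.0)
        disc_t = adm_t + timedelta(hours=float(stay_h))
        status = "dead" if died else "alive"

        if died:
            event_rows.append(
                {"admission_id": aid, "event_type": "death",
                 "event_time": disc_t, "anticipated": ""}
            )
        if icu_step[i] is not None:
            t = adm_t + timedelta(hours=float(min((icu_step[i] + 0.5) * step_h, stay_h)))
            event_rows.append(
                {"admission_id": aid, "event_type": "icu_admission",
                 "event_time": t, "anticipated": 0}
            )
        if anticipated_icu[i] and stay_h > 12:
            t = adm_t + timedelta(hours=float(rng.uniform(2, min(48, stay_h))))
            event_rows.append(
                {"admission_id": aid, "event_type": "icu_admission",
                 "event_time": t, "anticipated": 1}
            )
        if arrest_step[i] is not None:
            t = adm_t + timedelta(hours=float(min((arrest_step[i] + 0.5) * step_h, stay_h)))
            event_rows.append(
                {"admission_id": aid, "event_type": "cardiac_arrest",
                 "event_time": t, "anticipated": ""}
            )

        adm_rows.append(
            {
                "admission_id": aid,
                "hospital_id": hospital[i],
                "admitted_at": adm_t,
                "discharged_at": disc_t,
                "age_years": int(age[i]),
                "discharge_status": status,
                "oxygen_prescription_t2rf": int(documented[i]),
            }
        )

        # diagnoses
        if at_risk[i]:
            if rng.random() < 0.88:
                diag_rows.append({"admission_id": aid,
                                  "icd10_code": "J44." + str(rng.integers(0, 10))})
            elif rng.random() < 0.7:
                diag_rows.append({"admission_id": aid,
                                  "icd10_code": str(rng.choice(_QUALIFYING_STANDALONE))})
            else:
                diag_rows.append({"admission_id": aid,
                                  "icd10_code": str(rng.choice(_QUALIFYING_CONDITIONAL))})
                diag_rows.append({"admission_id": aid,
                                  "icd10_code": str(rng.choice(_J96))})
        for _ in range(int(rng.integers(0, 3))):
            diag_rows.append({"admission_id": aid,
                              "icd10_code": str(rng.choice(_BENIGN))})

        # --- observations ----------------------------------------------------
        sev = sev_paths[i]
        grid_h = np.arange(len(sev)) * step_h
        keep = grid_h <= stay_h
        if censored_tail[i] and not died:
            keep &= grid_h <= max(stay_h - rng.uniform(30, 72), 1.0)
        if not keep.any():
            keep[0] = True
        t_h = grid_h[keep] + rng.uniform(-0.5, 0.5, size=keep.sum())
        t_h = np.clip(t_h, 0, stay_h)
        # all observable responses react to the coupled severity, so the
        # vitals-severity coupling knob scales every channel coherently
        s = cfg.vitals_coupling * sev[keep]
        m = s.size

        rr = np.round(17 + 3.2 * s + rng.normal(0, 1.5, m))
        hr = np.round(78 + 11 * s + rng.normal(0, 6, m))
        sbp = np.round(122 - 11 * s + rng.normal(0, 9, m))
        temp = np.round(36.9 + 0.25 * s + rng.normal(0, 0.35, m), 1)

        if cls[i] == 0:
            setp = rng.normal(*cfg.spo2_documented)
        elif cls[i] == 1:
            setp = rng.normal(*cfg.spo2_at_risk)
        else:
            off, scale = cfg.spo2_not_at_risk
            setp = 100 - off - rng.exponential(scale)
        spo2_setpoints[i] = setp
        spo2 = np.round(setp - 0.8 * np.maximum(s, 0) + rng.normal(0, 1.0, m))
        spo2 = np.clip(spo2, 50, 100)
        rr = np.clip(rr, 4, 70)
        hr = np.clip(hr, 20, 220)
        sbp = np.clip(sbp, 50, 260)
        temp = np.clip(temp, 33.0, 42.0)

        p_oxy = cfg.oxygen_prob[cls[i]] + 0.15 * np.clip(s, 0, None)
        on_oxy = (rng.random(m) < np.clip(p_oxy, 0, 0.95)).astype(int)

        # consciousness: mostly alert; deeper impairment at high severity
        avpu_ord = np.zeros(m, dtype=int)
        avpu_ord[s > 1.8] = 1
        avpu_ord[s > 2.6] = 2
        avpu_ord[s > 3.2] = 3
        use_gcs = rng.random(m) < cfg.gcs_fraction
        gcs_map = np.array([15, 12, 6, 3])
        letters = np.array(["A", "V", "P", "U"])
        avpu_col = np.where(use_gcs, "", letters[avpu_ord])
        gcs_col = np.where(use_gcs, gcs_map[avpu_ord].astype(float), np.nan)

        obs_frames.append(
            (
                np.repeat(aid, m),
                (np.datetime64(adm_t, "s")
                 + np.round(t_h * 3600).astype("timedelta64[s]")).astype("datetime64[ns]"),
                hr, sbp, rr, temp, spo2, on_oxy, avpu_col, gcs_col,
            )
        )

    admissions = pd.DataFrame(adm_rows)
    cols = (
        "admission_id", "observed_at", "heart_rate", "systolic_bp",
        "respiratory_rate", "temperature", "spo2", "on_oxygen", "avpu", "gcs",
    )
    observations = pd.DataFrame(
        {c: np.concatenate([f[j] for f in obs_frames]) for j, c in enumerate(cols)}
    )
    diagnoses = pd.DataFrame(diag_rows)
    events = pd.DataFrame(
        event_rows, columns=["admission_id", "event_type", "event_time", "anticipated"]
    )

    if cfg.missingness_rate > 0:
        ouh_obs = observations["admission_id"].map(
            admissions.set_index("admission_id")["hospital_id"]
        ).isin(list(ouh_like))
        holes = inject_missingness(
            observations[ouh_obs], cfg.missingness_rate, seed=int(rng.integers(2**31))
        )
        observations = pd.concat(
            [holes, observations[~ouh_obs]], ignore_index=False
        ).sort_index().reset_index(drop=True)

    truth = GroundTruth(
        config=cfg,
        admission_class=pd.Series(
            class_names[cls], index=admissions["admission_id"], name="class"
        ),
        severity={f"A{i:06d}": sev_paths[i] for i in range(n)},
        hazard_intercepts={
            "death": tuple(alpha_death[g] for g in range(3)),
            "icu": tuple(alpha_icu[g] for g in range(3)),
            "arrest": tuple(alpha_arrest[g] for g in range(3)),
        },
        spo2_setpoint=pd.Series(
            spo2_setpoints, index=admissions["admission_id"], name="spo2_setpoint"
        ),
    )
    return admissions, observations, diagnoses, events, truth


def _masked_first(
    alpha: float, beta: float, sev: np.ndarray, uniforms: np.ndarray, mask: np.ndarray
) -> int | None:
    if not np.isfinite(alpha):
        return None
    p = -np.expm1(-np.exp(alpha + beta * sev))
    fired = np.flatnonzero((uniforms < p) & mask)
    return int(fired[0]) if fired.size else None


def simulate_binormal_scores(
    n_pos: int, n_neg: int, mu: float, seed: int = 0
) -> tuple[np.ndarray, np.ndarray, float]:
    """Binormal scores with analytic AUROC Phi(mu / sqrt(2)).

    Negatives are standard normal; positives are shifted by ``mu``.  Returns
    (scores, labels, true_auroc) — the closed-form oracle used to validate
    the empirical c-statistic.
    """
    from scipy.stats import norm

    if n_pos < 1 or n_neg < 1:
        raise ValueError("need at least one observation per class")
    rng = np.random.default_rng(seed)
    scores = np.concatenate([rng.normal(0, 1, n_neg), rng.normal(mu, 1, n_pos)])
    labels = np.concatenate([np.zeros(n_neg, bool), np.ones(n_pos, bool)])
    return scores, labels, float(norm.cdf(mu / np.sqrt(2)))


_BLANKABLE = ("heart_rate", "systolic_bp", "respiratory_rate", "temperature", "spo2")


def inject_missingness(
    observations: pd.DataFrame,
    rate: float,
    pattern: Literal["MCAR"] = "MCAR",
    seed: int = 0,
    include_consciousness: bool = True,
) -> pd.DataFrame:
    """Blank vital-sign cells completely at random at the given rate.

    Key fields (admission_id, observed_at) and the inspired-gas flag are
    never blanked.  ``rate`` = 1 is rejected: no complete row would remain.
    """
    if not 0 <= rate < 1:
        raise ValueError("rate must lie in [0, 1)")
    if pattern != "MCAR":
        raise ValueError(f"unsupported pattern {pattern!r}")
    out = observations.copy()
    if rate == 0:
        return out
    rng = np.random.default_rng(seed)
    n = len(out)
    for col in _BLANKABLE:
        mask = rng.random(n) < rate
        vals = pd.to_numeric(out[col], errors="coerce").astype(float)
        vals[mask] = np.nan
        out[col] = vals
    if include_consciousness:
        mask = rng.random(n) < rate
        if "avpu" in out:
            out.loc[mask, "avpu"] = pd.NA
        if "gcs" in out:
            out.loc[mask, "gcs"] = np.nan
    return out


def write_cohort_csvs(
    out_dir: str | Path,
    admissions: pd.DataFrame,
    observations: pd.DataFrame,
    diagnoses: pd.DataFrame,
    events: pd.DataFrame,
    truth: GroundTruth | None = None,
) -> dict[str, Path]:
    """Write the four cohort CSVs (plus the ground-truth sidecar) to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in (
        ("admissions", admissions),
        ("observations", observations),
        ("diagnoses", diagnoses),
        ("events", events),
    ):
        p = out / f"{name}.csv"
        df.to_csv(p, index=False)
        paths[name] = p
    if truth is not None:
        p = out / "ground_truth.json"
        p.write_text(truth.to_json())
        paths["ground_truth"] = p
    return paths
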