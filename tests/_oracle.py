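"""Independent oracles for the test suite.

The weight oracle below is hand-entered as explicit chained conditions from
the published NEWS/NEWS2 charts, deliberately *not* using the package's bin
machinery, so that the two paths can disagree.  The concordance oracle is a
brute-force loop over all positive-negative pairs.
"""

from __future__ import annotations

import numpy as np


def oracle_rr(v: int) -> int:
    if v <= 8:
        return 3
    if v <= 11:
        return 1
    if v <= 20:
        return 0
    if v <= 24:
        return 2
    return 3


def oracle_temp(v: float) -> int:
    # v in 0.1 degC recording units
    d = round(v * 10)
    if d <= 350:
        return 3
    if d <= 360:
        return 1
    if d <= 380:
        return 0
    if d <= 390:
        return 1
    return 2


def oracle_sbp(v: int) -> int:
    if v <= 90:
        return 3
    if v <= 100:
        return 2
    if v <= 110:
        return 1
    if v <= 219:
        return 0
    return 3


def oracle_hr(v: int) -> int:
    if v <= 40:
        return 3
    if v <= 50:
        return 1
    if v <= 90:
        return 0
    if v <= 110:
        return 1
    if v <= 130:
        return 2
    return 3


def oracle_spo2_scale1(v: int) -> int:
    if v <= 91:
        return 3
    if v <= 93:
        return 2
    if v <= 95:
        return 1
    return 0


def oracle_spo2_scale2(v: int, on_oxygen: bool) -> int:
    if v <= 83:
        return 3
    if v <= 85:
        return 2
    if v <= 87:
        return 1
    if v <= 92:
        return 0
    if not on_oxygen:
        return 0
    if v <= 94:
        return 1
    if v <= 96:
        return 2
    return 3


def oracle_avpu(cat: str) -> int:
    return 0 if cat == "A" else 3


def oracle_news(rr, temp, sbp, hr, spo2, on_oxygen, avpu) -> int:
    return (
        oracle_rr(rr)
        + oracle_temp(temp)
        + oracle_sbp(sbp)
        + oracle_hr(hr)
        + oracle_spo2_scale1(spo2)
        + (2 if on_oxygen else 0)
        + oracle_avpu(avpu)
    )


def oracle_news2_scale2(rr, temp, sbp, hr, spo2, on_oxygen, avpu) -> int:
    return (
        oracle_rr(rr)
        + oracle_temp(temp)
        + oracle_sbp(sbp)
        + oracle_hr(hr)
        + oracle_spo2_scale2(spo2, on_oxygen)
        + (2 if on_oxygen else 0)
        + oracle_avpu(avpu)
    )


def brute_force_concordance(scores, labels) -> float:
    """Tie-adjusted concordance by looping over every (pos, neg) pair."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos = scores[labels]
    neg = scores[~labels]
    wins = ties = 0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1
            elif p == q:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


# ---------------------------------------------------------------------------
# Vectorised oracle (hand-entered np.select chains; independent of the
# package's bin machinery)
# ---------------------------------------------------------------------------

def oracle_rr_vec(v):
    v = np.asarray(v)
    return np.select(
        [v <= 8, v <= 11, v <= 20, v <= 24], [3, 1, 0, 2], default=3
    )


def oracle_temp_vec(v):
    d = np.round(np.asarray(v) * 10).astype(int)
    return np.select(
        [d <= 350, d <= 360, d <= 380, d <= 390], [3, 1, 0, 1], default=2
    )


def oracle_sbp_vec(v):
    v = np.asarray(v)
    return np.select(
        [v <= 90, v <= 100, v <= 110, v <= 219], [3, 2, 1, 0], default=3
    )


def oracle_hr_vec(v):
    v = np.asarray(v)
    return np.select(
        [v <= 40, v <= 50, v <= 90, v <= 110, v <= 130], [3, 1, 0, 1, 2],
        default=3,
    )


def oracle_spo2_scale1_vec(v):
    v = np.asarray(v)
    return np.select([v <= 91, v <= 93, v <= 95], [3, 2, 1], default=0)


def oracle_spo2_scale2_vec(v, on_oxygen):
    v = np.asarray(v)
    on_oxygen = np.asarray(on_oxygen, dtype=bool)
    low = np.select([v <= 83, v <= 85, v <= 87, v <= 92], [3, 2, 1, 0],
                    default=0)
    high = np.select([v <= 92, v <= 94, v <= 96], [0, 1, 2], default=3)
    return np.where(v <= 92, low, np.where(on_oxygen, high, 0))


def oracle_news_vec(rr, temp, sbp, hr, spo2, on_oxygen, avpu_ord):
    return (
        oracle_rr_vec(rr) + oracle_temp_vec(temp) + oracle_sbp_vec(sbp)
        + oracle_hr_vec(hr) + oracle_spo2_scale1_vec(spo2)
        + 2 * np.asarray(on_oxygen, dtype=int)
        + np.where(np.asarray(avpu_ord) == 0, 0, 3)
    )


def oracle_news2_scale2_vec(rr, temp, sbp, hr, spo2, on_oxygen, avpu_ord):
    return (
        oracle_rr_vec(rr) + oracle_temp_vec(temp) + oracle_sbp_vec(sbp)
        + oracle_hr_vec(hr) + oracle_spo2_scale2_vec(spo2, on_oxygen)
        + 2 * np.asarray(on_oxygen, dtype=int)
        + np.where(np.asarray(avpu_ord) == 0, 0, 3)
    )
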