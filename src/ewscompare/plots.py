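"""Optional ROC and efficiency-curve figures (matplotlib, Agg backend)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .discrimination import efficiency_curve, roc_curve

_RISK_STRATA = ("documented_t2rf", "at_risk_t2rf", "not_at_risk")


def plot_roc_curves(
    table: pd.DataFrame, out_dir: str | Path, strata: str = "risk_group",
    endpoint: str = "death24",
) -> list[Path]:
    """One ROC + efficiency figure per stratum; returns written paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if strata == "risk_group":
        groups = [(g, table[table[g]]) for g in _RISK_STRATA]
    else:
        groups = list(table.groupby("hospital_id"))
    written = []
    for name, sub in groups:
        y = sub[endpoint].to_numpy(dtype=bool)
        if sub.empty or y.all() or not y.any():
            continue
        fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
        for system, color in (("news", "C0"), ("news2", "C1")):
            s = sub[system].to_numpy()
            rc = roc_curve(s, y)
            ax1.plot(1 - rc.specificity, rc.sensitivity, color,
                     label=f"{system.upper()} (AUROC {rc.auroc:.3f})")
            eff = efficiency_curve(s, y)
            ax2.plot(eff["workload"], eff["sensitivity"], color,
                     label=system.upper())
        ax1.plot([0, 1], [0, 1], "k:", lw=0.8)
        ax1.set_xlabel("1 - specificity")
        ax1.set_ylabel("sensitivity")
        ax1.legend(loc="lower right", fontsize=8)
        ax2.set_xlabel("workload (fraction triggering)")
        ax2.set_ylabel("sensitivity")
        ax2.legend(loc="lower right", fontsize=8)
        fig.suptitle(f"{name} / {endpoint}")
        fig.tight_layout()
        p = out / f"roc_{name}.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)
    return written
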