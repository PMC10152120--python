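"""Plotting helpers: Bland–Altman panels and half-life distributions.

Purely presentational — every number shown is computed by
:mod:`stpdosim.compare`; nothing here carries analysis logic.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .compare import ComparisonRecord, bland_altman_summary, records_to_frame


def bland_altman_plot(
    records: Iterable[ComparisonRecord],
    method: str,
    voi_group: str,
    path,
) -> None:
    """One Bland–Altman panel per nominal time for a method/VOI stratum."""
    frame = records_to_frame(records)
    frame = frame[(frame["method"] == method) & (frame["voi_group"] == voi_group)]
    times = sorted(frame["nominal_time_h"].unique())
    fig, axes = plt.subplots(1, max(len(times), 1),
                             figsize=(4 * max(len(times), 1), 3.5), squeeze=False)
    for ax, t in zip(axes[0], times):
        sub = frame[frame["nominal_time_h"] == t]
        ax.scatter(sub["tia_ref_MBq_h"], sub["pd_percent"], s=12, alpha=0.6)
        if len(sub) >= 2:
            ba = bland_altman_summary(sub["pd_percent"].to_numpy())
            for y, style in [(ba.mean_diff_percent, "-"),
                             (ba.loa_low_percent, "--"),
                             (ba.loa_high_percent, "--")]:
                ax.axhline(y, color="k", linestyle=style, linewidth=0.8)
        ax.set_title(f"{voi_group}, {method}, {t:.0f} h")
        ax.set_xlabel("MTP reference TIA (MBq·h)")
        ax.set_ylabel("difference (%)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def half_life_histograms(fit_frame, path) -> None:
    """Cycle-1 vs cycle-2 half-life histograms per VOI group."""
    from .compare import voi_group as _grp

    f = fit_frame[fit_frame["is_decaying"]].copy()
    f["voi_group"] = f["voi_type"].map(_grp)
    groups = sorted(f["voi_group"].unique())
    fig, axes = plt.subplots(1, max(len(groups), 1),
                             figsize=(4 * max(len(groups), 1), 3.5), squeeze=False)
    for ax, g in zip(axes[0], groups):
        for cycle, color in [(1, "tab:blue"), (2, "tab:orange")]:
            vals = f[(f["voi_group"] == g) & (f["cycle"] == cycle)][
                "half_life_eff_h"
            ]
            ax.hist(vals, bins=20, alpha=0.5, color=color,
                    label=f"cycle {cycle}")
        ax.set_title(g)
        ax.set_xlabel("effective half-life (h)")
        ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
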