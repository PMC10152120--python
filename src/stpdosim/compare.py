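"""Cohort-level comparison of single-time-point TIA estimates against the
multi-time-point reference.

The central quantity is the percentage difference (PD)

    PD = 100 * (TIA_STP - TIA_ref) / TIA_ref

computed per VOI, per STP method, per nominal imaging time. Summaries follow
standard method-comparison practice: Bland–Altman mean difference with
1.96-SD limits of agreement, Wilcoxon signed-rank tests between paired TIA
sets, and coverage tables of the fraction of VOIs whose PD falls within
±10% / ±20%. Strata pool left and right kidneys into a single "kidney"
group, mirroring how renal dosimetry results are reported.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DomainError, InsufficientDataError, ValidationError
from .stp import StpWindow, in_hanscheid_window, stp_hanscheid, stp_prior
from .tac import (
    LN2,
    MTP_REF,
    STP_H,
    STP_PRIOR,
    MonoExpFit,
    TiaEstimate,
    TimeActivityCurve,
    fit_monoexponential,
    tia_reference,
)

logger = logging.getLogger("stpdosim")

DEFAULT_STP_TIMES = (24.0, 48.0, 72.0)


def voi_group(voi_type: str) -> str:
    """Reporting stratum: left/right kidneys pool into 'kidney'."""
    return "kidney" if voi_type.startswith("kidney") else voi_type


@dataclass(frozen=True)
class ComparisonRecord:
    """PD of one STP estimate versus the MTP reference for one VOI."""

    patient_id: str
    cycle: int
    voi_id: str
    voi_type: str
    method: str
    nominal_time_h: float
    time_used_h: float
    tia_stp_MBq_h: float
    tia_ref_MBq_h: float
    pd_percent: float
    in_window: bool

    @property
    def within_10(self) -> bool:
        return abs(self.pd_percent) <= 10.0

    @property
    def within_20(self) -> bool:
        return abs(self.pd_percent) <= 20.0


def percent_difference(stp: TiaEstimate, ref: TiaEstimate) -> float:
    """``100 * (stp - ref) / ref`` with identity and method checks."""
    if ref.method != MTP_REF:
        raise ValidationError(f"reference estimate has method {ref.method!r}")
    if stp.method == MTP_REF:
        raise ValidationError("stp estimate must be a single-time-point method")
    if (
        stp.source_voi is not None
        and ref.source_voi is not None
        and stp.source_voi != ref.source_voi
    ):
        raise ValidationError(
            f"VOI mismatch: {stp.source_voi} vs {ref.source_voi}"
        )
    if ref.value_MBq_h <= 0:
        raise DomainError("reference TIA must be > 0")
    return 100.0 * (stp.value_MBq_h - ref.value_MBq_h) / ref.value_MBq_h


def _nearest_sample(curve: TimeActivityCurve, nominal_h: float, tol_h: float):
    times = curve.times_h
    i = int(np.argmin(np.abs(times - nominal_h)))
    if abs(times[i] - nominal_h) > tol_h:
        return None
    return curve.samples[i]


def compare_cohort(
    curves: Iterable[TimeActivityCurve],
    stp_times: Sequence[float] = DEFAULT_STP_TIMES,
    *,
    target_cycle: int = 2,
    prior_cycle: int = 1,
    time_tolerance_h: float = 6.0,
    window: StpWindow = StpWindow(),
) -> list[ComparisonRecord]:
    """Run the STP-vs-MTP comparison over a cohort of time–activity curves.

    For every VOI of ``target_cycle`` with a valid (decaying, >= 2 point)
    monoexponential fit, and for every nominal time with a measured sample
    within ``time_tolerance_h``, emits one record per STP method. The
    measured activity (not the model prediction) enters the STP formulas.
    The prior-information method uses the ``prior_cycle`` fit of the same
    VOI and is skipped (with a warning) when that cycle is absent; this
    mirrors restricting lesion analysis to lesions visible in both cycles.
    ``in_window`` is judged against the target cycle's fitted half-life.
    """
    by_voi: dict[tuple[str, str], dict[int, TimeActivityCurve]] = {}
    for c in curves:
        by_voi.setdefault((c.patient_id, c.voi_id), {})[c.cycle] = c

    records: list[ComparisonRecord] = []
    for (patient_id, voi_id), cycles in sorted(by_voi.items()):
        target = cycles.get(target_cycle)
        if target is None or len(target.samples) < 2:
            continue
        fit2 = fit_monoexponential(target)
        if not fit2.is_decaying:
            logger.warning(
                "skipping VOI %s/%s: non-decaying cycle-%d curve",
                patient_id, voi_id, target_cycle,
            )
            continue
        ref = tia_reference(fit2)

        prior_fit: MonoExpFit | None = None
        prior_curve = cycles.get(prior_cycle)
        if prior_curve is not None and len(prior_curve.samples) >= 2:
            cand = fit_monoexponential(prior_curve)
            if cand.is_decaying:
                prior_fit = cand
        if prior_fit is None:
            logger.warning(
                "VOI %s/%s: no usable cycle-%d fit, STP_prior skipped",
                patient_id, voi_id, prior_cycle,
            )

        for nominal in stp_times:
            sample = _nearest_sample(target, nominal, time_tolerance_h)
            if sample is None:
                logger.warning(
                    "VOI %s/%s: no sample within %.1f h of %.0f h",
                    patient_id, voi_id, time_tolerance_h, nominal,
                )
                continue
            in_win = in_hanscheid_window(
                sample.time_h, fit2.half_life_eff_h, window
            )
            estimates = []
            if prior_fit is not None:
                estimates.append(
                    stp_prior(
                        sample.activity_MBq,
                        sample.time_h,
                        prior_fit.half_life_eff_h,
                    )
                )
            estimates.append(stp_hanscheid(sample.activity_MBq, sample.time_h))
            for est in estimates:
                records.append(
                    ComparisonRecord(
                        patient_id=patient_id,
                        cycle=target_cycle,
                        voi_id=voi_id,
                        voi_type=target.voi_type,
                        method=est.method,
                        nominal_time_h=float(nominal),
                        time_used_h=est.time_used_h,
                        tia_stp_MBq_h=est.value_MBq_h,
                        tia_ref_MBq_h=ref.value_MBq_h,
                        pd_percent=percent_difference(est, ref),
                        in_window=in_win,
                    )
                )
    return records


def records_to_frame(records: Iterable[ComparisonRecord]) -> pd.DataFrame:
    rows = [
        {
            "patient_id": r.patient_id,
            "cycle": r.cycle,
            "voi_id": r.voi_id,
            "voi_type": r.voi_type,
            "voi_group": voi_group(r.voi_type),
            "method": r.method,
            "nominal_time_h": r.nominal_time_h,
            "time_used_h": r.time_used_h,
            "tia_stp_MBq_h": r.tia_stp_MBq_h,
            "tia_ref_MBq_h": r.tia_ref_MBq_h,
            "pd_percent": r.pd_percent,
            "within_10": r.within_10,
            "within_20": r.within_20,
            "in_window": r.in_window,
        }
        for r in records
    ]
    columns = [
        "patient_id", "cycle", "voi_id", "voi_type", "voi_group", "method",
        "nominal_time_h", "time_used_h", "tia_stp_MBq_h", "tia_ref_MBq_h",
        "pd_percent", "within_10", "within_20", "in_window",
    ]
    return pd.DataFrame(rows, columns=columns)


@dataclass(frozen=True)
class BlandAltmanSummary:
    """Mean difference and 1.96-SD limits of agreement of paired relative
    differences (percent)."""

    n: int
    mean_diff_percent: float
    sd_diff_percent: float
    loa_low_percent: float
    loa_high_percent: float


def relative_difference(
    stp_value: float, ref_value: float, denominator: str = "reference"
) -> float:
    """Per-pair relative difference in percent.

    ``denominator='reference'`` reproduces the PD definition (MTP reference
    in the denominator); ``'pair_mean'`` is the classical Bland–Altman
    variant with the pair mean in the denominator.
    """
    if denominator == "reference":
        den = ref_value
    elif denominator == "pair_mean":
        den = 0.5 * (stp_value + ref_value)
    else:
        raise ValidationError(f"unknown denominator {denominator!r}")
    if den <= 0:
        raise DomainError("denominator must be > 0")
    return 100.0 * (stp_value - ref_value) / den


def bland_altman_summary(
    diff_percent: Sequence[float], loa_multiplier: float = 1.96
) -> BlandAltmanSummary:
    """Summarize per-pair differences: mean, sample SD (n-1), and limits of
    agreement ``mean ± 1.96 * SD``."""
    d = np.asarray(diff_percent, dtype=float)
    if d.size < 2:
        raise InsufficientDataError(
            f"Bland–Altman summary needs >= 2 pairs, got {d.size}"
        )
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanSummary(
        n=int(d.size),
        mean_diff_percent=mean,
        sd_diff_percent=sd,
        loa_low_percent=mean - loa_multiplier * sd,
        loa_high_percent=mean + loa_multiplier * sd,
    )


def bland_altman_table(
    records: Iterable[ComparisonRecord],
    denominator: str = "reference",
    loa_multiplier: float = 1.96,
) -> pd.DataFrame:
    """Bland–Altman summary per voi_group x method x nominal time."""
    frame = records_to_frame(records)
    rows = []
    for (group, method, t), sub in frame.groupby(
        ["voi_group", "method", "nominal_time_h"], sort=True
    ):
        if len(sub) < 2:
            continue
        if denominator == "reference":
            diffs = sub["pd_percent"].to_numpy()
        else:
            diffs = np.array(
                [
                    relative_difference(s, r, denominator)
                    for s, r in zip(sub["tia_stp_MBq_h"], sub["tia_ref_MBq_h"])
                ]
            )
        ba = bland_altman_summary(diffs, loa_multiplier)
        rows.append(
            {
                "voi_group": group,
                "method": method,
                "nominal_time_h": t,
                "n": ba.n,
                "mean_diff_percent": ba.mean_diff_percent,
                "sd_diff_percent": ba.sd_diff_percent,
                "loa_low_percent": ba.loa_low_percent,
                "loa_high_percent": ba.loa_high_percent,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "voi_group", "method", "nominal_time_h", "n",
            "mean_diff_percent", "sd_diff_percent",
            "loa_low_percent", "loa_high_percent",
        ],
    )


@dataclass(frozen=True)
class WilcoxonResult:
    """Two-sided Wilcoxon signed-rank result.

    ``statistic_W`` is the sum of ranks of positive differences after
    zero differences are dropped and tied magnitudes receive mid-ranks.
    ``degenerate`` flags the all-zero-difference case (p fixed at 1).
    """

    n_used: int
    statistic_W: float
    p_value: float
    method: str  # "exact" | "normal-approximation" | "degenerate"

    @property
    def degenerate(self) -> bool:
        return self.method == "degenerate"


def _exact_two_sided_p(ranks: np.ndarray, w_obs: float) -> float:
    """Exact two-sided p over all 2^n equiprobable sign assignments.

    Works on doubled ranks so mid-ranks (k + 0.5) become integers, and
    accumulates the sign-sum distribution by dynamic programming; counts
    stay exact in double precision for n <= 25 (2^25 < 2^53).
    """
    d = np.rint(2 * ranks).astype(int)
    total = int(d.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in d:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    w2 = int(round(2 * w_obs))
    n_patterns = 2.0 ** len(d)
    p_le = counts[: w2 + 1].sum() / n_patterns
    p_ge = counts[w2:].sum() / n_patterns
    return min(1.0, 2.0 * min(p_le, p_ge))


def wilcoxon_signed_rank(
    x: Sequence[float], y: Sequence[float], exact_threshold: int = 25
) -> WilcoxonResult:
    """Paired two-sided Wilcoxon signed-rank test.

    Zero differences are dropped (classic Wilcoxon treatment). The exact
    null distribution is used for ``n_used <= exact_threshold`` (valid with
    tied magnitudes); larger samples use the normal approximation with
    tie-corrected variance and a 0.5 continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-D arrays of equal length")
    if x.size < 1:
        raise ValidationError("need at least one pair")
    d = x - y
    d = d[d != 0]
    n = d.size
    if n == 0:
        return WilcoxonResult(n_used=0, statistic_W=0.0, p_value=1.0,
                              method="degenerate")
    ranks = sps.rankdata(np.abs(d))
    w = float(ranks[d > 0].sum())
    if n <= exact_threshold:
        p = _exact_two_sided_p(ranks, w)
        return WilcoxonResult(n_used=n, statistic_W=w, p_value=p, method="exact")
    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var -= float(np.sum(tie_counts**3 - tie_counts)) / 48.0
    if var <= 0:  # all magnitudes tied into one group of even size etc.
        return WilcoxonResult(n_used=n, statistic_W=w, p_value=1.0,
                              method="normal-approximation")
    # continuity correction: shrink |W - mean| by 0.5
    z = (abs(w - mean) - 0.5) / math.sqrt(var)
    z = max(z, 0.0)
    p = min(1.0, 2.0 * float(sps.norm.sf(z)))
    return WilcoxonResult(
        n_used=n, statistic_W=w, p_value=p, method="normal-approximation"
    )


def coverage_table(records: Iterable[ComparisonRecord]) -> pd.DataFrame:
    """Fraction of VOIs whose PD is within ±10% and ±20%, per
    voi_group x method x nominal time (inclusive bounds)."""
    frame = records_to_frame(records)
    rows = []
    if len(frame):
        for (group, method, t), sub in frame.groupby(
            ["voi_group", "method", "nominal_time_h"], sort=True
        ):
            n = len(sub)
            rows.append(
                {
                    "voi_group": group,
                    "method": method,
                    "nominal_time_h": t,
                    "n": n,
                    "frac_within_10": float(sub["within_10"].mean()),
                    "frac_within_20": float(sub["within_20"].mean()),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "voi_group", "method", "nominal_time_h", "n",
            "frac_within_10", "frac_within_20",
        ],
    )


def window_coverage_table(
    fit_frame: pd.DataFrame,
    times: Sequence[float] = DEFAULT_STP_TIMES,
    window: StpWindow = StpWindow(),
) -> pd.DataFrame:
    """Count and whole-percent share of VOIs whose imaging time lies inside
    the Hänscheid validity window, per voi_group x cycle x time.

    ``fit_frame`` needs columns voi_type, cycle, half_life_eff_h; rows with
    non-positive half-life are excluded (the window is undefined for them).
    """
    required = {"voi_type", "cycle", "half_life_eff_h"}
    missing = required - set(fit_frame.columns)
    if missing:
        raise ValidationError(f"fit table lacks columns {sorted(missing)}")
    f = fit_frame[fit_frame["half_life_eff_h"] > 0].copy()
    f["voi_group"] = f["voi_type"].map(voi_group)
    rows = []
    for (group, cycle), sub in f.groupby(["voi_group", "cycle"], sort=True):
        for t in times:
            inside = [
                in_hanscheid_window(float(t), hl, window)
                for hl in sub["half_life_eff_h"]
            ]
            n = len(sub)
            n_in = int(np.sum(inside))
            rows.append(
                {
                    "voi_group": group,
                    "cycle": cycle,
                    "time_h": float(t),
                    "n": n,
                    "n_in_window": n_in,
                    "pct_in_window": int(round(100.0 * n_in / n)) if n else 0,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["voi_group", "cycle", "time_h", "n", "n_in_window",
                 "pct_in_window"],
    )


@dataclass(frozen=True)
class HalfLifeChangeStats:
    """Inter-cycle percentage change of fitted effective half-lives."""

    frame: pd.DataFrame  # patient_id, voi_id, voi_type, t1_h, t2_h, change_percent
    n: int
    n_exceeding_20: int

    @property
    def fraction_exceeding_20(self) -> float:
        return self.n_exceeding_20 / self.n if self.n else math.nan


def half_life_change_stats(
    fits_cycle1: Mapping[tuple[str, str], float],
    fits_cycle2: Mapping[tuple[str, str], float],
    voi_types: Mapping[tuple[str, str], str] | None = None,
) -> HalfLifeChangeStats:
    """Per-VOI percentage change ``100 * (T2 - T1) / T1`` for VOIs matched
    across cycles, and the count with a change strictly greater than ±20%.

    Unmatched VOIs are skipped with a warning.
    """
    rows = []
    for key in sorted(set(fits_cycle1) | set(fits_cycle2)):
        if key not in fits_cycle1 or key not in fits_cycle2:
            logger.warning("VOI %s present in only one cycle, skipped", key)
            continue
        t1, t2 = fits_cycle1[key], fits_cycle2[key]
        rows.append(
            {
                "patient_id": key[0],
                "voi_id": key[1],
                "voi_type": voi_types.get(key, "") if voi_types else "",
                "t1_h": t1,
                "t2_h": t2,
                "change_percent": 100.0 * (t2 - t1) / t1,
            }
        )
    frame = pd.DataFrame(
        rows,
        columns=["patient_id", "voi_id", "voi_type", "t1_h", "t2_h",
                 "change_percent"],
    )
    n_exc = int((frame["change_percent"].abs() > 20.0).sum()) if len(frame) else 0
    return HalfLifeChangeStats(frame=frame, n=len(frame), n_exceeding_20=n_exc)
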