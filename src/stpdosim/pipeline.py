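"""End-to-end pipeline driver: fit -> estimate -> compare -> summarize.

``run_pipeline`` executes the whole STP-vs-MTP analysis on either a CSV of
measured time–activity curves or a freshly simulated cohort, and writes a
deterministic report bundle (tidy CSV tables plus a JSON manifest). Given
the same configuration and seed, the bundle is byte-identical across runs:
no timestamps or machine-specific values enter the outputs.
"""

from __future__ import annotations

import json
import logging
import shutil
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import __version__
from .cohort import CohortParams, generate_cohort
from .compare import (
    DEFAULT_STP_TIMES,
    bland_altman_table,
    compare_cohort,
    coverage_table,
    half_life_change_stats,
    records_to_frame,
    voi_group,
    wilcoxon_signed_rank,
    window_coverage_table,
)
from .errors import StpDosimError, ValidationError
from .io import curves_to_frame, read_tac_csv
from .stp import StpWindow
from .tac import TimeActivityCurve, fit_monoexponential, tia_reference

logger = logging.getLogger("stpdosim")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``input_csv`` (measured data) or ``simulate`` (cohort
    parameters) must be provided.
    """

    output_dir: str
    input_csv: str | None = None
    simulate: CohortParams | None = None
    stp_times: tuple[float, ...] = DEFAULT_STP_TIMES
    time_tolerance_h: float = 6.0
    window_lower: float = 0.75
    window_upper: float = 2.5
    bland_altman_denominator: str = "reference"  # or "pair_mean"
    wilcoxon_exact_threshold: int = 25
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.input_csv is None) == (self.simulate is None):
            raise ValidationError(
                "provide exactly one of input_csv or simulate parameters"
            )
        times = tuple(self.stp_times)
        if len(set(times)) != len(times) or any(t <= 0 for t in times):
            raise ValidationError("stp_times must be positive and unique")

    @property
    def window(self) -> StpWindow:
        return StpWindow(self.window_lower, self.window_upper)


def load_config(path) -> RunConfig:
    """Load a RunConfig from YAML or JSON."""
    raw = yaml.safe_load(Path(path).read_text())
    sim = raw.pop("simulate", None)
    if sim is not None:
        sim = CohortParams(**sim)
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    if "stp_times" in raw:
        raw["stp_times"] = tuple(raw["stp_times"])
    return RunConfig(simulate=sim, **raw)


def fit_table(curves: Sequence[TimeActivityCurve]) -> pd.DataFrame:
    """Per-VOI monoexponential fit results (all cycles)."""
    rows = []
    for c in sorted(curves, key=lambda c: c.key):
        if len(c.samples) < 2 or (c.activities_MBq <= 0).any():
            logger.warning("VOI %s unfittable, excluded from fit table", c.key)
            continue
        f = fit_monoexponential(c)
        rows.append(
            {
                "patient_id": c.patient_id,
                "cycle": c.cycle,
                "voi_id": c.voi_id,
                "voi_type": c.voi_type,
                "A0_MBq": f.A0_MBq,
                "half_life_eff_h": f.half_life_eff_h,
                "decay_constant_per_h": f.decay_constant_per_h,
                "n_points": f.n_points,
                "rms_log_residual": f.rms_log_residual,
                "is_decaying": f.is_decaying,
                "tia_ref_MBq_h": (
                    tia_reference(f).value_MBq_h if f.is_decaying else float("nan")
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["patient_id", "cycle", "voi_id", "voi_type", "A0_MBq",
                 "half_life_eff_h", "decay_constant_per_h", "n_points",
                 "rms_log_residual", "is_decaying", "tia_ref_MBq_h"],
    )


def _wilcoxon_table(rec_frame: pd.DataFrame, exact_threshold: int) -> pd.DataFrame:
    """Paired STP-vs-reference Wilcoxon test per voi_group x method x time."""
    rows = []
    for (group, method, t), sub in rec_frame.groupby(
        ["voi_group", "method", "nominal_time_h"], sort=True
    ):
        res = wilcoxon_signed_rank(
            sub["tia_stp_MBq_h"].to_numpy(),
            sub["tia_ref_MBq_h"].to_numpy(),
            exact_threshold=exact_threshold,
        )
        rows.append(
            {
                "voi_group": group,
                "method": method,
                "nominal_time_h": t,
                "n_used": res.n_used,
                "statistic_W": res.statistic_W,
                "p_value": res.p_value,
                "test_method": res.method,
                "significant_0p05": res.p_value < 0.05,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["voi_group", "method", "nominal_time_h", "n_used",
                 "statistic_W", "p_value", "test_method", "significant_0p05"],
    )


def _halflife_change_table(fits: pd.DataFrame) -> pd.DataFrame:
    dec = fits[fits["is_decaying"]]
    key = ["patient_id", "voi_id"]
    c1 = dec[dec["cycle"] == 1].set_index(key)
    c2 = dec[dec["cycle"] == 2].set_index(key)
    stats = half_life_change_stats(
        c1["half_life_eff_h"].to_dict(),
        c2["half_life_eff_h"].to_dict(),
        voi_types=c1["voi_type"].to_dict(),
    )
    frame = stats.frame.copy()
    frame["voi_group"] = frame["voi_type"].map(voi_group)
    return frame


def _write_csv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, index=False, float_format="%.12g")


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute the full analysis and write the report bundle.

    Returns a mapping of artifact name to written path. Any stage failure
    aborts with a stage-labelled error and removes partial outputs.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    stage = "setup"
    try:
        stage = "input"
        if config.simulate is not None:
            params = replace(config.simulate, seed=config.seed)
            cohort = generate_cohort(params)
            curves = list(cohort.curves)
        else:
            curves = read_tac_csv(config.input_csv)

        stage = "fit"
        fits = fit_table(curves)
        written["fits"] = outdir / "fits.csv"
        _write_csv(fits, written["fits"])
        written["tac"] = outdir / "time_activity.csv"
        _write_csv(curves_to_frame(curves), written["tac"])

        stage = "compare"
        records = compare_cohort(
            curves,
            stp_times=config.stp_times,
            time_tolerance_h=config.time_tolerance_h,
            window=config.window,
        )
        rec_frame = records_to_frame(records)
        written["pd_records"] = outdir / "pd_records.csv"
        _write_csv(rec_frame, written["pd_records"])

        stage = "summaries"
        written["bland_altman"] = outdir / "bland_altman.csv"
        _write_csv(
            bland_altman_table(records,
                               denominator=config.bland_altman_denominator),
            written["bland_altman"],
        )
        written["coverage"] = outdir / "coverage.csv"
        _write_csv(coverage_table(records), written["coverage"])
        written["window_coverage"] = outdir / "window_coverage.csv"
        _write_csv(
            window_coverage_table(fits, times=config.stp_times,
                                  window=config.window),
            written["window_coverage"],
        )
        written["wilcoxon"] = outdir / "wilcoxon.csv"
        _write_csv(
            _wilcoxon_table(rec_frame, config.wilcoxon_exact_threshold),
            written["wilcoxon"],
        )
        written["halflife_change"] = outdir / "halflife_change.csv"
        _write_csv(_halflife_change_table(fits), written["halflife_change"])

        stage = "manifest"
        manifest = {
            "software": {"name": "stpdosim", "version": __version__},
            "seed": config.seed,
            "config": {
                "input_csv": config.input_csv,
                "simulate": config.simulate is not None,
                "n_patients": (
                    config.simulate.n_patients if config.simulate else None
                ),
                "stp_times": list(config.stp_times),
                "time_tolerance_h": config.time_tolerance_h,
                "window": [config.window_lower, config.window_upper],
                "bland_altman_denominator": config.bland_altman_denominator,
                "wilcoxon_exact_threshold": config.wilcoxon_exact_threshold,
            },
            "artifacts": {k: p.name for k, p in written.items()},
        }
        written["manifest"] = outdir / "manifest.json"
        written["manifest"].write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )
    except Exception as exc:
        for p in written.values():
            p.unlink(missing_ok=True)
        raise StpDosimError(f"pipeline failed at stage '{stage}': {exc}") from exc
    return written
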