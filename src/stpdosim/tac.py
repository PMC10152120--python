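"""Time–activity curves, monoexponential fitting, and the multi-time-point
reference time-integrated activity (TIA).

A VOI's activity after injection is modelled as a single exponential
washout,

    A(t) = A0 * 2**(-t / T_eff) = A0 * exp(-lambda_eff * t),

with ``A0`` the back-extrapolated activity at ``t = 0`` (MBq) and ``T_eff``
the effective half-life (hours), combining physical decay and biological
clearance. Fitting is ordinary least squares on ``ln A`` against ``t``
(the multiplicative-error assumption), which has a closed-form solution and
needs no starting values; with exactly two points it is the exact
interpolant. The reference TIA is the analytic integral of the fitted
model from zero to infinity:

    TIA_ref = A0 * T_eff / ln 2    [MBq * h].

Units are fixed to MBq and hours throughout the package; conversions happen
only at the I/O boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import DomainError, InsufficientDataError, ValidationError

LN2 = math.log(2.0)

# Method tags for TIA estimates.
MTP_REF = "MTP_ref"
STP_PRIOR = "STP_prior"
STP_H = "STP_H"

VOI_TYPES = ("kidney_left", "kidney_right", "lesion", "tb_fov")


@dataclass(frozen=True)
class ActivitySample:
    """One measured VOI activity: ``activity_MBq`` at ``time_h`` post injection."""

    time_h: float
    activity_MBq: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.time_h) and self.time_h > 0):
            raise ValidationError(f"time_h must be finite and > 0, got {self.time_h}")
        if not (math.isfinite(self.activity_MBq) and self.activity_MBq >= 0):
            raise ValidationError(
                f"activity_MBq must be finite and >= 0, got {self.activity_MBq}"
            )


@dataclass(frozen=True)
class TimeActivityCurve:
    """Ordered activity samples for one VOI in one therapy cycle."""

    patient_id: str
    cycle: int
    voi_id: str
    voi_type: str
    samples: tuple[ActivitySample, ...]

    def __post_init__(self) -> None:
        if self.voi_type not in VOI_TYPES:
            raise ValidationError(
                f"voi_type must be one of {VOI_TYPES}, got {self.voi_type!r}"
            )
        if self.cycle not in (1, 2):
            raise ValidationError(f"cycle must be 1 or 2, got {self.cycle}")
        samples = tuple(self.samples)
        object.__setattr__(self, "samples", samples)
        if len(samples) < 1:
            raise ValidationError("a TimeActivityCurve needs at least one sample")
        times = [s.time_h for s in samples]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValidationError(
                "samples must be sorted by strictly increasing time_h "
                f"(got times {times})"
            )

    @property
    def times_h(self) -> np.ndarray:
        return np.array([s.time_h for s in self.samples])

    @property
    def activities_MBq(self) -> np.ndarray:
        return np.array([s.activity_MBq for s in self.samples])

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.patient_id, self.cycle, self.voi_id)


def curve_from_arrays(
    patient_id: str,
    cycle: int,
    voi_id: str,
    voi_type: str,
    times_h: Iterable[float],
    activities_MBq: Iterable[float],
) -> TimeActivityCurve:
    """Build a curve from parallel arrays, sorting by time.

    Duplicate times are rejected (they would make the per-time activity
    ill-defined for a single VOI).
    """
    times = np.asarray(list(times_h), dtype=float)
    acts = np.asarray(list(activities_MBq), dtype=float)
    if times.shape != acts.shape:
        raise ValidationError("times and activities must have equal length")
    order = np.argsort(times, kind="stable")
    times, acts = times[order], acts[order]
    if np.any(np.diff(times) == 0):
        raise ValidationError(f"duplicate sample times in VOI {voi_id!r}: {times}")
    return TimeActivityCurve(
        patient_id=patient_id,
        cycle=cycle,
        voi_id=voi_id,
        voi_type=voi_type,
        samples=tuple(ActivitySample(t, a) for t, a in zip(times, acts)),
    )


@dataclass(frozen=True)
class MonoExpFit:
    """Result of a log-linear monoexponential fit.

    ``half_life_eff_h`` is negative (and ``is_decaying`` False) when the
    fitted slope implies a net-increasing curve; it is ``-inf`` for an
    exactly flat curve. Non-decaying fits are flagged, never silently
    truncated, and downstream TIA operations refuse them.
    """

    A0_MBq: float
    half_life_eff_h: float
    decay_constant_per_h: float
    n_points: int
    rms_log_residual: float

    @property
    def is_decaying(self) -> bool:
        return self.decay_constant_per_h > 0


@dataclass(frozen=True)
class TiaEstimate:
    """A time-integrated activity (MBq*h) tagged by estimation method.

    ``time_used_h`` is the single imaging time used and is present exactly
    when the method is a single-time-point one.
    """

    value_MBq_h: float
    method: str
    time_used_h: float | None = None
    source_voi: tuple[str, int, str] | None = None

    def __post_init__(self) -> None:
        if self.method not in (MTP_REF, STP_PRIOR, STP_H):
            raise ValidationError(f"unknown TIA method {self.method!r}")
        if (self.time_used_h is None) != (self.method == MTP_REF):
            raise ValidationError(
                "time_used_h must be present iff the method is single-time-point"
            )


def fit_monoexponential(curve: TimeActivityCurve) -> MonoExpFit:
    """Fit ``ln A(t) = ln A0 - lambda_eff * t`` by unweighted OLS.

    The two-parameter closed form is used (no iteration): with
    ``x = t`` and ``y = ln A``,

        lambda_eff = -cov(x, y) / var(x),   ln A0 = mean(y) + lambda_eff * mean(x).

    Raises
    ------
    InsufficientDataError
        Fewer than two samples.
    DomainError
        Any activity <= 0 (log undefined).
    """
    t = curve.times_h
    a = curve.activities_MBq
    if t.size < 2:
        raise InsufficientDataError(
            f"monoexponential fit needs >= 2 samples, got {t.size}"
        )
    if np.any(a <= 0):
        raise DomainError(
            f"all activities must be > 0 to fit in log space (VOI {curve.voi_id!r})"
        )
    y = np.log(a)
    tbar = t.mean()
    ybar = y.mean()
    sxx = float(np.sum((t - tbar) ** 2))
    sxy = float(np.sum((t - tbar) * (y - ybar)))
    lam = -sxy / sxx
    log_a0 = ybar + lam * tbar
    resid = y - (log_a0 - lam * t)
    rms = float(np.sqrt(np.mean(resid**2)))
    if lam == 0.0:
        half_life = -math.inf  # flat curve: flagged via the negative branch
    else:
        half_life = LN2 / lam
    return MonoExpFit(
        A0_MBq=float(np.exp(log_a0)),
        half_life_eff_h=half_life,
        decay_constant_per_h=lam,
        n_points=int(t.size),
        rms_log_residual=rms,
    )


def tia_reference(fit: MonoExpFit) -> TiaEstimate:
    """Multi-time-point reference TIA: the integral of the fitted model.

    ``TIA_ref = A0 * T_eff / ln 2``. Defined only for decaying fits.
    """
    if not fit.is_decaying:
        raise DomainError(
            "reference TIA is undefined for a non-decaying fit "
            f"(half-life {fit.half_life_eff_h} h)"
        )
    value = fit.A0_MBq * fit.half_life_eff_h / LN2
    return TiaEstimate(value_MBq_h=value, method=MTP_REF)


def predict_activity(fit: MonoExpFit, time_h: float) -> float:
    """Evaluate the fitted model: ``A0 * 2**(-t / T_eff)``."""
    if time_h < 0:
        raise ValidationError(f"time_h must be >= 0, got {time_h}")
    return fit.A0_MBq * 2.0 ** (-time_h / fit.half_life_eff_h)
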