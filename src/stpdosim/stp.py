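"""Single-time-point (STP) time-integrated-activity estimators.

Two STP estimators are implemented for a VOI measured once at time ``t``
post injection with activity ``A(t)``:

* prior-information estimator (``STP_prior``): back-decays the single
  measurement using a half-life known from prior imaging (in the study
  design, the monoexponential fit of the same VOI in the first therapy
  cycle) and integrates analytically,

      TIA = A(t) * 2**(t / T_prior) * T_prior / ln 2;

* Hänscheid estimator (``STP_H``): a prior-free approximation valid when
  the imaging time is close to the effective half-life,

      TIA ~= A(t) * 2 * t / ln 2.

For a perfect monoexponential curve with true half-life ``T`` the
Hänscheid estimate divided by the exact TIA equals ``2 * x * 2**(-x)``
with ``x = t / T``: exact at ``x = 1`` and ``x = 2``, at most +6.15% high
(at ``x = 1/ln 2``), and increasingly low outside. The conventional
validity window ``0.75 <= x <= 2.5`` is represented by :class:`StpWindow`;
its boundary errors are -10.81% and -11.61%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import DomainError, ValidationError
from .tac import LN2, STP_H, STP_PRIOR, TiaEstimate

VoiKey = tuple[str, int, str]


@dataclass(frozen=True)
class StpWindow:
    """Validity window for the Hänscheid estimator, as multiples of the
    effective half-life. Endpoints are inclusive."""

    lower_factor: float = 0.75
    upper_factor: float = 2.5

    def __post_init__(self) -> None:
        if not (0 < self.lower_factor < self.upper_factor):
            raise ValidationError(
                f"need 0 < lower_factor < upper_factor, got "
                f"({self.lower_factor}, {self.upper_factor})"
            )


def stp_prior(
    activity_MBq: float,
    time_h: float,
    prior_half_life_h: float,
    source_voi: VoiKey | None = None,
) -> TiaEstimate:
    """Prior-information STP TIA from one measurement and a known half-life."""
    if activity_MBq < 0:
        raise ValidationError(f"activity_MBq must be >= 0, got {activity_MBq}")
    if time_h <= 0:
        raise ValidationError(f"time_h must be > 0, got {time_h}")
    if prior_half_life_h <= 0:
        raise DomainError(
            f"prior half-life must be > 0, got {prior_half_life_h}"
        )
    value = activity_MBq * 2.0 ** (time_h / prior_half_life_h) * prior_half_life_h / LN2
    return TiaEstimate(
        value_MBq_h=value, method=STP_PRIOR, time_used_h=time_h, source_voi=source_voi
    )


def stp_hanscheid(
    activity_MBq: float,
    time_h: float,
    source_voi: VoiKey | None = None,
) -> TiaEstimate:
    """Hänscheid STP TIA: ``A(t) * 2 * t / ln 2``, no half-life required."""
    if activity_MBq < 0:
        raise ValidationError(f"activity_MBq must be >= 0, got {activity_MBq}")
    if time_h <= 0:
        raise ValidationError(f"time_h must be > 0, got {time_h}")
    value = activity_MBq * 2.0 * time_h / LN2
    return TiaEstimate(
        value_MBq_h=value, method=STP_H, time_used_h=time_h, source_voi=source_voi
    )


def in_hanscheid_window(
    time_h: float, half_life_eff_h: float, window: StpWindow = StpWindow()
) -> bool:
    """True iff ``lower * T_eff <= t <= upper * T_eff`` (inclusive)."""
    if time_h <= 0:
        raise ValidationError(f"time_h must be > 0, got {time_h}")
    if half_life_eff_h <= 0:
        raise ValidationError(
            f"half_life_eff_h must be > 0, got {half_life_eff_h}"
        )
    return (
        window.lower_factor * half_life_eff_h
        <= time_h
        <= window.upper_factor * half_life_eff_h
    )


def stp_h_relative_error(ratio_x: float) -> float:
    """Signed relative error of the Hänscheid estimator on an exact
    monoexponential curve observed at ``t = x * T_eff``:

        err(x) = 2 * x * 2**(-x) - 1.
    """
    if ratio_x <= 0:
        raise ValidationError(f"ratio_x must be > 0, got {ratio_x}")
    return 2.0 * ratio_x * 2.0 ** (-ratio_x) - 1.0


#: Location of the global maximum of :func:`stp_h_relative_error` (x = 1/ln 2).
STP_H_PEAK_RATIO = 1.0 / LN2

#: Value of the maximum relative error, 2/(e * ln 2) - 1 ~= +6.15%.
STP_H_PEAK_ERROR = 2.0 / (math.e * LN2) - 1.0
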