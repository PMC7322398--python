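"""Inclusion/exclusion rules for FRAP measurements on GUVs.

Four checks, all inclusive (>= / <=):

1. area — the bleach spot must be small relative to the observed membrane
   disc: sqrt(A / pi) / w >= area_ratio_min (default 5).
2. pulse — the bleach pulse must be short relative to the recovery:
   t_B <= pulse_ratio_max * t_half (default 1/10).
3. mobile — the mobile fraction must indicate an effectively infinite lipid
   reservoir: M >= mobile_min (default 0.75).
4. movement — the vesicle must not have drifted during acquisition:
   displacement <= movement_max_displacement (default w / 2).  Skipped with a
   warning when no movement information is supplied.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Union

from .frap import InvalidParameterError, RecoveryFit, SpotGeometry

__all__ = ["QCRules", "QCCheck", "QCReport", "apply_qc"]


@dataclass(frozen=True)
class QCRules:
    area_ratio_min: float = 5.0
    pulse_ratio_max: float = 0.1
    mobile_min: float = 0.75
    #: maximum allowed drift in µm; None means w / 2 of the measured spot
    movement_max_displacement: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("area_ratio_min", "pulse_ratio_max", "mobile_min"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be > 0")
        if self.movement_max_displacement is not None and self.movement_max_displacement <= 0:
            raise InvalidParameterError("movement_max_displacement must be > 0")


class QCCheck(NamedTuple):
    name: str
    value: float
    threshold: float
    passed: bool


@dataclass
class QCReport:
    passed: bool
    checks: list[QCCheck] = field(default_factory=list)
    excluded_reasons: list[str] = field(default_factory=list)


def apply_qc(
    geometry: SpotGeometry,
    fit: Optional[RecoveryFit],
    M: float,
    movement: Union[float, bool, None],
    rules: Optional[QCRules] = None,
) -> QCReport:
    """Evaluate the four inclusion criteria and aggregate into a report.

    A missing or unconverged fit makes the pulse check not evaluable and the
    report fails overall.  ``movement`` may be a drift distance in µm, a
    boolean moved flag, or None (check skipped with a warning).
    """
    rules = rules if rules is not None else QCRules()
    checks: list[QCCheck] = []
    reasons: list[str] = []

    # (1) spot small vs. membrane disc: effective-radius ratio
    ratio = math.sqrt(geometry.area / math.pi) / geometry.w
    ok = ratio >= rules.area_ratio_min
    checks.append(QCCheck("area", ratio, rules.area_ratio_min, ok))
    if not ok:
        reasons.append("area")

    # (2) bleach pulse short vs. recovery half-life
    if fit is None or not fit.converged or not math.isfinite(fit.t_half):
        checks.append(QCCheck("pulse", math.nan, math.nan, False))
        reasons.append("pulse_not_evaluable")
    else:
        limit = rules.pulse_ratio_max * fit.t_half
        ok = geometry.t_bleach <= limit
        checks.append(QCCheck("pulse", geometry.t_bleach, limit, ok))
        if not ok:
            reasons.append("pulse")

    # (3) mobile fraction (finite-reservoir guard)
    ok = M >= rules.mobile_min
    checks.append(QCCheck("mobile", M, rules.mobile_min, ok))
    if not ok:
        reasons.append("mobile")

    # (4) vesicle movement during acquisition
    max_disp = (
        rules.movement_max_displacement
        if rules.movement_max_displacement is not None
        else geometry.w / 2
    )
    if movement is None:
        warnings.warn(
            "no movement information supplied; movement check skipped",
            stacklevel=2,
        )
    elif isinstance(movement, bool):
        checks.append(QCCheck("movement", float(movement), 0.0, not movement))
        if movement:
            reasons.append("movement")
    else:
        ok = movement <= max_disp
        checks.append(QCCheck("movement", float(movement), max_disp, ok))
        if not ok:
            reasons.append("movement")

    return QCReport(passed=all(c.passed for c in checks), checks=checks, excluded_reasons=reasons)
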