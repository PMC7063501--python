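"""Hazard-ratio calibration of class-specific CRC mortality.

Published survival for the biomarker classes covers colorectal cancer of all
stages, while the model needs stage-1 (T1) monthly cause-specific death
probabilities. Under proportional hazards the all-stage hazard for class ``c``
and stage ``s`` is ``h0 * HR_class(c) * HR_stage(s)`` with a constant (monthly)
baseline hazard ``h0``. The calibration pipeline:

1. build the class-level all-stage survival curve as a stage mix of
   exponentials, ``S(t) = sum_s w_s * exp(-h0 * HR_c * HR_s * t)``;
2. fit ``h0`` by least squares against a target survival curve (published
   Kaplan-Meier curves in the original analysis; synthetic stand-ins here);
3. read off the stage-1 monthly death probability per class,
   ``1 - exp(-h0 * HR_c)``.

The MSI-H class sits outside the hazard-ratio ladder (no published HR for
BRAFV600E); its monthly rate is a direct input. The engine consumes the
packaged per-class rates by default — calibration is an auxiliary pipeline and
never silently overwrites them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.optimize import minimize_scalar

from .parameters import ClassId

__all__ = [
    "DEFAULT_CLASS_HRS",
    "DEFAULT_STAGE_HRS",
    "HazardRatios",
    "StageMix",
    "SurvivalCurve",
    "CalibrationError",
    "CalibrationResult",
    "monthly_rate",
    "stage_weighted_survival",
    "fit_baseline_hazard",
    "t1_class_rates",
]

# Overall-survival hazard ratios by biomarker class (reference: class 1).
DEFAULT_CLASS_HRS: dict[ClassId, float] = {
    ClassId.class0: 1.94,
    ClassId.class1: 1.00,
    ClassId.class2: 1.11,
    ClassId.class3: 1.48,
    ClassId.class4: 2.48,
}

# Hazard ratios by tumor stage at diagnosis (reference: stage 1).
DEFAULT_STAGE_HRS: dict[int, float] = {1: 1.00, 2: 2.11, 3: 7.99, 4: 52.2}


class CalibrationError(RuntimeError):
    """The 1-D fit failed or hit its bracket boundary."""


@dataclass(frozen=True)
class HazardRatios:
    class_hr: Mapping[ClassId, float] = field(default_factory=lambda: dict(DEFAULT_CLASS_HRS))
    stage_hr: Mapping[int, float] = field(default_factory=lambda: dict(DEFAULT_STAGE_HRS))

    def __post_init__(self):
        if any(v <= 0 for v in self.class_hr.values()) or any(
            v <= 0 for v in self.stage_hr.values()
        ):
            raise ValueError("hazard ratios must be positive")


@dataclass(frozen=True)
class StageMix:
    """Stage-at-diagnosis proportions used to mix the stage-specific curves."""

    proportions: Mapping[int, float]

    def __post_init__(self):
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"stage proportions sum to {total}, expected 1")
        if any(p < 0 for p in self.proportions.values()):
            raise ValueError("stage proportions must be non-negative")


@dataclass(frozen=True)
class SurvivalCurve:
    times: np.ndarray       # months
    survival: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        s = np.asarray(self.survival, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "survival", s)
        if t.size != s.size or t.size == 0:
            raise ValueError("times and survival must be equal-length, non-empty")
        if np.any(s < 0) or np.any(s > 1):
            raise ValueError("survival outside [0, 1]")
        if np.any(np.diff(s) > 1e-12):
            raise ValueError("survival must be non-increasing")


@dataclass(frozen=True)
class CalibrationResult:
    h0: float
    residual: float          # sum of squared deviations at the optimum
    at_boundary: bool
    bracket: tuple[float, float]


def monthly_rate(h0: float, hr_class: float, hr_stage: float = 1.0) -> float:
    """Monthly death probability under proportional hazards, 1 - exp(-h0*HRc*HRs)."""
    if h0 <= 0:
        raise ValueError(f"baseline hazard must be positive, got {h0}")
    return 1.0 - math.exp(-h0 * hr_class * hr_stage)


def stage_weighted_survival(
    h0: float,
    hrs: HazardRatios,
    cls: ClassId,
    mix: StageMix,
    horizon_months: int,
    times: np.ndarray | None = None,
) -> SurvivalCurve:
    """All-stage survival for one class: a stage mixture of exponentials."""
    if h0 <= 0:
        raise ValueError(f"baseline hazard must be positive, got {h0}")
    t = np.arange(horizon_months + 1, dtype=float) if times is None else np.asarray(times, float)
    hr_c = hrs.class_hr[cls]
    s = np.zeros_like(t)
    for stage, w in mix.proportions.items():
        s += w * np.exp(-h0 * hr_c * hrs.stage_hr[stage] * t)
    return SurvivalCurve(t, s)


def fit_baseline_hazard(
    target: SurvivalCurve,
    hrs: HazardRatios,
    cls: ClassId,
    mix: StageMix,
    bracket: tuple[float, float] = (1e-8, 0.5),
) -> CalibrationResult:
    """Least-squares fit of the baseline monthly hazard to a survival target.

    Minimizes the squared deviation on the survival scale (robust as S -> 0)
    with bounded 1-D minimization. A fit at the bracket boundary — e.g. for a
    degenerate flat target S = 1 — is flagged rather than trusted.
    """
    if target.times.size < 2:
        raise CalibrationError("target needs at least one interior time point")

    def sse(h0: float) -> float:
        model = stage_weighted_survival(h0, hrs, cls, mix, 0, times=target.times)
        return float(np.sum((model.survival - target.survival) ** 2))

    res = minimize_scalar(sse, bounds=bracket, method="bounded",
                          options={"xatol": 1e-14})
    if not res.success:
        raise CalibrationError(f"bounded minimization failed: {res.message}")
    h0 = float(res.x)
    span = bracket[1] - bracket[0]
    at_boundary = (h0 - bracket[0] < 1e-6 * span) or (bracket[1] - h0 < 1e-6 * span)
    return CalibrationResult(h0=h0, residual=float(res.fun),
                             at_boundary=at_boundary, bracket=bracket)


def t1_class_rates(h0: float, hrs: HazardRatios) -> dict[ClassId, float]:
    """Stage-1 monthly CRC death probability per class, 1 - exp(-h0 * HR_c)."""
    return {cls: monthly_rate(h0, hr, hrs.stage_hr[1]) for cls, hr in hrs.class_hr.items()}
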