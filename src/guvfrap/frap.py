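"""Core FRAP quantification: from a bleach-spot intensity trace to a lateral
diffusion coefficient.

The analysis chain mirrors the standard uniform-disk FRAP workflow on giant
unilamellar vesicles (GUVs):

1. ``extract_trace`` — mean intensity of a circular ROI per frame.
2. ``fractional_recovery`` — rescale to f(t) = (F(t) - F(0)) / (F(inf) - F(0))
   with F(0) the first post-bleach frame and F(inf) the mean of the last
   8 recovery frames; the mobile fraction is
   M = (F(inf) - F(0)) / (F(pre) - F(0)).
3. ``fit_recovery`` — least-squares fit of y0 * (1 - exp(-a t)), half-life
   t_1/2 = ln(2) / a.
4. ``diffusion_coefficient`` — D = 0.224 * w**2 / t_1/2 for a uniform circular
   bleach spot of radius w (the 0.224 is the rounded root of the
   Soumpasis closed form; see :func:`guvfrap.synthetic.solve_half_time_constant`).

``analyze_trace`` composes the chain and attaches quality-control verdicts;
excluded vesicles still carry their numbers plus the failure reasons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

if TYPE_CHECKING:  # pragma: no cover
    from .qc import QCReport, QCRules

__all__ = [
    "HALF_TIME_CONSTANT",
    "FrameSchedule",
    "SpotGeometry",
    "FrapTrace",
    "ImageStack",
    "FractionalTrace",
    "RecoveryFit",
    "FrapResult",
    "InvalidParameterError",
    "DegenerateTraceError",
    "GeometryError",
    "extract_trace",
    "fractional_recovery",
    "fit_recovery",
    "diffusion_coefficient",
    "analyze_trace",
    "analyze_batch",
    "results_to_frame",
]

#: Rounded dimensionless constant c = D * t_half / w**2 for uniform-disk bleach.
HALF_TIME_CONSTANT = 0.224

#: Number of frames averaged for the pre-bleach and plateau references.
N_REFERENCE_FRAMES = 8


class InvalidParameterError(ValueError):
    """A physical parameter is outside its valid domain."""


class DegenerateTraceError(ValueError):
    """The trace carries no usable recovery signal (flat, or no bleach)."""


class GeometryError(ValueError):
    """An ROI or spot geometry does not fit the image."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FrameSchedule:
    """Acquisition timing of one FRAP measurement.

    Time origin t = 0 is the first recovery frame; pre-bleach frames sit at
    negative times and the bleach pulse occupies (-t_bleach, 0).
    """

    n_pre: int = 8
    t_bleach: float = 0.1
    n_post: int = 100
    dt: float = 0.2

    def __post_init__(self) -> None:
        if self.n_pre < 1:
            raise InvalidParameterError("n_pre must be >= 1")
        if self.n_post < 2:
            raise InvalidParameterError("n_post must be >= 2")
        if self.dt <= 0:
            raise InvalidParameterError("dt must be > 0")
        if self.t_bleach < 0:
            raise InvalidParameterError("t_bleach must be >= 0")

    @property
    def n_frames(self) -> int:
        return self.n_pre + self.n_post

    def pre_times(self) -> np.ndarray:
        i = np.arange(self.n_pre)
        return -self.t_bleach - self.dt * (self.n_pre - i)

    def recovery_times(self) -> np.ndarray:
        return self.dt * np.arange(self.n_post)

    def times(self) -> np.ndarray:
        return np.concatenate([self.pre_times(), self.recovery_times()])


@dataclass(frozen=True)
class SpotGeometry:
    """Bleach-spot radius w, observed membrane disc area A and pulse length."""

    w: float
    area: float = math.inf
    t_bleach: float = 0.1

    def __post_init__(self) -> None:
        if self.w <= 0:
            raise InvalidParameterError("spot radius w must be > 0")
        if self.area <= 0:
            raise InvalidParameterError("membrane area must be > 0")
        if self.t_bleach < 0:
            raise InvalidParameterError("t_bleach must be >= 0")


@dataclass
class FrapTrace:
    """Raw per-frame ROI mean intensity with its schedule and geometry.

    ``movement`` is an externally supplied exclusion input: a displacement in
    µm, a boolean moved/static flag, or None when unknown.
    """

    times: np.ndarray
    intensities: np.ndarray
    schedule: FrameSchedule
    geometry: SpotGeometry
    movement: Union[float, bool, None] = None
    vesicle_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.shape != self.intensities.shape:
            raise InvalidParameterError("times and intensities must have equal length")
        if self.times.size != self.schedule.n_frames:
            raise InvalidParameterError(
                f"trace has {self.times.size} frames, schedule expects "
                f"{self.schedule.n_frames}"
            )
        if np.any(np.diff(self.times) <= 0):
            raise InvalidParameterError("times must be strictly increasing")
        if not np.all(np.isfinite(self.intensities)):
            raise InvalidParameterError("intensities must be finite")

    @property
    def pre_intensities(self) -> np.ndarray:
        return self.intensities[: self.schedule.n_pre]

    @property
    def recovery_times(self) -> np.ndarray:
        return self.times[self.schedule.n_pre :]

    @property
    def recovery_intensities(self) -> np.ndarray:
        return self.intensities[self.schedule.n_pre :]


@dataclass
class ImageStack:
    """Time-lapse single-channel image stack (time, y, x) with physical scale."""

    frames: np.ndarray
    pixel_size: float
    schedule: FrameSchedule
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise InvalidParameterError("frames must be a 3-D (time, y, x) array")
        if self.pixel_size <= 0:
            raise InvalidParameterError("pixel_size must be > 0")
        if self.frames.shape[0] != self.schedule.n_frames:
            raise InvalidParameterError(
                f"stack has {self.frames.shape[0]} pages, schedule expects "
                f"{self.schedule.n_frames}"
            )
        if np.min(self.frames) < 0:
            raise InvalidParameterError("intensities must be >= 0")


@dataclass
class FractionalTrace:
    """Normalized recovery f(t) over the post-bleach frames.

    By construction f = 0 at the first recovery frame and the mean of the
    last 8 f-values is 1.  M may exceed 1 under noise.
    """

    times: np.ndarray
    f_values: np.ndarray
    F0: float
    Finf: float
    Fpre: float
    M: float


@dataclass
class RecoveryFit:
    """Fitted y0 * (1 - exp(-a t)) recovery with half-life t_half = ln2 / a."""

    y0: float
    a: float
    t_half: float
    rss: float
    converged: bool


@dataclass
class FrapResult:
    """Per-vesicle outcome: D plus fit, mobile fraction and QC verdicts."""

    D: float
    fit: Optional[RecoveryFit]
    M: float
    qc: "QCReport"
    condition_label: str = ""
    vesicle_id: str = ""
    error: str = ""


# ---------------------------------------------------------------------------
# ROI extraction
# ---------------------------------------------------------------------------

def extract_trace(
    stack: ImageStack,
    center: tuple[float, float],
    w: float,
    area: Optional[float] = None,
) -> FrapTrace:
    """Mean intensity of a circular ROI of radius ``w`` (µm) per frame.

    ``center`` is (y, x) in µm with pixel centers at integer pixel
    coordinates.  The membrane disc area ``A`` for QC is taken, in order of
    preference, from the explicit ``area`` argument, the stack metadata keys
    ``area_um2`` or ``reservoir_radius_um``, else the full frame area.
    """
    if w <= 0:
        raise InvalidParameterError("spot radius w must be > 0")
    px = stack.pixel_size
    cy, cx = center[0] / px, center[1] / px
    r_px = w / px
    ny, nx = stack.frames.shape[1:]
    if cy - r_px < -0.5 or cx - r_px < -0.5 or cy + r_px > ny - 0.5 or cx + r_px > nx - 0.5:
        raise GeometryError(
            f"ROI (center={center} um, w={w} um) extends outside the "
            f"{ny}x{nx} px frame"
        )
    yy, xx = np.ogrid[:ny, :nx]
    mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= r_px**2
    if not mask.any():
        raise GeometryError("ROI covers no pixel; check pixel_size and w")
    values = stack.frames[:, mask].mean(axis=1)

    if area is None:
        if "area_um2" in stack.metadata:
            area = float(stack.metadata["area_um2"])
        elif "reservoir_radius_um" in stack.metadata:
            area = math.pi * float(stack.metadata["reservoir_radius_um"]) ** 2
        else:
            area = ny * nx * px**2
    geometry = SpotGeometry(w=w, area=area, t_bleach=stack.schedule.t_bleach)
    return FrapTrace(
        times=stack.schedule.times(),
        intensities=values,
        schedule=stack.schedule,
        geometry=geometry,
        vesicle_id=str(stack.metadata.get("vesicle_id", "")),
        condition=str(stack.metadata.get("condition", "")),
    )


# ---------------------------------------------------------------------------
# fractional recovery and mobile fraction
# ---------------------------------------------------------------------------

def fractional_recovery(trace: FrapTrace) -> FractionalTrace:
    """Rescale a raw trace to fractional recovery and compute M.

    References: F(0) is the intensity of the first post-bleach frame ("just
    after bleaching"), F(inf) the mean of the last 8 recovery frames, F(pre)
    the mean of the 8 frames recorded pre-bleaching.
    """
    n_ref = N_REFERENCE_FRAMES
    if trace.schedule.n_pre < n_ref:
        raise DegenerateTraceError(
            f"need >= {n_ref} pre-bleach frames, got {trace.schedule.n_pre}"
        )
    if trace.schedule.n_post < n_ref:
        raise DegenerateTraceError(
            f"need >= {n_ref} recovery frames, got {trace.schedule.n_post}"
        )
    rec = trace.recovery_intensities
    Fpre = float(trace.pre_intensities[-n_ref:].mean())
    F0 = float(rec[0])
    Finf = float(rec[-n_ref:].mean())
    scale = max(1.0, abs(Fpre), abs(Finf))
    if abs(Finf - F0) <= 1e-12 * scale:
        raise DegenerateTraceError("flat trace: F(inf) equals F(0), no recovery signal")
    if abs(Fpre - F0) <= 1e-12 * scale:
        raise DegenerateTraceError("no bleach: F(pre) equals F(0)")
    f = (rec - F0) / (Finf - F0)
    M = (Finf - F0) / (Fpre - F0)
    return FractionalTrace(
        times=trace.recovery_times.copy(),
        f_values=f,
        F0=F0,
        Finf=Finf,
        Fpre=Fpre,
        M=float(M),
    )


# ---------------------------------------------------------------------------
# exponential recovery fit
# ---------------------------------------------------------------------------

def _exp_model(t: np.ndarray, y0: float, a: float) -> np.ndarray:
    return y0 * -np.expm1(-a * t)


def fit_recovery(frac: FractionalTrace) -> RecoveryFit:
    """Unweighted least-squares fit of y0 * (1 - exp(-a t)) to f(t).

    Deterministic: the initial y0 is the plateau estimate (mean of the last
    8 f-values), the initial rate comes from the first half-crossing of that
    plateau, and up to three fixed rate perturbations are tried; the best
    residual wins.  Non-convergence yields ``converged=False``, never an
    exception.
    """
    t = np.asarray(frac.times, dtype=float)
    y = np.asarray(frac.f_values, dtype=float)
    if t.size < 5:
        raise InvalidParameterError("need >= 5 recovery points to fit")
    if np.any(t < 0):
        raise InvalidParameterError("recovery times must be >= 0")

    y0_init = float(np.clip(np.mean(y[-N_REFERENCE_FRAMES:]), 0.05, 1.5))
    above = np.nonzero((y >= y0_init / 2) & (t > 0))[0]
    t_cross = t[above[0]] if above.size else float(np.median(t[t > 0]))
    a_init = math.log(2) / max(t_cross, 1e-9)

    def resid(p: np.ndarray) -> np.ndarray:
        return _exp_model(t, p[0], p[1]) - y

    best = None
    for factor in (1.0, 0.3, 3.0):
        try:
            sol = least_squares(
                resid,
                x0=[y0_init, a_init * factor],
                bounds=([1e-12, 1e-12], [1.5, np.inf]),
                xtol=1e-8,
                ftol=1e-8,
                gtol=1e-8,
            )
        except Exception:
            continue
        rss = float(np.sum(sol.fun**2))
        if sol.success and (best is None or rss < best[0]):
            best = (rss, sol)

    if best is None:
        return RecoveryFit(y0=math.nan, a=math.nan, t_half=math.nan, rss=math.nan, converged=False)
    rss, sol = best
    y0, a = float(sol.x[0]), float(sol.x[1])
    if not (a > 0 and math.isfinite(a)):
        return RecoveryFit(y0=y0, a=a, t_half=math.nan, rss=rss, converged=False)
    return RecoveryFit(y0=y0, a=a, t_half=math.log(2) / a, rss=rss, converged=True)


def diffusion_coefficient(t_half: float, w: float, constant: float = HALF_TIME_CONSTANT) -> float:
    """Lateral diffusion coefficient D = c * w**2 / t_half (µm²/s)."""
    if t_half <= 0:
        raise InvalidParameterError("t_half must be > 0")
    if w <= 0:
        raise InvalidParameterError("spot radius w must be > 0")
    return constant * w**2 / t_half


# ---------------------------------------------------------------------------
# full per-vesicle pipeline
# ---------------------------------------------------------------------------

def analyze_trace(trace: FrapTrace, rules: Optional["QCRules"] = None) -> FrapResult:
    """Run the full chain on one trace and attach QC verdicts.

    Degenerate traces and failed fits are reported in the result (with
    ``D = nan`` and a failure reason), never raised, so batches survive bad
    vesicles.
    """
    from .qc import QCReport, QCRules, apply_qc

    rules = rules if rules is not None else QCRules()
    try:
        frac = fractional_recovery(trace)
    except DegenerateTraceError as exc:
        qc = QCReport(passed=False, checks=[], excluded_reasons=["degenerate_trace"])
        return FrapResult(
            D=math.nan, fit=None, M=math.nan, qc=qc,
            condition_label=trace.condition, vesicle_id=trace.vesicle_id,
            error=str(exc),
        )
    fit = fit_recovery(frac)
    qc = apply_qc(trace.geometry, fit, frac.M, trace.movement, rules)
    if fit.converged:
        D = diffusion_coefficient(fit.t_half, trace.geometry.w)
        error = ""
    else:
        D = math.nan
        error = "fit did not converge"
    return FrapResult(
        D=D, fit=fit, M=frac.M, qc=qc,
        condition_label=trace.condition, vesicle_id=trace.vesicle_id, error=error,
    )


def analyze_batch(traces: Sequence[FrapTrace], rules: Optional["QCRules"] = None) -> list[FrapResult]:
    """``analyze_trace`` over a batch; one result per input trace."""
    return [analyze_trace(tr, rules) for tr in traces]


def results_to_frame(results: Sequence[FrapResult]) -> pd.DataFrame:
    """Tabulate per-vesicle results (one TSV-ready row per trace)."""
    rows = []
    for i, r in enumerate(results):
        fit = r.fit
        rows.append(
            {
                "vesicle_id": r.vesicle_id or f"v{i:03d}",
                "condition": r.condition_label,
                "D_um2_s": r.D,
                "t_half_s": fit.t_half if fit else math.nan,
                "a_per_s": fit.a if fit else math.nan,
                "y0": fit.y0 if fit else math.nan,
                "M": r.M,
                "qc_pass": bool(r.qc.passed),
                "qc_reasons": ";".join(r.qc.excluded_reasons),
            }
        )
    return pd.DataFrame(rows)
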