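"""Membrane-composition quantification from vesicle equatorial-ring images.

Workflow: extract the mean intensity of each vesicle's fluorescent ring,
pool all vesicles of one binary lipid system in a zero-intercept linear
regression of intensity on the labelled-lipid relative concentration x
(1, 2, 3 for the 3:1, 2:2 and 1:3 mixing ratios), divide every intensity by
the fitted slope, and summarize per group.  If the lipid composition of the
lipid-octanol phase is maintained in the vesicles, the normalized group means
scale as 1-2-3.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .frap import InvalidParameterError

__all__ = [
    "RingDetectionError",
    "RingMeasurement",
    "CompositionDataset",
    "measure_ring_intensity",
    "fit_zero_intercept",
    "normalize_intensities",
    "summarize_composition",
]


class RingDetectionError(ValueError):
    """No fluorescent ring could be located in the image."""


@dataclass
class RingMeasurement:
    """Extracted equatorial ring: location, size and background-corrected mean."""

    vesicle_id: str
    center: tuple[float, float]  # (y, x) in µm
    radius: float  # µm
    band_width: float  # µm
    mean_intensity: float  # background-subtracted, a.u.
    background: float  # a.u.


@dataclass
class CompositionDataset:
    """Per-vesicle intensities with group labels; slope and normalized values
    are filled in by :meth:`fit_and_normalize`.

    ``records`` columns: vesicle_id, system, group, x_rel, intensity
    (plus ``normalized`` after fitting).
    """

    records: pd.DataFrame
    slope: Optional[float] = None

    REQUIRED = ("vesicle_id", "system", "group", "x_rel", "intensity")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.records.columns]
        if missing:
            raise InvalidParameterError(f"records missing columns: {missing}")
        if (self.records["x_rel"] <= 0).any():
            raise InvalidParameterError("x_rel must be > 0 for every record")

    def fit_and_normalize(self) -> "CompositionDataset":
        """Fit the pooled zero-intercept slope and attach normalized values."""
        self.slope = fit_zero_intercept(self.records["x_rel"], self.records["intensity"])
        self.records = normalize_intensities(self.records, self.slope)
        return self

    def summary(self) -> pd.DataFrame:
        if "normalized" not in self.records.columns:
            self.fit_and_normalize()
        return summarize_composition(self.records)


# ---------------------------------------------------------------------------
# ring extraction
# ---------------------------------------------------------------------------

def measure_ring_intensity(
    image: np.ndarray,
    pixel_size: float = 1.0,
    seed_center: Optional[tuple[float, float]] = None,
    band_width: float = 3.0,
    background_radius_factor: float = 1.5,
    subtract_background: bool = True,
    vesicle_id: str = "",
) -> RingMeasurement:
    """Locate a vesicle's fluorescent equatorial ring and measure its mean.

    The center starts at ``seed_center`` (µm) or the background-subtracted
    intensity centroid; the ring radius is the global argmax of the radial
    mean-intensity profile (nested rings yield a warning and the brighter
    one); the mean is taken over an annulus of ``band_width`` (µm) and the
    background — the median beyond ``background_radius_factor`` times the
    radius — is subtracted when requested.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise InvalidParameterError("image must be 2-D")
    if pixel_size <= 0:
        raise InvalidParameterError("pixel_size must be > 0")
    bg_global = float(np.median(img))
    if seed_center is None:
        weight = np.clip(img - bg_global, 0.0, None)
        total = weight.sum()
        if total <= 0:
            raise RingDetectionError("image has no signal above the background median")
        yy, xx = np.mgrid[: img.shape[0], : img.shape[1]]
        cy = float((weight * yy).sum() / total)
        cx = float((weight * xx).sum() / total)
    else:
        cy, cx = seed_center[0] / pixel_size, seed_center[1] / pixel_size

    yy, xx = np.mgrid[: img.shape[0], : img.shape[1]]
    r = np.hypot(yy - cy, xx - cx)
    r_int = np.round(r).astype(int)  # bin k covers [k - 0.5, k + 0.5)
    n_bins = int(r_int.max()) + 1
    counts = np.bincount(r_int.ravel(), minlength=n_bins)
    sums = np.bincount(r_int.ravel(), weights=img.ravel(), minlength=n_bins)
    profile = sums / np.maximum(counts, 1)

    noise = 1.4826 * float(np.median(np.abs(img - bg_global)))
    # ignore the innermost bins (few pixels, centroid artefacts)
    offset = 2
    signal = profile[offset:] - bg_global
    if signal.size == 0 or signal.max() <= max(4.0 * noise, 1e-9):
        raise RingDetectionError("no radial intensity peak above background")
    peaks, _ = find_peaks(signal, height=max(4.0 * noise, 1e-9))
    if peaks.size > 1:
        warnings.warn(
            f"{peaks.size} radial peaks detected; using the brightest ring",
            stacklevel=2,
        )
    k = int(np.argmax(signal))
    # refine: intensity-weighted mean radius over the half-max neighbourhood
    lo = k
    while lo > 0 and signal[lo - 1] >= signal[k] / 2:
        lo -= 1
    hi = k
    while hi < signal.size - 1 and signal[hi + 1] >= signal[k] / 2:
        hi += 1
    wgt = np.clip(signal[lo : hi + 1], 0.0, None)
    bins = np.arange(lo, hi + 1) + offset
    radius_px = float(np.average(bins, weights=wgt)) if wgt.sum() > 0 else float(k + offset)

    band_px = band_width / pixel_size
    annulus = np.abs(r - radius_px) <= band_px / 2.0
    outside = r > background_radius_factor * radius_px
    background = float(np.median(img[outside])) if outside.any() else bg_global
    mean = float(img[annulus].mean())
    if subtract_background:
        mean -= background
    return RingMeasurement(
        vesicle_id=vesicle_id,
        center=(cy * pixel_size, cx * pixel_size),
        radius=radius_px * pixel_size,
        band_width=band_width,
        mean_intensity=mean,
        background=background,
    )


# ---------------------------------------------------------------------------
# zero-intercept regression and normalization
# ---------------------------------------------------------------------------

def fit_zero_intercept(x: Sequence[float], intensity: Sequence[float]) -> float:
    """Least-squares slope of intensity on x through the origin.

    s = sum(x_i I_i) / sum(x_i^2), pooled over all vesicles of one lipid
    system (per-liposome points, not group means).
    """
    x = np.asarray(x, dtype=float)
    I = np.asarray(intensity, dtype=float)
    if x.size == 0 or x.size != I.size:
        raise InvalidParameterError("x and intensity must be non-empty and equal-length")
    sxx = float(np.dot(x, x))
    if sxx <= 0:
        raise InvalidParameterError("sum of x^2 must be positive to fit a slope")
    return float(np.dot(x, I) / sxx)


def normalize_intensities(records: pd.DataFrame, slope: float) -> pd.DataFrame:
    """Divide every intensity by the fitted slope.

    After normalization the zero-intercept regression of normalized value on
    x_rel has slope +1 by construction, so group means are expected at the
    relative concentrations themselves (1, 2, 3).
    """
    if slope <= 0:
        raise InvalidParameterError("slope must be > 0")
    out = records.copy()
    out["normalized"] = out["intensity"] / slope
    return out


def _quartiles(values: np.ndarray) -> tuple[float, float, float]:
    q1, med, q3 = np.percentile(values, [25, 50, 75])  # linear interpolation
    return float(q1), float(med), float(q3)


def summarize_composition(records: pd.DataFrame, value_col: str = "normalized") -> pd.DataFrame:
    """Per-group mean, sample sd, N plus boxplot statistics.

    Whiskers span the smallest and largest value of the set; points beyond
    1.5x the interquartile range from the quartiles are flagged as outliers
    but retained in every statistic.
    """
    if value_col not in records.columns:
        raise InvalidParameterError(f"records have no {value_col!r} column")
    rows = []
    for (system, group), sub in records.groupby(["system", "group"], sort=True):
        v = sub[value_col].to_numpy(dtype=float)
        q1, med, q3 = _quartiles(v)
        iqr = q3 - q1
        out_mask = (v < q1 - 1.5 * iqr) | (v > q3 + 1.5 * iqr)
        rows.append(
            {
                "system": system,
                "group": group,
                "x_rel": float(sub["x_rel"].iloc[0]),
                "n": int(v.size),
                "mean": float(v.mean()),
                "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0,
                "median": med,
                "q1": q1,
                "q3": q3,
                "whisker_low": float(v.min()),
                "whisker_high": float(v.max()),
                "n_outliers": int(out_mask.sum()),
            }
        )
    return pd.DataFrame(rows).sort_values(["system", "x_rel"]).reset_index(drop=True)
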