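"""File formats and configuration.

Conventions: multi-page grayscale TIFF (16-bit) for image stacks with a flat
``key: value`` metadata sidecar; trace CSV with header
``frame,time_s,intensity,phase`` where phase is pre/bleach/post; results and
summaries as TSV; all physical quantities in µm and seconds, intensities in
arbitrary units.  Image origin is top-left, (row, col) order, pixel centers
at integer coordinates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, fields as dc_fields
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import tifffile

from .frap import (
    FrameSchedule,
    FrapTrace,
    ImageStack,
    InvalidParameterError,
    SpotGeometry,
)
from .qc import QCRules

__all__ = [
    "FormatError",
    "RunConfig",
    "read_stack",
    "write_stack",
    "read_trace_csv",
    "write_trace_csv",
    "load_config",
]

TRACE_COLUMNS = ("frame", "time_s", "intensity", "phase")


class FormatError(ValueError):
    """An input file does not follow the expected format."""


# ---------------------------------------------------------------------------
# TIFF stacks
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.txt")


def write_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write a multi-page 16-bit grayscale TIFF plus a flat key:value sidecar."""
    path = Path(path)
    frames = np.clip(np.round(stack.frames), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    tifffile.imwrite(path, frames)
    meta = {
        "pixel_size": stack.pixel_size,
        "n_pre": stack.schedule.n_pre,
        "t_bleach": stack.schedule.t_bleach,
        "n_post": stack.schedule.n_post,
        "dt": stack.schedule.dt,
        **stack.metadata,
    }
    lines = [f"{k}: {v}" for k, v in meta.items()]
    _sidecar_path(path).write_text("\n".join(lines) + "\n")
    return path


def _parse_sidecar(path: Path) -> dict:
    meta: dict = {}
    for ln in path.read_text().splitlines():
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        if ":" not in ln:
            raise FormatError(f"malformed sidecar line in {path}: {ln!r}")
        k, v = ln.split(":", 1)
        v = v.strip()
        try:
            meta[k.strip()] = int(v)
        except ValueError:
            try:
                meta[k.strip()] = float(v)
            except ValueError:
                meta[k.strip()] = v
    return meta


def read_stack(path: str | Path, schedule: Optional[FrameSchedule] = None) -> ImageStack:
    """Read a multi-page grayscale TIFF; merge the metadata sidecar if present.

    The frame schedule comes from the sidecar (n_pre, t_bleach, n_post, dt)
    unless supplied explicitly.  RGB pages are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such stack: {path}")
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim != 3:
        raise FormatError(
            f"{path}: expected single-channel pages, got array of shape {frames.shape}"
        )
    meta: dict = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = _parse_sidecar(sidecar)
    if schedule is None:
        keys = ("n_pre", "t_bleach", "n_post", "dt")
        if not all(k in meta for k in keys):
            raise FormatError(
                f"{path}: no frame schedule; supply one or provide a sidecar "
                f"with keys {keys}"
            )
        schedule = FrameSchedule(
            n_pre=int(meta["n_pre"]),
            t_bleach=float(meta["t_bleach"]),
            n_post=int(meta["n_post"]),
            dt=float(meta["dt"]),
        )
    pixel_size = float(meta.get("pixel_size", 1.0))
    extra = {k: v for k, v in meta.items()
             if k not in ("pixel_size", "n_pre", "t_bleach", "n_post", "dt")}
    extra["dtype"] = str(frames.dtype)
    return ImageStack(
        frames=frames.astype(float),
        pixel_size=pixel_size,
        schedule=schedule,
        metadata=extra,
    )


# ---------------------------------------------------------------------------
# trace CSV
# ---------------------------------------------------------------------------

def write_trace_csv(trace: FrapTrace, path: str | Path) -> Path:
    """Write ``frame,time_s,intensity,phase`` rows for one trace."""
    path = Path(path)
    n_pre = trace.schedule.n_pre
    phase = ["pre"] * n_pre + ["post"] * trace.schedule.n_post
    df = pd.DataFrame(
        {
            "frame": np.arange(trace.times.size),
            "time_s": trace.times,
            "intensity": trace.intensities,
            "phase": phase,
        }
    )
    df.to_csv(path, index=False)
    return path


def read_trace_csv(
    path: str | Path,
    geometry: Optional[SpotGeometry] = None,
    vesicle_id: str = "",
    condition: str = "",
) -> FrapTrace:
    """Read a trace CSV back into a :class:`FrapTrace`.

    Bleach-phase rows are dropped (the pulse is not part of the analysis);
    extra columns are ignored with a warning.  At least 8 pre-bleach rows are
    required — the pre-bleach reference is their 8-frame average.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such trace: {path}")
    df = pd.read_csv(path)
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    extra = [c for c in df.columns if c not in TRACE_COLUMNS]
    if extra:
        warnings.warn(f"{path}: ignoring extra columns {extra}", stacklevel=2)
    bad = set(df["phase"]) - {"pre", "bleach", "post"}
    if bad:
        raise FormatError(f"{path}: unknown phase values {sorted(bad)}")
    df = df[df["phase"] != "bleach"]
    if np.any(np.diff(df["time_s"].to_numpy()) <= 0):
        raise FormatError(f"{path}: time_s must be strictly increasing")
    n_pre = int((df["phase"] == "pre").sum())
    n_post = int((df["phase"] == "post").sum())
    if n_pre < 8:
        raise FormatError(
            f"{path}: {n_pre} pre-bleach rows; at least 8 pre-bleach frames "
            "are required for the pre-bleach reference"
        )
    post_t = df.loc[df["phase"] == "post", "time_s"].to_numpy()
    dt = float(np.median(np.diff(post_t))) if n_post > 1 else 1.0
    pre_t = df.loc[df["phase"] == "pre", "time_s"].to_numpy()
    t_bleach = max(0.0, float(-pre_t[-1] - dt))
    schedule = FrameSchedule(n_pre=n_pre, t_bleach=t_bleach, n_post=n_post, dt=dt)
    if geometry is None:
        geometry = SpotGeometry(w=2.0, t_bleach=t_bleach)
    return FrapTrace(
        times=df["time_s"].to_numpy(float),
        intensities=df["intensity"].to_numpy(float),
        schedule=schedule,
        geometry=geometry,
        vesicle_id=vesicle_id or path.stem,
        condition=condition,
    )


# ---------------------------------------------------------------------------
# run configuration (flat typed key: value text file)
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Validated run settings shared by the CLI commands."""

    pixel_size: float = 0.2
    w: float = 2.0
    area: float = math.pi * 20.0**2
    n_pre: int = 8
    n_post: int = 100
    dt: float = 0.2
    t_bleach: float = 0.1
    seed: int = 0
    # simulation
    D_true: float = 1.0
    beta: float = 0.8
    M_true: float = 0.95
    F_pre: float = 100.0
    sigma_noise: float = 0.0
    reservoir_radius: float = 20.0
    curve_model: str = "closed_form"
    # composition simulation
    brightness_per_unit: float = 10.0
    n_per_group: int = 50
    composition_sigma: float = 1.0
    # QC thresholds
    area_ratio_min: float = 5.0
    pulse_ratio_max: float = 0.1
    mobile_min: float = 0.75
    movement_max_displacement: float = math.nan  # nan => w/2 default

    def schedule(self) -> FrameSchedule:
        return FrameSchedule(
            n_pre=self.n_pre, t_bleach=self.t_bleach, n_post=self.n_post, dt=self.dt
        )

    def geometry(self) -> SpotGeometry:
        return SpotGeometry(w=self.w, area=self.area, t_bleach=self.t_bleach)

    def qc_rules(self) -> QCRules:
        move = None if math.isnan(self.movement_max_displacement) else self.movement_max_displacement
        return QCRules(
            area_ratio_min=self.area_ratio_min,
            pulse_ratio_max=self.pulse_ratio_max,
            mobile_min=self.mobile_min,
            movement_max_displacement=move,
        )


def load_config(path: str | Path | None) -> RunConfig:
    """Load a flat ``key: value`` config file with explicit validation.

    Unknown keys and untypable values raise errors naming the offending key.
    A missing path yields the defaults.
    """
    cfg = RunConfig()
    if path is None:
        return cfg
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such config: {path}")
    types = {f.name: f.type for f in dc_fields(RunConfig)}
    casts = {"pixel_size": float, "w": float, "area": float, "n_pre": int,
             "n_post": int, "dt": float, "t_bleach": float, "seed": int,
             "D_true": float, "beta": float, "M_true": float, "F_pre": float,
             "sigma_noise": float, "reservoir_radius": float, "curve_model": str,
             "brightness_per_unit": float, "n_per_group": int,
             "composition_sigma": float, "area_ratio_min": float,
             "pulse_ratio_max": float, "mobile_min": float,
             "movement_max_displacement": float}
    for ln in path.read_text().splitlines():
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        if ":" not in ln:
            raise FormatError(f"{path}: malformed line (expected 'key: value'): {ln!r}")
        key, raw = (s.strip() for s in ln.split(":", 1))
        if key not in casts:
            raise InvalidParameterError(f"{path}: unknown config key {key!r}")
        try:
            setattr(cfg, key, casts[key](raw))
        except ValueError as exc:
            raise InvalidParameterError(
                f"{path}: bad value for key {key!r}: {raw!r} ({exc})"
            ) from None
    # fail fast on invalid combinations
    cfg.schedule()
    cfg.geometry()
    cfg.qc_rules()
    return cfg
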