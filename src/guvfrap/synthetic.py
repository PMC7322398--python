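"""Synthetic FRAP and composition data with known ground truth.

Everything the analysis pipeline consumes can be generated here, with the
statistical and physical structure the method assumes:

* the Soumpasis closed-form fractional recovery for a uniform circular bleach
  spot on an infinite membrane, f(t) = exp(-2 tau/t) [I0(2 tau/t) + I1(2 tau/t)]
  with tau = w^2 / (4 D);
* noisy ROI-mean traces following either that closed form or the exponential
  model family the pipeline fits (useful for unbiased parameter recovery);
* a Brownian-walker simulator of the bleach physics on a finite reflecting
  disc — an oracle independent of the closed form;
* rendered image stacks (bright membrane disc with an evolving dark spot);
* binary-lipid composition datasets whose ring intensity is proportional to
  the labelled-lipid relative concentration;
* labelled cohorts at the per-condition diffusion coefficients reported for
  electroformed and OLA-produced DOPC/POPC vesicles.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.optimize import brentq
from scipy.special import ive

from .frap import (
    FrameSchedule,
    FrapTrace,
    ImageStack,
    InvalidParameterError,
    SpotGeometry,
)

__all__ = [
    "SimConfig",
    "CompositionSimConfig",
    "ConditionPreset",
    "CONDITION_PRESETS",
    "soumpasis_fractional",
    "solve_half_time_constant",
    "generate_trace",
    "simulate_lattice_frap",
    "render_frap_stack",
    "render_ring_image",
    "generate_composition_dataset",
    "generate_cohort",
    "preset_config",
]


# ---------------------------------------------------------------------------
# closed-form recovery (uniform disk bleach, Soumpasis / Axelrod)
# ---------------------------------------------------------------------------

def soumpasis_fractional(t, w: float, D: float):
    """Fractional recovery of a uniform-disk bleach on an infinite membrane.

    f(t) = exp(-2 tau / t) * [I0(2 tau / t) + I1(2 tau / t)], tau = w^2/(4 D).

    Evaluated with exponentially scaled Bessel functions for stability at
    small t.  f(0) = 0, f is monotone non-decreasing and tends to 1.
    Accepts scalars or arrays for ``t`` (seconds); ``w`` in µm, ``D`` in µm²/s.
    """
    if w <= 0:
        raise InvalidParameterError("spot radius w must be > 0")
    if D <= 0:
        raise InvalidParameterError("diffusion coefficient D must be > 0")
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise InvalidParameterError("time t must be >= 0")
    tau = w**2 / (4.0 * D)
    with np.errstate(divide="ignore"):
        x = np.where(t_arr > 0, 2.0 * tau / np.where(t_arr > 0, t_arr, 1.0), np.inf)
    f = np.where(t_arr > 0, ive(0, x) + ive(1, x), 0.0)
    return f if f.ndim else float(f)


def solve_half_time_constant(w: float = 2.0, D: float = 1.0, rtol: float = 1e-10) -> float:
    """Dimensionless constant c = D * t_half / w^2 of the closed-form recovery.

    Root-solves f(t) = 1/2 by bracketing bisection (Brent) to relative
    tolerance; c is independent of the (w, D) pair used.  Rounds to the
    conventional 0.224 at three decimals.
    """
    tau = w**2 / (4.0 * D)

    def half_crossing(t: float) -> float:
        return soumpasis_fractional(t, w, D) - 0.5

    t_half = brentq(half_crossing, 1e-6 * tau, 1e6 * tau, rtol=min(rtol, 1e-8))
    return D * t_half / w**2


# ---------------------------------------------------------------------------
# simulation configuration
# ---------------------------------------------------------------------------

_CURVE_MODELS = ("closed_form", "exponential_model", "lattice")


@dataclass(frozen=True)
class SimConfig:
    """Ground-truth parameters of one simulated FRAP measurement.

    ``beta`` is the bleach depth (fraction of spot fluorescence destroyed),
    ``M_true`` the mobile fraction, ``reservoir_radius`` the radius of the
    observed membrane disc (None = unbounded plane).  ``curve_model`` selects
    the noise-free recovery shape: the physical closed form, the exponential
    family the pipeline fits, or the Brownian-walker lattice oracle.
    """

    D_true: float = 1.0
    w: float = 2.0
    beta: float = 0.8
    M_true: float = 0.95
    F_pre: float = 100.0
    sigma_noise: float = 0.0
    reservoir_radius: Optional[float] = 20.0
    curve_model: str = "closed_form"
    schedule: FrameSchedule = field(default_factory=FrameSchedule)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.D_true <= 0:
            raise InvalidParameterError("D_true must be > 0")
        if self.w <= 0:
            raise InvalidParameterError("w must be > 0")
        if not 0 < self.beta <= 1:
            raise InvalidParameterError("beta must be in (0, 1]")
        if not 0 <= self.M_true <= 1:
            raise InvalidParameterError("M_true must be in [0, 1]")
        if self.sigma_noise < 0:
            raise InvalidParameterError("sigma_noise must be >= 0")
        if self.reservoir_radius is not None and self.reservoir_radius <= self.w:
            raise InvalidParameterError("reservoir_radius must exceed the spot radius w")
        if self.curve_model not in _CURVE_MODELS:
            raise InvalidParameterError(
                f"curve_model must be one of {_CURVE_MODELS}, got {self.curve_model!r}"
            )

    @property
    def tau_d(self) -> float:
        """Characteristic diffusion time tau = w^2 / (4 D)."""
        return self.w**2 / (4.0 * self.D_true)

    def geometry(self) -> SpotGeometry:
        area = (
            math.inf
            if self.reservoir_radius is None
            else math.pi * self.reservoir_radius**2
        )
        return SpotGeometry(w=self.w, area=area, t_bleach=self.schedule.t_bleach)


# ---------------------------------------------------------------------------
# trace generators
# ---------------------------------------------------------------------------

def _recovery_shape(config: SimConfig, t: np.ndarray) -> np.ndarray:
    """Noise-free fractional recovery g(t) for the configured curve model."""
    if config.curve_model == "closed_form":
        return np.asarray(soumpasis_fractional(t, config.w, config.D_true))
    if config.curve_model == "exponential_model":
        t_half = solve_half_time_constant() * config.w**2 / config.D_true
        a = math.log(2) / t_half
        return -np.expm1(-a * t)
    raise InvalidParameterError(
        "generate_trace supports closed_form and exponential_model; "
        "use simulate_lattice_frap for the lattice oracle"
    )


def generate_trace(config: SimConfig) -> FrapTrace:
    """Simulate a noisy ROI-mean FRAP trace.

    Pre-bleach frames sit at F_pre; the first recovery frame at
    F(0) = F_pre (1 - beta); the noise-free recovery is
    F(t) = F(0) + (F_plateau - F(0)) g(t) with
    F_plateau = F(0) + M_true (F_pre - F(0)) and g the configured model.
    Additive zero-mean Gaussian noise of sd ``sigma_noise`` on every frame.
    """
    if config.curve_model == "lattice":
        return simulate_lattice_frap(config)
    rng = np.random.default_rng(config.seed)
    sched = config.schedule
    t = sched.recovery_times()
    F0 = config.F_pre * (1.0 - config.beta)
    F_plateau = F0 + config.M_true * (config.F_pre - F0)
    mean = np.concatenate(
        [
            np.full(sched.n_pre, config.F_pre),
            F0 + (F_plateau - F0) * _recovery_shape(config, t),
        ]
    )
    values = mean + rng.normal(0.0, config.sigma_noise, size=mean.size) if config.sigma_noise > 0 else mean
    return FrapTrace(
        times=sched.times(),
        intensities=values,
        schedule=sched,
        geometry=config.geometry(),
    )


def _reflect_radial(pos: np.ndarray, R: float) -> None:
    """Reflect walkers that stepped outside the disc of radius R (in place)."""
    r = np.hypot(pos[:, 0], pos[:, 1])
    out = r > R
    while out.any():
        scale = (2.0 * R - r[out]) / r[out]
        pos[out] *= scale[:, None]
        r = np.hypot(pos[:, 0], pos[:, 1])
        out = r > R


def simulate_lattice_frap(
    config: SimConfig, n_particles: int = 100_000
) -> FrapTrace:
    """Brownian-walker oracle for uniform-disk FRAP on a finite membrane disc.

    Walkers representing the bleach-origin dye start uniformly inside the
    spot (radius w) and take Gaussian steps of per-axis variance 2 D dt with
    radial reflection at the reservoir boundary R.  The ROI intensity is
    F(t) = F_pre (1 - beta u(t)) where u(t) is the fraction of walkers inside
    the spot: the unbleached dye field is uniform at equilibrium and stays so
    under reflecting boundaries, so its ROI mean is F_pre-proportional and
    constant, and the bleach probability beta enters the expectation exactly.
    Tracking only the bleach-origin population is a conditional Monte Carlo
    estimator of the same trace a full-field particle count would give, with
    variance ~1/N instead of ~(R/w)^2/N.

    An immobile fraction (1 - M_true) of walkers is frozen, producing the
    apparent immobile fraction the trace-level generator prescribes; a finite
    reservoir additionally caps the plateau at 1 - (w/R)^2 (conservation of
    bleached dye).
    """
    if config.curve_model != "lattice":
        raise InvalidParameterError("simulate_lattice_frap requires curve_model='lattice'")
    if config.reservoir_radius is None:
        raise InvalidParameterError("lattice oracle needs a finite reservoir_radius")
    if n_particles < 1_000:
        raise InvalidParameterError("n_particles must be >= 1000")

    rng = np.random.default_rng(config.seed)
    sched = config.schedule
    w, R, D = config.w, config.reservoir_radius, config.D_true

    # uniform placement inside the bleach spot
    r = w * np.sqrt(rng.random(n_particles))
    theta = 2.0 * math.pi * rng.random(n_particles)
    pos = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    n_immobile = int(round((1.0 - config.M_true) * n_particles))
    mobile = np.ones(n_particles, dtype=bool)
    mobile[:n_immobile] = False  # placement is already exchangeable

    step_sd = math.sqrt(2.0 * D * sched.dt)
    u = np.empty(sched.n_post)
    u[0] = 1.0  # all bleach-origin walkers start inside the spot
    w2 = w * w
    n_mobile = int(mobile.sum())
    for j in range(1, sched.n_post):
        if n_mobile and D > 0:
            pos[mobile] += rng.normal(0.0, step_sd, size=(n_mobile, 2))
            _reflect_radial(pos, R)
        inside = pos[:, 0] ** 2 + pos[:, 1] ** 2 <= w2
        u[j] = inside.mean()

    values = np.concatenate(
        [
            np.full(sched.n_pre, config.F_pre),
            config.F_pre * (1.0 - config.beta * u),
        ]
    )
    if config.sigma_noise > 0:
        values = values + rng.normal(0.0, config.sigma_noise, size=values.size)
    return FrapTrace(
        times=sched.times(),
        intensities=values,
        schedule=sched,
        geometry=config.geometry(),
    )


# ---------------------------------------------------------------------------
# image-stack rendering
# ---------------------------------------------------------------------------

def _closed_form_dark_profile(
    r_grid: np.ndarray, t: float, w: float, D: float
) -> np.ndarray:
    """Fraction of the initial disc-shaped bleach remaining at radius r, time t.

    Radial heat-kernel convolution of the disc indicator:
    u(r, t) = int_0^w (r'/(2 D t)) exp(-(r - r')^2 / (4 D t)) ive(0, r r'/(2 D t)) dr'.
    """
    if t <= 0:
        return (r_grid <= w).astype(float)
    s = 2.0 * D * t
    rp = np.linspace(0.0, w, 512)
    z = np.outer(r_grid, rp) / s
    integrand = (rp / s) * np.exp(-((r_grid[:, None] - rp[None, :]) ** 2) / (2.0 * s)) * ive(0, z)
    return np.trapezoid(integrand, rp, axis=1)


def render_frap_stack(
    config: SimConfig,
    pixel_size: float = 0.2,
    psf_sigma: float = 0.0,
    margin: float = 1.0,
    n_particles: int = 100_000,
    poisson_noise: bool = False,
) -> ImageStack:
    """Render a FRAP acquisition: bright membrane disc with a recovering
    dark spot centered on it.

    ``psf_sigma`` (µm) applies a Gaussian blur emulating the point-spread
    function; per-pixel noise is Gaussian of sd ``sigma_noise`` or Poisson
    when ``poisson_noise`` is set.  The mean ROI intensity of the rendered
    stack reproduces :func:`generate_trace` for the same config (up to pixel
    discretization).
    """
    if pixel_size <= 0:
        raise InvalidParameterError("pixel_size must be > 0")
    if config.reservoir_radius is None:
        raise InvalidParameterError("rendering needs a finite reservoir_radius")
    rng = np.random.default_rng(config.seed + 1)
    sched = config.schedule
    R, w = config.reservoir_radius, config.w
    half = R + margin
    n_px = int(math.ceil(2 * half / pixel_size)) | 1  # odd => center on a pixel
    c = n_px // 2
    yy, xx = np.mgrid[:n_px, :n_px]
    r_px = np.hypot(yy - c, xx - c) * pixel_size
    disc = r_px <= R

    frames = np.zeros((sched.n_frames, n_px, n_px))
    frames[: sched.n_pre, disc] = config.F_pre

    t_rec = sched.recovery_times()
    if config.curve_model == "lattice":
        dark_hist = _lattice_dark_histograms(config, rng, n_px, c, pixel_size, n_particles)
        for j in range(sched.n_post):
            img = np.where(disc, config.F_pre * (1.0 - config.beta * dark_hist[j]), 0.0)
            frames[sched.n_pre + j] = np.clip(img, 0.0, None)
    else:
        r_grid = np.linspace(0.0, r_px.max() + pixel_size, 400)
        in_spot = r_px <= w  # sharp edges evaluated per pixel, not interpolated
        for j, t in enumerate(t_rec):
            if t > 0:
                u_px = np.interp(r_px, r_grid, _closed_form_dark_profile(r_grid, t, w, config.D_true))
            else:
                u_px = in_spot.astype(float)
            dark = config.beta * ((1.0 - config.M_true) * in_spot + config.M_true * u_px)
            img = np.where(disc, config.F_pre * (1.0 - dark), 0.0)
            frames[sched.n_pre + j] = np.clip(img, 0.0, None)

    if psf_sigma > 0:
        sig_px = psf_sigma / pixel_size
        for k in range(frames.shape[0]):
            frames[k] = gaussian_filter(frames[k], sig_px)
    if poisson_noise:
        frames = rng.poisson(np.clip(frames, 0.0, None)).astype(float)
    elif config.sigma_noise > 0:
        frames = np.clip(frames + rng.normal(0.0, config.sigma_noise, frames.shape), 0.0, None)

    center_um = (c * pixel_size, c * pixel_size)
    meta = {
        "spot_center_y_um": center_um[0],
        "spot_center_x_um": center_um[1],
        "spot_radius_um": w,
        "reservoir_radius_um": R,
        "area_um2": math.pi * R**2,
    }
    return ImageStack(frames=frames, pixel_size=pixel_size, schedule=sched, metadata=meta)


def _lattice_dark_histograms(
    config: SimConfig,
    rng: np.random.Generator,
    n_px: int,
    c: int,
    pixel_size: float,
    n_particles: int,
) -> np.ndarray:
    """Per-frame normalized dark-walker density maps (1 = initial spot density)."""
    sched = config.schedule
    w, R, D = config.w, config.reservoir_radius, config.D_true
    r = w * np.sqrt(rng.random(n_particles))
    theta = 2.0 * math.pi * rng.random(n_particles)
    pos = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    n_immobile = int(round((1.0 - config.M_true) * n_particles))
    mobile = np.ones(n_particles, dtype=bool)
    mobile[:n_immobile] = False
    step_sd = math.sqrt(2.0 * D * sched.dt)
    # normalization: initial walker density inside the spot per pixel
    per_px = n_particles * (pixel_size**2) / (math.pi * w**2)
    edges = (np.arange(n_px + 1) - 0.5 - c) * pixel_size
    hists = np.empty((sched.n_post, n_px, n_px))
    for j in range(sched.n_post):
        if j > 0 and mobile.any() and D > 0:
            pos[mobile] += rng.normal(0.0, step_sd, size=(int(mobile.sum()), 2))
            _reflect_radial(pos, R)
        h, _, _ = np.histogram2d(pos[:, 0], pos[:, 1], bins=[edges, edges])
        hists[j] = np.clip(h / per_px, 0.0, 1.0)
    return hists


# ---------------------------------------------------------------------------
# composition datasets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CompositionSimConfig:
    """Synthetic binary-lipid composition experiment.

    Each vesicle's equatorial-ring intensity is
    I = brightness_per_unit * x_rel + Gaussian noise (truncated at 0), with
    x_rel the relative concentration of fluorescently labelled lipid (1, 2, 3
    for the 3:1, 2:2 and 1:3 non-fluorescent:fluorescent mixing ratios).
    """

    groups: tuple = (("3:1", 1.0), ("2:2", 2.0), ("1:3", 3.0))
    n_vesicles_per_group: int = 50
    brightness_per_unit: float = 10.0
    sigma_noise: float = 1.0
    system: str = "PCPE"
    render_images: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.groups) == 0:
            raise InvalidParameterError("groups must not be empty")
        for label, x in self.groups:
            if x <= 0:
                raise InvalidParameterError(f"x_rel must be > 0 (group {label!r})")
        if self.n_vesicles_per_group < 1:
            raise InvalidParameterError("n_vesicles_per_group must be >= 1")
        if self.brightness_per_unit <= 0:
            raise InvalidParameterError("brightness_per_unit must be > 0")
        if self.sigma_noise < 0:
            raise InvalidParameterError("sigma_noise must be >= 0")


def generate_composition_dataset(config: CompositionSimConfig):
    """Per-vesicle ring intensities proportional to labelled-lipid content.

    Returns a :class:`guvfrap.composition.CompositionDataset`; when
    ``render_images`` is set, also a list of (vesicle_id, 2-D image) ring
    renderings for end-to-end testing of the image path.
    """
    from .composition import CompositionDataset

    rng = np.random.default_rng(config.seed)
    rows = []
    images = []
    for label, x in config.groups:
        mean = config.brightness_per_unit * x
        noise = (
            rng.normal(0.0, config.sigma_noise, config.n_vesicles_per_group)
            if config.sigma_noise > 0
            else np.zeros(config.n_vesicles_per_group)
        )
        for k, intensity in enumerate(np.clip(mean + noise, 0.0, None)):
            vid = f"{config.system}_{label.replace(':', '')}_{k:03d}"
            rows.append(
                {
                    "vesicle_id": vid,
                    "system": config.system,
                    "group": label,
                    "x_rel": x,
                    "intensity": float(intensity),
                }
            )
            if config.render_images:
                images.append((vid, render_ring_image(float(intensity), seed=int(rng.integers(2**31)))))
    dataset = CompositionDataset(records=pd.DataFrame(rows))
    return (dataset, images) if config.render_images else dataset


def render_ring_image(
    ring_intensity: float,
    radius_px: float = 20.0,
    band_px: float = 3.0,
    size: int = 96,
    background: float = 5.0,
    sigma_noise: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Render an equatorial-ring vesicle image: a bright annulus over background."""
    rng = np.random.default_rng(seed)
    c = (size - 1) / 2.0
    yy, xx = np.mgrid[:size, :size]
    r = np.hypot(yy - c, xx - c)
    img = np.full((size, size), background, dtype=float)
    img[np.abs(r - radius_px) <= band_px / 2.0] += ring_intensity
    if sigma_noise > 0:
        img = np.clip(img + rng.normal(0.0, sigma_noise, img.shape), 0.0, None)
    return img


# ---------------------------------------------------------------------------
# condition presets and cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConditionPreset:
    """One experimental condition: production technique, lipid, environment."""

    label: str
    D: float  # reported mean lateral diffusion coefficient (µm²/s)
    sd: float  # reported between-vesicle standard deviation (µm²/s)
    n: int  # reported number of vesicles
    description: str = ""


#: Reported per-condition lateral diffusion coefficients (mean ± sd, N) for
#: electroformed and OLA-produced GUVs; keys name technique, lipid and
#: chemical environment.  Baseline conditions are at ~20 °C in 15% glycerol.
CONDITION_PRESETS: dict[str, ConditionPreset] = {
    p.label: p
    for p in [
        ConditionPreset("electro_DOPC", 1.0, 0.2, 17, "electroformed DOPC, no encapsulated P-188"),
        ConditionPreset("ola_DOPC", 1.1, 0.2, 34, "OLA DOPC, no encapsulated P-188"),
        ConditionPreset("electro_DOPC_P188", 1.2, 0.4, 14, "electroformed DOPC, 50 mg/mL P-188 inside"),
        ConditionPreset("ola_DOPC_P188", 1.0, 0.3, 30, "OLA DOPC, 50 mg/mL P-188 inside"),
        ConditionPreset("electro_POPC", 0.8, 0.2, 28, "electroformed POPC, no encapsulated P-188"),
        ConditionPreset("ola_POPC", 1.0, 0.3, 49, "OLA POPC, no encapsulated P-188"),
        ConditionPreset("electro_POPC_P188", 1.3, 0.4, 20, "electroformed POPC, 50 mg/mL P-188 inside"),
        ConditionPreset("ola_POPC_P188", 0.9, 0.3, 27, "OLA POPC, 50 mg/mL P-188 inside"),
        ConditionPreset("electro_DOPC_20C_0gly", 1.6, 0.2, 12, "electroformed DOPC, 20 C, 0% glycerol"),
        ConditionPreset("electro_DOPC_37C_15gly", 1.9, 0.6, 19, "electroformed DOPC, 37 C, 15% glycerol"),
        ConditionPreset("electro_DOPC_37C_0gly", 2.2, 0.5, 7, "electroformed DOPC, 37 C, 0% glycerol"),
    ]
}


def preset_config(name: str, **overrides) -> SimConfig:
    """SimConfig for a named condition preset (exponential model, 5% noise)."""
    if name not in CONDITION_PRESETS:
        raise InvalidParameterError(
            f"unknown preset {name!r}; available: {sorted(CONDITION_PRESETS)}"
        )
    base = SimConfig(
        D_true=CONDITION_PRESETS[name].D,
        curve_model="exponential_model",
        sigma_noise=5.0,  # 5% of the default F_pre = 100
    )
    return replace(base, **overrides) if overrides else base


def generate_cohort(
    presets: Union[dict[str, SimConfig], Sequence[tuple[str, SimConfig]]],
    n_per_condition: Union[int, dict[str, int]],
    seed: int = 0,
) -> list[FrapTrace]:
    """Labelled traces for a grid of conditions, ready for the full pipeline.

    ``presets`` maps condition labels to SimConfigs; ``n_per_condition`` is a
    single count or a per-label dict.  Per-trace seeds are spawned from
    ``seed`` so the cohort is reproducible as a whole.
    """
    items = list(presets.items()) if isinstance(presets, dict) else list(presets)
    if not items:
        raise InvalidParameterError("presets must not be empty")
    rng = np.random.default_rng(seed)
    traces: list[FrapTrace] = []
    for label, cfg in items:
        n = n_per_condition[label] if isinstance(n_per_condition, dict) else n_per_condition
        if n < 1:
            raise InvalidParameterError(f"n_per_condition must be >= 1 (condition {label!r})")
        for k in range(n):
            tr = generate_trace(replace(cfg, seed=int(rng.integers(2**31))))
            tr.condition = label
            tr.vesicle_id = f"{label}_{k:03d}"
            traces.append(tr)
    return traces
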