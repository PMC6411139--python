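"""Synthetic fluorescence-like image stacks with known ground-truth quality.

Real intravital captures of moving organs are not publicly available, so this
module generates stacks that emulate their salient features: bright, roughly
circular labelled cells on a dark background, with the cell count and positions
redrawn every frame (circulating cells move between exposures) and a per-frame
degradation — Gaussian defocus blur plus a proportional loss of fluorescence
signal — that drives a known true quality.  Gaussian read noise is added and
values are clipped and quantised to the configured bit depth.

True quality maps linearly from the blur width:
``true_quality = 5 * (1 - sigma / blur_sigma_max)``, so sigma = 0 is a perfect
frame (score 5) and maximal defocus scores 0.  A simulated "human" score adds
Gaussian noise (emulating inter-rater variability) then rounds and clips to
the integer 0-5 scale.

Generation is a pure function of the configuration, including its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .errors import InvalidConfigurationError
from .stats import FrameImage

__all__ = ["SynthConfig", "generate_stack", "standard_benchmark", "BENCHMARK_N_FRAMES"]

BENCHMARK_N_FRAMES = 200


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings.

    Defaults emulate a spinning-disk intravital capture of a 256 x 256 sensor
    region: 24-30 labelled cells of radius 4-8 px at amplitude 12000 grey
    units over a 4000-unit background (autofluorescence plus camera offset),
    read noise sd 1500, defocus blur up to 8 px with 50% signal loss at
    maximal defocus, small per-frame illumination/background fluctuations and
    per-cell labelling heterogeneity, and simulated-rater score noise of 0.4
    quality units.
    """

    n_frames: int = 50
    width: int = 256
    height: int = 256
    bit_depth: int = 16
    n_cells_range: tuple[int, int] = (24, 30)
    cell_radius_range: tuple[int, int] = (4, 8)
    cell_intensity: float = 12000.0  # amplitude above background
    background_level: float = 4000.0
    noise_sd: float = 1500.0
    blur_sigma_max: float = 8.0
    intensity_loss: float = 0.5  # fraction of cell amplitude lost at max defocus
    illumination_jitter: float = 0.02  # per-frame excitation fluctuation (uniform half-width)
    cell_intensity_jitter: float = 0.2  # per-cell labelling heterogeneity (uniform half-width)
    background_jitter: float = 0.02  # per-frame background drift (uniform half-width)
    gradient_max: float = 0.0  # optional per-frame illumination gradient (off by default)
    quality_profile: Literal["random", "periodic", "runs"] = "runs"
    score_noise_sd: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1 or self.width < 8 or self.height < 8:
            raise InvalidConfigurationError("stack must have >= 1 frame of >= 8x8 pixels")
        if self.bit_depth not in (8, 16):
            raise InvalidConfigurationError("bit_depth must be 8 or 16")
        lo, hi = self.n_cells_range
        rlo, rhi = self.cell_radius_range
        if lo > hi or lo < 0 or rlo > rhi or rlo < 1:
            raise InvalidConfigurationError("inconsistent cell count/radius ranges")
        if self.cell_intensity <= self.background_level:
            raise InvalidConfigurationError("cell_intensity must exceed background_level")
        if self.blur_sigma_max < 0 or self.score_noise_sd < 0 or self.noise_sd < 0:
            raise InvalidConfigurationError("noise and blur parameters must be >= 0")
        if not 0.0 <= self.intensity_loss <= 1.0:
            raise InvalidConfigurationError("intensity_loss must be in [0, 1]")
        for name in (
            "illumination_jitter",
            "cell_intensity_jitter",
            "background_jitter",
            "gradient_max",
        ):
            if not 0.0 <= getattr(self, name) < 1.0:
                raise InvalidConfigurationError(f"{name} must be in [0, 1)")
        if self.quality_profile not in ("random", "periodic", "runs"):
            raise InvalidConfigurationError(f"unknown quality_profile {self.quality_profile!r}")


def _blur_levels(config: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-frame relative defocus level in [0, 1] (sigma = level * blur_sigma_max)."""
    n = config.n_frames
    if config.quality_profile == "random":
        return rng.uniform(0.0, 1.0, size=n)
    if config.quality_profile == "periodic":
        # smooth contraction-like cycle, period 20 frames
        return (1.0 - np.cos(2.0 * np.pi * np.arange(n) / 20.0)) / 2.0
    # "runs": stretches of similar quality, as produced by an organ moving
    # through its cardiac/respiratory cycle.  Run lengths are 2-5 frames; run
    # levels cycle through four strata of the defocus range (shuffled within
    # each cycle of four runs, with run-level and per-frame jitter), so any
    # ~20-frame window spans the full quality range the way a short stretch of
    # a periodically moving organ does.  The last deep-defocus run of at least
    # 5 frames is pinned to the extreme of its stratum so every generated
    # stack contains a run of >= 5 badly defocused frames regardless of seed.
    strata = np.array([0.02, 0.35, 0.68, 0.95])
    levels = np.empty(n)
    pos = 0
    j = 0
    order = rng.permutation(4)
    poor_runs: list[tuple[int, int]] = []  # (start, length) of deep-defocus runs
    while pos < n:
        if j % 4 == 0:
            order = rng.permutation(4)
        stratum = int(order[j % 4])
        run = min(int(rng.integers(2, 6)), n - pos)
        level = float(np.clip(strata[stratum] + rng.uniform(-0.08, 0.08), 0.0, 1.0))
        jitter = rng.normal(0.0, 0.06, size=run)
        levels[pos : pos + run] = np.clip(level + jitter, 0.0, 1.0)
        if stratum == 3:
            poor_runs.append((pos, run))
        pos += run
        j += 1
    long_poor = [(s, r) for s, r in poor_runs if r >= 5]
    if long_poor:
        start, run = long_poor[-1]
    else:
        # extend the last deep-defocus run that has room, so the guaranteed
        # unusable stretch exists even when all natural runs are short
        candidates = [s for s, _ in poor_runs if s <= n - 5]
        start, run = (candidates[-1], 5) if candidates else (None, 0)
    if start is not None and run >= 5:
        levels[start : start + run] = np.clip(
            rng.uniform(0.92, 0.98) + rng.normal(0.0, 0.01, size=run), 0.0, 1.0
        )
    return levels


def _paint_cells(
    img: np.ndarray,
    amplitude: float,
    config: SynthConfig,
    rng: np.random.Generator,
) -> None:
    h, w = img.shape
    n_cells = int(rng.integers(config.n_cells_range[0], config.n_cells_range[1] + 1))
    jit = config.cell_intensity_jitter
    for _ in range(n_cells):
        r = float(rng.uniform(config.cell_radius_range[0], config.cell_radius_range[1]))
        cy = rng.uniform(0, h - 1)
        cx = rng.uniform(0, w - 1)
        cell_amp = amplitude * rng.uniform(1.0 - jit, 1.0 + jit)
        y0, y1 = max(0, int(cy - r) - 1), min(h, int(cy + r) + 2)
        x0, x1 = max(0, int(cx - r) - 1), min(w, int(cx + r) + 2)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
        img[y0:y1, x0:x1][mask] += cell_amp


def generate_stack(config: SynthConfig) -> tuple[list[FrameImage], pd.DataFrame]:
    """Generate a stack and its ground truth.

    Returns the frames plus a DataFrame indexed by frame with columns
    ``blur_sigma``, ``true_quality`` and ``human_score``.
    """
    rng = np.random.default_rng(config.seed)
    levels = _blur_levels(config, rng)
    sigmas = levels * config.blur_sigma_max
    if config.blur_sigma_max > 0:
        quality = 5.0 * (1.0 - sigmas / config.blur_sigma_max)
    else:
        quality = np.full(config.n_frames, 5.0)
    human = np.clip(
        np.round(quality + rng.normal(0.0, config.score_noise_sd, size=config.n_frames)),
        0,
        5,
    ).astype(int)

    max_grey = (1 << config.bit_depth) - 1
    dtype = np.uint8 if config.bit_depth == 8 else np.uint16
    # unit coordinate field for the per-frame illumination gradient
    yy, xx = np.mgrid[0 : config.height, 0 : config.width].astype(float)
    half = max(config.height, config.width) / 2.0
    ux = (xx - (config.width - 1) / 2.0) / half
    uy = (yy - (config.height - 1) / 2.0) / half
    frames: list[FrameImage] = []
    for i in range(config.n_frames):
        bg = config.background_level * rng.uniform(
            1.0 - config.background_jitter, 1.0 + config.background_jitter
        )
        img = np.full((config.height, config.width), bg, dtype=float)
        illumination = rng.uniform(
            1.0 - config.illumination_jitter, 1.0 + config.illumination_jitter
        )
        amplitude = (
            config.cell_intensity
            * illumination
            * (1.0 - config.intensity_loss * levels[i])
        )
        _paint_cells(img, amplitude, config, rng)
        if config.gradient_max > 0:
            # uneven illumination drifting between frames: a zero-mean linear
            # gradient of random orientation and strength, multiplicative on
            # the whole field (independent of the defocus level)
            theta = rng.uniform(0.0, 2.0 * np.pi)
            g = rng.uniform(0.0, config.gradient_max)
            img *= 1.0 + g * (ux * np.cos(theta) + uy * np.sin(theta))
        if sigmas[i] > 0:
            img = gaussian_filter(img, sigma=float(sigmas[i]))
        img += rng.normal(0.0, config.noise_sd, size=img.shape)
        pixels = np.clip(np.round(img), 0, max_grey).astype(dtype)
        frames.append(FrameImage(pixels=pixels, bit_depth=config.bit_depth, frame_index=i))

    truth = pd.DataFrame(
        {
            "frame": np.arange(config.n_frames),
            "blur_sigma": sigmas,
            "true_quality": quality,
            "human_score": human,
        }
    ).set_index("frame")
    return frames, truth


def standard_benchmark(seed: int) -> tuple[list[FrameImage], pd.DataFrame]:
    """The fixed 200-frame benchmark stack (runs profile, 256 x 256, 16-bit).

    Only the seed varies; all other settings are the published defaults, so
    results quoted against the benchmark are comparable across runs.
    """
    return generate_stack(replace(SynthConfig(), n_frames=BENCHMARK_N_FRAMES, seed=int(seed)))
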