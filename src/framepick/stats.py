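"""Per-frame image statistics used as explanatory variables for quality scoring.

Eleven statistics are computed per greyscale frame, treating the pixel grey
values as a population: unique grey values, mean, maximum, population standard
deviation, population skewness (Fisher-Pearson), population excess kurtosis,
Shannon entropy of the grey-level histogram (bits), integrated density (sum of
grey values), sum of squares, and two custom sharpness/uniformity statistics:

* **Sum pixel ramp** — the sum of absolute intensity differences between pixels
  separated vertically by the pixel step ``p``.  Bright objects (cells) have a
  sharp intensity interface at their edge; defocus blur lowers the statistic.
* **Segment intensity deviation (SID)** — the population standard deviation of
  summed (or, when normalized, mean) sampled intensities across a rectangular
  grid of segments.  Zero means perfectly uniform intensity across the frame.

Both custom statistics subsample the frame on a lattice with stride ``p`` in
both dimensions (the first compared row is ``y = p`` so every comparison stays
inside the frame), and can be normalized by the number of sampled comparisons
(pixels) so values are comparable across pixel-step settings.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as sp_stats

from .errors import InvalidConfigurationError, InvalidInputError

__all__ = [
    "CANONICAL_VARIABLES",
    "FrameImage",
    "StatisticsConfig",
    "FrameStatistics",
    "compute_basic_statistics",
    "compute_sum_pixel_ramp",
    "compute_sid",
    "compute_frame_statistics",
    "statistics_to_dataframe",
]

#: Canonical ordering of the explanatory variables (the statistics CSV column
#: order); also the tie-breaking order used by stepwise elimination.
CANONICAL_VARIABLES = (
    "unique_greys",
    "mean",
    "max",
    "std",
    "skewness",
    "kurtosis",
    "entropy",
    "integrated_density",
    "sum_of_squares",
    "sum_pixel_ramp",
    "sid",
)


@dataclass(frozen=True)
class StatisticsConfig:
    """Settings controlling the two custom statistics.

    Parameters
    ----------
    pixel_step : int
        Combined sampling stride and comparison offset ``p`` (default 3).
    normalize : bool
        Divide sum pixel ramp by the number of sampled comparisons and SID
        segment sums by their sampled-pixel counts, making both statistics
        stable under pixel-step changes (default True).
    sid_grid_rows, sid_grid_cols : int
        Segment grid for SID (default 4 x 4).  Remainder rows/columns are
        absorbed into the last segment row/column.
    """

    pixel_step: int = 3
    normalize: bool = True
    sid_grid_rows: int = 4
    sid_grid_cols: int = 4

    def __post_init__(self) -> None:
        if self.pixel_step < 1:
            raise InvalidConfigurationError("pixel_step must be >= 1")
        if self.sid_grid_rows < 1 or self.sid_grid_cols < 1:
            raise InvalidConfigurationError("SID grid dimensions must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "StatisticsConfig":
        return cls(
            pixel_step=int(d["pixel_step"]),
            normalize=bool(d["normalize"]),
            sid_grid_rows=int(d["sid_grid_rows"]),
            sid_grid_cols=int(d["sid_grid_cols"]),
        )


@dataclass
class FrameImage:
    """One greyscale frame of an image stack.

    ``pixels`` is a 2-D integer array (row-major; ``x`` = column, ``y`` = row,
    0-based).  Grey values must lie in ``[0, 2**bit_depth - 1]``.
    """

    pixels: np.ndarray
    bit_depth: int = 16
    frame_index: int = 0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise InvalidInputError(
                f"frame {self.frame_index}: expected a non-empty 2-D greyscale array, "
                f"got shape {self.pixels.shape}"
            )
        if not np.issubdtype(self.pixels.dtype, np.integer):
            raise InvalidInputError(
                f"frame {self.frame_index}: pixel values must be integers, "
                f"got dtype {self.pixels.dtype}"
            )
        if self.bit_depth not in (8, 16):
            raise InvalidInputError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        lo = int(self.pixels.min())
        hi = int(self.pixels.max())
        if lo < 0 or hi > (1 << self.bit_depth) - 1:
            raise InvalidInputError(
                f"frame {self.frame_index}: grey values [{lo}, {hi}] outside "
                f"[0, {(1 << self.bit_depth) - 1}] for bit depth {self.bit_depth}"
            )

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class FrameStatistics:
    """The explanatory-variable vector for one frame.

    The two custom fields are ``None`` until computed with a
    :class:`StatisticsConfig` (see :func:`compute_frame_statistics`).
    """

    frame_index: int
    unique_greys: int
    mean_grey: float
    max_grey: float
    std_grey: float
    skewness: float
    kurtosis: float
    entropy: float
    integrated_density: float
    sum_of_squares: float
    sum_pixel_ramp: float | None = None
    sid: float | None = None

    def as_variables(self) -> dict[str, float]:
        """Statistics keyed by the canonical variable names."""
        d = {
            "unique_greys": float(self.unique_greys),
            "mean": self.mean_grey,
            "max": self.max_grey,
            "std": self.std_grey,
            "skewness": self.skewness,
            "kurtosis": self.kurtosis,
            "entropy": self.entropy,
            "integrated_density": self.integrated_density,
            "sum_of_squares": self.sum_of_squares,
        }
        if self.sum_pixel_ramp is not None:
            d["sum_pixel_ramp"] = self.sum_pixel_ramp
        if self.sid is not None:
            d["sid"] = self.sid
        return d


def compute_basic_statistics(frame: FrameImage) -> FrameStatistics:
    """Compute the nine standard population statistics of a frame.

    Moments are population moments (not sample-corrected); skewness is the
    Fisher-Pearson coefficient ``m3 / m2**1.5`` and kurtosis is excess kurtosis
    ``m4 / m2**2 - 3``.  A constant frame has skewness and kurtosis 0 by the
    zero-variance convention, so degenerate frames remain scoreable.  Entropy is
    the Shannon entropy (bits) of the exact integer grey-level histogram.
    """
    values = frame.pixels.ravel()
    if values.size == 0:  # pragma: no cover - guarded by FrameImage
        raise InvalidInputError("empty frame")
    fvals = values.astype(np.float64)
    mean = float(fvals.mean())
    dev = fvals - mean
    m2 = float(np.mean(dev**2))
    if m2 == 0.0:
        skew = 0.0
        kurt = 0.0
    else:
        skew = float(np.mean(dev**3)) / m2**1.5
        kurt = float(np.mean(dev**4)) / m2**2 - 3.0
    counts = np.bincount(values)
    counts = counts[counts > 0]
    entropy = float(sp_stats.entropy(counts, base=2))
    return FrameStatistics(
        frame_index=frame.frame_index,
        unique_greys=int(counts.size),
        mean_grey=mean,
        max_grey=float(values.max()),
        std_grey=float(np.sqrt(m2)),
        skewness=skew,
        kurtosis=kurt,
        entropy=entropy,
        integrated_density=float(fvals.sum()),
        sum_of_squares=float(np.sum(fvals**2)),
    )


def _sample_lattice(frame: FrameImage, p: int) -> tuple[np.ndarray, np.ndarray]:
    """Sampled coordinates for the custom statistics.

    Columns start at x = 0; rows start at y = p so the comparison partner
    (x, y - p) always stays inside the frame.  Stride equals the comparison
    offset p in both dimensions.
    """
    if p >= frame.height:
        raise InvalidConfigurationError(
            f"pixel_step {p} >= frame height {frame.height}: no rows can be sampled"
        )
    ys = np.arange(p, frame.height, p)
    xs = np.arange(0, frame.width, p)
    return ys, xs


def compute_sum_pixel_ramp(frame: FrameImage, config: StatisticsConfig) -> float:
    """Sum of |I(x, y) - I(x, y - p)| over the sampled lattice.

    With ``config.normalize`` the sum is divided by the number of sampled
    comparisons, which removes the dependence on the pixel step.
    """
    p = config.pixel_step
    ys, xs = _sample_lattice(frame, p)
    a = frame.pixels.astype(np.int64)
    diffs = np.abs(a[np.ix_(ys, xs)] - a[np.ix_(ys - p, xs)])
    total = float(diffs.sum())
    if config.normalize:
        total /= diffs.size
    return total


def compute_sid(frame: FrameImage, config: StatisticsConfig) -> float:
    """Segment intensity deviation of a frame.

    The frame is split into ``sid_grid_rows x sid_grid_cols`` rectangular
    segments (remainder pixels join the last row/column of segments); per
    segment, the sampled pixel intensities are summed (sampling lattice shared
    with :func:`compute_sum_pixel_ramp`); the result is the population standard
    deviation of the segment sums.  In normalized mode each segment sum is first
    divided by the segment's sampled-pixel count, neutralising unequal segment
    sizes; a perfectly uniform frame then yields exactly 0 for any grid.
    """
    rows, cols = config.sid_grid_rows, config.sid_grid_cols
    p = config.pixel_step
    ys, xs = _sample_lattice(frame, p)
    if ys.size * xs.size < rows * cols:
        raise InvalidConfigurationError(
            f"SID grid {rows}x{cols} has more segments than the "
            f"{ys.size * xs.size} sampled pixels"
        )
    if frame.height < rows or frame.width < cols:
        raise InvalidConfigurationError(
            f"frame {frame.width}x{frame.height} smaller than SID grid {rows}x{cols}"
        )
    seg_h = frame.height // rows
    seg_w = frame.width // cols
    row_seg = np.minimum(ys // seg_h, rows - 1)
    col_seg = np.minimum(xs // seg_w, cols - 1)
    seg_idx = (row_seg[:, None] * cols + col_seg[None, :]).ravel()
    sampled = frame.pixels[np.ix_(ys, xs)].astype(np.float64).ravel()
    sums = np.bincount(seg_idx, weights=sampled, minlength=rows * cols)
    counts = np.bincount(seg_idx, minlength=rows * cols)
    if (counts == 0).any():
        empty = int(np.flatnonzero(counts == 0)[0])
        raise InvalidConfigurationError(
            f"SID segment {empty} contains no sampled pixels "
            f"(grid {rows}x{cols}, pixel_step {p}, frame {frame.width}x{frame.height})"
        )
    if config.normalize:
        sums = sums / counts
    return float(np.std(sums))


def compute_frame_statistics(
    stack: Sequence[FrameImage] | Iterable[FrameImage],
    config: StatisticsConfig | None = None,
) -> list[FrameStatistics]:
    """Compute the full 11-statistic vector for every frame of a stack.

    Frames must share dimensions and bit depth.  Each frame is processed
    independently, so the result order mirrors the stack order.
    """
    config = config or StatisticsConfig()
    frames = list(stack)
    if not frames:
        raise InvalidInputError("empty stack")
    ref = frames[0]
    out: list[FrameStatistics] = []
    for i, frame in enumerate(frames):
        if frame.pixels.shape != ref.pixels.shape or frame.bit_depth != ref.bit_depth:
            raise InvalidInputError(
                f"frame at position {i} (index {frame.frame_index}) has shape "
                f"{frame.pixels.shape}/{frame.bit_depth}-bit; expected "
                f"{ref.pixels.shape}/{ref.bit_depth}-bit"
            )
        s = compute_basic_statistics(frame)
        s.sum_pixel_ramp = compute_sum_pixel_ramp(frame, config)
        s.sid = compute_sid(frame, config)
        out.append(s)
    return out


def statistics_to_dataframe(stats: Sequence[FrameStatistics]):
    """Tabulate statistics as a DataFrame indexed by frame with canonical columns."""
    import pandas as pd

    rows = []
    for s in stats:
        row = {"frame": s.frame_index}
        row.update({k: s.as_variables().get(k, np.nan) for k in CANONICAL_VARIABLES})
        rows.append(row)
    return pd.DataFrame(rows).set_index("frame")
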