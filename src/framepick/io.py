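"""Readers and writers for stacks, statistics tables, scores and truth tables.

Stacks are read from a multi-page TIFF or from a directory of single-frame
TIFF/PNG files (sorted lexicographically by filename — zero-pad numeric names
if numeric order matters).  Only 8- and 16-bit greyscale frames are accepted;
RGB or floating-point images are rejected with a conversion hint.  Frame
indices are 0-based everywhere: in memory, in CSV files, and in messages.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InvalidInputError, ScoreParseError, UnsupportedFormatError
from .model import ScoreSet
from .stats import CANONICAL_VARIABLES, FrameImage, FrameStatistics, StatisticsConfig

__all__ = [
    "read_stack",
    "write_stack",
    "write_statistics",
    "read_statistics",
    "write_scores",
    "read_scores",
    "read_manual_scores",
    "write_config_sidecar",
    "read_config_sidecar",
]

_FRAME_SUFFIXES = {".tif", ".tiff", ".png"}

#: statistics CSV header (fixed column order across versions)
_STATS_COLUMNS = ["frame"] + list(CANONICAL_VARIABLES)
_STATS_HEADER = (
    "frame,unique_greys,mean,max,std,skewness,kurtosis,entropy,"
    "integrated_density,sum_of_squares,sum_pixel_ramp,sid"
)


def _frame_from_array(arr: np.ndarray, index: int, origin: str) -> FrameImage:
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[2] in (3, 4):
        raise UnsupportedFormatError(
            f"{origin}: RGB(A) images are not supported; convert to single-channel "
            f"greyscale first (e.g. extract one channel or convert to luminance)"
        )
    if arr.ndim != 2:
        raise UnsupportedFormatError(f"{origin}: expected a 2-D greyscale frame, got shape {arr.shape}")
    if arr.dtype == np.uint8:
        depth = 8
    elif arr.dtype == np.uint16:
        depth = 16
    else:
        raise UnsupportedFormatError(
            f"{origin}: dtype {arr.dtype} unsupported; convert to 8- or 16-bit "
            f"unsigned integer greyscale"
        )
    return FrameImage(pixels=arr, bit_depth=depth, frame_index=index)


def read_stack(path) -> list[FrameImage]:
    """Read an image stack from a multi-page TIFF or a directory of frames.

    Directory frames are ordered lexicographically by filename.  Returns a
    non-empty list of :class:`FrameImage` with 0-based ``frame_index``.
    """
    import imageio.v3 as iio
    import tifffile

    path = Path(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.suffix.lower() in _FRAME_SUFFIXES)
        if not files:
            raise InvalidInputError(f"{path}: no TIFF/PNG frames found")
        frames = []
        for i, f in enumerate(files):
            if f.suffix.lower() in (".tif", ".tiff"):
                arr = tifffile.imread(f)
            else:
                arr = iio.imread(f)
            frames.append(_frame_from_array(arr, i, str(f)))
    else:
        if not path.exists():
            raise InvalidInputError(f"{path}: no such file")
        if path.suffix.lower() in (".tif", ".tiff"):
            arr = tifffile.imread(path)
        else:
            # PNG and friends are single-frame formats; never a page stack
            return [_frame_from_array(iio.imread(path), 0, str(path))]
        if arr.ndim == 2:
            arr = arr[None, ...]
        if arr.ndim == 3 and arr.shape[-1] in (3, 4) and arr.shape[0] not in (3, 4):
            raise UnsupportedFormatError(
                f"{path}: RGB(A) images are not supported; convert to single-channel "
                f"greyscale first"
            )
        if arr.ndim != 3:
            raise UnsupportedFormatError(
                f"{path}: expected a (pages, height, width) greyscale stack, got shape {arr.shape}"
            )
        frames = [_frame_from_array(page, i, f"{path}[page {i}]") for i, page in enumerate(arr)]
    shapes = {f.pixels.shape for f in frames}
    if len(shapes) > 1:
        raise InvalidInputError(f"{path}: frames have mixed dimensions {sorted(shapes)}")
    return frames


def write_stack(frames: Sequence[FrameImage], path) -> None:
    """Write frames as a multi-page TIFF (page order = stack order)."""
    import tifffile

    data = np.stack([f.pixels for f in frames])
    tifffile.imwrite(path, data, photometric="minisblack")


def write_statistics(stats: Sequence[FrameStatistics], path) -> None:
    """Write per-frame statistics as CSV with the fixed canonical header."""
    rows = []
    for s in stats:
        v = s.as_variables()
        rows.append([s.frame_index] + [v.get(name, "") for name in CANONICAL_VARIABLES])
    df = pd.DataFrame(rows, columns=_STATS_COLUMNS)
    df.to_csv(path, index=False, float_format="%.10g")


def read_statistics(path) -> list[FrameStatistics]:
    """Read a statistics CSV back into :class:`FrameStatistics` records."""
    df = _read_csv(path, required=_STATS_COLUMNS)
    out = []
    for _, row in df.iterrows():
        out.append(
            FrameStatistics(
                frame_index=int(row["frame"]),
                unique_greys=int(row["unique_greys"]),
                mean_grey=float(row["mean"]),
                max_grey=float(row["max"]),
                std_grey=float(row["std"]),
                skewness=float(row["skewness"]),
                kurtosis=float(row["kurtosis"]),
                entropy=float(row["entropy"]),
                integrated_density=float(row["integrated_density"]),
                sum_of_squares=float(row["sum_of_squares"]),
                sum_pixel_ramp=float(row["sum_pixel_ramp"]),
                sid=float(row["sid"]),
            )
        )
    return out


def _read_csv(path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ScoreParseError(f"{path}: cannot parse CSV ({exc})") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ScoreParseError(
            f"{path}, line 1: header is missing column(s) {', '.join(missing)}"
        )
    bad = df[df[list(required)].isna().any(axis=1)]
    if len(bad):
        # +2: 1 for the header line, 1 for 1-based line numbers
        raise ScoreParseError(f"{path}, line {int(bad.index[0]) + 2}: malformed row")
    return df


def write_scores(scores: ScoreSet, path) -> None:
    """Write calculated scores as ``frame,score`` CSV (10 significant digits)."""
    df = pd.DataFrame({"frame": scores.frame_indices, "score": scores.scores})
    df.to_csv(path, index=False, float_format="%.10g")


def read_scores(path) -> ScoreSet:
    """Read a ``frame,score`` CSV back into a :class:`ScoreSet`.

    Provenance fields (model, range-adjustment flag) are not stored in the CSV
    and come back unset.
    """
    df = _read_csv(path, required=["frame", "score"])
    return ScoreSet(
        frame_indices=tuple(int(i) for i in df["frame"]),
        scores=df["score"].to_numpy(float),
    )


def read_manual_scores(path) -> dict[int, float]:
    """Read manual human scores (``frame,score`` CSV) as a frame -> score map."""
    df = _read_csv(path, required=["frame", "score"])
    return {int(r["frame"]): float(r["score"]) for _, r in df.iterrows()}


def write_config_sidecar(config: StatisticsConfig, stats_path) -> Path:
    """Record the statistics configuration next to a statistics CSV."""
    side = Path(stats_path).with_suffix(".config.json")
    side.write_text(json.dumps(config.to_dict(), indent=2))
    return side


def read_config_sidecar(stats_path) -> StatisticsConfig | None:
    """Load the sidecar configuration for a statistics CSV, if present."""
    side = Path(stats_path).with_suffix(".config.json")
    if not side.exists():
        return None
    return StatisticsConfig.from_dict(json.loads(side.read_text()))
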