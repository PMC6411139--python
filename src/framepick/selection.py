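"""Frame rejection and selection from a scored stack.

Two modes mirror the two ways a scored stack is reduced:

* **QA (quality alone)** — keep every frame whose calculated score reaches a
  cutoff.  Simple, but a long run of poor frames leaves a large temporal gap.
* **FW (frame windowing)** — partition the stack into consecutive windows of
  length ``n`` and keep the single best-scoring frame of each window.  Exactly
  one frame survives per window, so consecutive retained frames are never more
  than ``2n - 1`` apart and the macro-chronology of the capture is preserved.

:func:`minimum_window_size` scans window sizes 1, 2, ... up to 25% of the
stack length for the smallest ``n`` at which every window contains at least
one frame meeting a quality target.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import InvalidConfigurationError, InvalidInputError
from .model import ScoreSet
from .stats import FrameImage

__all__ = [
    "SelectionResult",
    "filter_by_cutoff",
    "frame_window_select",
    "minimum_window_size",
    "export_selection",
]


@dataclass
class SelectionResult:
    """Retained frame indices (strictly increasing, stack order) plus provenance."""

    retained_indices: tuple[int, ...]
    mode: str  # "QA" or "FW"
    parameter: float | int  # cutoff value (QA) or window size (FW)
    scores: ScoreSet
    window_ids: tuple[int, ...] | None = None  # FW only, parallel to retained_indices


def filter_by_cutoff(scores: ScoreSet, cutoff: float) -> SelectionResult:
    """Quality-alone selection: retain frames with score >= cutoff.

    The comparison is inclusive — frames *below* the cutoff are removed — and
    an empty selection is legal.
    """
    if len(scores) == 0:
        raise InvalidInputError("empty score set")
    keep = tuple(
        idx for idx, s in zip(scores.frame_indices, scores.scores) if s >= cutoff
    )
    return SelectionResult(retained_indices=keep, mode="QA", parameter=float(cutoff), scores=scores)


def frame_window_select(scores: ScoreSet, window: int) -> SelectionResult:
    """Frame-windowing selection: best frame per consecutive window of ``window``.

    The last window may be shorter and is still represented by its best frame.
    Ties go to the earliest frame in the window, minimising chronological
    distortion.
    """
    if window < 1:
        raise InvalidConfigurationError(f"window size must be >= 1, got {window}")
    if len(scores) == 0:
        raise InvalidInputError("empty score set")
    vals = scores.scores
    keep: list[int] = []
    wids: list[int] = []
    for w, start in enumerate(range(0, len(vals), window)):
        chunk = vals[start : start + window]
        best = start + int(np.argmax(chunk))  # argmax takes the first maximum
        keep.append(scores.frame_indices[best])
        wids.append(w)
    return SelectionResult(
        retained_indices=tuple(keep),
        mode="FW",
        parameter=int(window),
        scores=scores,
        window_ids=tuple(wids),
    )


def minimum_window_size(scores: ScoreSet, target: float) -> int | None:
    """Smallest window size at which every window holds a frame meeting ``target``.

    Window sizes are scanned in increments of 1 up to 25% of the stack length
    (``floor(0.25 * N)``, minimum 1).  Returns ``None`` when no size in range
    works — a value, not an error, since the caller may relax the target.
    """
    if len(scores) == 0:
        raise InvalidInputError("empty score set")
    ok = scores.scores >= target
    n_frames = len(ok)
    n_max = max(1, int(0.25 * n_frames))
    for n in range(1, n_max + 1):
        if all(ok[start : start + n].any() for start in range(0, n_frames, n)):
            return n
    return None


def export_selection(
    stack: Sequence[FrameImage],
    result: SelectionResult,
    out_dir,
) -> Path:
    """Write retained frames as numbered TIFFs plus a CSV manifest.

    The manifest records, per retained frame, the output filename, the original
    0-based frame index, its calculated score, and (FW mode) the window id.
    Returns the manifest path.  An empty selection writes a manifest only.
    """
    import tifffile

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    by_index = {f.frame_index: f for f in stack}
    bad = [i for i in result.retained_indices if i not in by_index]
    if bad:
        raise InvalidInputError(f"selection refers to frames not in the stack: {bad}")
    score_map = result.scores.as_dict()
    manifest = out_dir / "manifest.csv"
    if not result.retained_indices:
        warnings.warn("selection is empty; writing manifest only", stacklevel=2)
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["file", "original_index", "score", "window_id"])
        for pos, idx in enumerate(result.retained_indices):
            name = f"frame_{pos:05d}.tif"
            tifffile.imwrite(out_dir / name, by_index[idx].pixels)
            wid = result.window_ids[pos] if result.window_ids is not None else ""
            writer.writerow([name, idx, f"{score_map[idx]:.10g}", wid])
    return manifest
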