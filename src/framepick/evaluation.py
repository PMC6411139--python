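"""Agreement between calculated and manual quality scores.

The primary agreement measure is the Pearson product-moment correlation between
calculated scores and the human scores, reported both including and — the
headline figure — excluding the frames whose scores were used to train the
model.  The mean absolute score distance ``mean |S_provided - S_calculated|``
complements the correlation with an absolute-scale error, and correlations are
verbally labelled with the conventional strength bands for |r|
(0.00-0.19 very weak, 0.20-0.39 weak, 0.40-0.59 moderate, 0.60-0.79 strong,
0.80-1.0 very strong).

:func:`training_curve` replays the core benchmarking protocol: fit a stepwise
model on the first *n* scored frames for a grid of *n*, score the whole stack,
and tabulate the held-out agreement as a function of training-set size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidInputError, StepwiseEliminationError, UndefinedCorrelationError
from .model import FrameQualityModel, ScoredSample
from .stats import FrameStatistics, StatisticsConfig

__all__ = [
    "AgreementReport",
    "pearson_correlation",
    "mean_score_distance",
    "strength_label",
    "evaluate_agreement",
    "training_curve",
]

_BANDS = (
    (0.20, "very weak"),
    (0.40, "weak"),
    (0.60, "moderate"),
    (0.80, "strong"),
    (1.01, "very strong"),
)


@dataclass
class AgreementReport:
    """Agreement summary between calculated and manual scores for one run."""

    pearson_r: float
    pearson_r_excluding_training: float | None
    mean_distance: float
    n_compared: int
    strength_label: str


def pearson_correlation(a: Sequence[float], b: Sequence[float]) -> float:
    """Pearson product-moment correlation coefficient of two equal-length series."""
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidInputError("sequences must be 1-D and of equal length")
    if x.size < 3:
        raise InvalidInputError("need at least 3 paired values for a correlation")
    if x.std() == 0.0 or y.std() == 0.0:
        raise UndefinedCorrelationError("correlation undefined for zero-variance input")
    return float(np.corrcoef(x, y)[0, 1])


def mean_score_distance(
    provided: Mapping[int, float], calculated: Mapping[int, float]
) -> float:
    """Mean absolute distance |S_provided - S_calculated| over shared frames."""
    shared = sorted(set(provided) & set(calculated))
    if not shared:
        raise InvalidInputError("no shared frames between provided and calculated scores")
    return float(np.mean([abs(provided[i] - calculated[i]) for i in shared]))


def strength_label(r: float) -> str:
    """Verbal strength of a correlation from |r|, on the conventional 2-decimal bands."""
    if not math.isfinite(r) or abs(r) > 1.0 + 1e-12:
        raise InvalidInputError(f"|r| must be <= 1, got {r}")
    # The bands are printed to 2 decimals; round half away from zero first so
    # e.g. 0.195 -> 0.20 ("weak") while 0.19 stays "very weak".
    q = math.floor(abs(r) * 100 + 0.5 + 1e-9) / 100
    for upper, label in _BANDS:
        if q < upper:
            return label
    raise AssertionError("unreachable")  # pragma: no cover


def evaluate_agreement(
    provided: Mapping[int, float],
    calculated: Mapping[int, float],
    training_frames: Sequence[int] = (),
) -> AgreementReport:
    """Full agreement report; the strength label describes the held-out correlation.

    ``training_frames`` are excluded from the primary (held-out) correlation.
    When every shared frame was used for training, the held-out correlation is
    undefined and reported as ``None``; the including-training value is then
    labelled instead.
    """
    shared = sorted(set(provided) & set(calculated))
    if not shared:
        raise InvalidInputError("no shared frames to compare")
    train = set(training_frames)
    p_all = [provided[i] for i in shared]
    c_all = [calculated[i] for i in shared]
    r_all = pearson_correlation(p_all, c_all)
    held_out = [i for i in shared if i not in train]
    if len(held_out) >= 3:
        r_excl = pearson_correlation(
            [provided[i] for i in held_out], [calculated[i] for i in held_out]
        )
    elif train:
        raise InvalidInputError(
            f"only {len(held_out)} frames remain after excluding training frames; "
            f"cannot compute a held-out correlation"
        )
    else:
        r_excl = None
    primary = r_excl if r_excl is not None else r_all
    return AgreementReport(
        pearson_r=r_all,
        pearson_r_excluding_training=r_excl,
        mean_distance=mean_score_distance(provided, calculated),
        n_compared=len(shared),
        strength_label=strength_label(primary),
    )


def training_curve(
    samples: Sequence[ScoredSample],
    stats: Sequence[FrameStatistics],
    grid: Sequence[int],
    statistics_config: StatisticsConfig | None = None,
) -> pd.DataFrame:
    """Held-out agreement as a function of training-set size.

    For each ``n`` in ``grid``: fit a stepwise model on the first ``n`` scored
    samples, score every frame in ``stats``, and report the Pearson correlation
    against the manual scores excluding the ``n`` training frames, plus the
    mean absolute distance over all scored frames.  A stepwise failure (or a
    degenerate zero-variance correlation) at some ``n`` is recorded in the
    table (``error`` column) rather than raised.
    """
    if not samples:
        raise InvalidInputError("no scored samples")
    provided = {s.statistics.frame_index: float(s.manual_score) for s in samples}
    rows = []
    for n in grid:
        n = int(n)
        if n < 1 or n > len(samples):
            raise InvalidInputError(
                f"training size {n} infeasible for {len(samples)} scored frames"
            )
        row: dict = {"n_training": n}
        try:
            results = FrameQualityModel.from_samples(
                samples[:n], statistics_config=statistics_config
            ).fit_stepwise()
            scoreset = results.calculate_scores(stats)
            calculated = scoreset.as_dict()
            train_ids = [s.statistics.frame_index for s in samples[:n]]
            report = evaluate_agreement(provided, calculated, training_frames=train_ids)
            row.update(
                pearson_r=report.pearson_r,
                pearson_r_excluding_training=report.pearson_r_excluding_training,
                mean_distance=report.mean_distance,
                n_compared=report.n_compared,
                strength_label=report.strength_label,
                error="",
            )
        except (StepwiseEliminationError, UndefinedCorrelationError) as exc:
            row.update(
                pearson_r=np.nan,
                pearson_r_excluding_training=np.nan,
                mean_distance=np.nan,
                n_compared=0,
                strength_label="",
                error=str(exc),
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("n_training")
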