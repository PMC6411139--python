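"""Quality scoring by multiple linear regression.

A small sample of frames is scored manually on a 0-5 scale; ordinary least
squares links the per-frame image statistics (explanatory variables) to those
scores (dependent variable).  The fitted coefficients then predict a quality
score for every frame of the stack:

    y_i = b0 + b1 * X_i1 + ... + bn * X_in

:class:`FrameQualityModel` holds the training data; ``fit()`` performs a plain
OLS fit while ``fit_stepwise()`` additionally removes uninformative variables
by backward elimination (drop the highest p-value above 0.05; stop — restoring
the last variable — as soon as a removal lowers the adjusted R^2, or when every
remaining p-value is significant).  Both return a :class:`FrameQualityResults`
carrying the coefficients on the original variable scale, per-coefficient
two-sided t-test p-values, the adjusted R^2, and the statistics configuration
used at training; results can be saved to / loaded from a JSON coefficient
file and applied to new stacks.

Calculated scores are deliberately not clamped to [0, 5]; cross-set
coefficient transfer often range-shifts them, and :func:`range_adjust` maps a
score set affinely onto [0, 5] when comparability is needed.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import (
    AliasedVariableWarning,
    ConfigMismatchWarning,
    DegenerateRangeWarning,
    InvalidInputError,
    ModelFileError,
    StepwiseEliminationError,
)
from .stats import CANONICAL_VARIABLES, FrameStatistics, StatisticsConfig

__all__ = [
    "ScoredSample",
    "ScoreSet",
    "FrameQualityModel",
    "FrameQualityResults",
    "fit_mlr",
    "stepwise_backward_eliminate",
    "calculate_scores",
    "range_adjust",
    "consolidate",
    "save_model",
    "load_model",
]

MODEL_FILE_VERSION = 1
P_REMOVE = 0.05  # backward-elimination significance threshold


@dataclass
class ScoredSample:
    """Image statistics of one frame together with its manual human score."""

    statistics: FrameStatistics
    manual_score: float
    set_label: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= float(self.manual_score) <= 5.0:
            raise InvalidInputError(
                f"manual score {self.manual_score} outside the 0-5 scale "
                f"(frame {self.statistics.frame_index})"
            )


@dataclass
class ScoreSet:
    """Calculated scores for a stack, keyed by frame index (order = stack order)."""

    frame_indices: tuple[int, ...]
    scores: np.ndarray
    range_adjusted: bool = False
    model: "FrameQualityResults | None" = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.frame_indices) != len(self.scores):
            raise InvalidInputError("frame_indices and scores length mismatch")

    def __len__(self) -> int:
        return len(self.scores)

    def as_dict(self) -> dict[int, float]:
        return {int(i): float(s) for i, s in zip(self.frame_indices, self.scores)}


def _samples_to_xy(
    samples: Sequence[ScoredSample], variables: Sequence[str]
) -> tuple[pd.DataFrame, np.ndarray]:
    rows = [s.statistics.as_variables() for s in samples]
    X = pd.DataFrame(rows)
    missing = [v for v in variables if v not in X.columns or X[v].isna().any()]
    if missing:
        raise InvalidInputError(f"samples lack variables: {', '.join(missing)}")
    y = np.array([float(s.manual_score) for s in samples])
    return X[list(variables)], y


def _canonical_order(variables: Iterable[str]) -> list[str]:
    known = [v for v in CANONICAL_VARIABLES if v in set(variables)]
    extra = [v for v in variables if v not in CANONICAL_VARIABLES]
    return known + sorted(extra)


class FrameQualityModel:
    """Linear quality model linking image statistics to manual 0-5 scores.

    Parameters
    ----------
    scores : array-like
        Manual quality scores (the dependent variable), one per row of ``exog``.
    exog : pandas.DataFrame
        Explanatory image statistics, columns named by the canonical variable
        names (see :data:`framepick.stats.CANONICAL_VARIABLES`).
    variables : sequence of str, optional
        Subset of columns to use; defaults to every canonical column present.
    statistics_config : StatisticsConfig, optional
        Configuration the statistics were computed with; persisted with the
        fitted model so scoring can warn on mismatched conventions.
    """

    def __init__(
        self,
        scores,
        exog: pd.DataFrame,
        variables: Sequence[str] | None = None,
        statistics_config: StatisticsConfig | None = None,
    ) -> None:
        self.endog = np.asarray(scores, dtype=float)
        self.exog = exog.reset_index(drop=True)
        if variables is None:
            variables = [c for c in CANONICAL_VARIABLES if c in exog.columns]
        self.variables = _canonical_order(variables)
        if not self.variables:
            raise InvalidInputError("no explanatory variables supplied")
        unknown = [v for v in self.variables if v not in exog.columns]
        if unknown:
            raise InvalidInputError(f"variables not in data: {', '.join(unknown)}")
        if len(self.endog) != len(self.exog):
            raise InvalidInputError("scores and statistics row counts differ")
        self.statistics_config = statistics_config
        self.nobs = len(self.endog)

    # -- constructors -----------------------------------------------------

    @classmethod
    def from_samples(
        cls,
        samples: Sequence[ScoredSample],
        variables: Sequence[str] | None = None,
        statistics_config: StatisticsConfig | None = None,
    ) -> "FrameQualityModel":
        if not samples:
            raise InvalidInputError("no scored samples supplied")
        want = list(variables) if variables else list(CANONICAL_VARIABLES)
        if variables is None:
            # drop custom stats that were never computed
            have = samples[0].statistics.as_variables()
            want = [v for v in want if v in have]
        X, y = _samples_to_xy(samples, want)
        return cls(y, X, variables=want, statistics_config=statistics_config)

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        score_col: str = "score",
        variables: Sequence[str] | None = None,
        statistics_config: StatisticsConfig | None = None,
    ) -> "FrameQualityModel":
        if score_col not in data.columns:
            raise InvalidInputError(f"column {score_col!r} not found")
        if variables is None:
            variables = [c for c in CANONICAL_VARIABLES if c in data.columns]
        return cls(
            data[score_col].to_numpy(float),
            data,
            variables=variables,
            statistics_config=statistics_config,
        )

    # -- fitting ----------------------------------------------------------

    def _validate_size(self, k: int) -> None:
        if self.nobs <= k + 1:
            raise InvalidInputError(
                f"{self.nobs} samples cannot identify {k} coefficients plus an "
                f"intercept; need more than {k + 1} scored frames"
            )

    #: columns whose relative residual after projection on the already-kept
    #: columns falls below this are treated as aliased; loose enough to catch
    #: exact collinearity perturbed by CSV rounding (~1e-10), far below any
    #: genuine statistical correlation.
    _ALIAS_RTOL = 1e-8

    def _drop_aliased(self, variables: Sequence[str]) -> list[str]:
        """Greedily keep, in canonical order, a maximal independent column set."""
        X = self.exog[list(variables)].to_numpy(float)
        sd = X.std(axis=0)
        mu = X.mean(axis=0)
        kept: list[str] = []
        cols: list[np.ndarray] = []
        dropped: list[str] = []
        for j, name in enumerate(variables):
            # near-zero spread (relative to magnitude) means the column is a
            # float-rounded constant; standardizing it would amplify rounding
            # noise into a spurious variable
            if sd[j] <= 1e-12 * max(abs(mu[j]), 1.0):
                dropped.append(name)
                continue
            c = (X[:, j] - mu[j]) / sd[j]
            if cols:
                A = np.column_stack(cols)
                coef, *_ = np.linalg.lstsq(A, c, rcond=None)
                resid = c - A @ coef
                independent = np.linalg.norm(resid) > self._ALIAS_RTOL * np.linalg.norm(c)
            else:
                independent = True
            if independent:
                kept.append(name)
                cols.append(c)
            else:
                dropped.append(name)
        if dropped:
            warnings.warn(
                "dropping linearly dependent variable(s): " + ", ".join(dropped),
                AliasedVariableWarning,
                stacklevel=3,
            )
        if not kept:
            raise InvalidInputError("all explanatory variables are constant")
        return kept

    def _fit_subset(self, variables: Sequence[str]) -> "FrameQualityResults":
        X = self.exog[list(variables)].to_numpy(float)
        y = self.endog
        n, k = X.shape
        if y.std() == 0.0:
            # Degenerate but legal: constant scores fit exactly with zero slopes.
            return FrameQualityResults(
                intercept=float(y[0]),
                coefficients={v: 0.0 for v in variables},
                p_values={v: 1.0 for v in variables},
                adjusted_r2=0.0,
                statistics_config=self.statistics_config,
                n_training=n,
                model=self,
            )
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        Xs = (X - mu) / sd
        res = sm.OLS(y, sm.add_constant(Xs, has_constant="add")).fit()
        slopes_std = res.params[1:]
        slopes = slopes_std / sd
        intercept = float(res.params[0] - np.sum(slopes_std * mu / sd))
        pvals = res.pvalues[1:]
        return FrameQualityResults(
            intercept=intercept,
            coefficients={v: float(b) for v, b in zip(variables, slopes)},
            p_values={v: float(p) for v, p in zip(variables, pvals)},
            adjusted_r2=float(res.rsquared_adj),
            statistics_config=self.statistics_config,
            n_training=n,
            model=self,
        )

    def fit(self, variables: Sequence[str] | None = None) -> "FrameQualityResults":
        """Ordinary least squares on the requested (default: all) variables.

        Linearly dependent variables are dropped with a warning naming them
        (integrated density, for instance, is an exact multiple of the mean on
        fixed-size frames).
        """
        variables = _canonical_order(variables or self.variables)
        usable = self._drop_aliased(variables)
        self._validate_size(len(usable))
        return self._fit_subset(usable)

    def fit_stepwise(self, variables: Sequence[str] | None = None) -> "FrameQualityResults":
        """Backward elimination on p-values guarded by the adjusted R^2.

        Each round removes the variable with the highest p-value above 0.05
        (ties broken toward the variable later in the canonical order).  If the
        refit's adjusted R^2 is lower than before the removal, the variable is
        restored and the procedure stops; it also stops when no p-value exceeds
        0.05.  Removing the last remaining variable is a failure requiring user
        intervention, raised as :class:`StepwiseEliminationError`.
        """
        variables = _canonical_order(variables or self.variables)
        current = self._drop_aliased(variables)
        self._validate_size(len(current))
        results = self._fit_subset(current)
        while True:
            worst = None
            worst_p = P_REMOVE
            for name in current:  # canonical order; later ties win via >=
                if results.p_values[name] >= worst_p and results.p_values[name] > P_REMOVE:
                    worst, worst_p = name, results.p_values[name]
            if worst is None:
                return results
            if len(current) == 1:
                raise StepwiseEliminationError(
                    f"stepwise elimination would remove the last variable "
                    f"({worst}, p = {worst_p:.3g}); no variables are left and "
                    f"user intervention is required"
                )
            trial_vars = [v for v in current if v != worst]
            trial = self._fit_subset(trial_vars)
            if trial.adjusted_r2 < results.adjusted_r2:
                # Adjusted R^2 fell: restore the variable and stop.
                return results
            current, results = trial_vars, trial


@dataclass
class FrameQualityResults:
    """Fitted quality model: the persistable coefficients plus diagnostics."""

    intercept: float
    coefficients: dict[str, float]
    p_values: dict[str, float]
    adjusted_r2: float
    statistics_config: StatisticsConfig | None
    n_training: int
    model: FrameQualityModel | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.coefficients:
            raise InvalidInputError("a fitted model must retain at least one variable")
        if set(self.coefficients) != set(self.p_values):
            raise InvalidInputError("coefficients and p_values key sets differ")

    @property
    def variables(self) -> list[str]:
        return _canonical_order(self.coefficients)

    # -- prediction -------------------------------------------------------

    def predict(self, exog: pd.DataFrame | Mapping[str, float]) -> np.ndarray:
        if isinstance(exog, Mapping):
            exog = pd.DataFrame([exog])
        missing = [v for v in self.variables if v not in exog.columns]
        if missing:
            raise InvalidInputError(f"statistics lack model variables: {', '.join(missing)}")
        out = np.full(len(exog), self.intercept, dtype=float)
        for v in self.variables:
            out += self.coefficients[v] * exog[v].to_numpy(float)
        return out

    def calculate_scores(
        self,
        stats: Sequence[FrameStatistics] | pd.DataFrame,
        statistics_config: StatisticsConfig | None = None,
    ) -> ScoreSet:
        """Apply the score equation to every frame; values are not clamped to 0-5."""
        if isinstance(stats, pd.DataFrame):
            frames = tuple(int(i) for i in stats.index)
            exog = stats
        else:
            frames = tuple(int(s.frame_index) for s in stats)
            exog = pd.DataFrame([s.as_variables() for s in stats])
        cfg = statistics_config
        if cfg is not None and self.statistics_config is not None and cfg != self.statistics_config:
            warnings.warn(
                f"statistics config {cfg.to_dict()} differs from the model's "
                f"training config {self.statistics_config.to_dict()}; scores may "
                f"not be comparable",
                ConfigMismatchWarning,
                stacklevel=2,
            )
        return ScoreSet(frame_indices=frames, scores=self.predict(exog), model=self)

    # -- reporting --------------------------------------------------------

    def summary(self) -> str:
        lines = [
            "Frame quality model (ordinary least squares)",
            f"  n_training   : {self.n_training}",
            f"  adjusted R^2 : {self.adjusted_r2:.4f}",
            f"  intercept    : {self.intercept:.6g}",
            f"  {'variable':<20}{'coefficient':>15}{'p-value':>12}",
        ]
        for v in self.variables:
            lines.append(f"  {v:<20}{self.coefficients[v]:>15.6g}{self.p_values[v]:>12.4g}")
        return "\n".join(lines)

    # -- persistence --------------------------------------------------------

    def save(self, path) -> None:
        save_model(self, path)

    @classmethod
    def load(cls, path) -> "FrameQualityResults":
        return load_model(path)


# ---------------------------------------------------------------------------
# module-level operations


def fit_mlr(
    samples: Sequence[ScoredSample],
    variables: Sequence[str] | None = None,
    statistics_config: StatisticsConfig | None = None,
) -> FrameQualityResults:
    """OLS fit of manual scores on image statistics (all requested variables)."""
    return FrameQualityModel.from_samples(
        samples, variables=variables, statistics_config=statistics_config
    ).fit()


def stepwise_backward_eliminate(
    samples: Sequence[ScoredSample],
    initial_variables: Sequence[str] | None = None,
    statistics_config: StatisticsConfig | None = None,
) -> FrameQualityResults:
    """Automated variable selection by backward elimination (see ``fit_stepwise``)."""
    return FrameQualityModel.from_samples(
        samples, variables=initial_variables, statistics_config=statistics_config
    ).fit_stepwise()


def calculate_scores(
    stats: Sequence[FrameStatistics] | pd.DataFrame,
    model: FrameQualityResults,
    statistics_config: StatisticsConfig | None = None,
) -> ScoreSet:
    """Score every frame with a fitted model (see ``FrameQualityResults.calculate_scores``)."""
    return model.calculate_scores(stats, statistics_config=statistics_config)


def range_adjust(scores: ScoreSet) -> ScoreSet:
    """Affinely map a score set onto [0, 5]: (C - Cmin) / (Cmax - Cmin) * 5.

    Rank order is preserved.  If every score is identical the mapping is
    undefined; all scores become 0 and a :class:`DegenerateRangeWarning` is
    emitted so pipelines can continue.
    """
    if len(scores) == 0:
        raise InvalidInputError("cannot range-adjust an empty score set")
    c = scores.scores
    cmin, cmax = float(c.min()), float(c.max())
    if cmax == cmin:
        warnings.warn(
            "all calculated scores are identical; range adjustment maps them to 0",
            DegenerateRangeWarning,
            stacklevel=2,
        )
        adjusted = np.zeros_like(c)
    else:
        adjusted = (c - cmin) / (cmax - cmin) * 5.0
    return ScoreSet(
        frame_indices=scores.frame_indices,
        scores=adjusted,
        range_adjusted=True,
        model=scores.model,
    )


def consolidate(
    samplesets: Sequence[tuple[str, Sequence[ScoredSample]]],
    frames_per_set: int,
    configs: Mapping[str, StatisticsConfig] | None = None,
) -> list[ScoredSample]:
    """Concatenate the first ``frames_per_set`` scored samples of each image set.

    Pooling statistics and scores across sets lets one model capture the
    characteristics shared by an imaging modality rather than one capture.
    When per-set statistics configurations are supplied they must all agree.
    """
    if frames_per_set < 1:
        raise InvalidInputError("frames_per_set must be >= 1")
    if configs:
        distinct = {cfg for cfg in configs.values()}
        if len(distinct) > 1:
            raise InvalidInputError(
                "statistics configurations differ across sets; consolidated "
                "regression requires one shared configuration"
            )
    out: list[ScoredSample] = []
    for label, samples in samplesets:
        if len(samples) < frames_per_set:
            raise InvalidInputError(
                f"set {label!r} supplies {len(samples)} scored frames; "
                f"{frames_per_set} required"
            )
        for s in list(samples)[:frames_per_set]:
            out.append(ScoredSample(s.statistics, s.manual_score, set_label=label))
    return out


# ---------------------------------------------------------------------------
# coefficient-file persistence

_CONVENTIONS = {"kurtosis": "excess", "entropy": "bits", "moments": "population"}


def save_model(model: FrameQualityResults, path) -> str:
    """Write a coefficient file (JSON); returns the file's sha256 for logging."""
    payload = {
        "format_version": MODEL_FILE_VERSION,
        "variables": model.variables,
        "intercept": model.intercept,
        "coefficients": model.coefficients,
        "p_values": model.p_values,
        "adjusted_r2": model.adjusted_r2,
        "n_training": model.n_training,
        "statistics_config": (
            model.statistics_config.to_dict() if model.statistics_config else None
        ),
        "conventions": _CONVENTIONS,
    }
    text = json.dumps(payload, indent=2, sort_keys=True)
    Path(path).write_text(text)
    return hashlib.sha256(text.encode()).hexdigest()


def load_model(path) -> FrameQualityResults:
    """Read a coefficient file, validating schema, version and variable names."""
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ModelFileError(f"{path}: not valid JSON ({exc})") from exc
    if not isinstance(payload, dict) or "format_version" not in payload:
        raise ModelFileError(f"{path}: missing format_version; not a coefficient file")
    if payload["format_version"] != MODEL_FILE_VERSION:
        raise ModelFileError(
            f"{path}: coefficient file version {payload['format_version']} "
            f"unsupported (expected {MODEL_FILE_VERSION})"
        )
    required = {"variables", "intercept", "coefficients", "p_values", "adjusted_r2", "n_training"}
    missing = required - payload.keys()
    if missing:
        raise ModelFileError(f"{path}: missing fields: {', '.join(sorted(missing))}")
    unknown = [v for v in payload["variables"] if v not in CANONICAL_VARIABLES]
    if unknown:
        raise ModelFileError(f"{path}: unknown variable name(s): {', '.join(unknown)}")
    conv = payload.get("conventions", _CONVENTIONS)
    if conv != _CONVENTIONS:
        raise ModelFileError(
            f"{path}: statistic conventions {conv} differ from this version's "
            f"{_CONVENTIONS}; refusing to mix"
        )
    cfg = payload.get("statistics_config")
    return FrameQualityResults(
        intercept=float(payload["intercept"]),
        coefficients={k: float(v) for k, v in payload["coefficients"].items()},
        p_values={k: float(v) for k, v in payload["p_values"].items()},
        adjusted_r2=float(payload["adjusted_r2"]),
        statistics_config=StatisticsConfig.from_dict(cfg) if cfg else None,
        n_training=int(payload["n_training"]),
    )
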