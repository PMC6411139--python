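"""End-to-end processing: statistics -> fit/load model -> score -> select -> export.

The pipeline follows the tool's flow-based operation: compute the per-frame
statistics, obtain a quality model (fit from a manual-score CSV, optionally
with automated backward elimination, or load a saved coefficient file), score
every frame, optionally range-adjust, reduce the stack by quality cutoff (QA)
or frame windowing (FW), and export the retained frames plus CSV/JSON reports.
Every stage's parameters are logged so outputs are attributable to the exact
statistic conventions that produced them.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

from . import io as fio
from .errors import FramepickError, InvalidConfigurationError
from .evaluation import evaluate_agreement
from .model import (
    FrameQualityModel,
    ScoredSample,
    load_model,
    range_adjust,
    save_model,
)
from .selection import (
    export_selection,
    filter_by_cutoff,
    frame_window_select,
    minimum_window_size,
)
from .stats import StatisticsConfig, compute_frame_statistics

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("framepick")


class PipelineError(FramepickError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Fully resolved configuration of an end-to-end run."""

    input_path: str
    output_dir: str
    statistics: StatisticsConfig = dataclasses.field(default_factory=StatisticsConfig)
    manual_scores_path: str | None = None  # training scores (frame,score CSV)
    model_path: str | None = None  # load instead of fitting
    auto_stepwise: bool = True
    variables: tuple[str, ...] | None = None
    do_range_adjust: bool = False
    mode: str | None = None  # "qa", "fw" or None (score only)
    cutoff: float | None = None  # QA cutoff, or FW quality target with window=None
    window: int | None = None


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full flow; returns a dict of artifact paths and key numbers.

    Raises :class:`PipelineError` naming the failing stage.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log.info("run configuration: %s", config)
    artifacts: dict = {}

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise PipelineError(name, exc) from exc

    stack = stage("read_stack", fio.read_stack, config.input_path)
    log.info(
        "read %d frames of %dx%d (%d-bit)",
        len(stack),
        stack[0].width,
        stack[0].height,
        stack[0].bit_depth,
    )

    stats = stage("statistics", compute_frame_statistics, stack, config.statistics)
    stats_csv = out_dir / "statistics.csv"
    fio.write_statistics(stats, stats_csv)
    fio.write_config_sidecar(config.statistics, stats_csv)
    artifacts["statistics"] = str(stats_csv)
    log.info(
        "statistics: pixel_step=%d normalize=%s sid_grid=%dx%d",
        config.statistics.pixel_step,
        config.statistics.normalize,
        config.statistics.sid_grid_rows,
        config.statistics.sid_grid_cols,
    )

    if config.model_path:
        results = stage("load_model", load_model, config.model_path)
        log.info("loaded coefficient file %s", config.model_path)
    elif config.manual_scores_path:
        def _fit():
            manual = fio.read_manual_scores(config.manual_scores_path)
            by_index = {s.frame_index: s for s in stats}
            missing = sorted(set(manual) - set(by_index))
            if missing:
                raise InvalidConfigurationError(
                    f"manual scores refer to frames not in the stack: {missing[:5]}"
                )
            samples = [
                ScoredSample(by_index[i], manual[i]) for i in sorted(manual)
            ]
            model = FrameQualityModel.from_samples(
                samples,
                variables=config.variables,
                statistics_config=config.statistics,
            )
            return model.fit_stepwise() if config.auto_stepwise else model.fit()

        results = stage("fit", _fit)
    else:
        raise PipelineError(
            "fit", InvalidConfigurationError("neither manual scores nor a model file given")
        )
    model_json = out_dir / "model.json"
    digest = save_model(results, model_json)
    artifacts["model"] = str(model_json)
    log.info("model: %d variables, adjusted R^2 %.4f, sha256 %s",
             len(results.coefficients), results.adjusted_r2, digest)

    scores = stage("score", results.calculate_scores, stats, config.statistics)
    if config.do_range_adjust:
        scores = stage("range_adjust", range_adjust, scores)
    scores_csv = out_dir / "scores.csv"
    fio.write_scores(scores, scores_csv)
    artifacts["scores"] = str(scores_csv)

    if config.manual_scores_path:
        manual = fio.read_manual_scores(config.manual_scores_path)
        try:
            report = evaluate_agreement(manual, scores.as_dict())
            artifacts["agreement"] = dataclasses.asdict(report)
            log.info("agreement with manual scores: r=%.3f (%s)",
                     report.pearson_r, report.strength_label)
        except FramepickError:
            pass  # e.g. too few shared frames for a correlation

    if config.mode is None:
        return artifacts

    if config.mode == "qa":
        if config.cutoff is None:
            raise PipelineError("select", InvalidConfigurationError("QA mode needs a cutoff"))
        selection = stage("select", filter_by_cutoff, scores, config.cutoff)
    elif config.mode == "fw":
        window = config.window
        if window is None:
            if config.cutoff is None:
                raise PipelineError(
                    "select",
                    InvalidConfigurationError("FW mode needs a window size or a quality target"),
                )
            window = stage("minimum_window", minimum_window_size, scores, config.cutoff)
            artifacts["minimum_window"] = window
            if window is None:
                raise PipelineError(
                    "minimum_window",
                    InvalidConfigurationError(
                        f"no window size up to 25% of the stack meets target {config.cutoff}"
                    ),
                )
            log.info("minimum window size for target %.3g: %d", config.cutoff, window)
        selection = stage("select", frame_window_select, scores, window)
    else:
        raise PipelineError(
            "select", InvalidConfigurationError(f"unknown mode {config.mode!r}")
        )
    log.info("%s selection retains %d of %d frames",
             selection.mode, len(selection.retained_indices), len(stack))

    manifest = stage("export", export_selection, stack, selection, out_dir / "selected")
    artifacts["manifest"] = str(manifest)
    artifacts["retained"] = list(selection.retained_indices)
    return artifacts
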