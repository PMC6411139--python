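"""Regression/scoring module: OLS oracle agreement, stepwise rules, persistence."""

import json

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from framepick.errors import (
    AliasedVariableWarning,
    ConfigMismatchWarning,
    DegenerateRangeWarning,
    InvalidInputError,
    ModelFileError,
    StepwiseEliminationError,
)
from framepick.model import (
    FrameQualityModel,
    ScoredSample,
    ScoreSet,
    calculate_scores,
    consolidate,
    fit_mlr,
    load_model,
    range_adjust,
    save_model,
    stepwise_backward_eliminate,
)
from framepick.stats import StatisticsConfig

from conftest import make_statistics
from _oracles import ols_normal_equations


def samples_from(score_fn, var_values: dict[str, np.ndarray]) -> list[ScoredSample]:
    n = len(next(iter(var_values.values())))
    out = []
    for i in range(n):
        vals = {k: v[i] for k, v in var_values.items()}
        out.append(ScoredSample(make_statistics(frame_index=i, **vals), score_fn(i, vals)))
    return out


class TestFit:
    def test_exact_linear_relation_recovered(self):
        means = np.linspace(0.0, 1.0, 8)
        samples = samples_from(lambda i, v: 2 + 3 * v["mean"], {"mean": means})
        res = fit_mlr(samples, variables=["mean"])
        assert res.intercept == pytest.approx(2.0, abs=1e-9)
        assert res.coefficients["mean"] == pytest.approx(3.0, abs=1e-9)
        assert res.adjusted_r2 == pytest.approx(1.0, abs=1e-9)

    def test_constant_scores_give_zero_slopes(self):
        rng = np.random.default_rng(0)
        samples = samples_from(
            lambda i, v: 3.0, {"mean": rng.uniform(0, 100, 10), "std": rng.uniform(0, 10, 10)}
        )
        res = fit_mlr(samples, variables=["mean", "std"])
        assert res.intercept == 3.0
        assert all(b == 0.0 for b in res.coefficients.values())

    def test_coefficients_match_normal_equations_oracle(self):
        rng = np.random.default_rng(42)
        n, names = 30, ["mean", "std", "entropy", "sid"]
        X = rng.normal(size=(n, 4)) * [10, 3, 1, 50] + [50, 10, 6, 100]
        y = 1.5 + X @ [0.05, -0.2, 0.3, 0.01] + rng.normal(0, 0.5, n)
        data = pd.DataFrame(X, columns=names)
        res = FrameQualityModel(y, data, variables=names).fit()
        beta, _, pvals, adj = ols_normal_equations(X, y)
        assert res.intercept == pytest.approx(beta[0], abs=1e-8)
        for j, name in enumerate(names):
            assert res.coefficients[name] == pytest.approx(beta[j + 1], abs=1e-8)
            assert res.p_values[name] == pytest.approx(pvals[j + 1], abs=1e-8)
        assert res.adjusted_r2 == pytest.approx(adj, abs=1e-10)

    def test_too_few_samples_rejected(self):
        rng = np.random.default_rng(6)
        samples = samples_from(
            lambda i, v: v["mean"],
            {
                "mean": np.arange(3.0) / 3,
                "std": rng.uniform(1, 2, 3),
                "entropy": rng.uniform(5, 6, 3),
            },
        )
        with pytest.raises(InvalidInputError, match="scored frames"):
            fit_mlr(samples, variables=["mean", "std", "entropy"])

    def test_aliased_variable_dropped_with_warning(self):
        rng = np.random.default_rng(1)
        mean = rng.uniform(10, 60, 15)
        samples = samples_from(
            lambda i, v: 0.05 * v["mean"],
            {"mean": mean, "integrated_density": mean * 4096.0},
        )
        with pytest.warns(AliasedVariableWarning, match="integrated_density"):
            res = fit_mlr(samples, variables=["mean", "integrated_density"])
        assert "integrated_density" not in res.coefficients


class TestStepwise:
    def test_noise_variable_eliminated_informative_retained(self):
        rng = np.random.default_rng(7)
        n = 40
        informative = rng.uniform(0, 10, n)
        noise = rng.normal(size=n)
        scores = np.clip(0.5 + 0.4 * informative + rng.normal(0, 0.1, n), 0, 5)
        data = pd.DataFrame({"mean": informative, "skewness": noise})
        res = FrameQualityModel(scores, data).fit_stepwise()
        assert "mean" in res.coefficients
        assert "skewness" not in res.coefficients

    def test_all_significant_model_equals_plain_fit(self):
        rng = np.random.default_rng(2)
        n = 50
        a = rng.uniform(0, 10, n)
        b = rng.uniform(0, 10, n)
        y = 0.2 * a + 0.3 * b + rng.normal(0, 0.05, n)
        data = pd.DataFrame({"mean": a, "std": b})
        model = FrameQualityModel(y, data)
        full = model.fit()
        assert max(full.p_values.values()) <= 0.05
        step = model.fit_stepwise()
        assert step.coefficients == full.coefficients

    def test_removing_last_variable_fails_loudly(self):
        rng = np.random.default_rng(3)
        data = pd.DataFrame({"mean": rng.uniform(0, 10, 12)})
        y = rng.normal(2.5, 0.3, 12)  # unrelated to the variable
        with pytest.raises(StepwiseEliminationError, match="user intervention"):
            FrameQualityModel(y, data).fit_stepwise()

    def test_final_model_valid_per_stop_rule(self):
        # either all p <= 0.05, or the last tentative removal lowered adj R^2
        rng = np.random.default_rng(8)
        n = 35
        X = rng.normal(size=(n, 5))
        y = 1.0 + X[:, 0] * 0.8 + X[:, 1] * 0.1 + rng.normal(0, 0.4, n)
        names = ["mean", "std", "entropy", "skewness", "sid"]
        model = FrameQualityModel(y, pd.DataFrame(X, columns=names))
        res = model.fit_stepwise()
        if max(res.p_values.values()) > 0.05:
            worst = max(res.p_values, key=lambda v: res.p_values[v])
            remaining = [v for v in res.coefficients if v != worst]
            trial = model._fit_subset(remaining)
            assert trial.adjusted_r2 < res.adjusted_r2


class TestScoring:
    def test_direct_substitution(self):
        res = fit_mlr(
            samples_from(lambda i, v: 1 + 2 * v["mean"], {"mean": np.linspace(0, 2, 6)}),
            variables=["mean"],
        )
        scores = res.calculate_scores([make_statistics(frame_index=0, mean=3.0)])
        assert scores.as_dict()[0] == pytest.approx(7.0, abs=1e-9)

    def test_scores_below_zero_are_permitted(self):
        from framepick.model import FrameQualityResults

        res = FrameQualityResults(
            intercept=-1.0,
            coefficients={"mean": 0.0},
            p_values={"mean": 1.0},
            adjusted_r2=0.0,
            statistics_config=None,
            n_training=10,
        )
        scores = res.calculate_scores([make_statistics(frame_index=i) for i in range(3)])
        assert np.allclose(scores.scores, -1.0)

    def test_exact_fit_reproduces_training_scores(self):
        means = np.linspace(1, 4, 7)
        samples = samples_from(lambda i, v: 0.3 + 1.1 * v["mean"], {"mean": means})
        res = fit_mlr(samples, variables=["mean"])
        scores = calculate_scores([s.statistics for s in samples], res)
        for s in samples:
            assert scores.as_dict()[s.statistics.frame_index] == pytest.approx(
                s.manual_score, abs=1e-10
            )

    def test_scoring_is_affine_in_the_statistics(self):
        res = fit_mlr(
            samples_from(
                lambda i, v: 0.02 * v["mean"] + 0.1 * v["std"],
                {
                    "mean": np.linspace(10, 90, 8),
                    "std": np.array([2.0, 7.0, 3.5, 1.0, 8.0, 4.0, 6.0, 5.0]),
                },
            ),
            variables=["mean", "std"],
        )
        a = make_statistics(frame_index=0, mean=20.0, std=3.0)
        b = make_statistics(frame_index=1, mean=80.0, std=9.0)
        mid = make_statistics(frame_index=2, mean=50.0, std=6.0)
        s = res.calculate_scores([a, b, mid]).scores
        assert s[2] == pytest.approx((s[0] + s[1]) / 2, rel=1e-12)

    def test_missing_variable_rejected(self):
        res = fit_mlr(
            samples_from(lambda i, v: v["mean"] / 20, {"mean": np.linspace(10, 90, 6)}),
            variables=["mean"],
        )
        with pytest.raises(InvalidInputError, match="mean"):
            res.predict(pd.DataFrame({"std": [1.0]}))

    def test_config_mismatch_warns(self):
        cfg_train = StatisticsConfig(pixel_step=3)
        cfg_other = StatisticsConfig(pixel_step=5)
        res = fit_mlr(
            samples_from(lambda i, v: v["mean"] / 20, {"mean": np.linspace(10, 90, 6)}),
            variables=["mean"],
            statistics_config=cfg_train,
        )
        with pytest.warns(ConfigMismatchWarning):
            res.calculate_scores([make_statistics()], statistics_config=cfg_other)


class TestRangeAdjust:
    def test_paper_worked_range_example(self):
        scores = ScoreSet(frame_indices=(0, 1), scores=np.array([18.0, 34.0]))
        out = range_adjust(scores)
        assert list(out.scores) == [0.0, 5.0]
        assert out.range_adjusted

    def test_midpoint_maps_to_midscale(self):
        scores = ScoreSet(frame_indices=(0, 1, 2), scores=np.array([18.0, 26.0, 34.0]))
        assert list(range_adjust(scores).scores) == [0.0, 2.5, 5.0]

    def test_degenerate_range_warns_and_zeroes(self):
        scores = ScoreSet(frame_indices=(0, 1), scores=np.array([2.0, 2.0]))
        with pytest.warns(DegenerateRangeWarning):
            out = range_adjust(scores)
        assert list(out.scores) == [0.0, 0.0]

    @given(st.lists(st.floats(-50, 50), min_size=2, max_size=30, unique=True))
    def test_idempotent_and_rank_preserving(self, values):
        scores = ScoreSet(frame_indices=tuple(range(len(values))), scores=np.array(values))
        once = range_adjust(scores)
        twice = range_adjust(once)
        assert np.allclose(once.scores, twice.scores, atol=1e-12)
        assert once.scores.min() == 0.0 and once.scores.max() == 5.0
        # monotone: ordering by original score never decreases the adjusted one
        order = np.argsort(scores.scores, kind="stable")
        assert (np.diff(once.scores[order]) >= 0).all()


class TestConsolidate:
    def _set(self, label, n, offset=0.0):
        return [
            ScoredSample(make_statistics(frame_index=i, mean=10 * i + offset), 2.5, label)
            for i in range(n)
        ]

    def test_three_sets_of_twenty_give_sixty(self):
        sets = [("s1", self._set("s1", 25)), ("s2", self._set("s2", 20)), ("s3", self._set("s3", 22))]
        out = consolidate(sets, frames_per_set=20)
        assert len(out) == 60
        assert [s.set_label for s in out[:20]] == ["s1"] * 20

    def test_single_set_passthrough(self):
        samples = self._set("only", 12)
        out = consolidate([("only", samples)], frames_per_set=10)
        assert [s.statistics.frame_index for s in out] == list(range(10))

    def test_label_counts_by_construction(self):
        out = consolidate([("a", self._set("a", 15)), ("b", self._set("b", 15))], 15)
        assert sum(1 for s in out if s.set_label == "a") == 15
        assert sum(1 for s in out if s.set_label == "b") == 15

    def test_short_set_rejected(self):
        with pytest.raises(InvalidInputError, match="short"):
            consolidate([("short", self._set("short", 5))], frames_per_set=20)

    def test_config_mismatch_rejected(self):
        sets = [("a", self._set("a", 5)), ("b", self._set("b", 5))]
        configs = {"a": StatisticsConfig(pixel_step=3), "b": StatisticsConfig(pixel_step=5)}
        with pytest.raises(InvalidInputError, match="configuration"):
            consolidate(sets, frames_per_set=5, configs=configs)


class TestPersistence:
    def _fitted(self):
        return fit_mlr(
            samples_from(
                lambda i, v: 0.04 * v["mean"] + 0.001 * v["sum_pixel_ramp"] - 1.0,
                {
                    "mean": np.linspace(10, 90, 10),
                    "sum_pixel_ramp": np.linspace(600, 1200, 10) ** 1.01,
                },
            ),
            variables=["mean", "sum_pixel_ramp"],
            statistics_config=StatisticsConfig(),
        )

    def test_round_trip_identity(self, tmp_path):
        res = self._fitted()
        path = tmp_path / "model.json"
        save_model(res, path)
        back = load_model(path)
        assert back.intercept == res.intercept
        assert back.coefficients == res.coefficients
        assert back.p_values == res.p_values
        assert back.adjusted_r2 == res.adjusted_r2
        assert back.statistics_config == res.statistics_config
        assert back.n_training == res.n_training

    def test_unknown_variable_rejected_by_name(self, tmp_path):
        res = self._fitted()
        path = tmp_path / "model.json"
        save_model(res, path)
        payload = json.loads(path.read_text())
        payload["variables"] = ["not_a_statistic"]
        path.write_text(json.dumps(payload))
        with pytest.raises(ModelFileError, match="not_a_statistic"):
            load_model(path)

    def test_version_mismatch_rejected(self, tmp_path):
        res = self._fitted()
        path = tmp_path / "model.json"
        save_model(res, path)
        payload = json.loads(path.read_text())
        payload["format_version"] = 99
        path.write_text(json.dumps(payload))
        with pytest.raises(ModelFileError, match="version"):
            load_model(path)

    def test_loaded_model_warns_on_other_normalization(self, tmp_path):
        res = self._fitted()  # trained with normalize=True
        path = tmp_path / "model.json"
        save_model(res, path)
        back = load_model(path)
        with pytest.warns(ConfigMismatchWarning):
            back.calculate_scores(
                [make_statistics()], statistics_config=StatisticsConfig(normalize=False)
            )


class TestParameterRecovery:
    def test_known_linear_combination_recovered_within_three_se(self, population50_stats):
        stats = population50_stats
        rng = np.random.default_rng(123)
        names = ["std", "entropy", "sum_pixel_ramp"]
        X = np.array([[s.as_variables()[v] for v in names] for s in stats])
        truth = np.array([0.002, 0.8, 0.005])
        y = -6.0 + X @ truth + rng.normal(0, 0.1, len(stats))
        res = FrameQualityModel(y, pd.DataFrame(X, columns=names)).fit()
        _, se, _, _ = ols_normal_equations(X, y)
        assert abs(res.intercept - (-6.0)) <= 3 * se[0]
        for j, name in enumerate(names):
            assert abs(res.coefficients[name] - truth[j]) <= 3 * se[j + 1]
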