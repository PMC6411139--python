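import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from framepick.stats import (
    FrameImage,
    FrameStatistics,
    StatisticsConfig,
    compute_frame_statistics,
)
from framepick.synthetic import SynthConfig, generate_stack, standard_benchmark

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_statistics(frame_index: int = 0, **variables) -> FrameStatistics:
    """Fabricate a FrameStatistics record from canonical variable values."""
    defaults = dict(
        unique_greys=100,
        mean=50.0,
        max=200.0,
        std=10.0,
        skewness=0.5,
        kurtosis=0.2,
        entropy=6.0,
        integrated_density=5e5,
        sum_of_squares=3e7,
        sum_pixel_ramp=800.0,
        sid=40.0,
    )
    defaults.update(variables)
    return FrameStatistics(
        frame_index=frame_index,
        unique_greys=int(defaults["unique_greys"]),
        mean_grey=float(defaults["mean"]),
        max_grey=float(defaults["max"]),
        std_grey=float(defaults["std"]),
        skewness=float(defaults["skewness"]),
        kurtosis=float(defaults["kurtosis"]),
        entropy=float(defaults["entropy"]),
        integrated_density=float(defaults["integrated_density"]),
        sum_of_squares=float(defaults["sum_of_squares"]),
        sum_pixel_ramp=float(defaults["sum_pixel_ramp"]),
        sid=float(defaults["sid"]),
    )


def frame_of(array, bit_depth=16, index=0) -> FrameImage:
    return FrameImage(
        pixels=np.asarray(array, dtype=np.uint16 if bit_depth == 16 else np.uint8),
        bit_depth=bit_depth,
        frame_index=index,
    )


@pytest.fixture(scope="session")
def benchmark_stack():
    """The standard 200-frame benchmark at a fixed seed, with ground truth."""
    return standard_benchmark(42)


@pytest.fixture(scope="session")
def benchmark_stats(benchmark_stack):
    frames, _ = benchmark_stack
    return compute_frame_statistics(frames, StatisticsConfig())


@pytest.fixture(scope="session")
def population50():
    """A 50-frame generated population at defaults, for statistic-level checks."""
    return generate_stack(SynthConfig(n_frames=50, seed=7))


@pytest.fixture(scope="session")
def population50_stats(population50):
    frames, _ = population50
    return compute_frame_statistics(frames, StatisticsConfig())


@pytest.fixture()
def small_stack():
    """A quick 30-frame 128x128 stack for pipeline-level tests."""
    return generate_stack(SynthConfig(n_frames=30, width=128, height=128, seed=11))
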