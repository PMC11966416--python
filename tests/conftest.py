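import numpy as np
import pytest

from vmatqa.fixtures import (
    ImageFixtureConfig,
    RTPlanFixtureConfig,
    make_image_fixtures,
    make_rtplan_fixture,
)


@pytest.fixture(scope="session")
def static_plan_path(tmp_path_factory):
    d = tmp_path_factory.mktemp("plans")
    return make_rtplan_fixture(
        d / "static.dcm", RTPlanFixtureConfig(n_control_points=5))


@pytest.fixture(scope="session")
def modulated_plan_path(tmp_path_factory):
    d = tmp_path_factory.mktemp("plans_mod")
    return make_rtplan_fixture(
        d / "mod.dcm",
        RTPlanFixtureConfig(n_control_points=10, modulation_amplitude_mm=20.0),
    )


@pytest.fixture(scope="session")
def phantom(tmp_path_factory):
    d = tmp_path_factory.mktemp("phantom")
    return make_image_fixtures(d, ImageFixtureConfig())


@pytest.fixture(scope="session")
def phantom_cavity(tmp_path_factory):
    d = tmp_path_factory.mktemp("phantom_cav")
    return make_image_fixtures(d, ImageFixtureConfig(cavity=True))


@pytest.fixture(scope="session")
def small_cohort():
    """Tiny cohort for fast structural tests."""
    from vmatqa.synthetic import GeneratorConfig, make_cohort

    return make_cohort(GeneratorConfig(
        n_plans=12, n_fields=24, span_days=200, seed=7))


def toy_roi(values: np.ndarray, bin_width: float = 1.0):
    """DiscretizedROI over a full small array with unit spacing."""
    from vmatqa.volume_features import DiscretizedROI

    values = np.asarray(values, dtype=float)
    mask = np.ones(values.shape, dtype=bool)
    levels = np.floor((values - values.min()) / bin_width).astype(np.int64) + 1
    return DiscretizedROI(
        levels=levels, raw=values, mask=mask, bin_width=bin_width,
        Ng=int(levels.max()), spacing=(1.0, 1.0, 1.0),
    )
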