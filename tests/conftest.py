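import numpy as np
import pytest

from flagstorm import (
    AstigCalibration,
    AxisModel,
    FlagellumModel,
    corrupt_to_localizations,
    sample_emitters,
    to_cylindrical,
)


@pytest.fixture(scope="session")
def wt_model():
    """Continuous-stripe flagellum at default study conditions."""
    return FlagellumModel(seed=7)


@pytest.fixture(scope="session")
def null_model():
    """Fragmented-stripe flagellum: 800 nm gap period, duty 0.5."""
    return FlagellumModel(gap_period_nm=800.0, seed=7)


@pytest.fixture(scope="session")
def calibration():
    return AstigCalibration()


def true_axis(model: FlagellumModel) -> AxisModel:
    """AxisModel built from the generator's known geometry and frame."""
    e1, _ = model.frame()
    return AxisModel(direction=model.axis, annulus_point=model.origin,
                     reference_direction=e1)


def surface_cylindrical(model: FlagellumModel):
    """Simulate, project with the true axis, and return the cylindrical table."""
    truth = sample_emitters(model)
    table = corrupt_to_localizations(truth, model)
    return to_cylindrical(table, true_axis(model)), truth
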