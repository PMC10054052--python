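import numpy as np
import pytest

from mycorisk import ExposureParameters, SampleRecord


@pytest.fixture
def params():
    return ExposureParameters()


@pytest.fixture
def small_records():
    return [
        SampleRecord("Alder Grove", "L. scabrum", 0.50, 0.25, 0.10),
        SampleRecord("Alder Grove", "L. scabrum", 0.80, 0.40, 0.18),
        SampleRecord("Birch Hill", "L. albostipitatum", 1.20, 0.60, 0.04),
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20230222)
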