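import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from podometry.measurements import (
    BiopsyMeasurement,
    GlomerulusMeasurement,
    OpticalConfig,
)


@pytest.fixture
def optics() -> OpticalConfig:
    return OpticalConfig()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_glomerulus(
    gid="g1", area=10000.0, score=0, diameters=(7.1, 7.5), snp=1300.0
) -> GlomerulusMeasurement:
    return GlomerulusMeasurement(
        glomerulus_id=gid,
        tuft_area=area,
        sclerosis_score=score,
        nuclear_caliper_diameters=diameters,
        snp_area=snp,
    )


def make_biopsy(pid="p1", n_glomeruli=8, **kwargs) -> BiopsyMeasurement:
    gloms = tuple(
        make_glomerulus(gid=f"{pid}-g{i}", **kwargs) for i in range(n_glomeruli)
    )
    return BiopsyMeasurement(patient_id=pid, glomeruli=gloms)


@pytest.fixture
def biopsy() -> BiopsyMeasurement:
    return make_biopsy()
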