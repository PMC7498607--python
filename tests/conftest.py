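import numpy as np
import pytest

from ssrmine.presets import four_landraces
from ssrmine.marker_pipeline import run_pipeline


@pytest.fixture(scope="session")
def small_panel():
    """Reduced synthetic study panel (one contig, six planted SSRs)."""
    return four_landraces(seed=7, small=True)


@pytest.fixture(scope="session")
def small_result(small_panel):
    fx = small_panel
    extra = {"musa_like": fx.genomes["musa_like"]}
    return run_pipeline(fx.landrace_genomes, extra, fx.features or None)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
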