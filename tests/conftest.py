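import numpy as np
import pytest

from cfbrain.panel import MarkerPanel
from cfbrain.reads import AmpliconMatcher
from cfbrain.simulate import generate_marker_panel

#: The study-sized panel: 4 neuron, 3 astrocyte, 3 oligodendrocyte,
#: 3 whole-brain amplicons.
PANEL13_COUNTS = {"neuron": 4, "astrocyte": 3, "oligodendrocyte": 3, "whole_brain": 3}


@pytest.fixture(scope="session")
def panel13() -> MarkerPanel:
    return generate_marker_panel(PANEL13_COUNTS, seed=1)


@pytest.fixture(scope="session")
def small_panel() -> MarkerPanel:
    """Three short amplicons; cheap enough for per-read assertions."""
    return generate_marker_panel(
        {"neuron": 1, "astrocyte": 1, "oligodendrocyte": 1},
        n_cpgs_range=(2, 4),
        amplicon_length=60,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_matcher(small_panel) -> AmpliconMatcher:
    return AmpliconMatcher(small_panel)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
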