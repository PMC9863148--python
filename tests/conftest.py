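import numpy as np
import pytest

from cytoblot.layout import ArrayLayout
from cytoblot.simulate import SimulationConfig, default_layout, simulate_membrane


@pytest.fixture(scope="session")
def layout() -> ArrayLayout:
    return default_layout()


@pytest.fixture(scope="session")
def tiny_layout() -> ArrayLayout:
    """One 4x4 block, two analytes in adjacent-column duplicates."""
    positions = []
    for r in range(4):
        for c in range(4):
            if r == 0 and c == 0:
                analyte, role = "REF", "reference"
            elif r == 1:
                analyte, role = ("X", "analyte") if c < 2 else ("Y", "analyte")
            elif r == 2 and c < 2:
                analyte, role = "NEG", "negative"
            else:
                analyte, role = "", "empty"
            positions.append((0, 0, r, c, analyte, role))
    return ArrayLayout(
        name="tiny", n_block_rows=1, n_block_cols=1,
        rows_per_block=4, cols_per_block=4,
        pitch=10.0, alley_row=0.0, alley_col=0.0, spot_radius=3.0,
        positions=tuple(positions),
    ).check_valid()


@pytest.fixture(scope="session")
def clean_membrane():
    """Noise- and jitter-free membrane with its truth sidecar."""
    cfg = SimulationConfig(
        seed=5, technical_cv=0.0, corner_jitter_sd=0.0, spot_jitter_sd=0.0,
        read_noise_sd=0.0, missing_spot_prob=0.0,
    )
    img, truth = simulate_membrane(cfg, (1, "M", "control"))
    return cfg, img, truth


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
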