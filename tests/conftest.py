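import numpy as np
import pytest

from dcistil.synthetic_histology import default_tile_spec, generate_tile
from dcistil.til_scoring import analyze_tile


@pytest.fixture(scope="session")
def tile100():
    """One rendered tile at 100 lymphocytes/mm^2 with its ground truth."""
    spec = default_tile_spec(100.0, seed=3)
    image, truth = generate_tile(spec)
    return spec, image, truth


@pytest.fixture(scope="session")
def analysis100(tile100):
    """Segmentation of the 100/mm^2 tile against its true duct mask."""
    _, image, truth = tile100
    return analyze_tile(image, truth.duct_mask)


@pytest.fixture(scope="session")
def small_analyses():
    """Three small analysed tiles at distinct densities (for multi-patient
    operations that need >= 3 evaluable patients)."""
    out = []
    for i, dens in enumerate([40.0, 150.0, 350.0]):
        spec = default_tile_spec(dens, seed=10 + i, side_px=300)
        image, truth = generate_tile(spec)
        out.append((f"p{i}", analyze_tile(image, truth.duct_mask)))
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
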