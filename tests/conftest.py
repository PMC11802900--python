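import numpy as np
import pytest

from lepivision import (
    DEFAULT_GRID,
    Spectrum,
    ViewingConditions,
    d65_illuminant,
    make_visual_system,
)


@pytest.fixture(scope="session")
def grid():
    return DEFAULT_GRID


@pytest.fixture(scope="session")
def d65(grid):
    return d65_illuminant(grid)


@pytest.fixture(scope="session")
def flat_conditions(grid, d65):
    """D65 over a flat mid-grey background."""
    bg = Spectrum(grid, np.full(grid.size, 0.2), kind="reflectance", label="grey")
    return ViewingConditions(illuminant=d65, background=bg)


@pytest.fixture(scope="session")
def fessonia(grid):
    return make_visual_system("fessonia", grid)


@pytest.fixture(scope="session")
def uv_bird(grid):
    return make_visual_system("uv_bird", grid)


@pytest.fixture(scope="session")
def violet_bird(grid):
    return make_visual_system("violet_bird", grid)


def brute_force_chromatic(df, e):
    """Independent oracle: the noise-weighted line element restricted to the
    chromatic subspace equals min over uniform offsets c of
    sum((df_i - c)^2 / e_i^2)."""
    df = np.asarray(df, float)
    e = np.asarray(e, float)
    w = 1.0 / e**2
    c = float((df * w).sum() / w.sum())
    return float(np.sqrt(((df - c) ** 2 * w).sum()))
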