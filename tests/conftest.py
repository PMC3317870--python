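import numpy as np
import pytest

from spanel import (
    PanelData,
    SyntheticConfig,
    build_lattice_weights,
    lattice_for,
    row_standardize,
)


@pytest.fixture(scope="session")
def rook3() -> object:
    return build_lattice_weights(3, 3, "rook")


@pytest.fixture(scope="session")
def rook3_std(rook3) -> object:
    return row_standardize(rook3)


@pytest.fixture(scope="session")
def lattice20_std() -> object:
    return lattice_for(SyntheticConfig())


def make_panel(rng: np.random.Generator, n: int, t: int, k: int,
               region_prefix: str = "u") -> PanelData:
    """Random balanced panel with standard-normal outcome and design."""
    return PanelData(
        y=rng.standard_normal(n * t),
        X=rng.standard_normal((n * t, k)),
        region_ids=[f"{region_prefix}{i:03d}" for i in range(n)],
        period_labels=[f"t{s}" for s in range(t)],
        covariate_names=[f"x{j}" for j in range(k)],
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
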