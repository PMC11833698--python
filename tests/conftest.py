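import numpy as np
import pytest

from paoximetry.optics import ExtinctionTable, TissueSpec, load_tissue_specs


@pytest.fixture(scope="session")
def table() -> ExtinctionTable:
    return ExtinctionTable.from_package_data()


@pytest.fixture(scope="session")
def tissues() -> dict[str, TissueSpec]:
    return load_tissue_specs()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
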