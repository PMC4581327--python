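import numpy as np
import pytest

from idrptm.proteome import Proteome, ProteinRecord


@pytest.fixture
def tiny_proteome() -> Proteome:
    return Proteome(
        species_id="sp01",
        records=[
            ProteinRecord("p1", "sp01", "MKVSATNKSLYKPESTPDS"),
            ProteinRecord("p2", "sp01", "MSSTTYKNNSS"),
        ],
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
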