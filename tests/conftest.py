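import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from bvstereo.barcodes import (
    SubstituentSet,
    barcode_string,
    enumerate_isomers,
)
from bvstereo.structures import build_isomer


@pytest.fixture(scope="session")
def me2():
    return SubstituentSet.from_spec(["C:2"])


@pytest.fixture(scope="session")
def me2_structures(methyl_structures):
    """Best MMFF structure for each of the 15 dimethyl isomers."""
    return methyl_structures[2]


@pytest.fixture(scope="session")
def methyl_structures():
    """Best structure per isomer for the di-, tri- and tetramethyl ensembles."""
    out = {}
    for n in (2, 3, 4):
        s = SubstituentSet.from_spec([f"C:{n}"])
        out[n] = {
            barcode_string(d): build_isomer(d, s, n_conf=10, keep=1, seed=42).best
            for d in enumerate_isomers(s)
        }
    return out
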