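import numpy as np
import pytest

import ppii_ensemble as ppe
from ppii_ensemble import sampler
from ppii_ensemble.peptide import DihedralSet, SequenceSpec, build_conformer


@pytest.fixture(scope="session")
def two_hexapy() -> SequenceSpec:
    return ppe.TWO_HEXAPY


@pytest.fixture(scope="session")
def coil_pool(two_hexapy):
    """A small shared statistical-coil pool (fixed seed)."""
    return sampler.generate_pool(two_hexapy, 300, rng_seed=7)


@pytest.fixture(scope="session")
def beta_conformer(two_hexapy):
    return build_conformer(two_hexapy, DihedralSet.uniform(12, -139.0, 135.0))


@pytest.fixture(scope="session")
def ppii_conformer(two_hexapy):
    return build_conformer(two_hexapy, DihedralSet.uniform(12, -75.0, 145.0))


def circular_diff(a, b):
    """Smallest absolute angular difference in degrees."""
    return np.abs(ppe.peptide.wrap_angle(np.asarray(a) - np.asarray(b)))
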