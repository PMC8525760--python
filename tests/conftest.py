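import numpy as np
import pytest

from equipain import manifest_from_composition, reference_matrices


@pytest.fixture(scope="session")
def ref_mats():
    return reference_matrices()


@pytest.fixture(scope="session")
def table1_manifest():
    """Manifest mirroring the reference database composition (4850 rows)."""
    return manifest_from_composition()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
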