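import pytest

from tipiso.synthetic import dppc_reference


@pytest.fixture(scope="session")
def dppc25():
    """Noiseless three-region DPPC-like reference at 298.15 K."""
    return dppc_reference("25C", n_per_region=40)


@pytest.fixture(scope="session")
def dppc45():
    """Noiseless single-region supercritical reference at 318.15 K."""
    return dppc_reference("45C", n_per_region=60)
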