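import pytest

from hfmox import BloodConstants, BundleGeometry, CorrelationCoeffs


@pytest.fixture(scope="session")
def consts() -> BloodConstants:
    return BloodConstants()


@pytest.fixture(scope="session")
def geom() -> BundleGeometry:
    return BundleGeometry()


@pytest.fixture(scope="session")
def coeffs() -> CorrelationCoeffs:
    return CorrelationCoeffs()
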