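import numpy as np
import pytest

from hdnirs.forward import HeadModel, build_sensitivity
from hdnirs.probe import build_hd_layout, build_sparse_layout
from hdnirs.recon import stack_multispectral


@pytest.fixture(scope="session")
def sparse_layout():
    return build_sparse_layout()


@pytest.fixture(scope="session")
def hd_layout():
    return build_hd_layout()


@pytest.fixture(scope="session")
def head(sparse_layout, hd_layout):
    # 8 mm lateral sampling keeps the session-wide fixtures light
    return HeadModel.for_layout(sparse_layout, hd_layout, spacing=8.0)


@pytest.fixture(scope="session")
def S_sparse(sparse_layout, head):
    return build_sensitivity(sparse_layout, head)


@pytest.fixture(scope="session")
def S_hd(hd_layout, head):
    return build_sensitivity(hd_layout, head)


@pytest.fixture(scope="session")
def system_hd(S_hd):
    return stack_multispectral(S_hd)


@pytest.fixture(scope="session")
def system_sparse(S_sparse):
    return stack_multispectral(S_sparse)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
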