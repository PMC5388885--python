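import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_crb():
    """Three species, two of which share a barcode: A->X, B->X, C->Y.

    The classic hand-enumerable case: with only A and C in the reference,
    both X and Y look species-unique although X is shared in truth.
    """
    from barcodekit.refmodel import build_crb
    from barcodekit.seqio import BarcodeRecord

    X = "ACGTACGTAC"
    Y = "TTGTACGTAC"
    records = [
        BarcodeRecord("Aster alpha", "A1", "rbcL", X),
        BarcodeRecord("Aster beta", "B1", "rbcL", X),
        BarcodeRecord("Carex gamma", "C1", "rbcL", Y),
    ]
    return build_crb(records, combine=None)
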