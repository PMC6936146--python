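import numpy as np
import pytest

import gamnorm as gn


@pytest.fixture
def toy_coseg() -> gn.CosegregationMatrix:
    """Three contiguous bins A1-A3 observed by three NPs.

    NP1 and NP3 capture the whole A1..A3 fragment; NP2 captures only A1.
    Detection rows: A1=(1,1,1), A2=(1,0,1), A3=(1,0,1).
    """
    binning = gn.GenomeBinning.single(3, resolution=1_000_000)
    det = np.array([[1, 1, 1],
                    [1, 0, 1],
                    [1, 0, 1]])
    return gn.CosegregationMatrix(binning, ("NP1", "NP2", "NP3"), det)


def random_symmetric(n: int, seed: int, low: float = 0.1,
                     high: float = 1.0) -> np.ndarray:
    rng = np.random.default_rng(seed)
    a = rng.uniform(low, high, (n, n))
    return (a + a.T) / 2


@pytest.fixture
def signed_matrix() -> gn.ContactMatrix:
    """Small signed symmetric contact matrix on a 6-bin chromosome."""
    rng = np.random.default_rng(42)
    a = rng.normal(size=(6, 6))
    a = (a + a.T) / 2
    return gn.ContactMatrix(gn.GenomeBinning.single(6), "chr1", a)
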