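import numpy as np
import pytest

from longasv.seqio import QualRead


def qread(seq, q=93, rid="r1"):
    """Build a QualRead with constant (or explicit) qualities."""
    quals = np.full(len(seq), q, dtype=np.int16) if np.isscalar(q) \
        else np.asarray(q, dtype=np.int16)
    return QualRead(rid, seq, quals)


@pytest.fixture()
def rng():
    # fresh, order-independent stream per test
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_community():
    """Two distant strains with multi-copy alleles, short amplicons."""
    from longasv.simulate import make_alleles
    return make_alleles(2, [[3, 1, 1], [2, 1]], divergence=3, seed=7,
                        length=300)
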