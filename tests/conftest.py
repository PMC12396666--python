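import numpy as np
import pytest

from loudsum import Audiogram, NarrowbandReferenceSet
from loudsum.loudness import AUDIOMETRIC_FREQUENCIES_HZ


@pytest.fixture(scope="session")
def refs() -> NarrowbandReferenceSet:
    return NarrowbandReferenceSet.default()


@pytest.fixture(scope="session")
def ifnoise_ref(refs):
    return refs.broadband_reference("IFnoise")


def flat_audiogram(level_db_hl: float) -> Audiogram:
    return Audiogram({
        ear: {f: float(level_db_hl) for f in AUDIOMETRIC_FREQUENCIES_HZ}
        for ear in ("L", "R")
    })


@pytest.fixture(scope="session")
def nh_audiogram() -> Audiogram:
    return flat_audiogram(0.0)


@pytest.fixture(scope="session")
def flat60_audiogram() -> Audiogram:
    return flat_audiogram(60.0)


def grid_search_level(fn, target_cu: float, step: float = 0.01) -> float:
    """Brute-force inversion oracle: finest-|error| level on a 0.01 dB grid."""
    lo = fn.l_cut - 25.0 / fn.m_lo - 5.0
    hi = fn.l_cut + 25.0 / fn.m_hi + 5.0
    levels = np.arange(lo, hi, step)
    cus = fn.cu_at_level(levels)
    return float(levels[np.argmin(np.abs(cus - target_cu))])
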