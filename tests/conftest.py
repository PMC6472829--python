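import numpy as np
import pytest

from corepromoter import PromoterInterval, PromoterRecord, load_default_pwms, default_thresholds
from corepromoter.simulate import load_promoter_variants

GENES = ["en", "drm", "Sema5c", "Ppa", "Cad74A", "noc", "opa"]
VARIANTS = ["WT", "mDPE", "mBridgeI", "mDPE_27_29"]


@pytest.fixture(scope="session")
def pwms():
    return load_default_pwms()


@pytest.fixture(scope="session")
def thresholds():
    return default_thresholds()


@pytest.fixture(scope="session")
def promoter_variants():
    return load_promoter_variants()


@pytest.fixture(scope="session")
def wt_records(promoter_variants):
    return {g: promoter_variants[(g, "WT")] for g in GENES}


def random_record(rng, length=120, window_start=-40, name="r"):
    stop = window_start + length - 1
    if window_start < 0 <= stop:
        stop += 1
    seq = "".join(rng.choice(list("ACGT"), size=length))
    return PromoterRecord(name, seq, PromoterInterval(window_start, stop))
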