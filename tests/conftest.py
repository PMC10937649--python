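import numpy as np
import pytest

from evalstats import load_fixture


@pytest.fixture
def rng():
    return np.random.default_rng(20240313)


@pytest.fixture
def table1():
    return load_fixture("table1_confusion")


@pytest.fixture
def table2():
    return load_fixture("table2_confusion_4x4")


@pytest.fixture
def fig2_masks():
    return load_fixture("fig2_masks")


def random_confusion_2x2(rng, max_count: int = 200):
    """A random 2x2 confusion matrix with all marginals nonzero."""
    from evalstats import BinaryConfusion

    while True:
        tp, tn, fp, fn = rng.integers(0, max_count, size=4)
        cm = BinaryConfusion(tp=int(tp), tn=int(tn), fp=int(fp), fn=int(fn))
        if (
            (cm.tp + cm.fp) > 0
            and (cm.tp + cm.fn) > 0
            and (cm.tn + cm.fp) > 0
            and (cm.tn + cm.fn) > 0
        ):
            return cm
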