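import warnings

import numpy as np
import pytest

from stabletrees import TimeTree, TraitTable


@pytest.fixture(autouse=True)
def _quiet_convergence_warnings():
    # short test chains legitimately miss the PSRF target; keep the
    # warning machinery exercised but uncaptured
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="PSRF target")
        yield


@pytest.fixture
def two_tip_star():
    """Root with two pendant tips, both of duration 1."""
    return TimeTree([-1, 0, 0], [0.0, 1.0, 1.0], [None, "A", "B"])


@pytest.fixture
def three_tip_tree():
    """((A:0.7,B:1.3):1.0,C:2.5); root age 2.5, all extant except none."""
    return TimeTree(
        [-1, 0, 0, 1, 1],
        [0.0, 1.0, 2.5, 0.7, 1.3],
        [None, None, "C", "A", "B"],
    )


@pytest.fixture
def five_tip_tree():
    parent = [-1, 0, 0, 1, 1, 2, 2, 3, 3]
    dur = [0.0, 1.0, 2.0, 1.5, 2.5, 1.0, 1.0, 0.5, 0.5]
    labels = [None, None, None, None, "E", "A", "B", "C", "D"]
    return TimeTree(parent, dur, labels)


@pytest.fixture
def five_tip_traits(five_tip_tree):
    rng = np.random.default_rng(42)
    return TraitTable({
        l: float(10.0 ** rng.normal(0, 0.8)) for l in five_tip_tree.tip_labels()
    })
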