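import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # expose tests/_oracles.py

from restconn.connectome import BinaryNetwork
from restconn.synthetic import CohortSpec


def make_network(adj, subject_id="s", sparsity=0.2):
    adj = np.asarray(adj, dtype=np.uint8)
    return BinaryNetwork(subject_id=subject_id, sparsity=sparsity, adjacency=adj)


@pytest.fixture
def small_cohort_spec():
    """A scaled-down cohort for fast unit tests of the generator."""
    return CohortSpec(
        n_patients=4, n_controls=4, n_regions=30, n_timepoints=120,
        n_modules=3, seed=0,
    )


@pytest.fixture
def chorded_cycle():
    """4-cycle A-B-C-D plus chord A-C."""
    return make_network(
        [[0, 1, 1, 1],
         [1, 0, 1, 0],
         [1, 1, 0, 1],
         [1, 0, 1, 0]]
    )
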