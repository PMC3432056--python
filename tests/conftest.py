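import logging

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tdbn import three_gene_example

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

# keep expected-warning log lines out of test output
logging.getLogger("tdbn").setLevel(logging.ERROR)


@pytest.fixture
def e3():
    """The canonical three-gene network: (v1 OR v3) > v1', (v1 AND v3) > v2',
    v2 ~ v3'."""
    return three_gene_example()


def row_order_counts(row0, row1):
    """Build a flat 8-cell count vector from the two printed table rows.

    Count tables are conventionally printed as two rows (output 0 on top)
    over the input columns 00, 01, 10, 11; the package stores cells by the
    concatenated bit index (input bits then output bit).
    """
    counts = np.zeros(8, dtype=np.int64)
    for col, (a, b) in enumerate(zip(row0, row1)):
        counts[(col << 1) | 0] = a
        counts[(col << 1) | 1] = b
    return counts
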