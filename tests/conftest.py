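import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

from bzipscreen.qpcr import delta_ct
from bzipscreen.screen import run_expression_screen
from bzipscreen.synthetic import (
    generate_expression,
    generate_qpcr,
    qpcr_replica_preset,
    replica_preset,
)


@pytest.fixture(scope="session")
def expr_preset():
    """Study-replica expression matrix, its manifest, and the screen output."""
    matrix, manifest = generate_expression(replica_preset(seed=1))
    result = run_expression_screen(matrix)
    return matrix, manifest, result


@pytest.fixture(scope="session")
def qpcr_preset():
    """Study-replica Ct table, its manifest, and the dCt profiles."""
    table, manifest = generate_qpcr(qpcr_replica_preset(seed=1))
    return table, manifest, delta_ct(table)
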