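import numpy as np
import pandas as pd
import pytest

from flowtarget import (
    ExpressionMatrix,
    build_flow_network,
    figure2_fixture,
    max_flow_push_relabel,
)


def make_matrix(values, genes=None, cancer=None, normal=None):
    """Build an ExpressionMatrix from a 2-D array and group sizes."""
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    genes = genes or [f"g{i}" for i in range(n_genes)]
    cancer = cancer if cancer is not None else n_samples // 2
    normal = normal if normal is not None else n_samples - cancer
    assert cancer + normal == n_samples
    samples = [f"c{i}" for i in range(cancer)] + [f"n{i}" for i in range(normal)]
    cond = {s: ("cancer" if s.startswith("c") else "normal") for s in samples}
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), cond)


@pytest.fixture(scope="session")
def fig2():
    return figure2_fixture()


@pytest.fixture(scope="session")
def fig2_solved(fig2):
    fn = build_flow_network(fig2.network, "G1", fig2.disease, fig2.candidates)
    fr = max_flow_push_relabel(fn)
    return fn, fr


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
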