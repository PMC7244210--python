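import numpy as np
import pandas as pd
import pytest

import clustercore as cc


@pytest.fixture(scope="session")
def toy_catalog():
    """Six reactions covering single genes, a complex, isoenzymes,
    a shared enzyme and a gene-free reaction."""
    rules = [
        ("R1", "pathA", "g1"),
        ("R2", "pathA", "g1 and g2"),
        ("R3", "pathB", "g3 or (g2 and g4)"),
        ("R4", "pathB", "g1 and g2"),  # shares R2's enzyme
        ("R5", "exchange", ""),
        ("R6", "pathC", "g5"),
    ]
    return cc.catalog_from_rules(rules)


@pytest.fixture(scope="session")
def toy_expression():
    data = pd.DataFrame(
        {
            "c1": [5.0, 3.0, 8.0, 2.0, 0.0],
            "c2": [1.0, 6.0, 0.0, 4.0, 7.0],
            "c3": [9.0, 2.0, 5.0, 1.0, 3.0],
        },
        index=["g1", "g2", "g3", "g4", "g5"],
    )
    return cc.ExpressionMatrix(data)


@pytest.fixture(scope="session")
def default_fixture():
    return cc.generate_fixture(cc.FixtureSpec(seed=0))


@pytest.fixture(scope="session")
def default_enzyme_expression(default_fixture):
    enz, _ = cc.compute_enzyme_expression(
        default_fixture.expression, default_fixture.catalog
    )
    return enz


def random_instance(seed, n_enzymes=None, n_contexts=None, n_clusters=None):
    """Random enzyme matrix + cluster assignment for oracle checks."""
    rng = np.random.default_rng(seed)
    n_enzymes = n_enzymes or int(rng.integers(6, 51))
    n_contexts = n_contexts or int(rng.integers(3, 11))
    n_clusters = n_clusters or int(rng.integers(2, min(6, n_enzymes)))
    values = 10.0 ** rng.normal(1.0, 1.2, size=(n_enzymes, n_contexts))
    values[rng.random(values.shape) < 0.15] = 0.0
    # every enzyme keeps at least one positive value
    for i in range(n_enzymes):
        if (values[i] == 0).all():
            values[i, int(rng.integers(n_contexts))] = 10.0 ** rng.normal(1.0, 1.2)
    enzyme_ids = [f"e{i:03d}" for i in range(n_enzymes)]
    contexts = [f"s{j:02d}" for j in range(n_contexts)]
    enz = cc.EnzymeExpressionMatrix(
        pd.DataFrame(values, index=enzyme_ids, columns=contexts)
    )
    labels = rng.integers(1, n_clusters + 1, size=n_enzymes)
    labels[:n_clusters] = np.arange(1, n_clusters + 1)  # no empty cluster
    assignment = dict(zip(enzyme_ids, (int(c) for c in labels)))
    return enz, assignment
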