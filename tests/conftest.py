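import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import hrrgcn as h

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def small_matrix() -> h.ExpressionMatrix:
    """Deterministic 6-probeset x 5-array matrix with no degenerate rows."""
    rng = np.random.default_rng(42)
    ids = [f"PS{i:03d}" for i in range(6)]
    arrays = [f"A{j:02d}" for j in range(5)]
    return h.ExpressionMatrix(ids, arrays, rng.normal(8.0, 1.0, size=(6, 5)))


@pytest.fixture(scope="session")
def planted_compendium():
    """300-gene, 40-array compendium with two 35-gene modules, one fruit-only.

    Module size exceeds the HRR30 cutoff so that every member's reciprocal
    rank neighbourhood is intra-module — the separability condition for
    graph clustering at that threshold.
    """
    modules = [
        h.ModuleSpec("M1", size=35, within_correlation=0.9,
                     planted_terms=("GO:0000101",)),
        h.ModuleSpec("M2", size=35, within_correlation=0.9,
                     active_conditions={"organ": "fruit"},
                     planted_terms=("GO:0000102",)),
    ]
    return h.generate(n_genes=300, n_arrays=40, modules=modules, seed=7)


@pytest.fixture(scope="session")
def two_cliques_edges():
    """Two 4-cliques joined by a single bridge edge, unit weights."""
    import itertools

    import pandas as pd

    c1 = [f"L{i}" for i in range(4)]
    c2 = [f"R{i}" for i in range(4)]
    rows = [(a, b, 1.0) for clique in (c1, c2) for a, b in itertools.combinations(clique, 2)]
    rows.append((c1[0], c2[0], 1.0))
    return pd.DataFrame(rows, columns=["probeset_a", "probeset_b", "weight"])
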