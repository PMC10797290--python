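import numpy as np
import pandas as pd
import pytest

import nescore as ns


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def tiny_expr():
    """3 genes x 2 samples, kind=log (small values allowed)."""
    df = pd.DataFrame(
        [[3.0, 1.0], [2.0, 2.0], [1.0, 3.0]],
        index=["g1", "g2", "g3"],
        columns=["s1", "s2"],
    )
    return ns.ExpressionMatrix(df, "log")


@pytest.fixture(scope="session")
def atlas():
    """Planted single-cell atlas shared across tests (read-only)."""
    cfg = ns.SimConfig(seed=11, n_qc_violators=12)
    counts, ann, truth = ns.simulate_sc_atlas(cfg)
    return counts, ann, truth


@pytest.fixture(scope="session")
def bulk_cohort():
    cfg = ns.SimConfig(seed=13)
    return ns.simulate_bulk_cohort(cfg)


@pytest.fixture(scope="session")
def evidence_streams(atlas):
    """Truth markers diluted with decoys, mimicking external evidence."""
    counts, _, truth = atlas
    gen = np.random.default_rng(99)
    bg = [
        g
        for g in counts.genes
        if g not in set(truth.up) | set(truth.down) and not g.startswith("MT-")
    ]
    meta = set(truth.up) | set(truth.down) | set(gen.choice(bg, 200, replace=False))
    modules = set(truth.up) | set(gen.choice(bg, 100, replace=False))
    return meta, modules


@pytest.fixture(scope="session")
def derived(atlas, evidence_streams):
    counts, ann, _ = atlas
    meta, modules = evidence_streams
    return ns.derive_signature(counts, ann, meta, modules)
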