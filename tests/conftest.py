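import numpy as np
import pandas as pd
import pytest

import lrcomm as lc


@pytest.fixture
def small_expr() -> pd.DataFrame:
    """5 genes x 6 samples, distinct values, no zeros."""
    rng = np.random.default_rng(11)
    x = rng.lognormal(1, 1, size=(5, 6))
    return pd.DataFrame(
        x, index=[f"g{i}" for i in range(5)], columns=[f"s{j}" for j in range(6)]
    )


@pytest.fixture
def planted_fixture():
    """Standard planted-pair fixture: 200 genes x 20 samples, 20 pairs
    forced into the top decile of >=80% of samples."""
    spec = lc.FixtureSpec(
        seed=101, n_genes=200, n_samples=20, n_planted_pairs=20,
        planted_quantile=0.9, planted_sample_fraction=0.8,
    )
    return lc.make_expression(spec)


@pytest.fixture
def lr_csv(tmp_path):
    """Three-row LR source file with one duplicate row."""
    p = tmp_path / "src1.csv"
    p.write_text("ligand,receptor\nTNF,TNFRSF1A\nIL6,IL6R\nTNF,TNFRSF1A\n")
    return p


def make_catalog(pairs, species="human", source="srcX", evidence=lc.EVIDENCE_PREDICTED):
    """Build a catalog directly from (ligand, receptor) keys."""
    cat = lc.LRCatalog(species=species)
    for lig, rec in pairs:
        cat.add(
            lc.LRPair(
                ligand_id=lig, receptor_id=rec, species=species,
                sources=frozenset({source}), evidence=evidence,
            )
        )
    return cat
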