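import numpy as np
import pytest

import drugformer as df


@pytest.fixture(scope="session")
def tiny_model_config():
    """Small architecture used throughout the unit tests."""
    return df.ModelConfig(embed_dim=8, n_heads=2, n_tokens=8, encoder_count=2, ffn_hidden=16)


@pytest.fixture(scope="session")
def tiny_dataset():
    cfg = df.SyntheticConfig(
        n_cells=60, n_genes=40, n_signature_genes=8, effect_size=3.0,
        score_cluster_spread=0.0, n_score_clusters=4, seed=7,
    )
    return df.generate_dataset(cfg)


@pytest.fixture(scope="session")
def tiny_graph(tiny_dataset):
    return df.build_graph(tiny_dataset.scores, tau=0.05)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
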