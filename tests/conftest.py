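import warnings

import numpy as np
import pytest

import schsc
from schsc.inference_metrics import embed_all, final_clustering
from schsc.training import TrainConfig, train


@pytest.fixture(scope="session")
def fixture_small():
    """The preconfigured 5-cluster synthetic instance (spec, counts, labels)."""
    spec, cm, labels, truth = schsc.fixture_small()
    return spec, cm, labels, truth


@pytest.fixture(scope="session")
def preprocessed(fixture_small):
    _, cm, labels, _ = fixture_small
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # p > n_genes keeps all genes
        data = schsc.preprocess(cm, p=2000)
    return data, labels


@pytest.fixture(scope="session")
def trained(preprocessed):
    """One full default-config training run on the fixture, shared across
    tests; returns (model, history, graph, X_filtered, clustering, labels)."""
    data, labels = preprocessed
    cfg = TrainConfig(K_target=5)
    model, history, graph, Xf = train(data, cfg)
    emb = embed_all(Xf, graph.adjacency_sym, model)
    result = final_clustering(emb, k=cfg.k, K_target=5, seed=cfg.seed)
    return model, history, graph, Xf, result, labels


def random_unit_rows(rng, m, d):
    z = rng.normal(size=(m, d))
    return z / np.linalg.norm(z, axis=1, keepdims=True)
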