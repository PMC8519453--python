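import numpy as np
import pytest

from embed2net import (CorpusSpec, Embedding, PreprocessConfig,
                       generate_corpus, load_synonym_table,
                       preprocess_corpus, train_embedding)
from embed2net.embedding import EmbeddingConfig
from embed2net.synthetic import write_synonym_table


@pytest.fixture(scope="session")
def toy_embedding() -> Embedding:
    """Hand-set 6-term embedding with two tight clusters and one outlier."""
    vectors = np.array([
        [1.0, 0.0, 0.0],
        [0.99, 0.1, 0.0],
        [0.97, 0.15, 0.1],
        [0.0, 1.0, 0.0],
        [0.05, 0.99, 0.0],
        [0.0, 0.0, 1.0],
    ])
    vocab = ["abc1", "abc2", "abc3", "xyz1", "xyz2", "lone1"]
    types = {t: "gene" for t in vocab[:5]}
    types["lone1"] = "drug"
    return Embedding(vocab, vectors, types)


@pytest.fixture(scope="session")
def random_embedding() -> Embedding:
    rng = np.random.default_rng(42)
    vocab = [f"t{i:03d}" for i in range(40)]
    return Embedding(vocab, rng.normal(size=(40, 8)))


@pytest.fixture(scope="session")
def small_corpus():
    """Small planted-structure corpus with its ground truth and synonym table."""
    spec = CorpusSpec(n_documents=600, n_gene_groups=4, gene_group_size=6,
                      n_disease_groups=2, disease_group_size=4, n_drugs=6,
                      background_vocab=200, seed=7)
    documents, truth = generate_corpus(spec)
    return documents, truth


@pytest.fixture(scope="session")
def small_synonym_table(small_corpus, tmp_path_factory):
    _, truth = small_corpus
    path = tmp_path_factory.mktemp("syn") / "synonyms.tsv"
    write_synonym_table(path, truth)
    return load_synonym_table(path)


@pytest.fixture(scope="session")
def small_embedding(small_corpus, small_synonym_table):
    documents, truth = small_corpus
    seqs = preprocess_corpus(documents, PreprocessConfig(),
                             small_synonym_table)
    config = EmbeddingConfig(dimension=48, epochs=3, min_count=3, seed=11)
    return train_embedding(seqs, config, truth.entity_types)
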