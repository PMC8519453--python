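# embed2net

Text-mining pipeline for systems biology: train word2vec-style embeddings on
a biomedical corpus with **synonym normalization**, validate the embedding
against knowledgebase structure, extract **cosine-similarity gene–gene
networks**, and evaluate those networks as priors for a **Chebyshev spectral
graph-convolutional classifier** on gene expression data.

The package is aimed at computational biologists who want to test whether
literature-derived term similarities carry usable biological signal: do genes
in the same pathway sit closer in embedding space than random gene pairs, and
does a network built from those similarities help a graph-structured
classifier predict a clinical endpoint?

## The model in brief

**Embeddings.** Skip-gram with negative sampling: for each (center, context)
token pair the training objective is

    log σ(u_c · v_o) + Σ_{i=1..k} E_{w~P_n} [ log σ(−u_c · v_w) ],

with dynamic context windows (size 5), minimum token count 5, 300
dimensions, and unigram^0.75 negative sampling. Before training, synonyms of
genes, diseases and drugs are replaced by their preferred terms
("p73" → "tp73", "mood disorder" → "mood_disorders"), so all mentions of a
concept pool their contexts into a single vector.

**Validation.** Relatedness is cosine similarity. Within each knowledgebase
group (pathway, biological process, disease-ontology group) with x member
terms present in the embedding, the x·(x−1)/2 pairwise cosines are
summarized by quartiles; the trend of the median against group size is
fitted with the decay curve f(x) = (x^a + b)^−1 or a Loess smoother.
Protein-protein-interaction pairs and drug pairs sharing target genes are
compared against equally sized random-pair arms.

**Networks.** A gene–gene network connects two gene terms when their cosine
reaches a threshold t (default 0.65), weighted by the cosine. Controls:
an 8-out random graph (each vertex draws 8 partners with repetition,
collapsed to a simple graph), vertex permutation, and random edge weights.

**Graph-CNN.** Signals on the network's main connected component are
filtered with K-term Chebyshev polynomials in the rescaled normalized
Laplacian, y = Σ_k θ_k T_k(L̃) x (K = 7, i.e. 6-hop-localized filters);
two convolutional layers of 32 filters with size-2 max pooling on a
heavy-edge-matching coarsening hierarchy, then fully connected layers of
512 and 128 units and a 2-class softmax. Performance is measured by
stratified 10-fold cross-validation: AUC, accuracy and weighted F1 in
percent, reported as mean ± SEM across folds.

Because the original 16M-abstract corpus and the clinical microarray series
are far beyond desk scale, the package ships first-class synthetic
generators: a corpus with planted entity co-occurrence groups and synonym
variants, a matching knowledgebase (GMT groups, PPI pairs, drug targets),
and graph-smooth two-class expression data (40:60 imbalance).

## Worked example

```python
from embed2net import (CorpusSpec, EntityGroup, PreprocessConfig,
                       generate_corpus, group_similarity_summary,
                       load_synonym_table, preprocess_corpus,
                       train_embedding)
from embed2net.embedding import EmbeddingConfig
from embed2net.synthetic import write_synonym_table

documents, truth = generate_corpus(CorpusSpec(seed=1))
write_synonym_table("synonyms.tsv", truth)
table = load_synonym_table("synonyms.tsv")
tokens = preprocess_corpus(documents, PreprocessConfig(), table)
emb = train_embedding(tokens, EmbeddingConfig(dimension=100, seed=1),
                      truth.entity_types)
groups = [EntityGroup(gid, "gene", frozenset(m))
          for gid, m in truth.gene_groups.items()]
for s in group_similarity_summary(emb, groups, min_size=10, max_size=3000):
    print(s.group_id, s.size, round(s.median, 3))
```

prints one line per planted pathway-like group, e.g.

```
gene_group_00 10 0.97
gene_group_01 10 0.965
...
gene_group_09 10 0.959
```

— the median within-group cosine sits near 0.96 for every planted group,
while the median over 2000 random gene pairs on the same embedding is about
0.46: group structure planted in the corpus is recovered by the embedding,
the qualitative pattern the validation stage is designed to detect.

The same pipeline is scriptable: `embed2net preprocess`, `train-embed`,
`neighbors`, `validate`, `build-net`, `control-net`, `import-net`,
`prep-expr`, `gcnn-cv`, `simulate`, and `run --config pipeline.yaml` for a
multi-stage run with one global seed.

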