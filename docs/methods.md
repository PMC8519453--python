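# Methods

This note documents the models, the synthetic data, the numerical choices,
and the limits of what the test suite shows.

## Corpus preprocessing

Normalization lowercases, replaces every non-word character by whitespace,
drops purely numeric tokens (an integer pattern after punctuation removal,
so alphanumeric gene symbols like `brca1` survive), and optionally
lemmatizes. The lemmatizer is a small rule-based component written for this
package: an exception dictionary for common irregular forms plus
conservative suffix rules (plural `-s/-es/-ies`, past `-ed/-ied`,
progressive `-ing` with consonant undoubling). It is intentionally modest —
a stand-in for the unspecified lemmatization step of classical text
pipelines — and never touches tokens containing digits or underscores.

Synonym substitution is dictionary-based: greedy longest match,
left-to-right, non-overlapping, over the token sequence. Table phrases are
matched on their surface form first and on their lemmatized form second.
Multi-word preferred terms are emitted as single underscore-joined tokens
(`mood_disorders`), so substitution never increases the token count. A
synonym phrase mapping to two distinct preferred terms is rejected at load
time: silent resolution of ambiguous dictionary entries is not auditable.

## Embedding trainer

Skip-gram with negative sampling, written in numpy:

* dynamic windows — the effective window per center is uniform on
  1..`window` (default 5), as in the reference word2vec implementation;
* unigram^0.75 negative sampling, 5 negatives;
* frequent-token subsampling with the conventional threshold 1e-3
  (`subsample=0` disables it; the toy-scale tests do, because on a
  few-thousand-token corpus the threshold would decimate exactly the
  planted tokens it is meant to protect);
* learning rate decaying linearly from 0.025 to 1e-4 over the run;
* updates applied in vectorized mini-batches of (center, context,
  negatives) triples with a sort/segment-sum scatter-add.

Training is single-threaded and driven by one seeded generator, so runs are
bit-reproducible; `deterministic_mode` exists in the config for interface
completeness but the implementation is always deterministic. Defaults
(dimension 300, window 5, min_count 5, 5 epochs) follow common biomedical
word2vec practice; the synthetic-corpus experiments in the test suite use
dimension 100 and the default 5 epochs, a deliberate desk-scale choice that
leaves the qualitative group-structure signal intact.

## Validation statistics

Within-group similarity uses all pairwise cosines of the group members
present in the embedding, summarized by quartiles under numpy's
linear-interpolation convention (declared so oracle tests can be exact).
Group-size filters default to the pathway bounds (10, 3000) for genes and
are parameters everywhere. The decay curve f(x) = (x^a + b)^-1 is fitted by
bounded nonlinear least squares (a > 0, b > -0.999), initialized at (1, 0)
with multi-start over a in {0.1, 0.5, 1, 2}; the Loess trend is local
linear regression (statsmodels lowess) with default span 0.75. Random-pair
arms are drawn uniformly without replacement, excluding the positive pairs,
from the embedding vocabulary restricted to the entity type under study.

## Similarity networks

Edges are included with a closed bound (cosine >= t) so the canonical
threshold 0.65 includes equality. Components are ordered by size with ties
broken by the lexicographically smallest member. `threshold_for_size`
processes observed edge weights in descending order through a union-find,
handling tied weights as a block, and returns the largest threshold whose
main component reaches the target — equivalent to, but much faster than, an
exhaustive scan (which remains the test oracle). The k-out random control
draws, for every vertex, k partners uniformly from the other vertices with
repetition and collapses duplicates and reciprocal draws into a simple
undirected graph; on 6888 vertices with k = 8 this yields the expected
degree distribution with mean just under 2k (≈ 15.98), median 16 and
standard deviation ≈ 2.8.

## Graph-CNN

The classifier implements Chebyshev spectral graph convolution:
y = Σ_{k<K} θ_k T_k(L̃) x with L̃ = 2L/λ_max − I and the symmetric
normalized Laplacian L. Filters of order K are exactly (K−1)-hop localized;
K defaults to 7 per layer. Pooling uses a greedy heavy-edge-matching
coarsening hierarchy (vertices visited in ascending degree order; matched
pairs maximize w·(1/d_u + 1/d_v)), with disconnected zero-feature padding
vertices so every level has exactly twice the vertices of the next and
size-2 max pooling is a reshape. Padded vertices are masked to zero after
every convolution, so they provably never influence real outputs.

Architecture: two convolutional layers of 32 filters, pooling 2 after each,
fully connected layers of 512 and 128 units, 2-class softmax. Training is
mini-batch Adam (lr 1e-3, batch 32) on cross-entropy with dropout 0.5 on
the fully connected layers; forward and backward passes are hand-written in
float32 numpy (the backward pass through the Chebyshev expansion uses a
Clenshaw-style reverse recurrence, K sparse products instead of O(K²)),
and were verified against numerical differentiation. Inputs stay
non-negative as the data protocol requires; internally the model freezes a
centering/scale constant from the training fold at fit time (a
preconditioner, not a data transformation — without it, mean-shifted inputs
saturate the softmax at initialization and gradient descent stalls at the
class prior). Per-fold convergence is recorded (final loss finite and not
above the initial loss) and reported alongside the metrics rather than
silently averaged.

Cross-validation is stratified 10-fold (protecting the 40:60 class
imbalance), metrics are AUC, accuracy and support-weighted F1 in percent,
with SEM = across-fold sd / √folds. The cross-validated experiment in the
acceptance suite trains 20 epochs per fold; on the synthetic signal the
optimizer converges within about 10.

## Synthetic data

The corpus generator plants co-occurrence groups: each document is "about"
one gene group (probability 0.7), one disease group (0.2) or one drug
(0.1). Members of the topical group are mentioned with probability
q = sqrt(within_rate), so two members co-occur in a topical document at the
stated within_rate (default 0.3); every off-topic entity is mentioned with
the background rate (default 0.01 per document). Mentions are placed as a
contiguous block inside Zipf-distributed background text so that a window-5
trainer actually observes the planted co-occurrence; documents average 40
background tokens. Each entity has synonym variants (default 2; diseases
include a multi-word variant to exercise phrase matching) emitted in place
of the preferred form with probability synonym_prob (default 0.5). Drugs
are mentioned together with a sample of their target genes. The
knowledgebase emitted from the ground truth contains exactly the planted
groups, all within-group gene pairs as PPIs, and drug-target sets built so
drug pairs realize shared-target counts of 0, 1–5 and 6–9.

The expression generator draws class-0 samples i.i.d. Gaussian per gene and
adds, for class-1 samples (40% of 300 by default, emulating a 393:576
imbalance), a mean shift on a connected breadth-first signal subnetwork,
attenuated as exp(−0.5 · hops) from the seed vertex; the matrix is then
shifted to a non-negative range. What this does *not* emulate: real
microarray noise structure, gene-gene correlation outside the planted
signal, batch effects, and realistic language — tests passing on these data
show the machinery recovers planted structure, not that the method works on
clinical data.

## The synonym-substitution comparison

Substituting synonyms pools all evidence about a concept into one vector.
Whether that raises the measured within-group cosine depends on the
training regime, and the generator makes the mechanism visible: variants
are contextually exchangeable by construction, so the only cost of leaving
them unmerged is that each surface form sees a fraction of the data. In a
strongly under-trained regime (few epochs relative to corpus size) all
group members cling to a shared dominant context direction and pairwise
cosines sit near a ceiling; there, *less* data per token means *higher*
within-group cosine, and merging synonyms appears to hurt. Once vectors are
trained to (near) convergence they individuate, the ceiling disappears, and
the split-data arms pay for their extra estimation noise with lower
cosines — the direction the substitution procedure is designed to produce.
The comparison experiment therefore trains to convergence at desk scale
(dimension 50, 10 epochs on the default corpus), where the data-ablation
diagnostic (mean within-group cosine as a function of corpus fraction) is
no longer in the inverted regime.

## Orchestration

`run_pipeline` executes named stages in order, derives per-stage seeds as
global seed + stage index, passes artifacts through an in-memory context,
writes every output under the run directory, and records a JSON manifest
(stage, parameters, seed, outputs, wall time). A failed stage aborts the
run with the stage named; re-running an identical config reproduces
identical artifacts.

## Known limitations

* The lemmatizer is rule-based and English-only; stemming-grade errors on
  rare morphology are expected and harmless downstream (tokens with digits
  or underscores are never altered).
* The embedding trainer applies mini-batch (not strictly sequential) SGNS
  updates; with the small batch default this matches reference behavior
  statistically but not update-for-update.
* `threshold_for_size` assumes the threshold is chosen among observed pair
  weights; with all-pairs cosine input the graph is complete at the minimum
  weight, so any target up to the term count is reachable.
* The graph-CNN supports exactly the two-conv/two-pool architecture family
  of its reference design; pooling sizes other than 2 are rejected.
* Quantile normalization of expression inputs is assumed done upstream;
  only probe collapse, the non-negative shift and graph alignment are
  implemented here.
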