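# Methods

`mdlinker` predicts which of five evidence types — genetics, epigenetics,
circulating miRNAs, tissue expression, miRNA–target interaction — link an
miRNA to a disease.  The method embeds an attributed multi-layer
miRNA–disease network (one layer per evidence type) and classifies candidate
(miRNA, disease, type) triples from the concatenated endpoint embeddings.
This note records the model, its assumptions, the defaults, and what the
synthetic benchmark does and does not establish.

## Disease semantic similarity

Disease relationships are given as dot-separated hierarchy tree codes
(MeSH-style).  Truncating the last segment of a code yields its parent, so
each disease P induces an ancestor closure N_P.  Semantic values decay by a
factor α per generation, taking the best chain when a disease sits at
several tree positions:

    D_P(P) = 1,    D_P(t) = α · max{ D_P(t') : t' ∈ children(t) ∩ N_P }

    sim(P, Q) = Σ_{t ∈ N_P ∩ N_Q} (D_P(t) + D_Q(t)) / (DV(P) + DV(Q)),
    DV(P) = Σ_{t ∈ N_P} D_P(t)

α defaults to 0.5 (the customary choice for this decay scheme) and is
configurable.  Tree positions that carry no disease name in the input are
retained as anonymous DAG nodes; multiple positions of the same disease
collapse onto one node via the max.  `sim` is symmetric, lies in [0, 1] and
is exactly 1 on the diagonal.

## miRNA sequence similarity (chaos game representation)

Each precursor sequence is mapped into the unit square by the chaos game:
corners A=(0,0), C=(0,1), G=(1,1), U=(1,0); starting from the centre, each
nucleotide moves the point halfway toward its corner.  The square is divided
into 2^k × 2^k subregions (k = 3 by default, 64 regions) and the visit
frequencies of the L iterated points (the seed point is not counted) form a
profile.  The region distance between two miRNAs is the Frobenius distance
between profiles, inverted to a similarity by min–max scaling
(sim = 1 − d/d_max, unit diagonal).  Resolution, corner assignment and the
inversion are all configuration surface: the literature describes the
region-distance idea without fixing these constants, so they are explicit
package choices.

## Node attributes (biased second-order walks + skip-gram)

Each node class gets NE-dimensional attributes (NE = 128) from its own
similarity network: second-order random walks with return parameter p = 1
and in–out parameter q = 2 (favouring local, similarity-weighted
exploration) generate a corpus — 10 walks of length 80 per node — and
skip-gram with negative sampling (window 5, 5 negatives, 5 epochs, unigram
noise^0.75) trains one vector per node.  The trainer is a vectorised
minibatch SGD implementation; batches are sized so that any node appears
only a bounded number of times per update, because accumulating many
stale-gradient contributions for the same embedding row diverges on small
dense graphs.  A node with no walk context keeps a zero vector and is
reported.

The full weighted similarity graph is used (no top-K sparsification): the
walk law weights transitions by similarity directly, and the networks at
package scale are dense.

## Multiplex embedding

The association network has the same node set in every layer; layer r holds
the bipartite miRNA–disease edges of evidence type r.  Node i's embedding in
layer r is

    v_{i,r} = β_r D_z^T x_i + b_i + u_{i,r}

* **attribute term** — a learned linear map D_z of the node's attributes,
  one per node class z ∈ {miRNA, disease};
* **base embedding** b_i = h_z(x_i), an affine map shared across layers
  (the inductive parameterisation: every component is a function of the
  attributes, so the model extends to nodes unseen during training);
* **layer term** u_{i,r} = α_r M_r^T D_i a_{i,r}, where the edge embedding
  d_{i,r} starts from an affine map g_{z,r}(x_i) and is aggregated K = 2
  levels over layer-r neighbours (mean aggregator with tanh, max-pooling
  optional; a node isolated in a layer passes its previous level through, so
  every node is embedded in every layer), D_i stacks the edge embeddings of
  all m = 5 layers, and a_{i,r} = softmax(w_r^T tanh(W_r D_i)) is a
  per-target-layer attention head that lets information flow across layers.

α_r and β_r are fixed at 1 by default (trainable via config).  Dimensions:
BE = DE = 32, attention hidden size 16.

Training maximises skip-gram likelihood over within-layer walks (the
bipartite layers make every walk alternate miRNA/disease, i.e. the
miRNA–disease–miRNA meta-path), with 5 negatives drawn from the same node
class's unigram^0.75 distribution.  All gradients — through the attention
head and the aggregation chains — are derived analytically and applied by
plain SGD: dense shared parameters take batch-mean gradients (learning rate
0.05, linear decay), per-node context rows take per-pair updates.  Walk
corpus defaults (6 walks of length 10 per node per layer, window 3,
2 epochs) were sized once for the ~100-node problem scale this package
targets; held-out performance on the planted benchmark was flat across
substantially larger corpora, so the smaller corpus is the default.

## Triple features, negatives, classifier

A candidate triple (m, d, r) is represented by [v_{m,r} ‖ v_{d,r}]
(64 dims).  Since confirmed negatives do not exist, reliable negatives for
type r are the unconfirmed triples whose Euclidean distance from the mean
positive feature f_avg,r strictly exceeds the mean such distance dis_r;
training samples as many negatives as positives per type.  One random
forest (200 trees, √-features per split, seeded) is shared across the five
types — the type is already encoded in the layer-specific embedding halves;
a per-type-classifier mode exists behind a flag.

## Evaluation protocols

* **CV-Type** (10-fold over associated pairs): for each held-out pair all
  five type scores are ranked; a hit means the top type is a true type.
  Top-1 precision = hits / test pairs; top-1 recall = hits / true test
  triples; F1 is their harmonic mean.  Ties break by the fixed type order
  (genetics, epigenetics, circulating, target, tissue).
* **CV-Triple** (10-fold over triples): held-out positives against equally
  many pool negatives, reporting ROC-AUC (tie-aware rank statistic), AUPR
  (step integration) and F1 at probability threshold 0.5.

Attribute features depend only on the similarity networks and are shared
across folds; the multiplex embedding, the negative pools and the classifier
are retrained per fold from training edges only, and in CV-Type every triple
of a held-out pair is excluded from the training universe, so no label
information leaks.  Negatives for the test fold are drawn from the pool
excluding the training negatives.

**Consensus ranking** repeats the full stochastic pipeline n times with
distinct derived seeds, collects each run's top-scored unknown triples
(2k per run), and ranks by appearance frequency, ties by mean probability.

## Synthetic benchmark

The planted generator matches miRNA blocks to disease blocks 1:1 (default
60 miRNAs, 40 diseases, 3 blocks) and plants triples independently per type
at probability 0.3 within matched blocks and 0.02 across; with probability
0.5 an associated pair gains one additional type, emulating the prevalence
of multi-type associations in curated databases.  Disease blocks occupy
separate subtrees of the generated hierarchy; miRNA blocks descend from
per-block ancestor sequences with 5% point mutation.  Sequence lengths are
drawn from 60–110 nt (precursor-like).  Every fixture is a pure function of
its seed.

What the benchmark shows: the pipeline recovers planted cross-layer block
structure well above chance under leakage-free cross-validation, and the
whole chain (similarity → walks → multiplex embedding → negative sampling →
classification → metrics) is deterministic given a master seed.  What it
does not show: performance on real curated data, whose degree
distributions, ontology depths and type imbalances the generator does not
imitate.

### A measured limitation of distance-filtered negatives

With symmetric planted blocks the mean-distance negative filter is
block-blind: for concatenated features, the squared distance to f_avg,r
decomposes into each endpoint's squared distance to its class centroid, which
is the same whether or not the endpoints' blocks match.  The negative pool
therefore retains the universe share (~20–25%) of within-matched-block
candidates.  Those are information-theoretically hard: with types planted
independently per pair, no classifier can separate a held-out within-block
positive from an unplanted within-block candidate beyond the weak
multi-type-correlation signal.  A Bayes-optimal scorer given the generator's
true posteriors (`mdlinker.synthetic.bayes_optimal_auc`) reaches CV-Triple
AUC ≈ 0.89 under this pool composition (≈ 0.98 if the pool were purely
cross-block); the pipeline's measured AUC sits at that ceiling, as the
acceptance benchmark shows.  On real data, where disease clusters are
asymmetric and type prevalences skewed, the filter is less degenerate.

Similarly, CV-Type top-1 precision on the planted benchmark is bounded by
E[#true types | ≥1]/5 ≈ 0.43 (types are exchangeable given the pair), and
the pipeline attains ≈ 0.43 — i.e. both protocols extract essentially all
the information the generator plants.

## Numerical choices and degenerate inputs

* All randomness flows from one master seed through derived child seeds;
  repeated runs are bit-identical within one environment.
* Softmax attention is computed with max-subtraction; sigmoid arguments are
  clipped at ±30; skip-gram losses use log-clamping at 1e-12.
* An empty layer trains no walks but still receives embeddings (isolated
  pass-through + attention over the other layers).
* Degenerate pools (all candidates at exactly the mean distance) are empty
  and raise at sampling time; pools smaller than the positive count return
  everything with a warning.
* Identical sequences give region distance 0 and similarity 1; when all
  sequences are identical the whole similarity matrix is 1.

## Problem sizes

Defaults target networks of a few hundred nodes (the planted benchmark uses
100).  The random-forest size (200 trees) and the embedding corpus sizes
above were fixed once against that scale; both are configurable for larger
studies.
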