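# Methods

`repath` implements case-based, path-explainable drug repositioning on a
heterogeneous biomedical knowledge graph (KG), together with the synthetic
test bed and the evaluation protocols used to validate it. This note
records the model, the design decisions that were genuinely open, the
numerical choices, and what the synthetic experiments do and do not show.

## Link prediction: retrieve, reuse, revise

**Retrieve.** Each drug *u* is summarized by a binary relation profile
r_u ∈ {0,1}^|R|: one indicator per relation type, set when the drug has at
least one outgoing edge of that type. Drug–drug similarity is the cosine
S_uv = r_uᵀr_v / (‖r_u‖‖r_v‖), defined as 0 when either profile is empty.
The k most similar drugs that have known indications serve as *cases*
(default k = 15). Two choices the formulation leaves open:

- The indication relation is excluded from profiles. It is the label being
  predicted; letting it into the retrieval signal would leak evaluation
  targets. (An inner-product variant of the similarity is a config option;
  cosine is the default.)
- Ties break lexicographically by node id, for determinism.

**Reuse.** For every case, all simple paths of ≤ `MaxHops` steps (default
3) from the case drug to each of its indications are enumerated —
traversal may walk stored edges backwards (flagged inverse hops) — except
the direct indication edge itself. Each path is abstracted to a
*meta-path*: its alternating node-type / relation-label sequence, with
inverse flags preserved. Meta-paths are re-instantiated from the query
drug by exact hop-by-hop matching on relation labels and node types, with
a per-meta-path cap (default 10,000 instances) against combinatorial
blowup. The union of the instances is the query subgraph; its
Disease-typed path termini are the candidate diseases. Paths are simple
(no repeated node): mechanism chains with cycles are not interpretable as
mechanisms. All case meta-paths are used (`min_metapath_support` = 1 by
default); a support filter is available but off, since rare meta-paths are
exactly the ones that carry case-specific mechanisms.

**Revise.** A relational graph convolutional encoder embeds every node of
the query and case subgraphs. Per layer, a node receives, for each
relation channel (forward and inverse twins; 2|R| channels), the mean of
relation-specifically transformed neighbour vectors, plus a self-loop
transform, followed by tanh. Relation weights use basis decomposition
(4 bases) to control parameters for large |R|. Initial features are one
learned vector per *node type*, not per node — parameters must transfer
across query subgraphs with disjoint node sets, which per-node features
would prevent. Candidates are ranked by

    score(d_i) = Σ_c mean_{d ∈ D_c} cos(e(d_i), e(d)),

the summed mean cosine between the candidate's embedding in the query
subgraph and the case's indication embeddings in the case's own subgraph.

The encoder and all gradients are implemented directly in NumPy: the
reverse pass is exact reverse-mode differentiation of the message-passing
forward pass, including gradients with respect to per-edge mask weights.
Finite-difference agreement is asserted in the test suite.

**Training.** Parameters are trained with a margin ranking objective: for
each training drug, the score of each held-in indication must exceed that
of sampled non-indicated candidate diseases by a margin, with uniform
negative sampling (5 negatives per positive) and Adam (lr 0.01, 40
epochs). One seed controls initialization, query-order shuffling and
negative sampling; training queries are canonically sorted first, so the
caller's input order is irrelevant. The margin is 0.25: scores are sums of
cosines and the achievable positive–negative gap on realistic subgraphs is
well under 1, so a margin of 1 can never be satisfied and keeps pushing
the encoder toward a degenerate solution in which tanh units saturate and
all disease embeddings collapse to near-identical directions (we observed
exactly this: ~60% of units at |h| > 0.99 and candidate scores tied at the
ceiling). An attainable margin lets the hinge switch off and preserves
fine-grained discrimination.

## Explanation: path-enforcing edge mask

With the encoder frozen, each subgraph edge *e* gets a weight
M_e = σ(θ_e) ∈ [0,1] from a free latent θ_e. The mask scales every
per-edge message in every layer (self-loops are never masked). The
objective is

    L(M) = L_prediction + c_path · L_path + c_s · mean(M) + c_H · mean(H(M)),

where L_prediction is the squared distance between the target disease's
embedding under the masked and the unmasked subgraph, L_path is the
negative mean score of the current top-5 drug→disease paths, and the last
two terms are sparsity and binary-entropy regularizers. A path's score is

    (Π_{e ∈ path} M_e) × (Π_{v interior} degree_score(deg(v), λ)),

with degree_score(d, λ) = min(d, λ)/max(d, λ): unimodal with its peak at
the preferred degree λ (default 10), penalizing promiscuous hubs and
barely connected nodes symmetrically in ratio. Degrees are counted inside
the query subgraph.

Numerical choices, set by a planted-mechanism recovery experiment (one
planted 3-hop chain, a hub decoy route, a near-isolated decoy route, and
noise edges; mask ROC-AUC against planted edges is the criterion):
c_path = 2.0, c_s = 1.0, c_H = 0.1, Adam lr 0.05, 200 steps. Latents are
initialized at N(0, 0.1) — mask weights start at ≈ 0.5, the maximal-entropy
point, so the loss terms rather than the initialization decide which side
an edge falls. Initializing weights high (a common default elsewhere)
interacts badly with Adam here: the entropy term then pushes *every* edge
toward 1 with a small but consistent gradient that Adam's per-coordinate
normalization amplifies to full speed. Non-finite loss raises immediately,
reporting the step index.

Path extraction is iterative: Dijkstra over costs max(0, −log(M_e + ε))
(ε = 1e−9; the clamp guards the exact-1.0 weight case), record the
min-cost path with its score, delete its weakest edge, repeat until the
requested number of paths or disconnection; the reported list is sorted by
path score. Deleting the weakest edge diversifies the path set — plain
k-shortest-paths returns near-duplicates. Reported paths use the original
relation vocabulary with inverse hops flagged, never rewritten.

## Evaluation protocols

- **Ranking**: filtered protocol (the query's other true indications are
  removed from the candidate list before ranking each truth); MRR and
  Hits@{1,3,5,10} over (query, truth) pairs. A truth missing from the
  candidate set counts at rank |candidates|+1 and is logged.
- **Explanation accuracy**: mask weights as edge scores against curated
  (or planted) mechanism edges — ROC-AUC (midrank ties) and edge hit rate
  HR@K. Truth edges match in either orientation; mechanism databases and
  KGs disagree on edge direction conventions. Truth edges outside the
  subgraph are dropped with a logged count.
- **Faithfulness**: deletion and insertion curves. Edges are ranked by
  mask weight; sliding windows of width 10% of |E| shift by 0.2% of |E|
  per position (counts rounded half-up, minimum one edge, 50 positions).
  Deletion removes the windowed edges, re-encodes, and records the
  Euclidean distance of the target disease's embedding from its original
  value; the curve is prefixed with the empty-window point (0, 0).
  Insertion starts from only the top-10% edges and reintroduces the rest
  in rank order. Nodes are never removed, so a fully disconnected disease
  falls back to its closed-form isolated-node embedding.
- **Stability**: re-optimize the mask (same seed policy) after adding
  random type-consistent edges — signatures sampled from the subgraph's
  observed (head type, relation, tail type) triples — at a fraction of
  |E|; Pearson correlation of weights over the original edge set, mean ±
  sd over replicates. Fewer than three common edges → reported missing.

## The synthetic test bed

The generator emulates the regularities case-based repositioning relies
on, at a scale (~310 nodes, ~640 edges by default) where the full
train/explain/evaluate cycle runs in minutes on one CPU:

- **Drug families** (6 × 8 drugs): each family has a distinct 3-hop
  relation template (e.g. targets/participates_in/associated_with) —
  pharmacological classes with characteristic interaction vocabularies,
  which is what makes binary relation profiles informative.
- **Disease modules**: each disease owns a canonical pathway and a small
  dedicated pool of druggable genes; drugs treating it pick (partially
  shared, `gene_sharing` = 0.5) genes from that pool. Drugs in a family
  thus act through different gene targets while converging on the same
  pathways. The module structure is what makes planted labels *valid*:
  mechanism-shaped reachability implies indication, so an ideal learner
  could recover the labels.
- **Shared diseases** (4): cross-family indications with their own
  gene/pathway modules, each treated by ~half the drugs. They link the
  families through genuine co-indication and widen candidate sets beyond
  a single family — without them, candidate lists are so short that even
  a label-shuffled control scores well under the missing-truth
  convention.
- **Held-out truth**: 25% of each drug's indications (1 of 4) are
  withheld from the graph but kept, with their planted mechanisms, in the
  ground truth; the construction is audited (withheld edges absent,
  held-in present, planted paths present) at generation time.
- **Hubs**: promiscuously bound genes (drug→hub edges only, through each
  drug's own interaction relation). Hubs deliberately do *not*
  participate in pathways: a hub bridging drugs to pathways would
  manufacture mechanism-shaped routes to arbitrary diseases — false
  labels no learner could reject.
- **Noise**: 10% random edges with observed type signatures, never the
  indication relation (a random treats edge would silently become a false
  evaluation label). Noise *can* create spurious gene→pathway and
  pathway→disease links; the residual ranking errors of the trained model
  trace to exactly these, which is the intended failure mode.

What passing on this test bed shows: that the pipeline recovers planted
mechanistic regularities from structure alone, end to end, under hub and
noise nuisance. What it does not show: performance on real KGs — real
node/relation vocabularies are orders of magnitude larger, mechanisms are
not 3-hop-clean, indications are incomplete rather than exhaustively
labelled, and retrieval on real graphs faces far more heterogeneous drug
neighbourhoods. Absolute metric values here do not transfer to real data.

## Sensitivity analyses

The MaxHops sweep evaluates one trained encoder under varying
inference-time subgraph depth: with 3-hop planted mechanisms, MaxHops = 2
subgraphs cannot contain them and ranking collapses, while MaxHops = 3
recovers them. The k-sweep retrains per neighbourhood size; on the
synthetic test bed it shows an interior optimum (k = 5 beats both k = 1
and large k), but k = 1 is *not* clearly worst here: each synthetic
family carries a single uniform meta-path template, so one same-family
case already contributes every reusable mechanism pattern, and the
single-case penalty that heterogeneous real KGs show shrinks to within
seed noise. That is a limitation of the test bed's homogeneity, not a
property of the method. The λ-sweep on the planted-mask fixture shows the
unimodal quality curve around λ = 10 by construction of the decoy routes
(hub degree 60, sparse route degree 2, planted interior degree 10).

## Known limitations

- Stability of the mask under perturbation averages r ≈ 0.8 at 5% edge
  addition on the planted fixture but individual replicates range roughly
  0.5–1.0, and the average itself shifts by a few hundredths with the
  random encoder draw: near-binary masks make Pearson sensitive to a
  handful of support flips.
- The per-meta-path instantiation cap truncates silently-logged; on
  graphs with high-degree compound neighbourhoods the subgraph becomes an
  under-sample rather than the exact union.
- The encoder is NumPy on one CPU; it is sized for query-subgraph-scale
  graphs (hundreds of edges), not whole-KG message passing — which the
  method by design never needs.
- Retrieval is a single inner-product/cosine over relation profiles;
  drugs with identical relation vocabularies but different targets are
  indistinguishable at the retrieval stage and only separated downstream.
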