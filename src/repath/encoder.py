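"""Step 3 — revise: a relational graph convolutional encoder over query and
case subgraphs, with margin-contrastive training of the disease ranking.

The encoder is a standard R-GCN: per layer, each node receives, for every
relation channel, the mean of relation-specifically transformed neighbour
vectors, plus a self-loop transform, followed by tanh.  Relation weights use
basis decomposition (``num_bases`` shared bases with per-relation
coefficients).  Every stored edge contributes two channels — forward and an
inverse twin — so information flows both ways along directed mechanism
chains.  Initial node features are one learned vector per *node type*, which
lets a single parameter set transfer across query subgraphs with disjoint
node sets.

Forward and reverse passes are written directly in NumPy; the reverse pass
computes exact analytic gradients with respect to all parameters and,
optionally, with respect to per-edge mask weights (used by the explainer).
Gradient correctness is checked against finite differences in the test
suite.

Candidate diseases are ranked by ``score(d_i) = Σ_c sim(d_i, D_c)`` where
``sim`` is the mean cosine similarity between the candidate's embedding in
the query subgraph and the embeddings of the case drug's indication
diseases in that case's own subgraph.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .kg import KnowledgeGraph, QuerySubgraph, Triple
from .paths import construct_query_subgraph, build_case_subgraph
from .retrieval import DrugCase, retrieve_knn

logger = logging.getLogger(__name__)


@dataclass
class EncoderConfig:
    """Hyperparameters of the R-GCN encoder and its contrastive training."""

    embedding_dim: int = 64
    num_layers: int = 2
    num_bases: int = 4
    dropout: float = 0.0
    learning_rate: float = 0.01
    epochs: int = 40
    margin: float = 0.25
    num_negatives: int = 5
    k: int = 15           # retrieved cases per query during training
    max_hops: int = 3     # path length bound for subgraph construction
    seed: int = 0

    def __post_init__(self) -> None:
        if self.embedding_dim <= 0 or self.num_layers <= 0 or self.num_bases <= 0:
            raise ValueError("dims, layers and bases must be positive")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must be in [0, 1)")


class EncoderParams:
    """Learned parameters: per-type input features, per-layer relation bases,
    coefficients and self-loop transforms.  Tied to a type vocabulary and a
    relation vocabulary; scoring a KG with a different relation vocabulary
    is refused unless overridden."""

    def __init__(
        self,
        config: EncoderConfig,
        type_vocab: Sequence[str],
        relations: Sequence[str],
        rng: np.random.Generator,
    ) -> None:
        self.config = config
        self.type_vocab = tuple(sorted(type_vocab))
        self.relations = tuple(relations)
        d, nb = config.embedding_dim, config.num_bases
        n_channels = 2 * len(self.relations)  # forward + inverse twins
        scale = 1.0 / np.sqrt(d)
        self.arrays: dict[str, np.ndarray] = {
            "X": rng.normal(0.0, 1.0, size=(len(self.type_vocab), d))
        }
        for layer in range(config.num_layers):
            self.arrays[f"A{layer}"] = rng.normal(0.0, 1.0 / np.sqrt(nb), size=(n_channels, nb))
            self.arrays[f"B{layer}"] = rng.normal(0.0, scale, size=(nb, d, d))
            self.arrays[f"S{layer}"] = rng.normal(0.0, scale, size=(d, d))
        self.loss_history: list[float] = []

    def type_index(self, type_label: str) -> int:
        try:
            return self.type_vocab.index(type_label)
        except ValueError:
            raise KeyError(f"node type {type_label!r} unknown to the encoder") from None

    def zero_grads(self) -> dict[str, np.ndarray]:
        return {k: np.zeros_like(v) for k, v in self.arrays.items()}

    def checksum(self) -> str:
        h = hashlib.sha256()
        for key in sorted(self.arrays):
            h.update(key.encode())
            h.update(np.ascontiguousarray(self.arrays[key]).tobytes())
        return h.hexdigest()

    def copy(self) -> "EncoderParams":
        clone = EncoderParams.__new__(EncoderParams)
        clone.config = self.config
        clone.type_vocab = self.type_vocab
        clone.relations = self.relations
        clone.arrays = {k: v.copy() for k, v in self.arrays.items()}
        clone.loss_history = list(self.loss_history)
        return clone

    # -- persistence ------------------------------------------------------

    def save(self, path: str | Path, kg_checksum: str | None = None) -> None:
        meta = {
            "config": asdict(self.config),
            "type_vocab": list(self.type_vocab),
            "relations": list(self.relations),
            "loss_history": self.loss_history,
            "kg_checksum": kg_checksum,
        }
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **self.arrays)

    @classmethod
    def load(cls, path: str | Path) -> "EncoderParams":
        data = np.load(path)
        meta = json.loads(bytes(data["__meta__"]).decode())
        params = cls.__new__(cls)
        params.config = EncoderConfig(**meta["config"])
        params.type_vocab = tuple(meta["type_vocab"])
        params.relations = tuple(meta["relations"])
        params.arrays = {k: data[k] for k in data.files if k != "__meta__"}
        params.loss_history = list(meta["loss_history"])
        return params

    def check_compatible(self, g: KnowledgeGraph, override: bool = False) -> None:
        if tuple(g.relations) != self.relations:
            msg = (
                "relation vocabulary differs from the one this encoder was "
                f"trained on ({len(g.relations)} vs {len(self.relations)} relations)"
            )
            if override:
                logger.warning("%s -- override requested, proceeding", msg)
            else:
                raise ValueError(msg + "; pass override=True to force")


@dataclass
class NodeEmbeddings:
    """Embeddings of every node in one subgraph."""

    subgraph: str
    vectors: dict[str, np.ndarray]


@dataclass
class RankedPrediction:
    query_drug: str
    ranking: list[tuple[str, float]]  # (disease, score), descending


# ---------------------------------------------------------------------------
# Compiled message-passing structure
# ---------------------------------------------------------------------------

class CompiledSubgraph:
    """Index arrays for vectorized message passing over one subgraph.

    Channel c < |R| carries stored edges of relation R[c] forward
    (head → tail); channel |R| + c carries their inverse twins.  ``norm`` is
    the 1/|N_{c}(dst)| mean-normalization constant.  ``eid`` maps each
    channel entry back to its position in the sorted edge list, which is
    also the indexing convention for edge masks.
    """

    def __init__(self, sg: QuerySubgraph) -> None:
        g = sg.graph
        self.subgraph_id = sg.query_drug
        self.nodes: list[str] = sorted(g.node_type)
        self.index = {n: i for i, n in enumerate(self.nodes)}
        self.edge_list: list[Triple] = sg.edge_list
        self.edge_index = {e: i for i, e in enumerate(self.edge_list)}
        self.n_nodes = len(self.nodes)
        self.relations = g.relations
        rel_idx = {r: i for i, r in enumerate(g.relations)}

        per_channel: dict[int, list[tuple[int, int, int]]] = {}
        for ei, e in enumerate(self.edge_list):
            c = rel_idx[e.relation]
            h, t = self.index[e.head], self.index[e.tail]
            per_channel.setdefault(c, []).append((h, t, ei))
            per_channel.setdefault(c + len(g.relations), []).append((t, h, ei))

        self.channels: dict[int, dict[str, np.ndarray]] = {}
        for c, entries in per_channel.items():
            src = np.array([s for s, _, _ in entries], dtype=np.intp)
            dst = np.array([t for _, t, _ in entries], dtype=np.intp)
            eid = np.array([e for _, _, e in entries], dtype=np.intp)
            counts = np.bincount(dst, minlength=self.n_nodes)
            self.channels[c] = {
                "src": src,
                "dst": dst,
                "eid": eid,
                "norm": 1.0 / counts[dst],
            }

    def type_indices(self, params: EncoderParams, g: KnowledgeGraph) -> np.ndarray:
        return np.array([params.type_index(g.type_of(n)) for n in self.nodes],
                        dtype=np.intp)


def _channel_weight(params: EncoderParams, layer: int, c: int) -> np.ndarray:
    return np.tensordot(params.arrays[f"A{layer}"][c], params.arrays[f"B{layer}"], axes=1)


def forward(
    params: EncoderParams,
    cs: CompiledSubgraph,
    type_idx: np.ndarray,
    mask_weights: np.ndarray | None = None,
    dropout_rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, dict]:
    """Run message passing; returns final node embeddings (n × d) and a cache
    for the reverse pass.  ``mask_weights`` (aligned with ``cs.edge_list``)
    multiplicatively scales every per-edge message in every layer.  Dropout
    is applied to hidden layers only when ``dropout_rng`` is given
    (training); inference is deterministic."""
    cfg = params.config
    H = params.arrays["X"][type_idx]
    cache: dict = {"H_in": [], "H_out": [], "drop": [], "type_idx": type_idx}
    for layer in range(cfg.num_layers):
        cache["H_in"].append(H)
        Z = H @ params.arrays[f"S{layer}"].T
        for c, ch in cs.channels.items():
            W = _channel_weight(params, layer, c)
            msg = H[ch["src"]] @ W.T
            if mask_weights is not None:
                msg = msg * mask_weights[ch["eid"]][:, None]
            msg = msg * ch["norm"][:, None]
            np.add.at(Z, ch["dst"], msg)
        H = np.tanh(Z)
        drop = None
        if dropout_rng is not None and cfg.dropout > 0.0 and layer < cfg.num_layers - 1:
            keep = 1.0 - cfg.dropout
            drop = (dropout_rng.random(H.shape) < keep) / keep
            H = H * drop
        cache["H_out"].append(H)
        cache["drop"].append(drop)
    return H, cache


def backward(
    params: EncoderParams,
    cs: CompiledSubgraph,
    cache: dict,
    dH_final: np.ndarray,
    mask_weights: np.ndarray | None = None,
    need_mask_grad: bool = False,
) -> tuple[dict[str, np.ndarray], np.ndarray | None]:
    """Exact reverse pass.  Returns parameter gradients and, if requested,
    the gradient with respect to the edge-mask weights."""
    cfg = params.config
    grads = params.zero_grads()
    dmask = np.zeros(len(cs.edge_list)) if need_mask_grad else None
    dH = dH_final
    for layer in reversed(range(cfg.num_layers)):
        H_in = cache["H_in"][layer]
        H_out = cache["H_out"][layer]
        drop = cache["drop"][layer]
        if drop is not None:
            dH = dH * drop
            H_pre = H_out / np.where(drop == 0.0, 1.0, drop)
        else:
            H_pre = H_out
        dZ = dH * (1.0 - H_pre * H_pre)
        grads[f"S{layer}"] += dZ.T @ H_in
        dH_in = dZ @ params.arrays[f"S{layer}"]
        for c, ch in cs.channels.items():
            W = _channel_weight(params, layer, c)
            dMsg = dZ[ch["dst"]] * ch["norm"][:, None]
            src_h = H_in[ch["src"]]
            if mask_weights is not None:
                m = mask_weights[ch["eid"]]
                if need_mask_grad:
                    wx = src_h @ W.T
                    np.add.at(dmask, ch["eid"], np.sum(dMsg * wx, axis=1))
                dMsg_eff = dMsg * m[:, None]
            else:
                dMsg_eff = dMsg
            dW = dMsg_eff.T @ src_h
            grads[f"A{layer}"][c] += np.tensordot(
                dW, params.arrays[f"B{layer}"], axes=([0, 1], [1, 2])
            )
            grads[f"B{layer}"] += params.arrays[f"A{layer}"][c][:, None, None] * dW[None, :, :]
            np.add.at(dH_in, ch["src"], dMsg_eff @ W)
        dH = dH_in
    np.add.at(grads["X"], cache["type_idx"], dH)
    return grads, dmask


def encode(
    sg: QuerySubgraph,
    params: EncoderParams,
    config: EncoderConfig | None = None,
    mask_weights: np.ndarray | None = None,
) -> NodeEmbeddings:
    """Deterministic inference-mode embeddings for every node of ``sg``."""
    if not sg.graph.node_type:
        return NodeEmbeddings(subgraph=sg.query_drug, vectors={})
    cs = CompiledSubgraph(sg)
    type_idx = cs.type_indices(params, sg.graph)
    H, _ = forward(params, cs, type_idx, mask_weights=mask_weights)
    return NodeEmbeddings(
        subgraph=sg.query_drug,
        vectors={n: H[i].copy() for i, n in enumerate(cs.nodes)},
    )


def encode_isolated(params: EncoderParams, type_label: str) -> np.ndarray:
    """Closed-form embedding of a node with no neighbours: repeated
    tanh(self-loop transform) applied to its type feature vector."""
    h = params.arrays["X"][params.type_index(type_label)]
    for layer in range(params.config.num_layers):
        h = np.tanh(params.arrays[f"S{layer}"] @ h)
    return h


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(a @ b / (na * nb))


def score_diseases(
    q_emb: NodeEmbeddings,
    cases: Sequence[DrugCase],
    case_embs: Sequence[NodeEmbeddings],
    candidates: Iterable[str],
) -> RankedPrediction:
    """Rank candidate diseases by summed mean-cosine similarity to case
    indication embeddings.  Cases whose encoded subgraph contains none of
    their indications contribute zero.  Ties break lexicographically."""
    candidates = sorted(candidates)
    if not candidates:
        logger.warning("no candidate diseases for %s: empty ranking", q_emb.subgraph)
        return RankedPrediction(query_drug=q_emb.subgraph, ranking=[])
    scores: dict[str, float] = {}
    for d_i in candidates:
        total = 0.0
        v = q_emb.vectors[d_i]
        for case, cemb in zip(cases, case_embs):
            ind_vecs = [cemb.vectors[d] for d in sorted(case.indications)
                        if d in cemb.vectors]
            if ind_vecs:
                total += float(np.mean([_cosine(v, w) for w in ind_vecs]))
        scores[d_i] = total
    ranking = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    return RankedPrediction(query_drug=q_emb.subgraph, ranking=ranking)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def margin_ranking_loss(
    pos_scores: Sequence[float], neg_scores: Sequence[float], margin: float
) -> float:
    """Mean hinge over aligned (positive, negative) score pairs: zero once
    every positive beats its negative by at least the margin."""
    if len(pos_scores) != len(neg_scores):
        raise ValueError("need aligned positive/negative score pairs")
    return float(np.mean([max(0.0, margin - p + n)
                          for p, n in zip(pos_scores, neg_scores)]))


class Adam:
    """Adam over a dict of parameter arrays."""

    def __init__(self, arrays: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.arrays = arrays
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in arrays.items()}
        self.v = {k: np.zeros_like(v) for k, v in arrays.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for key, g in grads.items():
            self.m[key] = self.b1 * self.m[key] + (1 - self.b1) * g
            self.v[key] = self.b2 * self.v[key] + (1 - self.b2) * g * g
            mhat = self.m[key] / (1 - self.b1 ** self.t)
            vhat = self.v[key] / (1 - self.b2 ** self.t)
            self.arrays[key] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


@dataclass
class _QueryBundle:
    drug: str
    sg: QuerySubgraph
    cs: CompiledSubgraph
    type_idx: np.ndarray
    candidates: list[str]
    positives: list[str]
    neg_pool: list[str]
    cases: list[DrugCase]
    case_cs: list[CompiledSubgraph]
    case_type_idx: list[np.ndarray]
    case_ind_nodes: list[list[str]]


def _prepare_query(
    g: KnowledgeGraph, drug: str, positives: set[str], config: EncoderConfig
) -> _QueryBundle | None:
    cases = retrieve_knn(g, drug, config.k)
    if not cases:
        return None
    sg, _ = construct_query_subgraph(g, drug, cases, max_hops=config.max_hops)
    candidates = sorted(sg.candidate_diseases)
    pos = sorted(set(positives) & set(candidates))
    known = set(positives) | g.indications_of(drug)
    neg_pool = sorted(set(candidates) - known)
    if not pos or not neg_pool:
        return None
    case_cs, case_ind, kept_cases = [], [], []
    for case in cases:
        csg = build_case_subgraph(g, case, max_hops=config.max_hops)
        ind_nodes = sorted(set(case.indications) & set(csg.graph.node_type))
        if not ind_nodes:
            continue
        case_cs.append(CompiledSubgraph(csg))
        case_ind.append(ind_nodes)
        kept_cases.append(case)
    if not case_cs:
        return None
    qcs = CompiledSubgraph(sg)
    return _QueryBundle(
        drug=drug, sg=sg, cs=qcs, type_idx=np.empty(0, dtype=np.intp),
        candidates=candidates, positives=pos, neg_pool=neg_pool,
        cases=kept_cases, case_cs=case_cs, case_type_idx=[],
        case_ind_nodes=case_ind,
    )


def _cosine_grads(a: np.ndarray, b: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        return 0.0, np.zeros_like(a), np.zeros_like(b)
    cos = float(a @ b / (na * nb))
    da = b / (na * nb) - cos * a / (na * na)
    db = a / (na * nb) - cos * b / (nb * nb)
    return cos, da, db


def train_encoder(
    training_queries: Sequence[tuple[str, set[str]]],
    g: KnowledgeGraph,
    config: EncoderConfig,
) -> EncoderParams:
    """Margin-based contrastive training of the shared encoder.

    For each training drug, the score of each held-in indication disease
    must exceed that of uniformly sampled non-indicated candidate diseases
    by at least ``margin``; subgradients flow through both the query-side
    and case-side embeddings into the shared parameters.  All randomness
    (init, query order shuffling, negative sampling) derives from
    ``config.seed``; the per-epoch mean loss is recorded in
    ``params.loss_history``.
    """
    rng = np.random.default_rng(config.seed)
    # canonical order first so the caller's input ordering is irrelevant
    queries = sorted(
        {(drug, frozenset(pos)) for drug, pos in training_queries},
        key=lambda q: q[0],
    )
    bundles: list[_QueryBundle] = []
    for drug, pos in queries:
        b = _prepare_query(g, drug, set(pos), config)
        if b is None:
            logger.info("query %s not trainable (no positives/negatives/cases)", drug)
        else:
            bundles.append(b)
    if not bundles:
        raise ValueError("no trainable queries")

    types = sorted(set(g.node_type.values()))
    params = EncoderParams(config, types, g.relations, rng)
    for b in bundles:
        b.type_idx = b.cs.type_indices(params, b.sg.graph)
        b.case_type_idx = [
            ccs.type_indices(params, g) for ccs in b.case_cs
        ]
    opt = Adam(params.arrays, lr=config.learning_rate)

    for epoch in range(config.epochs):
        order = rng.permutation(len(bundles))
        epoch_losses = []
        for qi in order:
            b = bundles[qi]
            loss = _train_step(params, b, opt, config, rng)
            epoch_losses.append(loss)
        mean_loss = float(np.mean(epoch_losses))
        params.loss_history.append(mean_loss)
        logger.info("epoch %d: mean margin loss %.4f", epoch, mean_loss)
    return params


def _train_step(
    params: EncoderParams,
    b: _QueryBundle,
    opt: Adam,
    config: EncoderConfig,
    rng: np.random.Generator,
) -> float:
    drop_rng = (np.random.default_rng(rng.integers(2**31))
                if config.dropout > 0.0 else None)
    Hq, cache_q = forward(params, b.cs, b.type_idx, dropout_rng=drop_rng)
    case_states = []
    for ccs, cti in zip(b.case_cs, b.case_type_idx):
        Hc, cache_c = forward(params, ccs, cti)
        case_states.append((Hc, cache_c))

    cand_idx = {d: b.cs.index[d] for d in b.candidates}
    # score every candidate, remembering cosine gradients for backprop
    scores: dict[str, float] = {}
    grads_sc: dict[str, list[tuple[int, int, np.ndarray, np.ndarray]]] = {}
    for d_i in b.candidates:
        v = Hq[cand_idx[d_i]]
        total = 0.0
        pieces = []
        for ci, (ccs, ind_nodes) in enumerate(zip(b.case_cs, b.case_ind_nodes)):
            Hc = case_states[ci][0]
            w = 1.0 / len(ind_nodes)
            for d in ind_nodes:
                j = ccs.index[d]
                cos, da, db = _cosine_grads(v, Hc[j])
                total += w * cos
                pieces.append((ci, j, w * da, w * db))
        scores[d_i] = total
        grads_sc[d_i] = pieces

    # hinge loss over (positive, sampled negative) pairs
    n_neg = min(config.num_negatives, len(b.neg_pool))
    pairs: list[tuple[str, str]] = []
    for p in b.positives:
        negs = rng.choice(len(b.neg_pool), size=n_neg, replace=False)
        pairs.extend((p, b.neg_pool[int(ni)]) for ni in negs)
    dscore: dict[str, float] = {d: 0.0 for d in b.candidates}
    total_loss = 0.0
    for p, n in pairs:
        violation = config.margin - scores[p] + scores[n]
        if violation > 0.0:
            total_loss += violation
            dscore[p] -= 1.0 / len(pairs)
            dscore[n] += 1.0 / len(pairs)
    total_loss /= len(pairs)
    if all(v == 0.0 for v in dscore.values()):
        return total_loss

    dHq = np.zeros_like(Hq)
    dHc_all = [np.zeros_like(Hc) for Hc, _ in case_states]
    for d_i, gsc in dscore.items():
        if gsc == 0.0:
            continue
        for ci, j, da, db in grads_sc[d_i]:
            dHq[cand_idx[d_i]] += gsc * da
            dHc_all[ci][j] += gsc * db

    grads, _ = backward(params, b.cs, cache_q, dHq)
    for ci, (Hc, cache_c) in enumerate(case_states):
        if not np.any(dHc_all[ci]):
            continue
        g_c, _ = backward(params, b.case_cs[ci], cache_c, dHc_all[ci])
        for key in grads:
            grads[key] += g_c[key]
    opt.step(grads)
    return total_loss
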