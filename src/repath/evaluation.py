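"""Ranking, explanation-accuracy, faithfulness and stability metrics.

Link prediction is scored with the filtered ranking protocol standard in
KG completion: when ranking one true indication, the query's other true
indications are removed from the candidate list first.  Explanations are
scored against curated mechanism edges (ROC-AUC of mask weights, edge hit
rate), by deletion/insertion faithfulness curves (sliding rank windows of
width 10% of edges shifting in 0.2% steps), and by stability (Pearson
correlation of mask weights before and after random edge additions).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score

from .encoder import CompiledSubgraph, EncoderParams, RankedPrediction, forward
from .explainer import EdgeMask, ExplainerConfig, optimize_mask
from .kg import KnowledgeGraph, QuerySubgraph, Triple

logger = logging.getLogger(__name__)

HITS_KS = (1, 3, 5, 10)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


# ---------------------------------------------------------------------------
# Link-prediction ranking
# ---------------------------------------------------------------------------

@dataclass
class RankReport:
    """Filtered ranks of every (query, true indication) pair + aggregates."""

    records: list[tuple[str, str, int, int]]  # (drug, truth, rank, n_candidates)
    mrr: float
    hits: dict[int, float]


def rank_metrics(
    rankings: list[RankedPrediction],
    truths: dict[str, set[str]],
    hits_ks: tuple[int, ...] = HITS_KS,
    universe_size: int | None = None,
) -> RankReport:
    """Aggregate MRR and Hits@K over (query, truth) pairs.

    A truth missing from its candidate list is counted at rank
    ``len(candidates) + 1`` (logged), so unreachable targets still penalize
    the aggregate rather than being silently skipped.  When the candidate
    list is *empty* the method produced no ranking at all; with
    ``universe_size`` given (the number of scoreable diseases) such pairs
    are counted at rank ``universe_size + 1`` instead of the degenerate 1."""
    records: list[tuple[str, str, int, int]] = []
    for rp in rankings:
        truth_set = truths.get(rp.query_drug, set())
        if not truth_set:
            continue
        ordered = [d for d, _ in rp.ranking]
        for t in sorted(truth_set):
            filtered = [d for d in ordered if d == t or d not in truth_set]
            if t in filtered:
                rank = filtered.index(t) + 1
            else:
                rank = len(filtered) + 1
                if not filtered and universe_size is not None:
                    rank = universe_size + 1
                logger.info(
                    "truth %s absent from candidates of %s: rank set to %d",
                    t, rp.query_drug, rank,
                )
            records.append((rp.query_drug, t, rank, len(filtered)))
    if not records:
        raise ValueError("empty evaluation set: no (query, truth) pairs")
    ranks = np.array([r for _, _, r, _ in records], dtype=float)
    return RankReport(
        records=records,
        mrr=float(np.mean(1.0 / ranks)),
        hits={k: float(np.mean(ranks <= k)) for k in hits_ks},
    )


# ---------------------------------------------------------------------------
# Explanation accuracy vs curated mechanism edges
# ---------------------------------------------------------------------------

def _match_truth(edge_list: list[Triple], truth_edges: set[Triple]) -> np.ndarray:
    """Direction-insensitive membership: either orientation of a subgraph
    edge may appear in the curated mechanism set."""
    flipped = {Triple(t, r, h) for h, r, t in truth_edges}
    labels = np.array(
        [e in truth_edges or e in flipped for e in edge_list], dtype=int
    )
    matched = {e for e in truth_edges
               if e in set(edge_list) or Triple(e.tail, e.relation, e.head) in set(edge_list)}
    dropped = len(truth_edges) - len(matched)
    if dropped:
        logger.info("%d curated mechanism edges fall outside the subgraph", dropped)
    return labels


def explanation_auc(mask: EdgeMask, truth_edges: set[Triple]) -> float | None:
    """ROC-AUC of mask weights as edge scores, curated edges positive.

    Midrank tie handling.  Undefined (None) when the subgraph has no
    positive or no negative edges after intersection."""
    edge_list = list(mask.edge_list)
    labels = _match_truth(edge_list, truth_edges)
    if labels.sum() == 0 or labels.sum() == len(labels):
        logger.warning("ROC-AUC undefined: need both positive and negative edges")
        return None
    return float(roc_auc_score(labels, mask.weights))


def edge_hit_rate(
    mask: EdgeMask,
    truth_edges: set[Triple],
    k_grid: tuple[int, ...] = (1, 3, 5, 10, 20),
) -> dict[int, float] | None:
    """HR@K: fraction of curated mechanism edges among the K highest-weight
    edges (lexicographic tie-break on the triple)."""
    edge_list = list(mask.edge_list)
    labels = _match_truth(edge_list, truth_edges)
    n_pos = int(labels.sum())
    if n_pos == 0:
        logger.warning("edge hit rate undefined: no curated edge in subgraph")
        return None
    w = mask.weights
    order = sorted(range(len(edge_list)), key=lambda i: (-w[i], edge_list[i]))
    out: dict[int, float] = {}
    for k in k_grid:
        top = order[:k]
        out[k] = float(sum(labels[i] for i in top)) / n_pos
    return out


# ---------------------------------------------------------------------------
# Faithfulness: deletion / insertion curves
# ---------------------------------------------------------------------------

def _disease_embedding(
    params: EncoderParams, sg: QuerySubgraph, keep_edges: set[Triple], disease: str
) -> np.ndarray:
    """Embed ``disease`` in the subgraph restricted to ``keep_edges`` (all
    nodes retained, so a fully disconnected disease falls back to its
    isolated-node embedding)."""
    sub = QuerySubgraph(
        query_drug=sg.query_drug,
        graph=sg.graph.copy_without_edges(set(sg.graph.edges) - keep_edges),
        candidate_diseases=set(),
        provenance={},
    )
    cs = CompiledSubgraph(sub)
    H, _ = forward(params, cs, cs.type_indices(params, sub.graph))
    return H[cs.index[disease]]


def _ranked_edges(mask: EdgeMask) -> list[Triple]:
    w = mask.weights
    order = sorted(range(len(mask.edge_list)),
                   key=lambda i: (-w[i], mask.edge_list[i]))
    return [mask.edge_list[i] for i in order]


def deletion_curve(
    sg: QuerySubgraph,
    mask: EdgeMask,
    params: EncoderParams,
    disease: str,
    window_frac: float = 0.10,
    step_frac: float = 0.002,
    n_windows: int = 50,
) -> list[tuple[float, float]]:
    """Distance of the disease embedding from its original value as rank
    windows of top-weighted edges are removed.

    Windows have width ``window_frac * |E|`` (rounded half-up, >= 1 edge)
    and shift by ``step_frac * |E|`` per position; the first point is the
    empty window at fraction 0, which has distance exactly 0."""
    edges = _ranked_edges(mask)
    n_e = len(edges)
    if n_e == 0:
        return [(0.0, 0.0)]
    all_edges = set(sg.graph.edges)
    original = _disease_embedding(params, sg, all_edges, disease)
    width = max(1, _round_half_up(window_frac * n_e))
    curve: list[tuple[float, float]] = [(0.0, 0.0)]
    for i in range(n_windows):
        start = min(_round_half_up(i * step_frac * n_e), n_e - 1)
        window = set(edges[start:start + width])
        emb = _disease_embedding(params, sg, all_edges - window, disease)
        if not any(e.head == disease or e.tail == disease
                   for e in all_edges - window):
            logger.info("window %d isolates %s: distance vs isolated-node "
                        "embedding", i, disease)
        curve.append((start / n_e, float(np.linalg.norm(emb - original))))
    return curve


def insertion_curve(
    sg: QuerySubgraph,
    mask: EdgeMask,
    params: EncoderParams,
    disease: str,
    window_frac: float = 0.10,
    step_frac: float = 0.002,
    n_windows: int = 50,
) -> list[tuple[float, float]]:
    """Mirror of deletion: start from only the top ``window_frac`` of edges
    and reintroduce the rest in decreasing weight order, tracking the same
    embedding distance (0 once every edge is back)."""
    edges = _ranked_edges(mask)
    n_e = len(edges)
    if n_e == 0:
        return [(0.0, 0.0)]
    all_edges = set(sg.graph.edges)
    original = _disease_embedding(params, sg, all_edges, disease)
    width = max(1, _round_half_up(window_frac * n_e))
    curve: list[tuple[float, float]] = []
    for i in range(n_windows):
        extra = _round_half_up(i * step_frac * n_e)
        kept = set(edges[:width + extra])
        emb = _disease_embedding(params, sg, kept, disease)
        curve.append((extra / n_e, float(np.linalg.norm(emb - original))))
        if width + extra >= n_e:
            break
    return curve


# ---------------------------------------------------------------------------
# Stability under random edge additions
# ---------------------------------------------------------------------------

def _perturb_subgraph(
    sg: QuerySubgraph, n_add: int, rng: np.random.Generator
) -> QuerySubgraph:
    """Add ``n_add`` type-consistent random edges: sample an observed
    (head type, relation, tail type) signature, then endpoints of those
    types from the subgraph's nodes."""
    g = sg.graph
    signatures = sorted({(g.type_of(e.head), e.relation, g.type_of(e.tail))
                         for e in g.edges})
    by_type: dict[str, list[str]] = {}
    for n, t in g.node_type.items():
        by_type.setdefault(t, []).append(n)
    for t in by_type:
        by_type[t].sort()
    new_edges = set(g.edges)
    attempts = 0
    added = 0
    while added < n_add and attempts < 100 * max(n_add, 1):
        attempts += 1
        ht, r, tt = signatures[int(rng.integers(len(signatures)))]
        h = by_type[ht][int(rng.integers(len(by_type[ht])))]
        t = by_type[tt][int(rng.integers(len(by_type[tt])))]
        e = Triple(h, r, t)
        if h == t or e in new_edges:
            continue
        new_edges.add(e)
        added += 1
    if added < n_add:
        logger.warning("could only add %d of %d perturbation edges", added, n_add)
    graph = KnowledgeGraph(
        node_type=dict(g.node_type),
        edges=new_edges,
        indication_relation=g.indication_relation,
        relations=g.relations,
    )
    return QuerySubgraph(
        query_drug=sg.query_drug,
        graph=graph,
        candidate_diseases=set(sg.candidate_diseases),
        provenance=dict(sg.provenance),
    )


@dataclass
class StabilityResult:
    mean: float | None
    sd: float | None
    values: list[float] = field(default_factory=list)


def pearson(a: np.ndarray, b: np.ndarray) -> float | None:
    if len(a) < 3:
        return None
    if np.array_equal(a, b):
        return 1.0
    if np.std(a) == 0.0 or np.std(b) == 0.0:
        return None
    return float(stats.pearsonr(a, b).statistic)


def stability(
    sg: QuerySubgraph,
    disease: str,
    params: EncoderParams,
    config: ExplainerConfig,
    perturb_fracs: tuple[float, ...] = (0.05, 0.10, 0.20),
    n_reps: int = 3,
    seed: int = 0,
) -> dict[float, StabilityResult]:
    """Pearson correlation between original and re-optimized mask weights
    over the original edge set, after adding random type-consistent edges at
    each fraction of |E|; per-fraction mean and sd over replicates."""
    base_mask, _ = optimize_mask(sg, params, disease, config)
    base_w = base_mask.weights
    base_edges = list(base_mask.edge_list)
    results: dict[float, StabilityResult] = {}
    rng = np.random.default_rng(seed)
    for frac in perturb_fracs:
        values: list[float] = []
        for _rep in range(n_reps):
            n_add = _round_half_up(frac * len(base_edges))
            if n_add == 0:
                pert_sg = sg
            else:
                pert_sg = _perturb_subgraph(sg, n_add, rng)
            pert_mask, _ = optimize_mask(pert_sg, params, disease, config)
            pw = pert_mask.as_dict()
            common = [e for e in base_edges if e in pw]
            if len(common) < 3:
                logger.warning("fewer than 3 common edges: stability undefined")
                continue
            a = np.array([base_w[base_edges.index(e)] for e in common])
            b = np.array([pw[e] for e in common])
            r = pearson(a, b)
            if r is not None:
                values.append(r)
        results[frac] = StabilityResult(
            mean=float(np.mean(values)) if values else None,
            sd=float(np.std(values)) if values else None,
            values=values,
        )
    return results


# ---------------------------------------------------------------------------
# Plotting
# ---------------------------------------------------------------------------

def plot_faithfulness_curves(
    curves: dict[str, list[tuple[float, float]]], path: str
) -> None:
    """Write deletion/insertion curves (fraction on x, embedding distance on
    y) to an image file."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for label, curve in curves.items():
        xs = [x for x, _ in curve]
        ys = [y for _, y in curve]
        ax.plot(xs, ys, marker="o", markersize=2, label=label)
    ax.set_xlabel("fraction of edges (window shift)")
    ax.set_ylabel("embedding distance to original")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
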