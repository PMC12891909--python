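"""Independent brute-force oracles the implementation is checked against.

These deliberately avoid the package's own traversal, ranking and metric
code paths: path enumeration is a plain recursive search over explicit
adjacency built here, AUC is the O(P·N) pairwise comparison, MRR/Hits are
naive loops, and top-path selection is exhaustive enumeration.
"""

from __future__ import annotations

import numpy as np


def all_simple_paths(kg, source, target, max_hops):
    """Exhaustive enumeration of simple paths source→target of length
    <= max_hops, walking stored edges in both directions.

    Returns a set of hashable path signatures:
    (nodes tuple, hops tuple of (relation, inverse) pairs).
    """
    steps = {}  # node -> list of ((relation, inverse), neighbour, stored triple)
    for e in kg.edges:
        steps.setdefault(e.head, []).append(((e.relation, False), e.tail, e))
        steps.setdefault(e.tail, []).append(((e.relation, True), e.head, e))
    found = set()

    def recurse(node, nodes, hops, used_edges):
        if node == target and hops:
            found.add((tuple(nodes), tuple(hops)))
            return
        if len(hops) == max_hops:
            return
        for hop, nxt, triple in steps.get(node, []):
            if nxt in nodes:
                continue
            recurse(nxt, nodes + [nxt], hops + [hop], used_edges + [triple])

    recurse(source, [source], [], [])
    return found


def pairwise_auc(scores, labels):
    """O(P*N) probability that a random positive outscores a random
    negative, ties counting half."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    if not pos or not neg:
        return None
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def naive_rank_metrics(rank_lists, hits_ks=(1, 3, 5, 10)):
    """MRR and Hits@K from a flat list of integer ranks."""
    rr = [1.0 / r for r in rank_lists]
    return (
        sum(rr) / len(rr),
        {k: sum(1 for r in rank_lists if r <= k) / len(rank_lists)
         for k in hits_ks},
    )


def brute_force_knn(kg, query, k, profile_fn, similarity_fn):
    """Full sort over every other drug with indications, ties broken by id."""
    rows = []
    qp = profile_fn(kg, query)
    for drug in sorted(kg.nodes_of_type("Compound")):
        if drug == query:
            continue
        if not kg.indications_of(drug):
            continue
        rows.append((similarity_fn(qp, profile_fn(kg, drug)), drug))
    rows.sort(key=lambda r: (-r[0], r[1]))
    return rows[:k]


def exhaustive_best_product_path(kg, weights, source, target, max_hops=10):
    """The simple path with the largest product of edge mask weights,
    enumerated exhaustively (weights keyed by stored triple)."""
    best = None
    for nodes, hops in all_simple_paths(kg, source, target, max_hops):
        product = 1.0
        for i, (rel, inv) in enumerate(hops):
            u, v = nodes[i], nodes[i + 1]
            triple = (v, rel, u) if inv else (u, rel, v)
            product *= weights[triple]
        if best is None or product > best[0]:
            best = (product, nodes, hops)
    return best


def double_loop_scores(q_vectors, cases, case_vectors, candidates):
    """score(d) = sum over cases of mean cosine to the case's indication
    embeddings, written as explicit loops."""
    def cos(a, b):
        na, nb = np.linalg.norm(a), np.linalg.norm(b)
        return 0.0 if na == 0 or nb == 0 else float(a @ b / (na * nb))

    out = {}
    for d in candidates:
        total = 0.0
        for case, vecs in zip(cases, case_vectors):
            sims = [cos(q_vectors[d], vecs[ind])
                    for ind in sorted(case.indications) if ind in vecs]
            if sims:
                total += sum(sims) / len(sims)
        out[d] = total
    return out
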