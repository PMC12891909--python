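"""Step 1 — retrieve: binary relation profiles and k-nearest drug cases.

A drug is summarized by which relation types it has at least one outgoing
edge of (a binary vector over the relation vocabulary).  Drugs with similar
profiles are assumed to act in comparable mechanistic environments; the top
k most cosine-similar drugs that have known indications serve as reasoning
cases.

The indication relation itself is excluded from profiles: it is the label
being predicted, and letting it into the retrieval signal would leak
evaluation targets into the pipeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .kg import KnowledgeGraph

logger = logging.getLogger(__name__)

COMPOUND_TYPE = "Compound"


@dataclass(frozen=True)
class RelationProfile:
    """Binary outgoing-relation indicator vector for one drug.

    The vector has one entry per relation in ``R`` *except* the indication
    relation; entry order follows the KG's sorted vocabulary.
    """

    drug: str
    vector: tuple[int, ...]


def profile_relations(g: KnowledgeGraph) -> tuple[str, ...]:
    """Relations spanning the profile space: R minus the indication relation."""
    return tuple(r for r in g.relations if r != g.indication_relation)


def relation_profile(g: KnowledgeGraph, drug: str) -> RelationProfile:
    if drug not in g.node_type:
        raise KeyError(f"unknown node {drug!r}")
    outgoing = {r for r, _ in g.out_edges(drug)}
    vector = tuple(int(r in outgoing) for r in profile_relations(g))
    return RelationProfile(drug=drug, vector=vector)


def profile_similarity(
    r_u: RelationProfile, r_v: RelationProfile, metric: str = "cosine"
) -> float:
    """Profile similarity: cosine (default) or the plain inner product of
    the connectivity patterns; cosine is 0.0 if either vector is all-zero."""
    if len(r_u.vector) != len(r_v.vector):
        raise ValueError(
            f"profile length mismatch: {len(r_u.vector)} vs {len(r_v.vector)}"
        )
    u = np.asarray(r_u.vector, dtype=float)
    v = np.asarray(r_v.vector, dtype=float)
    if metric == "inner":
        return float(u @ v)
    if metric != "cosine":
        raise ValueError(f"unknown similarity metric {metric!r}")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        return 0.0
    return float(u @ v / (nu * nv))


@dataclass(frozen=True)
class DrugCase:
    """A retrieved case: a similar drug together with its known indications."""

    drug: str
    similarity: float
    indications: frozenset[str]


def retrieve_knn(g: KnowledgeGraph, query_drug: str, k: int,
                 metric: str = "cosine") -> list[DrugCase]:
    """The ``k`` most profile-similar drugs to ``query_drug`` (query excluded).

    Drugs without any indication edge cannot contribute reasoning paths and
    are skipped before ranking.  Ties in similarity break lexicographically
    by node id.  Fewer than ``k`` eligible drugs is not an error: all
    eligible cases are returned with a warning.
    """
    if g.type_of(query_drug) != COMPOUND_TYPE:
        raise ValueError(
            f"query {query_drug!r} has type {g.type_of(query_drug)!r}, "
            f"expected {COMPOUND_TYPE!r}"
        )
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")

    q_profile = relation_profile(g, query_drug)
    scored: list[tuple[float, str, frozenset[str]]] = []
    for drug in g.nodes_of_type(COMPOUND_TYPE):
        if drug == query_drug:
            continue
        indications = frozenset(g.indications_of(drug))
        if not indications:
            continue
        sim = profile_similarity(q_profile, relation_profile(g, drug),
                                 metric=metric)
        scored.append((sim, drug, indications))

    scored.sort(key=lambda item: (-item[0], item[1]))
    if len(scored) < k:
        logger.warning(
            "only %d eligible case drugs for query %s (k=%d)",
            len(scored), query_drug, k,
        )
    return [
        DrugCase(drug=d, similarity=s, indications=ind)
        for s, d, ind in scored[:k]
    ]


def save_similarity_cache(g: KnowledgeGraph, path: str) -> None:
    """Precompute all pairwise drug similarities to a TSV (KG checksum in the
    header line so stale caches are detectable)."""
    drugs = g.nodes_of_type(COMPOUND_TYPE)
    profiles = {d: relation_profile(g, d) for d in drugs}
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# kg_checksum={g.checksum()}\n")
        fh.write("drug_a\tdrug_b\tsimilarity\n")
        for i, a in enumerate(drugs):
            for b in drugs[i + 1:]:
                fh.write(f"{a}\t{b}\t{profile_similarity(profiles[a], profiles[b]):.10g}\n")


def load_similarity_cache(g: KnowledgeGraph, path: str) -> dict[tuple[str, str], float]:
    with open(path, encoding="utf-8") as fh:
        first = fh.readline().strip()
        if first != f"# kg_checksum={g.checksum()}":
            raise ValueError(
                f"{path}: similarity cache was built for a different KG "
                "(checksum mismatch); regenerate it"
            )
        fh.readline()  # column header
        cache: dict[tuple[str, str], float] = {}
        for line in fh:
            if not line.strip():
                continue
            a, b, s = line.rstrip("\n").split("\t")
            cache[(a, b)] = float(s)
            cache[(b, a)] = float(s)
    return cache
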