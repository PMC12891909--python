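"""Step 2 — reuse: mine mechanistic chains from case drugs, abstract them to
meta-paths, re-instantiate them from the query drug, and union the matches
into a query-specific subgraph.

A *path instance* is a concrete simple path drug → ... → disease of at most
``max_hops`` steps; traversal may walk stored edges backwards (inverse
twins, flagged).  A *meta-path* abstracts an instance to its alternating
sequence of node types and (direction-flagged) relation labels.  Matching a
meta-path from the query is exact on both relation labels and node types,
hop by hop.

The direct indication edge between a drug and the disease being reached is
never part of a mined or instantiated path: it is the very link the model
predicts, and including it would trivialize both prediction and
explanation.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .kg import Hop, KnowledgeGraph, Provenance, QuerySubgraph, Triple
from .retrieval import DrugCase

logger = logging.getLogger(__name__)

DISEASE_TYPE = "Disease"

DEFAULT_MAX_HOPS = 3
DEFAULT_INSTANTIATION_CAP = 10_000


@dataclass(frozen=True)
class PathInstance:
    """A concrete simple path: nodes [v0..vL] and the L hops between them."""

    nodes: tuple[str, ...]
    hops: tuple[Hop, ...]

    def __post_init__(self) -> None:
        if len(self.hops) != len(self.nodes) - 1:
            raise ValueError("hop count must be len(nodes) - 1")
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("paths must be simple (no repeated node)")

    @property
    def length(self) -> int:
        return len(self.hops)

    def stored_edges(self) -> list[Triple]:
        """The underlying stored triples, in forward (as-stored) orientation."""
        out = []
        for i, hop in enumerate(self.hops):
            u, v = self.nodes[i], self.nodes[i + 1]
            out.append(Triple(v, hop.relation, u) if hop.inverse else Triple(u, hop.relation, v))
        return out

    def as_record(self) -> list[str]:
        """Interleaved [node, hop, node, ...] text form (``^rel`` = inverse)."""
        rec = [self.nodes[0]]
        for hop, node in zip(self.hops, self.nodes[1:]):
            rec.extend([str(hop), node])
        return rec


@dataclass(frozen=True)
class MetaPath:
    """Alternating node-type / hop-label sequence abstracted from a path."""

    type_sequence: tuple[str, ...]

    @property
    def id(self) -> str:
        digest = hashlib.sha1("|".join(self.type_sequence).encode()).hexdigest()
        return digest[:12]

    @property
    def length(self) -> int:
        return len(self.type_sequence) // 2

    def hop_at(self, i: int) -> Hop:
        return Hop.parse(self.type_sequence[2 * i + 1])

    def type_at(self, i: int) -> str:
        return self.type_sequence[2 * i]


def _edge_of_hop(u: str, hop: Hop, v: str) -> Triple:
    return Triple(v, hop.relation, u) if hop.inverse else Triple(u, hop.relation, v)


def enumerate_case_paths(
    g: KnowledgeGraph, case: DrugCase, max_hops: int = DEFAULT_MAX_HOPS
) -> list[PathInstance]:
    """All simple paths of length <= max_hops from the case drug to each of
    its indications, excluding the direct indication edge itself (in either
    traversal direction)."""
    if max_hops < 1:
        raise ValueError(f"max_hops must be >= 1, got {max_hops}")
    results: list[PathInstance] = []
    for disease in sorted(case.indications):
        forbidden = Triple(case.drug, g.indication_relation, disease)
        stack_nodes = [case.drug]
        stack_hops: list[Hop] = []

        def dfs(current: str) -> None:
            if current == disease and stack_hops:
                results.append(
                    PathInstance(tuple(stack_nodes), tuple(stack_hops))
                )
                return  # extending past the target cannot stay simple & end there
            if len(stack_hops) == max_hops:
                return
            for hop, nxt in g.neighbors(current):
                if nxt in stack_nodes:
                    continue
                if _edge_of_hop(current, hop, nxt) == forbidden:
                    continue
                stack_nodes.append(nxt)
                stack_hops.append(hop)
                dfs(nxt)
                stack_nodes.pop()
                stack_hops.pop()

        dfs(case.drug)
    return sorted(results, key=lambda p: (p.length, p.nodes, p.hops))


def abstract_meta_path(p: PathInstance, g: KnowledgeGraph) -> MetaPath:
    seq: list[str] = [g.type_of(p.nodes[0])]
    for hop, node in zip(p.hops, p.nodes[1:]):
        seq.append(str(hop))
        seq.append(g.type_of(node))
    return MetaPath(tuple(seq))


def instantiate_meta_paths(
    g: KnowledgeGraph,
    query_drug: str,
    metapaths: Iterable[MetaPath],
    cap: int = DEFAULT_INSTANTIATION_CAP,
) -> list[tuple[PathInstance, MetaPath]]:
    """Every simple path from ``query_drug`` whose hop-by-hop relation labels,
    direction flags and node types exactly match one of ``metapaths``.

    A per-meta-path cap (discovery order) guards combinatorial blowup;
    truncation is logged.  A match whose final hop is the query's own direct
    indication edge to the path terminus is discarded (that edge is the
    prediction target, see module docstring).
    """
    out: list[tuple[PathInstance, MetaPath]] = []
    query_type = g.type_of(query_drug)
    for mp in sorted(set(metapaths), key=lambda m: m.id):
        if mp.type_at(0) != query_type:
            continue
        found = 0
        truncated = False
        stack_nodes = [query_drug]
        stack_hops: list[Hop] = []

        def dfs(current: str, depth: int) -> None:
            nonlocal found, truncated
            if truncated:
                return
            if depth == mp.length:
                last_edge = _edge_of_hop(
                    stack_nodes[-2], stack_hops[-1], stack_nodes[-1]
                )
                if last_edge == Triple(query_drug, g.indication_relation, current):
                    return
                if found >= cap:
                    truncated = True
                    return
                out.append((PathInstance(tuple(stack_nodes), tuple(stack_hops)), mp))
                found += 1
                return
            want_hop = mp.hop_at(depth)
            want_type = mp.type_at(depth + 1)
            for hop, nxt in g.neighbors(current):
                if hop != want_hop or nxt in stack_nodes:
                    continue
                if g.type_of(nxt) != want_type:
                    continue
                stack_nodes.append(nxt)
                stack_hops.append(hop)
                dfs(nxt, depth + 1)
                stack_nodes.pop()
                stack_hops.pop()

        dfs(query_drug, 0)
        if truncated:
            logger.warning(
                "instantiation cap %d hit for meta-path %s from %s",
                cap, mp.id, query_drug,
            )
    return out


def build_query_subgraph(
    g: KnowledgeGraph,
    query_drug: str,
    instances: Sequence[PathInstance],
    provenance: Sequence[Provenance],
) -> QuerySubgraph:
    """Union the instantiated paths into one query-specific subgraph.

    ``provenance`` pairs (case_drug, meta_path_id) align with ``instances``;
    an edge shared by several instances accumulates every record.  Candidate
    diseases are the Disease-typed path termini.  The result is insensitive
    to instance ordering (edges and provenance are set-merged).
    """
    if len(instances) != len(provenance):
        raise ValueError("instances and provenance must align")
    for inst in instances:
        if inst.nodes[0] != query_drug:
            raise ValueError(
                f"instance starting at {inst.nodes[0]!r} does not start "
                f"at query drug {query_drug!r}"
            )
    if not instances:
        logger.warning("no path instances for query %s: empty subgraph", query_drug)

    edges: set[Triple] = set()
    prov_map: dict[Triple, set[Provenance]] = {}
    node_type: dict[str, str] = {query_drug: g.type_of(query_drug)}
    candidates: set[str] = set()
    for inst, prov in zip(instances, provenance):
        for node in inst.nodes:
            node_type[node] = g.type_of(node)
        terminal = inst.nodes[-1]
        if g.type_of(terminal) == DISEASE_TYPE:
            candidates.add(terminal)
        for edge in inst.stored_edges():
            edges.add(edge)
            prov_map.setdefault(edge, set()).add(prov)

    sub_kg = KnowledgeGraph(
        node_type=node_type,
        edges=edges,
        indication_relation=g.indication_relation,
        relations=g.relations,  # keep the parent vocabulary: stable indexing
    )
    return QuerySubgraph(
        query_drug=query_drug,
        graph=sub_kg,
        candidate_diseases=candidates,
        provenance={e: sorted(v) for e, v in prov_map.items()},
    )


def build_case_subgraph(
    g: KnowledgeGraph, case: DrugCase, max_hops: int = DEFAULT_MAX_HOPS
) -> QuerySubgraph:
    """The case drug's own reasoning subgraph: the union of its mined paths."""
    instances = enumerate_case_paths(g, case, max_hops)
    provenance = [
        (case.drug, abstract_meta_path(p, g).id) for p in instances
    ]
    return build_query_subgraph(g, case.drug, instances, provenance)


def construct_query_subgraph(
    g: KnowledgeGraph,
    query_drug: str,
    cases: Sequence[DrugCase],
    max_hops: int = DEFAULT_MAX_HOPS,
    cap: int = DEFAULT_INSTANTIATION_CAP,
    min_metapath_support: int = 1,
) -> tuple[QuerySubgraph, dict[str, MetaPath]]:
    """Full reuse step: mine case paths, abstract, filter by support across
    cases, instantiate from the query, and union.  Returns the subgraph and
    the meta-path library used (id → MetaPath)."""
    support: dict[MetaPath, set[str]] = {}
    mp_cases: dict[MetaPath, list[str]] = {}
    for case in cases:
        for p in enumerate_case_paths(g, case, max_hops):
            mp = abstract_meta_path(p, g)
            support.setdefault(mp, set()).add(case.drug)
            mp_cases.setdefault(mp, []).append(case.drug)
    kept = {
        mp for mp, drugs in support.items() if len(drugs) >= min_metapath_support
    }
    matches = instantiate_meta_paths(g, query_drug, kept, cap=cap)
    instances = [inst for inst, _ in matches]
    provenance: list[Provenance] = [
        (sorted(support[mp])[0], mp.id) for _, mp in matches
    ]
    sg = build_query_subgraph(g, query_drug, instances, provenance)
    return sg, {mp.id: mp for mp in kept}


def save_metapaths(metapaths: Iterable[MetaPath], path: str | Path) -> None:
    """Serialize a meta-path library as JSON lines ({id, type_sequence})."""
    with open(path, "w", encoding="utf-8") as fh:
        for mp in sorted(set(metapaths), key=lambda m: m.id):
            fh.write(json.dumps({"id": mp.id, "type_sequence": list(mp.type_sequence)}) + "\n")


def load_metapaths(path: str | Path) -> list[MetaPath]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                rec = json.loads(line)
                out.append(MetaPath(tuple(rec["type_sequence"])))
    return out
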