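"""Heterogeneous knowledge-graph data model, file I/O and basic graph queries.

A knowledge graph here is a typed multigraph over opaque string node
identifiers (CURIEs are fine): every node carries a type label (Compound,
Gene, Pathway, Disease, ...), every directed edge carries a relation label
drawn from an ordered relation vocabulary ``R``.  One relation is designated
the *indication relation* (drug → disease treatment edges); it is the link
type being predicted and is treated specially throughout the package.

Edges are stored as directed triples.  Mechanism chains are traversed in
either direction, so adjacency views expose each stored edge twice: once
forward and once as a flagged *inverse twin*.  Inverse twins never appear in
serialized output.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

logger = logging.getLogger(__name__)


class Triple(NamedTuple):
    """A directed typed edge (head, relation, tail)."""

    head: str
    relation: str
    tail: str


class Hop(NamedTuple):
    """One traversal step along a path: a relation label plus a direction flag.

    ``inverse=True`` means the underlying stored edge points the other way
    (the hop walked head←tail).  The label is always the user-facing relation
    from ``R``; inverse twins are a traversal device, not vocabulary.
    """

    relation: str
    inverse: bool = False

    def __str__(self) -> str:  # "^rel" marks an inverse hop in text formats
        return ("^" + self.relation) if self.inverse else self.relation

    @classmethod
    def parse(cls, text: str) -> "Hop":
        if text.startswith("^"):
            return cls(text[1:], True)
        return cls(text, False)


@dataclass
class KnowledgeGraph:
    """Typed nodes plus a deduplicated set of directed typed triples.

    ``relations`` is the sorted, stable relation vocabulary; relation
    profiles and encoder parameter channels index into it, so its order must
    survive save/load round trips (sorting makes that automatic).
    """

    node_type: dict[str, str]
    edges: set[Triple]
    indication_relation: str
    relations: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if not self.relations:
            self.relations = tuple(sorted({e.relation for e in self.edges}))
        self._validate()
        self._out: dict[str, list[tuple[str, str]]] | None = None
        self._in: dict[str, list[tuple[str, str]]] | None = None

    def _validate(self) -> None:
        rel_set = set(self.relations)
        for e in self.edges:
            if e.head not in self.node_type:
                raise ValueError(f"edge endpoint {e.head!r} has no node-type entry")
            if e.tail not in self.node_type:
                raise ValueError(f"edge endpoint {e.tail!r} has no node-type entry")
            if e.relation not in rel_set:
                raise ValueError(f"edge relation {e.relation!r} not in vocabulary")
        if self.indication_relation not in rel_set:
            raise ValueError(
                f"indication relation {self.indication_relation!r} not among "
                f"relations {sorted(rel_set)}"
            )

    # -- basic views ------------------------------------------------------

    @property
    def nodes(self) -> set[str]:
        return set(self.node_type)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def type_of(self, node: str) -> str:
        try:
            return self.node_type[node]
        except KeyError:
            raise KeyError(f"unknown node {node!r}") from None

    def nodes_of_type(self, type_label: str) -> list[str]:
        return sorted(n for n, t in self.node_type.items() if t == type_label)

    def relation_index(self, relation: str) -> int:
        return self.relations.index(relation)

    def _build_adjacency(self) -> None:
        out: dict[str, list[tuple[str, str]]] = {n: [] for n in self.node_type}
        inc: dict[str, list[tuple[str, str]]] = {n: [] for n in self.node_type}
        for e in sorted(self.edges):
            out[e.head].append((e.relation, e.tail))
            inc[e.tail].append((e.relation, e.head))
        self._out, self._in = out, inc

    def out_edges(self, node: str) -> list[tuple[str, str]]:
        """Sorted (relation, tail) pairs for stored edges leaving ``node``."""
        if self._out is None:
            self._build_adjacency()
        if node not in self.node_type:
            raise KeyError(f"unknown node {node!r}")
        return self._out[node]  # type: ignore[index]

    def in_edges(self, node: str) -> list[tuple[str, str]]:
        """Sorted (relation, head) pairs for stored edges entering ``node``."""
        if self._in is None:
            self._build_adjacency()
        if node not in self.node_type:
            raise KeyError(f"unknown node {node!r}")
        return self._in[node]  # type: ignore[index]

    def neighbors(self, node: str) -> list[tuple[Hop, str]]:
        """All traversal steps from ``node``: forward edges plus inverse twins."""
        steps = [(Hop(r, False), t) for r, t in self.out_edges(node)]
        steps += [(Hop(r, True), h) for r, h in self.in_edges(node)]
        return steps

    def has_edge(self, head: str, relation: str, tail: str) -> bool:
        return Triple(head, relation, tail) in self.edges

    def indications_of(self, drug: str) -> set[str]:
        """Disease nodes linked from ``drug`` by the indication relation."""
        return {t for r, t in self.out_edges(drug) if r == self.indication_relation}

    def checksum(self) -> str:
        """Stable content hash over sorted triples, types and the vocabulary."""
        h = hashlib.sha256()
        for e in sorted(self.edges):
            h.update(("\t".join(e) + "\n").encode())
        for n in sorted(self.node_type):
            h.update(f"{n}\t{self.node_type[n]}\n".encode())
        h.update("|".join(self.relations).encode())
        h.update(self.indication_relation.encode())
        return h.hexdigest()[:16]

    def copy_without_edges(self, removed: Iterable[Triple]) -> "KnowledgeGraph":
        removed = set(removed)
        return KnowledgeGraph(
            node_type=dict(self.node_type),
            edges={e for e in self.edges if e not in removed},
            indication_relation=self.indication_relation,
            relations=self.relations,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, KnowledgeGraph):
            return NotImplemented
        return (
            self.node_type == other.node_type
            and self.edges == other.edges
            and self.relations == other.relations
            and self.indication_relation == other.indication_relation
        )


def node_degree(g: KnowledgeGraph, v: str) -> int:
    """Total degree (in + out) of ``v`` counting each stored typed edge once."""
    return len(g.out_edges(v)) + len(g.in_edges(v))


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------

def load_kg(
    triple_table_path: str | Path,
    node_type_path: str | Path,
    indication_relation: str,
) -> KnowledgeGraph:
    """Read a KG from a triple TSV (``head  relation  tail``) and a node-type
    TSV (``node  type``).  Exact duplicate triples are dropped (count logged).
    """
    node_type: dict[str, str] = {}
    with open(node_type_path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["node", "type"]:
            raise ValueError(f"{node_type_path}: expected header 'node\\ttype'")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise ValueError(f"{node_type_path}:{lineno}: expected 2 columns")
            node_type[parts[0]] = parts[1]

    edges: set[Triple] = set()
    n_rows = 0
    with open(triple_table_path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["head", "relation", "tail"]:
            raise ValueError(
                f"{triple_table_path}: expected header 'head\\trelation\\ttail'"
            )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3:
                raise ValueError(f"{triple_table_path}:{lineno}: expected 3 columns")
            h, r, t = parts
            for endpoint in (h, t):
                if endpoint not in node_type:
                    raise ValueError(
                        f"{triple_table_path}:{lineno}: node {endpoint!r} missing "
                        f"from node-type table {node_type_path}"
                    )
            n_rows += 1
            edges.add(Triple(h, r, t))

    dropped = n_rows - len(edges)
    if dropped:
        logger.info("dropped %d exact-duplicate triples", dropped)
    relations = tuple(sorted({e.relation for e in edges}))
    if indication_relation not in relations:
        raise ValueError(
            f"indication relation {indication_relation!r} not found; "
            f"available relations: {list(relations)}"
        )
    kg = KnowledgeGraph(
        node_type=node_type,
        edges=edges,
        indication_relation=indication_relation,
        relations=relations,
    )
    logger.info(
        "loaded KG: %d nodes, %d edges, %d relation types",
        len(kg.nodes), kg.n_edges, len(relations),
    )
    return kg


def save_kg(g: KnowledgeGraph, triple_table_path: str | Path,
            node_type_path: str | Path) -> None:
    with open(triple_table_path, "w", encoding="utf-8") as fh:
        fh.write("head\trelation\ttail\n")
        for e in sorted(g.edges):
            fh.write(f"{e.head}\t{e.relation}\t{e.tail}\n")
    with open(node_type_path, "w", encoding="utf-8") as fh:
        fh.write("node\ttype\n")
        for n in sorted(g.node_type):
            fh.write(f"{n}\t{g.node_type[n]}\n")


# ---------------------------------------------------------------------------
# Query subgraphs
# ---------------------------------------------------------------------------

Provenance = tuple[str, str]  # (case_drug, meta_path_id)


@dataclass
class QuerySubgraph:
    """Union of instantiated reasoning paths rooted at a query drug.

    ``graph`` is a KnowledgeGraph restricted to the instantiated edges
    (the edge set E_i of the explainer); ``provenance`` records, per edge,
    which case drug and meta-path produced it.
    """

    query_drug: str
    graph: KnowledgeGraph
    candidate_diseases: set[str]
    provenance: dict[Triple, list[Provenance]]

    @property
    def edge_list(self) -> list[Triple]:
        """Deterministic (sorted) edge order; mask vectors index into this."""
        return sorted(self.graph.edges)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, QuerySubgraph):
            return NotImplemented
        return (
            self.query_drug == other.query_drug
            and self.graph == other.graph
            and self.candidate_diseases == other.candidate_diseases
            and {k: sorted(v) for k, v in self.provenance.items()}
            == {k: sorted(v) for k, v in other.provenance.items()}
        )


def save_subgraph(sg: QuerySubgraph, path: str | Path) -> None:
    """Write a subgraph as a triple TSV (with node types and a metadata header
    comment) plus a ``.prov.tsv`` sidecar mapping edges to provenance records.
    """
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# query_drug={sg.query_drug}\n")
        fh.write(f"# indication_relation={sg.graph.indication_relation}\n")
        fh.write(f"# relations={','.join(sg.graph.relations)}\n")
        fh.write(f"# candidates={','.join(sorted(sg.candidate_diseases))}\n")
        fh.write(f"# query_drug_type={sg.graph.type_of(sg.query_drug)}\n")
        fh.write("head\thead_type\trelation\ttail\ttail_type\n")
        for e in sorted(sg.graph.edges):
            fh.write(
                f"{e.head}\t{sg.graph.type_of(e.head)}\t{e.relation}"
                f"\t{e.tail}\t{sg.graph.type_of(e.tail)}\n"
            )
    with open(path.with_suffix(path.suffix + ".prov.tsv"), "w", encoding="utf-8") as fh:
        fh.write("head\trelation\ttail\tcase_drug\tmeta_path_id\n")
        for e in sorted(sg.provenance):
            for case_drug, mp_id in sorted(sg.provenance[e]):
                fh.write(f"{e.head}\t{e.relation}\t{e.tail}\t{case_drug}\t{mp_id}\n")


def load_subgraph(path: str | Path) -> QuerySubgraph:
    path = Path(path)
    meta: dict[str, str] = {}
    node_type: dict[str, str] = {}
    edges: set[Triple] = set()
    with open(path, encoding="utf-8") as fh:
        lineno = 0
        header_seen = False
        for line in fh:
            lineno += 1
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("# "):
                try:
                    key, value = line[2:].split("=", 1)
                except ValueError:
                    raise ValueError(f"{path}:{lineno}: malformed metadata line")
                meta[key] = value
                continue
            if not header_seen:
                if line.split("\t") != ["head", "head_type", "relation", "tail", "tail_type"]:
                    raise ValueError(f"{path}:{lineno}: unexpected column header")
                header_seen = True
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise ValueError(f"{path}:{lineno}: expected 5 columns, got {len(parts)}")
            h, ht, r, t, tt = parts
            node_type[h] = ht
            node_type[t] = tt
            edges.add(Triple(h, r, t))
    for key in ("query_drug", "indication_relation", "relations", "query_drug_type"):
        if key not in meta:
            raise ValueError(f"{path}: missing metadata line '# {key}=...'")
    node_type.setdefault(meta["query_drug"], meta["query_drug_type"])
    candidates = set(filter(None, meta.get("candidates", "").split(",")))
    relations = tuple(filter(None, meta["relations"].split(",")))

    provenance: dict[Triple, list[Provenance]] = {}
    prov_path = path.with_suffix(path.suffix + ".prov.tsv")
    if prov_path.exists():
        with open(prov_path, encoding="utf-8") as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header != ["head", "relation", "tail", "case_drug", "meta_path_id"]:
                raise ValueError(f"{prov_path}:1: unexpected column header")
            for lineno, line in enumerate(fh, start=2):
                if not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) != 5:
                    raise ValueError(f"{prov_path}:{lineno}: expected 5 columns")
                h, r, t, case_drug, mp_id = parts
                provenance.setdefault(Triple(h, r, t), []).append((case_drug, mp_id))

    graph = KnowledgeGraph(
        node_type=node_type,
        edges=edges,
        indication_relation=meta["indication_relation"],
        relations=relations,
    )
    return QuerySubgraph(
        query_drug=meta["query_drug"],
        graph=graph,
        candidate_diseases=candidates,
        provenance=provenance,
    )


# ---------------------------------------------------------------------------
# Ground-truth mechanism path files
# ---------------------------------------------------------------------------

def load_truth_paths(path: str | Path) -> dict[tuple[str, str], list[list[str]]]:
    """Read curated mechanism paths: one JSON record per drug–disease pair,
    ``{"drug": ..., "disease": ..., "paths": [[node, rel, node, ..., node]]}``,
    either as a JSON array or as JSON lines.
    """
    text = Path(path).read_text(encoding="utf-8").strip()
    if not text:
        return {}
    if text.startswith("["):
        records = json.loads(text)
    else:
        records = [json.loads(line) for line in text.splitlines() if line.strip()]
    truth: dict[tuple[str, str], list[list[str]]] = {}
    for rec in records:
        key = (rec["drug"], rec["disease"])
        truth.setdefault(key, []).extend([list(p) for p in rec["paths"]])
    return truth


def save_truth_paths(
    truth: Mapping[tuple[str, str], Sequence[Sequence[str]]], path: str | Path
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for (drug, disease) in sorted(truth):
            rec = {
                "drug": drug,
                "disease": disease,
                "paths": [list(p) for p in truth[(drug, disease)]],
            }
            fh.write(json.dumps(rec) + "\n")


def truth_path_edges(paths: Iterable[Sequence[str]]) -> set[Triple]:
    """Edge set of interleaved [node, rel, node, rel, ..., node] path records."""
    out: set[Triple] = set()
    for p in paths:
        if len(p) < 3 or len(p) % 2 == 0:
            raise ValueError(f"malformed path record of length {len(p)}")
        for i in range(0, len(p) - 2, 2):
            out.add(Triple(p[i], p[i + 1], p[i + 2]))
    return out
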