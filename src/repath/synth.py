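"""Seeded generator of small heterogeneous KGs with planted structure.

The generator emulates the regularities that case-based repositioning
exploits: *families* of drugs (pharmacological classes) that share a
meta-path-shaped mechanism template (drug → gene → pathway → disease) with
family-specific relation labels; *disease modules* (each disease has a
canonical pathway, reached through partially shared gene targets, so drugs
in a family can act through different genes while converging on the same
pathways); planted indication edges, a held-out fraction of which is
withheld from the graph but kept in the ground truth; high-degree hub
nodes; and type-consistent random noise edges.

Everything is reproducible from the seed, and the planted mechanisms are
exported in the same curated-mechanism JSON format the evaluation module
consumes, so synthetic truth flows through the exact pipeline real curated
mechanisms would.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

from .kg import Hop, KnowledgeGraph, QuerySubgraph, Triple, save_truth_paths
from .paths import PathInstance

INDICATION_RELATION = "treats"

# relation label pools per hop position; families draw distinct combinations
FIRST_HOP = ["targets", "binds", "inhibits", "activates", "modulates", "antagonizes"]
SECOND_HOP = ["participates_in", "member_of", "regulates"]
THIRD_HOP = ["associated_with", "involved_in", "disrupts"]


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass
class SynthConfig:
    """Study conditions of the synthetic test bed (all counts per family)."""

    n_families: int = 6
    drugs_per_family: int = 8
    genes_per_family: int = 24     # partitioned into per-disease module pools
    pathways_per_family: int = 8   # one canonical pathway per disease
    diseases_per_family: int = 8
    indications_per_drug: int = 4
    held_out_frac: float = 0.25    # 1 of 4 indications withheld per drug
    gene_sharing: float = 0.5      # P(planted path reuses the module's canonical gene)
    shared_diseases: int = 4       # cross-family indications (inflammation-like)
    shared_genes_per_disease: int = 3
    shared_indication_prob: float = 0.5  # P(a drug also treats a shared disease)
    hub_count: int = 2
    hub_degree: int = 15   # bounded by the number of drugs in the graph
    noise_edge_frac: float = 0.1
    family_templates: list[tuple[str, str, str]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_families", "drugs_per_family", "genes_per_family",
                     "pathways_per_family", "diseases_per_family",
                     "indications_per_drug"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("held_out_frac", "noise_edge_frac"):
            if not (0.0 <= getattr(self, name) < 1.0):
                raise ValueError(f"{name} must be in [0, 1)")
        if self.indications_per_drug > self.diseases_per_family:
            raise ValueError("indications_per_drug exceeds diseases_per_family")
        n_held = _round_half_up(self.held_out_frac * self.indications_per_drug)
        if n_held >= self.indications_per_drug:
            raise ValueError(
                "held_out_frac would withhold every indication of a drug; "
                "lower it or raise indications_per_drug"
            )

    def templates(self) -> list[tuple[str, str, str]]:
        if self.family_templates is not None:
            if len(self.family_templates) < self.n_families:
                raise ValueError("need one meta-path template per family")
            return [tuple(t) for t in self.family_templates]
        combos = list(itertools.product(THIRD_HOP, SECOND_HOP, FIRST_HOP))
        if self.n_families > len(combos):
            raise ValueError("too many families for the built-in template pool")
        # reversed component order above makes the first hop vary fastest,
        # so small family counts already get distinct relation signatures
        return [(c[2], c[1], c[0]) for c in combos[: self.n_families]]


@dataclass
class GroundTruth:
    """Planted labels: full indication sets, the withheld subset, and the
    planted mechanism path(s) per (drug, disease) pair."""

    indications: dict[str, set[str]]
    held_out: dict[str, set[str]]
    mechanisms: dict[tuple[str, str], list[PathInstance]]
    family_of: dict[str, int] = field(default_factory=dict)

    def mechanism_edges(self, drug: str, disease: str) -> set[Triple]:
        edges: set[Triple] = set()
        for p in self.mechanisms.get((drug, disease), []):
            edges.update(p.stored_edges())
        return edges

    def all_mechanism_edges(self) -> set[Triple]:
        out: set[Triple] = set()
        for key in self.mechanisms:
            out |= self.mechanism_edges(*key)
        return out


def generate(config: SynthConfig) -> tuple[KnowledgeGraph, GroundTruth]:
    """Build the KG and its ground truth; identical output for equal seeds."""
    rng = np.random.default_rng(config.seed)
    templates = config.templates()

    node_type: dict[str, str] = {}
    edges: set[Triple] = set()
    truth = GroundTruth(indications={}, held_out={}, mechanisms={})

    # cross-family ("common") diseases with their own gene/pathway modules;
    # drugs from any family may treat them, through their own relation
    # vocabulary, which links the families via genuine co-indication
    shared_dis = [f"shared_dis{j}" for j in range(config.shared_diseases)]
    shared_path = [f"shared_path{j}" for j in range(config.shared_diseases)]
    shared_genes = {
        j: [f"shared_gene{j}_{i}" for i in range(config.shared_genes_per_disease)]
        for j in range(config.shared_diseases)
    }
    for j in range(config.shared_diseases):
        node_type[shared_dis[j]] = "Disease"
        node_type[shared_path[j]] = "Pathway"
        truth.family_of[shared_dis[j]] = -1
        truth.family_of[shared_path[j]] = -1
        for gene in shared_genes[j]:
            node_type[gene] = "Gene"
            truth.family_of[gene] = -1

    for f in range(config.n_families):
        r1, r2, r3 = templates[f]
        drugs = [f"F{f}_drug{i}" for i in range(config.drugs_per_family)]
        genes = [f"F{f}_gene{j}" for j in range(config.genes_per_family)]
        pathways = [f"F{f}_path{m}" for m in range(config.pathways_per_family)]
        diseases = [f"F{f}_dis{m}" for m in range(config.diseases_per_family)]
        for n, t in itertools.chain(
            ((d, "Compound") for d in drugs),
            ((g, "Gene") for g in genes),
            ((p, "Pathway") for p in pathways),
            ((d, "Disease") for d in diseases),
        ):
            node_type[n] = t
            truth.family_of[n] = f

        for drug in drugs:
            picked = rng.choice(config.diseases_per_family,
                                size=config.indications_per_drug, replace=False)
            indications = [diseases[int(m)] for m in sorted(picked)]
            if config.shared_diseases and rng.random() < config.shared_indication_prob:
                indications.append(
                    shared_dis[int(rng.integers(config.shared_diseases))]
                )
            truth.indications[drug] = set(indications)
            n_held = _round_half_up(config.held_out_frac * len(indications))
            held_idx = rng.choice(len(indications), size=n_held, replace=False)
            held = {indications[int(i)] for i in held_idx}
            truth.held_out[drug] = held

            for disease in indications:
                if disease in shared_dis:
                    j = shared_dis.index(disease)
                    pathway = shared_path[j]
                    module_genes = shared_genes[j]
                else:
                    m = diseases.index(disease)
                    pathway = pathways[m % config.pathways_per_family]
                    # each disease module owns a dedicated pool of druggable
                    # genes: drugs treating it act through different targets
                    # that converge on the module's pathway
                    module_genes = [genes[j] for j in range(config.genes_per_family)
                                    if j % config.diseases_per_family == m]
                if rng.random() < config.gene_sharing:
                    gene = module_genes[0]  # canonical target
                else:
                    gene = module_genes[int(rng.integers(len(module_genes)))]
                path = PathInstance(
                    nodes=(drug, gene, pathway, disease),
                    hops=(Hop(r1), Hop(r2), Hop(r3)),
                )
                truth.mechanisms.setdefault((drug, disease), []).append(path)
                edges.update(path.stored_edges())
                if disease not in held:
                    edges.add(Triple(drug, INDICATION_RELATION, disease))

    # hub nodes: promiscuously bound genes (CYP/albumin-like) that many
    # drugs engage through their characteristic interaction relation but
    # that participate in no disease pathway — high degree without
    # manufacturing mechanism-shaped routes to unrelated diseases
    for h in range(config.hub_count):
        hub = f"hub{h}"
        node_type[hub] = "Gene"
        truth.family_of[hub] = -1
        drugs_all = sorted(n for n, t in node_type.items() if t == "Compound")
        degree = 0
        attempts = 0
        while degree < config.hub_degree and attempts < 50 * config.hub_degree:
            attempts += 1
            drug = drugs_all[int(rng.integers(len(drugs_all)))]
            e = Triple(drug, templates[truth.family_of[drug]][0], hub)
            if e not in edges:
                edges.add(e)
                degree += 1
        if degree < config.hub_degree:
            logger.info("hub %s capped at degree %d", hub, degree)

    # type-consistent random noise (never the indication relation: those
    # edges would silently become false labels)
    n_noise = _round_half_up(config.noise_edge_frac * len(edges))
    signatures = sorted({(node_type[e.head], e.relation, node_type[e.tail])
                         for e in edges if e.relation != INDICATION_RELATION})
    by_type: dict[str, list[str]] = {}
    for n, t in sorted(node_type.items()):
        by_type.setdefault(t, []).append(n)
    added = 0
    attempts = 0
    while added < n_noise and attempts < 100 * max(n_noise, 1):
        attempts += 1
        ht, r, tt = signatures[int(rng.integers(len(signatures)))]
        h = by_type[ht][int(rng.integers(len(by_type[ht])))]
        t = by_type[tt][int(rng.integers(len(by_type[tt])))]
        if ht == "Compound" and truth.family_of.get(h, -1) >= 0:
            r = templates[truth.family_of[h]][0]  # drug keeps its own vocabulary
        e = Triple(h, r, t)
        if h == t or e in edges:
            continue
        edges.add(e)
        added += 1

    kg = KnowledgeGraph(
        node_type=node_type,
        edges=edges,
        indication_relation=INDICATION_RELATION,
    )
    audit(kg, truth)
    return kg, truth


def audit(kg: KnowledgeGraph, truth: GroundTruth) -> None:
    """Verify the construction invariants: planted mechanism edges exist in
    the KG, withheld indication edges do not, held-in ones do."""
    for (drug, disease), paths in truth.mechanisms.items():
        for p in paths:
            for e in p.stored_edges():
                if e not in kg.edges:
                    raise AssertionError(f"planted mechanism edge {e} missing")
    for drug, all_ind in truth.indications.items():
        held = truth.held_out.get(drug, set())
        for disease in all_ind:
            edge = Triple(drug, INDICATION_RELATION, disease)
            if disease in held and edge in kg.edges:
                raise AssertionError(f"held-out edge {edge} leaked into the KG")
            if disease not in held and edge not in kg.edges:
                raise AssertionError(f"held-in edge {edge} missing from the KG")


def export_truth_paths(truth: GroundTruth, path: str | Path) -> None:
    """Write planted mechanisms in the curated-mechanism JSON-lines format."""
    records = {
        key: [p.as_record() for p in paths]
        for key, paths in truth.mechanisms.items()
    }
    save_truth_paths(records, path)


# ---------------------------------------------------------------------------
# Standalone explanation fixture
# ---------------------------------------------------------------------------

def planted_mask_fixture(
    seed: int = 0,
    n_noise: int = 12,
    hub_degree: int = 60,
    planted_interior_degree: int = 10,
) -> tuple[QuerySubgraph, str, set[Triple]]:
    """A query subgraph with one planted 3-hop mechanism and two decoy
    routes to the same disease — one through a degree-``hub_degree`` hub,
    one through near-isolated nodes — plus random noise edges.

    The planted route's interior nodes sit at ``planted_interior_degree``
    (the explainer's preferred connectivity at λ = 10); the decoys bracket
    it from above and below, so degree scoring is what separates them.
    Returns (subgraph, target disease, planted edge set).
    """
    rng = np.random.default_rng(seed)
    node_type: dict[str, str] = {
        "Q": "Compound", "X": "Disease",
        "G1": "Gene", "P1": "Pathway",              # planted route
        "HUB": "Gene", "PH": "Pathway",             # hub decoy route
        "S": "Gene", "PS": "Pathway",               # sparse decoy route
    }
    planted = {
        Triple("Q", "targets", "G1"),
        Triple("G1", "participates_in", "P1"),
        Triple("P1", "associated_with", "X"),
    }
    edges = set(planted)
    edges |= {
        Triple("Q", "targets", "HUB"),
        Triple("HUB", "participates_in", "PH"),
        Triple("PH", "associated_with", "X"),
        Triple("Q", "targets", "S"),
        Triple("S", "participates_in", "PS"),
        Triple("PS", "associated_with", "X"),
    }
    # bring planted interiors up to the preferred degree with filler leaves
    for i in range(planted_interior_degree - 2):
        node_type[f"FPg{i}"] = "Pathway"
        edges.add(Triple("G1", "participates_in", f"FPg{i}"))
        node_type[f"FGp{i}"] = "Gene"
        edges.add(Triple(f"FGp{i}", "participates_in", "P1"))
    # inflate the hub
    for i in range(hub_degree - 2):
        node_type[f"HF{i}"] = "Pathway"
        edges.add(Triple("HUB", "participates_in", f"HF{i}"))
    # noise: random gene→pathway links among filler nodes (never touching X)
    genes = [n for n, t in sorted(node_type.items())
             if t == "Gene" and n not in ("G1", "HUB", "S")]
    paths_ = [n for n, t in sorted(node_type.items())
              if t == "Pathway" and n not in ("P1", "PH", "PS")]
    added = 0
    attempts = 0
    while added < n_noise and attempts < 100 * n_noise:
        attempts += 1
        g_ = genes[int(rng.integers(len(genes)))]
        p_ = paths_[int(rng.integers(len(paths_)))]
        e = Triple(g_, "regulates", p_)
        if e not in edges:
            edges.add(e)
            added += 1
    graph = KnowledgeGraph(
        node_type=node_type,
        edges=edges,
        indication_relation="treats",
        relations=tuple(sorted({e.relation for e in edges} | {"treats"})),
    )
    sg = QuerySubgraph(
        query_drug="Q", graph=graph, candidate_diseases={"X"}, provenance={},
    )
    return sg, "X", planted
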