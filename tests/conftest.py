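import numpy as np
import pytest

from repath.encoder import EncoderConfig, EncoderParams
from repath.kg import KnowledgeGraph, QuerySubgraph, Triple
from repath.pipeline import RunConfig, evaluate_heldout, shuffled_control, train
from repath.synth import SynthConfig, generate


def make_kg(edges, node_type, indication_relation="treats", relations=None):
    return KnowledgeGraph(
        node_type=dict(node_type),
        edges={Triple(*e) for e in edges},
        indication_relation=indication_relation,
        relations=tuple(relations) if relations else (),
    )


@pytest.fixture
def chain_kg():
    """A mechanism chain: drug → gene → pathway → disease plus the treats edge."""
    return make_kg(
        edges=[
            ("C1", "targets", "G1"),
            ("G1", "participates_in", "P1"),
            ("P1", "associated_with", "D1"),
            ("C1", "treats", "D1"),
        ],
        node_type={"C1": "Compound", "G1": "Gene", "P1": "Pathway",
                   "D1": "Disease"},
    )


@pytest.fixture
def diamond_kg():
    """Two gene routes from one drug to one disease (plus the treats edge)."""
    return make_kg(
        edges=[
            ("C1", "targets", "Ga"),
            ("C1", "targets", "Gb"),
            ("Ga", "associated_with", "D1"),
            ("Gb", "associated_with", "D1"),
            ("C1", "treats", "D1"),
        ],
        node_type={"C1": "Compound", "Ga": "Gene", "Gb": "Gene",
                   "D1": "Disease"},
    )


@pytest.fixture(scope="session")
def synth_kg():
    kg, truth = generate(SynthConfig(seed=0))
    return kg, truth


def subgraph_of(kg, query_drug, edges=None):
    edges = set(edges) if edges is not None else set(kg.edges)
    graph = KnowledgeGraph(
        node_type=dict(kg.node_type),
        edges=edges,
        indication_relation=kg.indication_relation,
        relations=kg.relations,
    )
    candidates = {n for n, t in kg.node_type.items() if t == "Disease"}
    return QuerySubgraph(query_drug=query_drug, graph=graph,
                         candidate_diseases=candidates, provenance={})


def random_params(graph, seed=0, dim=16, layers=2, bases=3):
    cfg = EncoderConfig(embedding_dim=dim, num_layers=layers, num_bases=bases,
                        seed=seed)
    return EncoderParams(cfg, sorted(set(graph.node_type.values())),
                         graph.relations, np.random.default_rng(seed))


def default_params(graph, seed=0):
    """An encoder of the package-default architecture, randomly initialized."""
    cfg = EncoderConfig(seed=seed)
    return EncoderParams(cfg, sorted(set(graph.node_type.values())),
                         graph.relations, np.random.default_rng(seed))


@pytest.fixture(scope="session")
def trained_seed0(synth_kg):
    """One full training run on the default synthetic KG (shared across the
    suite: training is the expensive step)."""
    kg, truth = synth_kg
    params = train(kg, RunConfig(seed=0))
    report, rankings = evaluate_heldout(kg, truth.held_out, params)
    control = shuffled_control(rankings, truth.held_out, seed=0)
    return {"kg": kg, "truth": truth, "params": params,
            "report": report, "rankings": rankings, "control": control}
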