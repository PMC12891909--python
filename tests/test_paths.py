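import random

import pytest

from repath.kg import Hop, Triple
from repath.paths import (
    MetaPath,
    PathInstance,
    abstract_meta_path,
    build_case_subgraph,
    build_query_subgraph,
    construct_query_subgraph,
    enumerate_case_paths,
    instantiate_meta_paths,
)
from repath.retrieval import DrugCase, retrieve_knn

from conftest import make_kg
from oracles import all_simple_paths


def case(drug, indications, sim=1.0):
    return DrugCase(drug=drug, similarity=sim, indications=frozenset(indications))


def signatures(paths):
    return {(p.nodes, tuple((h.relation, h.inverse) for h in p.hops))
            for p in paths}


class TestEnumerateCasePaths:
    def test_direct_indication_edge_only_gives_nothing(self):
        kg = make_kg([("c", "treats", "x")],
                     {"c": "Compound", "x": "Disease"})
        assert enumerate_case_paths(kg, case("c", {"x"}), 3) == []

    def test_three_hop_chain_found_only_at_sufficient_depth(self, chain_kg):
        c = case("C1", {"D1"})
        found3 = enumerate_case_paths(chain_kg, c, 3)
        assert signatures(found3) == {(
            ("C1", "G1", "P1", "D1"),
            (("targets", False), ("participates_in", False),
             ("associated_with", False)),
        )}
        assert enumerate_case_paths(chain_kg, c, 2) == []

    def test_diamond_motif_yields_two_paths(self, diamond_kg):
        found = enumerate_case_paths(diamond_kg, case("C1", {"D1"}), 3)
        assert len(found) == 2

    def test_matches_exhaustive_search(self, synth_kg):
        kg, truth = synth_kg
        drug = kg.nodes_of_type("Compound")[0]
        indications = kg.indications_of(drug)
        got = enumerate_case_paths(kg, case(drug, indications), 3)
        expected = set()
        for disease in indications:
            forbidden = (Triple(drug, "treats", disease),)
            for nodes, hops in all_simple_paths(kg, drug, disease, 3):
                used = [
                    (nodes[i + 1], rel, nodes[i]) if inv
                    else (nodes[i], rel, nodes[i + 1])
                    for i, (rel, inv) in enumerate(hops)
                ]
                if Triple(drug, "treats", disease) in {Triple(*u) for u in used}:
                    continue
                expected.add((nodes, hops))
        assert signatures(got) == expected

    def test_deeper_search_is_monotone(self, synth_kg):
        kg, _ = synth_kg
        drug = kg.nodes_of_type("Compound")[3]
        c = case(drug, kg.indications_of(drug))
        assert signatures(enumerate_case_paths(kg, c, 2)) <= signatures(
            enumerate_case_paths(kg, c, 3)
        )


class TestMetaPath:
    def test_chain_abstraction(self, chain_kg):
        p = PathInstance(("C1", "G1", "P1", "D1"),
                         (Hop("targets"), Hop("participates_in"),
                          Hop("associated_with")))
        mp = abstract_meta_path(p, chain_kg)
        assert mp.type_sequence == (
            "Compound", "targets", "Gene", "participates_in", "Pathway",
            "associated_with", "Disease",
        )

    def test_same_types_collapse_to_same_id(self, diamond_kg):
        pa = PathInstance(("C1", "Ga", "D1"),
                          (Hop("targets"), Hop("associated_with")))
        pb = PathInstance(("C1", "Gb", "D1"),
                          (Hop("targets"), Hop("associated_with")))
        assert (abstract_meta_path(pa, diamond_kg).id
                == abstract_meta_path(pb, diamond_kg).id)

    def test_inverse_flag_is_preserved(self, chain_kg):
        p = PathInstance(("G1", "C1"), (Hop("targets", True),))
        mp = abstract_meta_path(p, chain_kg)
        assert mp.type_sequence == ("Gene", "^targets", "Compound")
        assert mp.hop_at(0) == Hop("targets", True)


class TestInstantiate:
    def test_no_matching_first_hop_gives_empty(self, chain_kg):
        mp = MetaPath(("Compound", "binds", "Gene"))
        assert instantiate_meta_paths(chain_kg, "C1", [mp]) == []

    def test_two_genes_match_twice(self, diamond_kg):
        mp = MetaPath(("Compound", "targets", "Gene",
                       "associated_with", "Disease"))
        matches = instantiate_meta_paths(diamond_kg, "C1", [mp])
        assert len(matches) == 2
        assert {inst.nodes[1] for inst, _ in matches} == {"Ga", "Gb"}

    def test_direct_indication_edge_is_never_a_path(self):
        kg = make_kg(
            [("c", "treats", "x"), ("c2", "treats", "x")],
            {"c": "Compound", "c2": "Compound", "x": "Disease"},
        )
        mp = MetaPath(("Compound", "treats", "Disease"))
        matches = instantiate_meta_paths(kg, "c", [mp])
        assert matches == []

    def test_cap_truncates(self, diamond_kg):
        mp = MetaPath(("Compound", "targets", "Gene",
                       "associated_with", "Disease"))
        matches = instantiate_meta_paths(diamond_kg, "C1", [mp], cap=1)
        assert len(matches) == 1

    def test_equals_typed_exhaustive_search(self, synth_kg):
        """Instantiation agrees with filtering an exhaustive path search
        by the meta-path's type/relation signature."""
        kg, _ = synth_kg
        drug = kg.nodes_of_type("Compound")[5]
        cases = retrieve_knn(kg, drug, 5)
        mps = set()
        for c in cases:
            for p in enumerate_case_paths(kg, c, 3):
                mps.add(abstract_meta_path(p, kg))
        got = instantiate_meta_paths(kg, drug, mps)
        diseases = set(kg.nodes_of_type("Disease"))
        expected = set()
        for nodes, hops in all_simple_paths_any_target(kg, drug, 3):
            seq = [kg.type_of(nodes[0])]
            for (rel, inv), node in zip(hops, nodes[1:]):
                seq.append(("^" if inv else "") + rel)
                seq.append(kg.type_of(node))
            if MetaPath(tuple(seq)) not in mps:
                continue
            last_rel, last_inv = hops[-1]
            if (not last_inv and len(nodes) == 2
                    and Triple(nodes[0], "treats", nodes[1]) in kg.edges
                    and last_rel == "treats"):
                continue
            expected.add((nodes, hops))
        assert signatures(inst for inst, _ in got) == expected


def all_simple_paths_any_target(kg, source, max_hops):
    """Exhaustive simple walks from source (any endpoint), both directions."""
    steps = {}
    for e in kg.edges:
        steps.setdefault(e.head, []).append(((e.relation, False), e.tail))
        steps.setdefault(e.tail, []).append(((e.relation, True), e.head))
    out = []

    def recurse(node, nodes, hops):
        if hops:
            out.append((tuple(nodes), tuple(hops)))
        if len(hops) == max_hops:
            return
        for hop, nxt in steps.get(node, []):
            if nxt in nodes:
                continue
            recurse(nxt, nodes + [nxt], hops + [hop])

    recurse(source, [source], [])
    return out


class TestBuildQuerySubgraph:
    def test_single_path(self, chain_kg):
        inst = PathInstance(("C1", "G1", "P1", "D1"),
                            (Hop("targets"), Hop("participates_in"),
                             Hop("associated_with")))
        sg = build_query_subgraph(chain_kg, "C1", [inst], [("caseA", "mp")])
        assert len(sg.graph.nodes) == 4
        assert sg.graph.n_edges == 3
        assert sg.candidate_diseases == {"D1"}

    def test_shared_edge_merges_provenance(self, diamond_kg):
        p1 = PathInstance(("C1", "Ga", "D1"),
                          (Hop("targets"), Hop("associated_with")))
        p2 = PathInstance(("C1", "Ga"), (Hop("targets"),))
        sg = build_query_subgraph(diamond_kg, "C1", [p1, p2],
                                  [("a", "m1"), ("b", "m2")])
        assert sg.provenance[Triple("C1", "targets", "Ga")] == [
            ("a", "m1"), ("b", "m2")
        ]

    def test_order_insensitive(self, synth_kg):
        kg, _ = synth_kg
        drug = kg.nodes_of_type("Compound")[0]
        c = DrugCase(drug=drug, similarity=1.0,
                     indications=frozenset(kg.indications_of(drug)))
        insts = enumerate_case_paths(kg, c, 3)
        prov = [(drug, abstract_meta_path(p, kg).id) for p in insts]
        sg1 = build_query_subgraph(kg, drug, insts, prov)
        shuffled = list(zip(insts, prov))
        random.Random(1).shuffle(shuffled)
        sg2 = build_query_subgraph(kg, drug, [i for i, _ in shuffled],
                                   [p for _, p in shuffled])
        assert sg1 == sg2

    def test_wrong_start_rejected(self, chain_kg):
        inst = PathInstance(("G1", "P1"), (Hop("participates_in"),))
        with pytest.raises(ValueError):
            build_query_subgraph(chain_kg, "C1", [inst], [("a", "m")])

    def test_empty_instances_allowed(self, chain_kg):
        sg = build_query_subgraph(chain_kg, "C1", [], [])
        assert sg.graph.n_edges == 0
        assert sg.candidate_diseases == set()


class TestEndToEndReuse:
    def test_candidates_are_path_termini(self, synth_kg):
        kg, _ = synth_kg
        drug = kg.nodes_of_type("Compound")[0]
        cases = retrieve_knn(kg, drug, 15)
        sg, _ = construct_query_subgraph(kg, drug, cases)
        assert sg.query_drug == drug
        for d in sg.candidate_diseases:
            assert kg.type_of(d) == "Disease"
            assert d in sg.graph.node_type
        # every edge carries provenance
        assert set(sg.provenance) == set(sg.graph.edges)

    def test_case_subgraph_contains_its_indications(self, synth_kg):
        kg, _ = synth_kg
        drug = kg.nodes_of_type("Compound")[2]
        c = DrugCase(drug=drug, similarity=1.0,
                     indications=frozenset(kg.indications_of(drug)))
        csg = build_case_subgraph(kg, c)
        assert set(c.indications) & set(csg.graph.node_type)
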