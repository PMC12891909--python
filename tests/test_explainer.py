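import numpy as np
import pytest

from repath.explainer import (
    EdgeMask,
    ExplainerConfig,
    degree_score,
    extract_top_paths,
    optimize_mask,
    path_loss,
    prediction_loss,
    regularizer,
    _prediction_loss_grad,
)
from repath.encoder import encode_isolated, encode
from repath.kg import QuerySubgraph, Triple
from repath.synth import planted_mask_fixture

from conftest import make_kg, random_params, subgraph_of
from oracles import exhaustive_best_product_path


def mask_with_weights(sg, weights):
    w = np.asarray(weights, dtype=float)
    w = np.clip(w, 1e-12, 1 - 1e-12)
    return EdgeMask(sg.query_drug, tuple(sg.edge_list), np.log(w / (1 - w)))


def saturated_mask(sg, value):
    latents = np.full(len(sg.edge_list), 40.0 if value else -40.0)
    return EdgeMask(sg.query_drug, tuple(sg.edge_list), latents)


@pytest.fixture
def path_sg():
    """A single drug→gene→pathway→disease chain (interior degrees 2)."""
    kg = make_kg(
        [("q", "targets", "g"), ("g", "participates_in", "p"),
         ("p", "associated_with", "x")],
        {"q": "Compound", "g": "Gene", "p": "Pathway", "x": "Disease"},
        indication_relation="targets",
    )
    return subgraph_of(kg, "q")


class TestDegreeScore:
    def test_peak_at_lambda(self):
        assert degree_score(10, 10.0) == 1.0

    def test_low_degree_penalty(self):
        assert degree_score(1, 10.0) == pytest.approx(0.1)

    def test_hub_penalty_mirrors_low_degree(self):
        assert degree_score(100, 10.0) == pytest.approx(0.1)

    def test_invalid_degree_rejected(self):
        with pytest.raises(ValueError):
            degree_score(0, 10.0)


class TestPredictionLoss:
    def test_full_mask_is_exactly_zero(self, path_sg):
        params = random_params(path_sg.graph)
        mask = saturated_mask(path_sg, True)
        assert prediction_loss(mask, path_sg, params, "x") == 0.0

    def test_zero_mask_reaches_isolated_embedding(self, path_sg):
        params = random_params(path_sg.graph)
        mask = saturated_mask(path_sg, False)
        loss = prediction_loss(mask, path_sg, params, "x")
        full = encode(path_sg, params).vectors["x"]
        isolated = encode_isolated(params, "Disease")
        assert loss == pytest.approx(float(np.sum((full - isolated) ** 2)))

    def test_gradient_matches_finite_differences(self, path_sg):
        params = random_params(path_sg.graph, seed=2)
        rng = np.random.default_rng(0)
        w = rng.uniform(0.2, 0.8, size=len(path_sg.edge_list))
        _, grad = _prediction_loss_grad(w, path_sg, params, "x")
        eps = 1e-6
        for ei in range(len(w)):
            orig = w[ei]
            w[ei] = orig + eps
            lp, _ = _prediction_loss_grad(w, path_sg, params, "x",
                                          need_grad=False)
            w[ei] = orig - eps
            lm, _ = _prediction_loss_grad(w, path_sg, params, "x",
                                          need_grad=False)
            w[ei] = orig
            assert grad[ei] == pytest.approx((lp - lm) / (2 * eps), abs=1e-5)

    def test_unknown_disease_rejected(self, path_sg):
        params = random_params(path_sg.graph)
        with pytest.raises(KeyError):
            prediction_loss(saturated_mask(path_sg, True), path_sg, params,
                            "absent")


class TestPathLoss:
    def test_perfect_chain_scores_minus_one(self, path_sg):
        # interior degrees are 2; λ=2 puts the degree score at its peak
        mask = saturated_mask(path_sg, True)
        assert path_loss(mask, path_sg, "x", lam=2.0) == pytest.approx(-1.0)

    def test_halving_one_edge_halves_the_score(self, path_sg):
        w = [1.0, 0.5, 1.0]
        mask = mask_with_weights(path_sg, w)
        assert path_loss(mask, path_sg, "x", lam=2.0) == pytest.approx(
            -0.5, abs=1e-6)

    def test_off_path_edges_are_irrelevant(self, path_sg):
        base = path_loss(saturated_mask(path_sg, True), path_sg, "x", lam=2.0)
        kg2 = make_kg(
            list(path_sg.graph.edges) + [("s", "targets", "t")],
            dict(path_sg.graph.node_type) | {"s": "Compound", "t": "Gene"},
            indication_relation="targets",
        )
        sg2 = subgraph_of(kg2, "q")
        w2 = saturated_mask(sg2, True)
        # degree structure of the chain is unchanged by the stray edge
        assert path_loss(w2, sg2, "x", lam=2.0) == pytest.approx(base)

    def test_disconnected_pair_contributes_zero(self, path_sg):
        kg = make_kg([("q", "targets", "g")],
                     {"q": "Compound", "g": "Gene", "x": "Disease"},
                     indication_relation="targets")
        sg = subgraph_of(kg, "q")
        assert path_loss(saturated_mask(sg, True), sg, "x", lam=2.0) == 0.0


class TestRegularizer:
    def test_all_zero_weights(self, path_sg):
        mask = saturated_mask(path_sg, False)
        assert regularizer(mask, 1.0, 1.0) == pytest.approx(0.0, abs=1e-9)

    def test_half_weights_maximize_entropy(self, path_sg):
        mask = mask_with_weights(path_sg, [0.5] * 3)
        assert regularizer(mask, 0.0, 1.0) == pytest.approx(np.log(2))
        assert regularizer(mask, 1.0, 0.0) == pytest.approx(0.5)

    def test_all_one_weights(self, path_sg):
        mask = saturated_mask(path_sg, True)
        assert regularizer(mask, 1.0, 0.0) == pytest.approx(1.0)
        assert regularizer(mask, 0.0, 1.0) == pytest.approx(0.0, abs=1e-9)


class TestOptimizeMask:
    def test_same_seed_same_weights(self, path_sg):
        params = random_params(path_sg.graph)
        cfg = ExplainerConfig(steps=20, seed=4)
        m1, t1 = optimize_mask(path_sg, params, "x", cfg)
        m2, t2 = optimize_mask(path_sg, params, "x", cfg)
        assert np.array_equal(m1.latents, m2.latents)
        assert t1 == t2

    def test_encoder_parameters_are_frozen(self, path_sg):
        params = random_params(path_sg.graph)
        before = params.checksum()
        optimize_mask(path_sg, params, "x", ExplainerConfig(steps=30, seed=0))
        assert params.checksum() == before

    def test_planted_path_gets_top_weights(self):
        """One planted chain + 10 disconnected noise edges: the three
        mechanism edges must carry the three largest mask weights."""
        for seed in range(5):
            planted = {Triple("q", "targets", "g"),
                       Triple("g", "participates_in", "p"),
                       Triple("p", "associated_with", "x")}
            edges = set(planted)
            types = {"q": "Compound", "g": "Gene", "p": "Pathway",
                     "x": "Disease"}
            rng = np.random.default_rng(seed)
            for i in range(10):
                types[f"ng{i}"] = "Gene"
                types[f"np{i}"] = "Pathway"
            for i in range(10):
                edges.add(Triple(f"ng{int(rng.integers(10))}", "regulates",
                                 f"np{int(rng.integers(10))}"))
            kg = make_kg(edges, types, indication_relation="targets")
            sg = subgraph_of(kg, "q")
            params = random_params(sg.graph, seed=seed, dim=16)
            mask, _ = optimize_mask(sg, params, "x",
                                    ExplainerConfig(lambda_degree=2.0,
                                                    seed=seed))
            weights = mask.as_dict()
            top3 = set(sorted(weights, key=lambda e: -weights[e])[:3])
            assert top3 == planted, f"seed {seed}: top weights {top3}"

    def test_sparsity_collapses_weights_without_path_term(self, path_sg):
        params = random_params(path_sg.graph)
        cfg = ExplainerConfig(path_coef=0.0, sparsity_coef=5.0,
                              entropy_coef=0.0, steps=150, seed=0)
        mask, _ = optimize_mask(path_sg, params, "x", cfg)
        # the drug-side edge is two hops from the disease and barely
        # affects its embedding: sparsity should crush it
        assert mask.weight_of(Triple("q", "targets", "g")) < 0.2

    def test_empty_subgraph_is_valid(self):
        kg = make_kg([], {"q": "Compound"}, relations=("treats",))
        sg = QuerySubgraph("q", kg, set(), {})
        params = random_params(small_graph())
        mask, trace = optimize_mask(sg, params, "q", ExplainerConfig(seed=0))
        assert len(mask.latents) == 0 and trace == []


def small_graph():
    return make_kg(
        [("q", "targets", "g")],
        {"q": "Compound", "g": "Gene"},
        indication_relation="targets",
    ).copy_without_edges(set()) or None


class TestExtractTopPaths:
    def test_single_path_recovered_with_product_score(self, path_sg):
        w = [0.9, 0.8, 0.7]
        mask = mask_with_weights(path_sg, w)
        expl = extract_top_paths(mask, path_sg, "q", "x", n=3, lam=2.0)
        assert len(expl.paths) == 1
        p, score = expl.paths[0]
        assert p.nodes == ("q", "g", "p", "x")
        assert score == pytest.approx(0.9 * 0.8 * 0.7, rel=1e-6)

    def test_parallel_paths_ordered_by_weight_product(self, diamond_kg):
        sg = subgraph_of(diamond_kg, "C1",
                         edges={e for e in diamond_kg.edges
                                if e.relation != "treats"})
        weights = {Triple("C1", "targets", "Ga"): 0.9,
                   Triple("C1", "targets", "Gb"): 0.6,
                   Triple("Ga", "associated_with", "D1"): 0.9,
                   Triple("Gb", "associated_with", "D1"): 0.6}
        mask = mask_with_weights(sg, [weights[e] for e in sg.edge_list])
        expl = extract_top_paths(mask, sg, "C1", "D1", n=5, lam=2.0)
        assert [p.nodes[1] for p, _ in expl.paths] == ["Ga", "Gb"]
        scores = [s for _, s in expl.paths]
        assert scores == sorted(scores, reverse=True)
        best = exhaustive_best_product_path(
            sg.graph, {tuple(e): w for e, w in zip(sg.edge_list,
                                                   mask.weights)},
            "C1", "D1")
        assert expl.paths[0][0].nodes == best[1]

    def test_zero_requested_paths(self, path_sg):
        mask = saturated_mask(path_sg, True)
        expl = extract_top_paths(mask, path_sg, "q", "x", n=0)
        assert expl.paths == []

    def test_disconnected_endpoints_give_empty_list(self):
        kg = make_kg([("q", "targets", "g")],
                     {"q": "Compound", "g": "Gene", "x": "Disease"},
                     indication_relation="targets")
        sg = subgraph_of(kg, "q")
        mask = saturated_mask(sg, True)
        expl = extract_top_paths(mask, sg, "q", "x", n=3)
        assert expl.paths == []

    def test_inverse_hops_keep_stored_orientation(self):
        # disease→pathway stored edge, traversed backwards from the pathway
        kg = make_kg(
            [("q", "targets", "g"), ("x", "produces", "g")],
            {"q": "Compound", "g": "Gene", "x": "Disease"},
            indication_relation="targets",
        )
        sg = subgraph_of(kg, "q")
        mask = saturated_mask(sg, True)
        expl = extract_top_paths(mask, sg, "q", "x", n=1, lam=2.0)
        (p, _), = expl.paths
        assert p.hops[-1].inverse
        assert p.stored_edges()[-1] == Triple("x", "produces", "g")
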