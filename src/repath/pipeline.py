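"""End-to-end orchestration: simulate → train → predict → explain → evaluate.

These functions are the library's high-level surface; the command-line
interface is a thin wrapper around them, and the test bed drives them
directly.  One seed fans out deterministically to every stochastic
component.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .encoder import (
    EncoderConfig,
    EncoderParams,
    NodeEmbeddings,
    RankedPrediction,
    encode,
    score_diseases,
    train_encoder,
)
from .evaluation import (
    RankReport,
    deletion_curve,
    edge_hit_rate,
    explanation_auc,
    insertion_curve,
    rank_metrics,
    stability,
)
from .explainer import EdgeMask, Explanation, ExplainerConfig, extract_top_paths, optimize_mask
from .kg import KnowledgeGraph, QuerySubgraph, Triple, load_truth_paths, truth_path_edges
from .paths import build_case_subgraph, construct_query_subgraph
from .retrieval import DrugCase, retrieve_knn

logger = logging.getLogger(__name__)

DEFAULT_K = 15
DEFAULT_MAX_HOPS = 3


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    k: int = DEFAULT_K
    max_hops: int = DEFAULT_MAX_HOPS
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    explainer: ExplainerConfig = field(default_factory=ExplainerConfig)
    seed: int = 0

    def resolved(self) -> dict:
        return {
            "k": self.k,
            "max_hops": self.max_hops,
            "encoder": asdict(self.encoder),
            "explainer": asdict(self.explainer),
            "seed": self.seed,
        }


def training_queries_from_kg(g: KnowledgeGraph) -> list[tuple[str, set[str]]]:
    """Every drug with at least one indication edge, paired with its
    (held-in) indication set."""
    out = []
    for drug in g.nodes_of_type("Compound"):
        ind = g.indications_of(drug)
        if ind:
            out.append((drug, ind))
    return out


def train(g: KnowledgeGraph, config: RunConfig) -> EncoderParams:
    enc_cfg = EncoderConfig(**{**asdict(config.encoder),
                               "k": config.k, "max_hops": config.max_hops,
                               "seed": config.seed})
    return train_encoder(training_queries_from_kg(g), g, enc_cfg)


class Predictor:
    """Scores candidate diseases for query drugs, caching per-case subgraph
    encodings (cases recur across queries)."""

    def __init__(self, g: KnowledgeGraph, params: EncoderParams,
                 k: int = DEFAULT_K, max_hops: int = DEFAULT_MAX_HOPS):
        params.check_compatible(g)
        self.g = g
        self.params = params
        self.k = k
        self.max_hops = max_hops
        self._case_cache: dict[str, tuple[DrugCase, NodeEmbeddings]] = {}

    def _case_embedding(self, case: DrugCase) -> NodeEmbeddings:
        hit = self._case_cache.get(case.drug)
        if hit is None:
            csg = build_case_subgraph(self.g, case, max_hops=self.max_hops)
            hit = (case, encode(csg, self.params))
            self._case_cache[case.drug] = hit
        return hit[1]

    def subgraph_for(self, drug: str) -> tuple[QuerySubgraph, list[DrugCase]]:
        cases = retrieve_knn(self.g, drug, self.k)
        sg, _ = construct_query_subgraph(
            self.g, drug, cases, max_hops=self.max_hops
        )
        return sg, cases

    def predict(self, drug: str) -> tuple[RankedPrediction, QuerySubgraph]:
        sg, cases = self.subgraph_for(drug)
        q_emb = encode(sg, self.params)
        case_embs = [self._case_embedding(c) for c in cases]
        ranked = score_diseases(q_emb, cases, case_embs, sg.candidate_diseases)
        return ranked, sg


def evaluate_heldout(
    g: KnowledgeGraph,
    held_out: dict[str, set[str]],
    params: EncoderParams,
    k: int = DEFAULT_K,
    max_hops: int = DEFAULT_MAX_HOPS,
) -> tuple[RankReport, list[RankedPrediction]]:
    """Filtered held-out ranking: each query's known (held-in) indications
    are removed from its candidate list before the held-out truth is
    ranked.  Held-out edges must already be absent from ``g`` — the
    no-leakage contract is the caller's to honour and is asserted in tests.
    """
    predictor = Predictor(g, params, k=k, max_hops=max_hops)
    rankings = []
    for drug in sorted(d for d, t in held_out.items() if t):
        ranked, _ = predictor.predict(drug)
        known = g.indications_of(drug)
        filtered = [(d, s) for d, s in ranked.ranking if d not in known]
        rankings.append(RankedPrediction(query_drug=drug, ranking=filtered))
    universe = len(g.nodes_of_type("Disease"))
    report = rank_metrics(rankings, held_out, universe_size=universe)
    return report, rankings


def shuffled_control(
    rankings: list[RankedPrediction],
    held_out: dict[str, set[str]],
    seed: int = 0,
) -> RankReport:
    """Label-shuffled floor: permute the held-out truth sets across queries
    and re-score the same rankings."""
    rng = np.random.default_rng(seed)
    drugs = sorted(d for d in held_out if held_out[d])
    perm = rng.permutation(len(drugs))
    shuffled = {drugs[i]: set(held_out[drugs[int(j)]])
                for i, j in enumerate(perm)}
    return rank_metrics(rankings, shuffled)


def explain(
    g: KnowledgeGraph,
    params: EncoderParams,
    drug: str,
    disease: str,
    config: ExplainerConfig,
    k: int = DEFAULT_K,
    max_hops: int = DEFAULT_MAX_HOPS,
) -> tuple[Explanation, QuerySubgraph, list[float]]:
    """Optimize an edge mask for one drug–disease pair and extract the
    top-ranked mechanistic paths."""
    predictor = Predictor(g, params, k=k, max_hops=max_hops)
    sg, _ = predictor.subgraph_for(drug)
    if disease not in sg.graph.node_type:
        raise ValueError(
            f"{disease!r} is not reachable in the query subgraph of {drug!r}"
        )
    mask, trace = optimize_mask(sg, params, disease, config)
    explanation = extract_top_paths(
        mask, sg, drug, disease, config.top_paths, lam=config.lambda_degree
    )
    return explanation, sg, trace


def explanation_metrics_for_pairs(
    g: KnowledgeGraph,
    params: EncoderParams,
    truth_paths: dict[tuple[str, str], list[list[str]]],
    pairs: list[tuple[str, str]],
    config: ExplainerConfig,
    k: int = DEFAULT_K,
    max_hops: int = DEFAULT_MAX_HOPS,
    hr_grid: tuple[int, ...] = (1, 3, 5, 10, 20),
) -> dict:
    """Mask ROC-AUC and edge hit rate against curated mechanism edges,
    averaged over the given drug–disease pairs."""
    aucs, hrs = [], []
    for drug, disease in pairs:
        try:
            explanation, sg, _ = explain(
                g, params, drug, disease, config, k=k, max_hops=max_hops
            )
        except ValueError as err:
            logger.warning("skipping (%s, %s): %s", drug, disease, err)
            continue
        truth = truth_path_edges(truth_paths.get((drug, disease), []))
        auc = explanation_auc(explanation.mask, truth)
        hr = edge_hit_rate(explanation.mask, truth, hr_grid)
        if auc is not None:
            aucs.append(auc)
        if hr is not None:
            hrs.append(hr)
    return {
        "mask_auc": float(np.mean(aucs)) if aucs else None,
        "mask_auc_n": len(aucs),
        "hit_rate": {
            key: float(np.mean([h[key] for h in hrs])) for key in hr_grid
        } if hrs else None,
    }


def k_sweep(
    g: KnowledgeGraph,
    held_out: dict[str, set[str]],
    params: EncoderParams | None = None,
    k_values: tuple[int, ...] = (1, 5, 10, 15, 20, 30),
    max_hops: int = DEFAULT_MAX_HOPS,
    retrain: bool = False,
    seed: int = 0,
) -> dict[int, float]:
    """Held-out MRR as a function of the retrieved neighbourhood size.

    With ``retrain`` the encoder is retrained under each k (the sweep
    protocol of the sensitivity study); otherwise the given parameters are
    reused and only retrieval/scoring change at inference time."""
    out = {}
    for k in k_values:
        if retrain:
            k_params = train(g, RunConfig(k=k, max_hops=max_hops,
                                          encoder=EncoderConfig(),
                                          seed=seed))
        else:
            if params is None:
                raise ValueError("params required when retrain=False")
            k_params = params
        report, _ = evaluate_heldout(g, held_out, k_params, k=k,
                                     max_hops=max_hops)
        out[k] = report.mrr
    return out


def max_hops_sweep(
    g: KnowledgeGraph,
    held_out: dict[str, set[str]],
    params: EncoderParams,
    hop_values: tuple[int, ...] = (2, 3, 4, 5),
    k: int = DEFAULT_K,
) -> dict[int, float]:
    """Held-out MRR as a function of the path-length bound."""
    out = {}
    for hops in hop_values:
        report, _ = evaluate_heldout(g, held_out, params, k=k, max_hops=hops)
        out[hops] = report.mrr
    return out


def lambda_sweep(
    sg: QuerySubgraph,
    disease: str,
    params: EncoderParams,
    planted_edges: set[Triple],
    lambdas: tuple[float, ...] = (1.0, 10.0, 1000.0),
    base_config: ExplainerConfig | None = None,
    seeds: tuple[int, ...] = (0, 1, 2),
) -> dict[float, float]:
    """Mean mask ROC-AUC against planted mechanism edges across λ values."""
    base = base_config or ExplainerConfig()
    out: dict[float, float] = {}
    for lam in lambdas:
        aucs = []
        for seed in seeds:
            cfg = ExplainerConfig(**{**asdict(base), "lambda_degree": lam,
                                     "seed": seed})
            mask, _ = optimize_mask(sg, params, disease, cfg)
            auc = explanation_auc(mask, planted_edges)
            if auc is not None:
                aucs.append(auc)
        out[lam] = float(np.mean(aucs)) if aucs else float("nan")
    return out


def shuffled_mask(mask: EdgeMask, seed: int = 0) -> EdgeMask:
    """Control mask: the same latents randomly permuted across edges."""
    rng = np.random.default_rng(seed)
    return EdgeMask(
        subgraph_id=mask.subgraph_id,
        edge_list=mask.edge_list,
        latents=mask.latents[rng.permutation(len(mask.latents))],
    )


def save_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n",
                          encoding="utf-8")


def load_heldout_tsv(path: str | Path) -> dict[str, set[str]]:
    held: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["drug", "disease"]:
            raise ValueError(f"{path}: expected header 'drug\\tdisease'")
        for line in fh:
            if line.strip():
                drug, disease = line.rstrip("\n").split("\t")[:2]
                held.setdefault(drug, set()).add(disease)
    return held


def save_heldout_tsv(held: dict[str, set[str]], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("drug\tdisease\n")
        for drug in sorted(held):
            for disease in sorted(held[drug]):
                fh.write(f"{drug}\t{disease}\n")
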