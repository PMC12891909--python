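"""Generate a synthetic biomedical knowledge graph with planted structure.

The generator plants drug families that share mechanism templates
(drug → gene → pathway → disease), indication edges (some withheld as
held-out evaluation truth), promiscuous hub genes, and noise edges.
"""

from collections import Counter

from repath import SynthConfig, generate
from repath.synth import export_truth_paths
from repath.kg import save_kg

kg, truth = generate(SynthConfig(seed=0))

print(f"nodes: {len(kg.nodes)}   edges: {kg.n_edges}")
print("node types:", dict(Counter(kg.node_type.values())))
print("relations:", list(kg.relations))

n_held = sum(len(v) for v in truth.held_out.values())
n_ind = sum(len(v) for v in truth.indications.values())
print(f"indications: {n_ind} total, {n_held} withheld from the graph as "
      "evaluation truth")

drug = kg.nodes_of_type("Compound")[0]
disease = sorted(truth.indications[drug])[0]
path = truth.mechanisms[(drug, disease)][0]
print(f"example planted mechanism for ({drug}, {disease}):")
print("  " + " -> ".join(path.as_record()))

save_kg(kg, "scratch_triples.tsv", "scratch_node_types.tsv")
export_truth_paths(truth, "scratch_truth_paths.jsonl")
print("wrote scratch_triples.tsv / scratch_node_types.tsv / "
      "scratch_truth_paths.jsonl")
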