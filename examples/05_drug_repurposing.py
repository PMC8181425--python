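"""Drug-gene overlay and repurposing candidates from common networks.

Genes appearing in statistically significant common cell-gene networks
between diseases, and that are targets of (approved) drugs, are nominated
as repurposing candidates — the rationale being that a drug hitting a
mechanism shared by two diseases may transfer between them.
"""

from dime import synthetic
from dime.compare import compare_networks
from dime.core import DimeConfig, build_dime_network, run_dime
from dime.drugs import annotate_druggable, repurposing_candidates

imm, truth, diseases = synthetic.comparison_instance(seed=1)
drug_net = synthetic.generate_drug_table(truth, druggable_fraction=0.2, seed=8)
config = DimeConfig(n_restarts=5, n_runs_consensus=8, k_max=4)

results, networks = {}, {}
for did in sorted(diseases.diseases):
    res = run_dime(imm, diseases, did, seed=1, config=config)
    results[did] = res
    networks[did] = annotate_druggable(build_dime_network(res, imm), drug_net)

universe = len(imm.cell_ids) * len(diseases.gene_universe())
comparison = compare_networks(networks, universe_size=universe)
candidates = repurposing_candidates(comparison, results, drug_net, alpha=0.05)

print(f"druggable genes in the drug-gene table: {len(drug_net)}")
print(f"repurposing candidates: {len(candidates)}\n")
print(candidates.head(10).to_string(index=False))
# Candidates are druggable genes inside the significant D1-D2 common network
# (the shared planted module); `top_cluster_target` marks genes that are top
# DAGs of the rank-1 cluster in every disease listed — the strongest tier.
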