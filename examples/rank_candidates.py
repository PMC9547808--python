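"""Rank candidate genes and diseases around a seed gene.

Builds a three-layer network (disease-gene annotations, pathway
memberships from GMT, a small protein-interaction layer) from inline
text, propagates a random walk with restart from the seed gene CHCHD6,
and prints the ranked candidates of each type.  Scores are the walker's
stationary visiting probabilities: a higher score means the entity is
reachable from the seed through more, shorter, less diluted paths
across all three evidence layers at once.
"""

from gppdn import (
    EntityRef,
    JumpSpec,
    PropagationConfig,
    aggregate_entity_scores,
    assemble_transition,
    build_gppdn,
    init_seed_vector,
    propagate_to_convergence,
    rank_by_type,
    read_edge_list,
    read_gene_sets_gmt,
)

DISEASE_GENE = """\
source_id\tsource_type\ttarget_id\ttarget_type
Alzheimer disease\tdisease\tAPP\tgene
Alzheimer disease\tdisease\tPSEN1\tgene
cardiomyopathy\tdisease\tMYH7\tgene
"""

PATHWAYS_GMT = """\
mitochondrial organization\tdesc\tCHCHD6\tCHCHD3\tIMMT
amyloid processing\tdesc\tAPP\tPSEN1\tBACE1
"""

PPI = """\
source_id\tsource_type\ttarget_id\ttarget_type\tweight
CHCHD6\tgene\tCHCHD3\tgene\t0.9
CHCHD6\tgene\tAPP\tgene\t0.8
CHCHD3\tgene\tIMMT\tgene\t0.9
APP\tgene\tBACE1\tgene\t0.7
"""

net = build_gppdn(
    [
        read_edge_list(DISEASE_GENE, "dgn", directed=True),
        read_gene_sets_gmt(PATHWAYS_GMT, "pathways"),
        read_edge_list(PPI, "ppi"),
    ]
)
seed = EntityRef.parse("gene:CHCHD6")
cfg = PropagationConfig(seed_entities=[seed], alpha=0.7)
tm = assemble_transition(net, JumpSpec.default_for(net))
result = propagate_to_convergence(tm, init_seed_vector(net, [seed]), cfg)
print(f"converged in {result.iteration} iterations (residual {result.residual:.1e})")

scores = aggregate_entity_scores(result, net)
for entity_type in ("gene", "disease", "pathway"):
    table = rank_by_type(scores, entity_type, seeds=[seed])
    print(f"\ntop {entity_type}s ({table.n_candidates} candidates):")
    print(table.frame.head(5).to_string(index=False))
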