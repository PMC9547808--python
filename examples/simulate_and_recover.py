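"""Planted-partner recovery on synthetic multi-layer networks.

Generates toy gene-pathway-phenotype-disease networks in which one
"partner" gene is deliberately tied to the seed gene in all three
layers, runs the full prioritization pipeline on each replicate, and
reports how often the partner comes out rank 1 among all genes.  A
fraction near 1 means the propagation reliably concentrates mass on an
entity that shares multi-layer evidence with the seed; the null run
(no planted signal) shows the partner drifting to the middle of the
ranking, i.e. the signal, not the network scaffold, drives recovery.
"""

import dataclasses

from gppdn import REFERENCE_PARAMS, planted_recovery_experiment

report = planted_recovery_experiment(
    REFERENCE_PARAMS, n_replicates=20, base_rng_seed=0
)
print("planted in all 3 layers:")
print(f"  fraction of replicates with partner at rank 1: {report.fraction_rank1:.2f}")
print(f"  median partner rank:       {report.median_rank:.1f}")
print(f"  median partner percentile: {report.median_percentile:.2f}%")

null_params = dataclasses.replace(REFERENCE_PARAMS, planted_partner_degree=0)
null = planted_recovery_experiment(null_params, n_replicates=20, base_rng_seed=0)
print("\nno planted signal (null):")
print(f"  fraction of replicates with partner at rank 1: {null.fraction_rank1:.2f}")
print(f"  median partner percentile: {null.median_percentile:.2f}% (~50% expected)")
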