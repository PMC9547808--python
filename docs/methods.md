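# Methods

## Network model

A heterogeneous network is an ordered list of K sub-networks
("layers"), each a typed edge list over entities of kind gene, disease,
pathway, phenotype or chemical.  The unique key of an entity is
(type, identifier); gene identifiers are upper-cased on ingestion so
the same symbol spelled differently in two source databases resolves to
one entity, while all other identifiers are matched verbatim.

Shared entities are represented in **multiplex (replica) style**: an
entity present in m layers exists as m distinct nodes, one per layer,
joined pairwise by cross-layer links of weight 1.  The alternative —
merging shared entities into single global nodes — would collapse the
between-layer blocks of the transition matrix and make per-layer jump
control impossible; the block structure of the model requires replicas.
Layer order only determines the global node indexing: permuting the
input layers permutes indices but leaves cross links and all
entity-level scores unchanged (tested).

Ingestion conventions: duplicate (source, target) rows are collapsed
with weights summed (total evidence mass is preserved) and a warning
logged; self-loops are dropped, since staying put is already modeled by
the diagonal-block stay probability; an unweighted layer forces all
weights to 1.  Directed layers (e.g. disease→gene annotation sets) are
symmetrized for walk purposes by default — under literal direction a
gene seed could never reach disease nodes through disease→gene edges —
but direction metadata is retained and `respect_direction=true`
restores it.

## Transition matrix

The global matrix M is a K×K grid of blocks (49 blocks for the
seven-layer configuration).  With A_Ni the within-layer adjacency and
A_NiNj the bipartite coupling matrix:

* **Off-diagonal block (i, j)**: each row of A_NiNj is divided by its
  sum and multiplied by the jumping probability lambda_ij; an all-zero
  row (no cross link) stays all-zero.
* **Diagonal block i**: each row k of A_Ni is divided by its sum and
  multiplied by the stay probability `1 - sum_j I_kj * lambda_ij`,
  where the per-node indicator I_kj is 1 iff row k of A_NiNj contains
  a nonzero element.  The indicator is deliberately per node, not per
  layer: a node with no cross link into layer j keeps the jump mass
  lambda_ij as stay mass.

Consequently every row of a node with at least one within-layer edge
sums to exactly 1 (machine precision).  A node with *no* within-layer
edge poses a degenerate case — its diagonal row would require dividing
by a zero row sum.  We extend the zero-row convention to the diagonal:
the row stays all-zero and the node's row becomes substochastic (its
stay mass is dropped).  Redirecting that mass to the cross links was
considered and rejected: it is not what the normalization equations
say, and convergence does not need it — the spectral radius of alpha·M
is at most alpha < 1 regardless.  The per-row mass deficit is recorded
in the `TransitionMatrix` for auditing.

**Jumping probabilities.** The lambda matrix is user-configurable, may
be asymmetric, has zero diagonal, entries in [0, 1), and off-diagonal
row sums at most 1 (so stay probabilities cannot go negative).  The
default splits a total jump mass of 0.5 equally among the layers a
given layer actually shares entities with (lambda_ij = 0.5 / d_i).
This is a convention, not a reconstruction: the original screen's
lambda values were never reported.

## Propagation

Scores follow S_{k+1} = alpha·M^T S_k + (1 − alpha)·S_0.

* **alpha** (walk continuation; restart probability 1 − alpha):
  default 0.7, a conventional choice for network propagation;
  configurable, never tuned here.
* **S_0**: unit mass split equally over seed entities, then equally
  over each entity's layer replicas.
* **Convergence**: plain fixed-point iteration until the L1 change
  falls below 1e-9 (default), capped at 1000 iterations; hitting the
  cap sets `converged=False` and logs a warning, never fails silently.
  The iteration is a contraction with factor at most alpha, so the
  residual decays geometrically and the default tolerance is reached
  in roughly log(tol)/log(alpha) ≈ 60 iterations at alpha = 0.7.
* **Oracle**: `closed_form_solution` solves (I − alpha·M^T) S =
  (1 − alpha) S_0 by a dense linear solve (guarded to ≤ 5000 nodes).
  It exists for testing; the test suite additionally carries a second,
  independently coded dense construction of M itself, so both the
  assembly and the engine are checked against code they do not share.

When all rows of M sum to 1, total score mass is conserved exactly at
every step; with within-layer-isolated nodes it can only shrink.
Propagation contains no randomness.

## Ranking

Replica scores are collapsed per entity by **summation**, preserving
total probability mass (a `max` collapse is available for sensitivity
analysis).  Each entity type is ranked by descending score with
competition ranks (ties share the minimal rank; output order among ties
is lexicographic by identifier) and percentile rank 100·rank/n, where n
counts the candidates actually ranked.  Display formatting rounds
percentiles to three decimals — rank 1 among 30,049 genes prints as
0.003.  Seed entities are excluded from their own type's ranking by
default (the query should not compete with its candidates) but remain
countable via `exclude_seeds=False`; whether a full-scale screen's
denominator includes the seed is a convention, and ours is "seed
excluded from ranking, included in any externally quoted screen size".

## Synthetic benchmark

The generator emulates the statistical structure of the integrated
network at toy scale, not its size: K typed layers (layer 1
disease–gene, layer 2 pathway–gene, layer 3 phenotype–gene, further
layers gene–gene), sparse Bernoulli within-layer edges, and coupling
arising *only* from gene symbols reused across layers.  Defaults — and
the reference benchmark conditions — are 3 layers, 50 genes per layer,
20 other typed nodes per layer, edge probability 0.05, 30% of gene
symbols shared across layers, 20 noise edges.  Every gene receives at
least one within-layer edge, mirroring how a gene enters a knowledge
layer only by having at least one recorded association; this also keeps
generated networks free of isolated nodes, so the conservation
guarantees hold exactly on them.

The **planted partner** is a designated gene placed in
max(planted_partner_degree, 1) layers with a direct edge to the seed in
each of the first `planted_partner_degree` layers.  At degree 0 (the
null) the partner is an ordinary single-layer gene with only random
edges.  This asymmetry is deliberate: entities replicated across layers
receive systematically more aggregate walk mass than single-layer
entities, so a "null" partner forcibly replicated everywhere would sit
far above the 50th percentile for structural reasons unrelated to any
planted signal.  The null partner must be exchangeable with a typical
gene, and is.

The recovery experiment regenerates the network per replicate with
`rng_seed = base + replicate_index` (any replicate reproducible in
isolation), runs the full pipeline with the synthetic seed, and records
the partner's rank and percentile among genes.  One hundred replicates
run in a few seconds at reference scale.  All randomness flows through
one explicitly seeded NumPy generator; identical parameters give
byte-identical networks and reports.

## What the synthetic benchmark does and does not show

Passing the planted-recovery benchmark shows the pipeline concentrates
score mass on an entity with coherent multi-layer evidence, and the
null shows the scaffold alone does not.  The toy networks do not
reproduce the degree heterogeneity, annotation bias, or sheer size of
real curated databases (hundreds of thousands of edges), nor
identifier-mapping noise between sources; results at full scale depend
on those snapshots and on the unreported lambda/alpha values used
there, and are expressly out of scope.

## Problem sizes used in checks

Structural and convention checks run on networks of tens of nodes;
oracle-equivalence sweeps use 100 random networks of 2–5 layers
(roughly 50–200 global nodes each); recovery experiments use 100
replicates at the reference scale (~210 global nodes).  These sizes
were chosen as the smallest at which every property is exercised
non-trivially.

## Known limitations

* No identifier-mapping service: cross-layer identity is exact
  (type, normalized identifier) equality.
* No downloaders for the source databases; readers ingest edge-list
  TSV and GMT only, and a chemical-layer reader is not shipped even
  though the chemical entity type exists.
* Row normalization only; column-stochastic or symmetric/Laplacian
  diffusion variants are out of scope.
* The dense closed-form solver is a test oracle, not a production
  path; production propagation is the sparse iteration.
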