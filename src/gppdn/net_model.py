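"""Typed multi-layer networks: domain types, readers/writers, and assembly.

A heterogeneous knowledge network is built from sub-networks ("layers"),
each an edge list over typed biomedical entities (genes, diseases,
pathways, phenotypes, chemicals).  Layers are coupled in multiplex style:
an entity present in several layers exists as one node *replica* per
layer, and replicas of the same entity are joined by cross-layer links.
Each unordered layer pair (i, j) therefore owns a bipartite coupling
matrix ``A_NiNj`` with one nonzero per shared entity, and
``A_NiNj == A_NjNi.T`` by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from io import StringIO
from typing import IO, Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import ConfigError, InputError, ParseError

logger = logging.getLogger(__name__)


class EntityType(str, Enum):
    """The kinds of biomedical entities a layer may contain."""

    GENE = "gene"
    DISEASE = "disease"
    PATHWAY = "pathway"
    PHENOTYPE = "phenotype"
    CHEMICAL = "chemical"


@dataclass(frozen=True, order=True)
class EntityRef:
    """A typed, namespaced biomedical entity; the unit of ranking.

    The unique key of an entity is ``(entity_type, identifier)``.  Gene
    identifiers are upper-cased on construction (via :meth:`of`) so that
    the same symbol spelled differently in two source databases resolves
    to one entity; all other identifiers are kept verbatim.
    """

    entity_type: EntityType
    identifier: str

    def __post_init__(self) -> None:
        if not self.identifier or not self.identifier.strip():
            raise ValueError("entity identifier must be non-empty")

    @classmethod
    def of(cls, entity_type: EntityType | str, identifier: str) -> "EntityRef":
        """Build an entity with case normalization applied."""
        if not isinstance(entity_type, EntityType):
            try:
                entity_type = EntityType(str(entity_type).strip().lower())
            except ValueError:
                valid = ", ".join(t.value for t in EntityType)
                raise InputError(
                    f"unknown entity_type {entity_type!r} "
                    f"(expected one of: {valid})"
                ) from None
        identifier = identifier.strip()
        if entity_type is EntityType.GENE:
            identifier = identifier.upper()
        return cls(entity_type, identifier)

    @classmethod
    def parse(cls, text: str) -> "EntityRef":
        """Parse a ``type:identifier`` token, e.g. ``gene:CHCHD6``."""
        if ":" not in text:
            raise ValueError(f"expected 'type:identifier', got {text!r}")
        type_part, ident = text.split(":", 1)
        return cls.of(type_part, ident)

    @property
    def key(self) -> tuple[str, str]:
        return (self.entity_type.value, self.identifier)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.entity_type.value}:{self.identifier}"


Edge = tuple[EntityRef, EntityRef, float]


@dataclass
class SubNetwork:
    """One knowledge layer: a typed node set plus an (optionally weighted,
    optionally directed) edge list, with a sparse adjacency over a sorted
    node index.

    Invariants maintained by :meth:`from_edges`: no self-loops, no
    duplicate (source, target) pairs, positive weights, weight 1
    everywhere when ``weighted`` is false.
    """

    name: str
    nodes: tuple[EntityRef, ...]
    edges: list[Edge]
    weighted: bool = False
    directed: bool = False
    _index: dict[EntityRef, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._index = {e: i for i, e in enumerate(self.nodes)}
        for s, t, w in self.edges:
            if s not in self._index or t not in self._index:
                raise ValueError(f"edge endpoint not in node set: {s} -> {t}")
            if w <= 0:
                raise ValueError(f"non-positive edge weight {w} on {s} -> {t}")
            if s == t:
                raise ValueError(f"self-loop on {s}")

    @classmethod
    def from_edges(
        cls,
        name: str,
        edges: Iterable[Edge],
        *,
        weighted: bool = False,
        directed: bool = False,
        extra_nodes: Iterable[EntityRef] = (),
    ) -> "SubNetwork":
        """Build a layer, collapsing duplicate edges (weights summed) and
        dropping self-loops, each with a logged warning."""
        collapsed: dict[tuple[EntityRef, EntityRef], float] = {}
        n_dups = n_loops = 0
        for s, t, w in edges:
            if s == t:
                n_loops += 1
                continue
            key = (s, t)
            if key in collapsed:
                n_dups += 1
                collapsed[key] += w
            else:
                collapsed[key] = w
        if n_loops:
            logger.warning("%s: dropped %d self-loop edge(s)", name, n_loops)
        if n_dups:
            logger.warning(
                "%s: collapsed %d duplicate edge(s), summing weights", name, n_dups
            )
        if not weighted:
            collapsed = {k: 1.0 for k in collapsed}
        node_set = {e for pair in collapsed for e in pair}
        node_set.update(extra_nodes)
        nodes = tuple(sorted(node_set, key=lambda e: e.key))
        edge_list = sorted(
            ((s, t, w) for (s, t), w in collapsed.items()),
            key=lambda e: (e[0].key, e[1].key),
        )
        return cls(name, nodes, edge_list, weighted=weighted, directed=directed)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def index_of(self, entity: EntityRef) -> int:
        return self._index[entity]

    def __contains__(self, entity: EntityRef) -> bool:
        return entity in self._index

    def adjacency(self, respect_direction: bool = False) -> sp.csr_matrix:
        """Sparse nonnegative adjacency ``A_Ni`` over the layer node index.

        Directed layers are symmetrized (elementwise max of A and A.T)
        unless ``respect_direction`` is set, so that a random walker can
        traverse e.g. disease->gene annotations in both directions.
        Undirected layers are always symmetric.
        """
        n = self.n_nodes
        if not self.edges:
            return sp.csr_matrix((n, n))
        rows = [self._index[s] for s, _, _ in self.edges]
        cols = [self._index[t] for _, t, _ in self.edges]
        vals = [w for _, _, w in self.edges]
        a = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
        if self.directed and respect_direction:
            return a
        return a.maximum(a.T).tocsr()

    def nodes_of_type(self, entity_type: EntityType) -> list[EntityRef]:
        return [e for e in self.nodes if e.entity_type is entity_type]


@dataclass(frozen=True)
class CrossLayerLink:
    """A link joining the replicas of one entity in two distinct layers."""

    layer_a: int
    layer_b: int
    entity: EntityRef
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.layer_a == self.layer_b:
            raise ValueError("cross link must join two distinct layers")
        if self.weight <= 0:
            raise ValueError("cross link weight must be positive")


class HeterogeneousNetwork:
    """Ordered sub-networks coupled through shared entities.

    Global node ids are contiguous, assigned layer-by-layer in input
    order and, within a layer, by sorted entity key.  The bipartite
    coupling block ``A_NiNj`` has a nonzero at (k, l) iff node k of layer
    i and node l of layer j are replicas of the same entity.
    """

    def __init__(
        self,
        layers: Sequence[SubNetwork],
        cross_links: Sequence[CrossLayerLink],
        respect_direction: bool = False,
    ):
        self.layers = list(layers)
        self.cross_links = list(cross_links)
        self.respect_direction = respect_direction
        self.layer_offsets = np.concatenate(
            [[0], np.cumsum([ly.n_nodes for ly in self.layers])]
        ).astype(int)
        self.n_nodes = int(self.layer_offsets[-1])
        self._replicas: dict[EntityRef, list[tuple[int, int]]] = {}
        for li, layer in enumerate(self.layers):
            for e in layer.nodes:
                gid = int(self.layer_offsets[li]) + layer.index_of(e)
                self._replicas.setdefault(e, []).append((li, gid))
        self._bipartite: dict[tuple[int, int], sp.csr_matrix] = {}
        for link in self.cross_links:
            for i, j in ((link.layer_a, link.layer_b), (link.layer_b, link.layer_a)):
                block = self._bipartite.setdefault(
                    (i, j),
                    sp.lil_matrix((self.layers[i].n_nodes, self.layers[j].n_nodes)),
                )
                block[
                    self.layers[i].index_of(link.entity),
                    self.layers[j].index_of(link.entity),
                ] = link.weight
        self._bipartite = {k: v.tocsr() for k, v in self._bipartite.items()}

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    def global_id(self, layer: int, entity: EntityRef) -> int:
        return int(self.layer_offsets[layer]) + self.layers[layer].index_of(entity)

    def node_at(self, gid: int) -> tuple[int, EntityRef]:
        """Inverse of the global index: (layer index, entity) at a global id."""
        layer = int(np.searchsorted(self.layer_offsets, gid, side="right")) - 1
        return layer, self.layers[layer].nodes[gid - int(self.layer_offsets[layer])]

    def replicas(self, entity: EntityRef) -> list[tuple[int, int]]:
        """All (layer index, global id) replicas of an entity; [] if absent."""
        return list(self._replicas.get(entity, []))

    def entities(self) -> Iterator[EntityRef]:
        return iter(self._replicas)

    def bipartite_block(self, i: int, j: int) -> sp.csr_matrix:
        """Coupling matrix A_NiNj (|Ni| x |Nj|); empty if no shared entity."""
        if i == j:
            raise ValueError("bipartite block requires two distinct layers")
        block = self._bipartite.get((i, j))
        if block is None:
            return sp.csr_matrix((self.layers[i].n_nodes, self.layers[j].n_nodes))
        return block

    def layer_adjacency(self, i: int) -> sp.csr_matrix:
        return self.layers[i].adjacency(respect_direction=self.respect_direction)


def build_gppdn(
    layers: Sequence[SubNetwork], respect_direction: bool = False
) -> HeterogeneousNetwork:
    """Assemble a heterogeneous network by shared-node coupling.

    Exactly one cross link (weight 1) is created per (unordered layer
    pair, shared entity); entities match across layers iff their
    (type, case-normalized identifier) keys match.
    """
    if not layers:
        raise ConfigError("at least one layer is required")
    names = [ly.name for ly in layers]
    if len(set(names)) != len(names):
        raise ConfigError(f"duplicate layer names: {sorted(names)}")
    links: list[CrossLayerLink] = []
    for i in range(len(layers)):
        for j in range(i + 1, len(layers)):
            shared = set(layers[i].nodes) & set(layers[j].nodes)
            links.extend(
                CrossLayerLink(i, j, e) for e in sorted(shared, key=lambda e: e.key)
            )
    return HeterogeneousNetwork(layers, links, respect_direction=respect_direction)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_EDGE_COLUMNS = ("source_id", "source_type", "target_id", "target_type")


def read_edge_list(
    stream: IO[str] | str,
    layer_name: str,
    *,
    directed: bool = False,
) -> SubNetwork:
    """Read a layer from tab-separated text.

    Expected header: ``source_id  source_type  target_id  target_type``
    with an optional trailing ``weight`` column (its presence makes the
    layer weighted).  Lines starting with '#' are ignored.  Duplicate
    (source, target) rows are collapsed with weights summed; self-loops
    are dropped; both are logged as warnings.
    """
    if isinstance(stream, str):
        stream = StringIO(stream)
    header: list[str] | None = None
    weighted = False
    edges: list[Edge] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if header is None:
            if tuple(fields[:4]) != _EDGE_COLUMNS:
                raise ParseError(
                    f"expected header {' '.join(_EDGE_COLUMNS)}[ weight], "
                    f"got {fields!r}",
                    lineno,
                )
            if len(fields) == 5 and fields[4] == "weight":
                weighted = True
            elif len(fields) != 4:
                raise ParseError(f"unexpected header columns {fields!r}", lineno)
            header = fields
            continue
        expected = 5 if weighted else 4
        if len(fields) != expected:
            raise ParseError(
                f"expected {expected} tab-separated fields, got {len(fields)}", lineno
            )
        try:
            source = EntityRef.of(fields[1], fields[0])
            target = EntityRef.of(fields[3], fields[2])
        except (InputError, ValueError) as exc:
            raise ParseError(str(exc), lineno) from None
        weight = 1.0
        if weighted:
            try:
                weight = float(fields[4])
            except ValueError:
                raise ParseError(f"non-numeric weight {fields[4]!r}", lineno) from None
            if weight <= 0:
                raise ParseError(f"non-positive weight {weight}", lineno)
        edges.append((source, target, weight))
    return SubNetwork.from_edges(
        layer_name, edges, weighted=weighted, directed=directed
    )


def write_edge_list(net: SubNetwork, stream: IO[str]) -> None:
    """Write a layer back to the edge-list TSV format read_edge_list accepts."""
    cols = list(_EDGE_COLUMNS) + (["weight"] if net.weighted else [])
    stream.write("\t".join(cols) + "\n")
    for s, t, w in net.edges:
        row = [s.identifier, s.entity_type.value, t.identifier, t.entity_type.value]
        if net.weighted:
            row.append(repr(w))
        stream.write("\t".join(row) + "\n")


def read_gene_sets_gmt(stream: IO[str] | str, layer_name: str) -> SubNetwork:
    """Read a pathway-gene membership layer from GMT gene-set format.

    Each line is ``set_name<TAB>description<TAB>gene1<TAB>gene2...``;
    one pathway node per line, one gene node per distinct symbol, one
    unweighted pathway-gene edge per membership.
    """
    if isinstance(stream, str):
        stream = StringIO(stream)
    edges: list[Edge] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ParseError(
                f"GMT line needs set name, description and >=1 member, "
                f"got {len(fields)} field(s)",
                lineno,
            )
        pathway = EntityRef.of(EntityType.PATHWAY, fields[0])
        for symbol in fields[2:]:
            if symbol.strip():
                edges.append(
                    (pathway, EntityRef.of(EntityType.GENE, symbol), 1.0)
                )
    return SubNetwork.from_edges(layer_name, edges, weighted=False, directed=False)


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------


@dataclass
class NetworkDiagnostics:
    """Structural report on a heterogeneous network (never mutates it)."""

    layer_summary: pd.DataFrame  # one row per layer
    pair_summary: pd.DataFrame  # one row per unordered layer pair
    isolated_nodes: list[tuple[int, EntityRef]]  # no within-layer edge, no cross link

    @property
    def n_isolated(self) -> int:
        return len(self.isolated_nodes)


def validate_network(net: HeterogeneousNetwork) -> NetworkDiagnostics:
    """Per-layer node/edge counts by type, cross links per layer pair, and
    isolated nodes (no within-layer edge and no cross link)."""
    layer_rows = []
    for li, layer in enumerate(net.layers):
        counts = {t.value + "_nodes": 0 for t in EntityType}
        for e in layer.nodes:
            counts[e.entity_type.value + "_nodes"] += 1
        layer_rows.append(
            {"layer": li, "name": layer.name, "n_nodes": layer.n_nodes,
             "n_edges": layer.n_edges, **counts}
        )
    pair_counts: dict[tuple[int, int], int] = {
        (i, j): 0
        for i in range(net.n_layers)
        for j in range(i + 1, net.n_layers)
    }
    for link in net.cross_links:
        a, b = sorted((link.layer_a, link.layer_b))
        pair_counts[(a, b)] += 1
    pair_rows = [
        {"layer_a": net.layers[i].name, "layer_b": net.layers[j].name,
         "n_cross_links": c}
        for (i, j), c in sorted(pair_counts.items())
    ]
    linked = {
        (li, link.entity)
        for link in net.cross_links
        for li in (link.layer_a, link.layer_b)
    }
    isolated = []
    for li, layer in enumerate(net.layers):
        adj = net.layer_adjacency(li)
        degree = np.asarray(adj.sum(axis=1)).ravel() + np.asarray(
            adj.sum(axis=0)
        ).ravel()
        for k, e in enumerate(layer.nodes):
            if degree[k] == 0 and (li, e) not in linked:
                isolated.append((li, e))
    pair_cols = ["layer_a", "layer_b", "n_cross_links"]
    return NetworkDiagnostics(
        layer_summary=pd.DataFrame(layer_rows),
        pair_summary=pd.DataFrame(pair_rows, columns=pair_cols),
        isolated_nodes=isolated,
    )
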