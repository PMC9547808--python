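"""Structured run configuration: layer declarations, jumps, walk settings.

A config file (YAML or JSON) declares the layers of the network, how the
walker jumps between them, and the restart-iteration parameters::

    layers:
      - name: omimDGN
        file: omim_edges.tsv
        format: edge_list        # or: gmt
        directed: true
    jumping:
      total_mass: 0.5            # split equally over coupled layer pairs
      # or an explicit K x K table:
      # table: [[0, 0.2], [0.3, 0]]
    alpha: 0.7
    tolerance: 1.0e-9
    max_iterations: 1000
    respect_direction: false
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigError
from .net_model import (
    HeterogeneousNetwork,
    SubNetwork,
    build_gppdn,
    read_edge_list,
    read_gene_sets_gmt,
)
from .transition import JumpSpec

#: The seven-layer schema of the full-scale integrated network: three
#: disease–gene layers, a pathway–gene layer, a protein interaction
#: layer, a mutational-phenotype layer and a chemical layer.
SEVEN_LAYER_SCHEMA = (
    "omimDGN",
    "clinvarDGN",
    "gwasDGN",
    "PathGN",
    "PPIN",
    "PhenGN",
    "ChemicalGN",
)

PRESETS: dict[str, tuple[str, ...]] = {"gppdn7": SEVEN_LAYER_SCHEMA}

_FORMATS = ("edge_list", "gmt")


@dataclass
class LayerSpec:
    name: str
    file: str
    format: str = "edge_list"
    directed: bool = False

    def __post_init__(self) -> None:
        if self.format not in _FORMATS:
            raise ConfigError(
                f"layer {self.name!r}: unknown format {self.format!r} "
                f"(expected one of {_FORMATS})"
            )


@dataclass
class RunConfig:
    layers: list[LayerSpec]
    total_jump_mass: float = 0.5
    jump_table: np.ndarray | None = None
    alpha: float = 0.7
    tolerance: float = 1e-9
    max_iterations: int = 1000
    respect_direction: bool = False
    base_dir: Path = field(default_factory=Path)

    def jump_spec(self, net: HeterogeneousNetwork) -> JumpSpec:
        if self.jump_table is not None:
            return JumpSpec(self.jump_table)
        return JumpSpec.default_for(net, self.total_jump_mass)


def load_config(path: str | Path) -> RunConfig:
    """Parse a YAML or JSON run configuration."""
    path = Path(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(raw, dict) or "layers" not in raw:
        raise ConfigError(f"{path}: config must be a mapping with a 'layers' list")
    layers = [
        LayerSpec(
            name=str(entry["name"]),
            file=str(entry["file"]),
            format=str(entry.get("format", "edge_list")),
            directed=bool(entry.get("directed", False)),
        )
        for entry in raw["layers"]
    ]
    jumping = raw.get("jumping") or {}
    table = jumping.get("table")
    return RunConfig(
        layers=layers,
        total_jump_mass=float(jumping.get("total_mass", 0.5)),
        jump_table=None if table is None else np.asarray(table, dtype=float),
        alpha=float(raw.get("alpha", 0.7)),
        tolerance=float(raw.get("tolerance", 1e-9)),
        max_iterations=int(raw.get("max_iterations", 1000)),
        respect_direction=bool(raw.get("respect_direction", False)),
        base_dir=path.parent,
    )


def build_network(cfg: RunConfig) -> HeterogeneousNetwork:
    """Read every declared layer file and assemble the coupled network."""
    layers: list[SubNetwork] = []
    for spec in cfg.layers:
        file_path = cfg.base_dir / spec.file
        with open(file_path, encoding="utf-8") as fh:
            if spec.format == "gmt":
                layers.append(read_gene_sets_gmt(fh, spec.name))
            else:
                layers.append(
                    read_edge_list(fh, spec.name, directed=spec.directed)
                )
    return build_gppdn(layers, respect_direction=cfg.respect_direction)
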