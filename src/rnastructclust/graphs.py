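"""Labeled-graph encoding of a folded window for the decomposition kernel.

The primary component is the structure graph: one vertex per nucleotide
(labeled A/C/G/U/N), backbone edges between consecutive positions, and
base-pair edges mirroring the predicted structure.  Optionally a disjoint
"path graph" copy of the nucleotide string is appended so that sequence-only
features contribute to the kernel independently of the predicted structure.
"""

from __future__ import annotations

import networkx as nx

from .folding import SecondaryStructure
from .preprocess import Window

BACKBONE = "backbone"
BASEPAIR = "basepair"
PATH_BACKBONE = "path_backbone"


def encode(
    window: Window, structure: SecondaryStructure, include_path_graph: bool = True
) -> nx.Graph:
    """Build the labeled graph for one window.

    Vertices carry a ``label`` attribute (the nucleotide); edges carry a
    ``relation`` attribute.  With ``include_path_graph`` a second,
    vertex-disjoint component with only ``path_backbone`` edges is added.
    """
    n = len(window)
    if structure.length != n:
        raise ValueError(
            f"structure length {structure.length} != window length {n} "
            f"for {window.window_id}"
        )
    g = nx.Graph()
    for i, base in enumerate(window.sequence):
        g.add_node(i, label=base)
    for i in range(n - 1):
        g.add_edge(i, i + 1, relation=BACKBONE)
    for i, j in sorted(structure.pairs):
        if window.sequence[i] == "N" or window.sequence[j] == "N":
            continue  # N never pairs
        g.add_edge(i, j, relation=BASEPAIR)
    if include_path_graph:
        for i, base in enumerate(window.sequence):
            g.add_node(n + i, label=base)
        for i in range(n - 1):
            g.add_edge(n + i, n + i + 1, relation=PATH_BACKBONE)
    return g


def to_edge_list(graph: nx.Graph) -> str:
    """Debug serialization: vertex lines then edge lines, canonically ordered."""
    lines = [f"v {u} {graph.nodes[u]['label']}" for u in sorted(graph.nodes)]
    for u, v in sorted(tuple(sorted(e)) for e in graph.edges):
        lines.append(f"e {u} {v} {graph.edges[u, v]['relation']}")
    return "\n".join(lines)
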