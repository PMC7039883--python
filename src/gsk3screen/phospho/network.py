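"""Protein–protein interaction components over a regulated protein set.

The interaction evidence itself is an input (a two-column TSV or SIF edge
list from any interaction database); this module restricts it to the
proteins of interest, finds connected components among proteins with at
least one interaction, and reports the connected fraction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx


class EdgeListError(ValueError):
    """A line of the edge list could not be parsed."""


@dataclass
class InteractionGraph:
    """Connected components of an interaction network over a protein set."""

    graph: nx.Graph
    proteins: set[str]
    components: list[set[str]]
    singletons: set[str]
    n_dropped_edges: int

    @property
    def connected_nodes(self) -> set[str]:
        return {n for comp in self.components for n in comp}

    @property
    def fraction_connected(self) -> float:
        if not self.proteins:
            return 0.0
        return len(self.connected_nodes) / len(self.proteins)

    def degree(self, node: str) -> int:
        return self.graph.degree(node) if node in self.graph else 0

    def components_frame(self):
        import pandas as pd

        rows = [
            {"component": i, "protein": p, "degree": self.degree(p)}
            for i, comp in enumerate(
                sorted(self.components, key=len, reverse=True), start=1
            )
            for p in sorted(comp)
        ]
        return pd.DataFrame(rows, columns=["component", "protein", "degree"])


def read_edge_list(path: str | Path) -> list[tuple[str, str]]:
    """Parse a 2-column TSV or 3-column SIF ("A relation B") edge list."""
    edges = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) == 2:
                a, b = fields
            elif len(fields) >= 3:
                a, b = fields[0], fields[2]  # SIF: source relation target...
            else:
                raise EdgeListError(
                    f"{path}:{lineno}: expected 2 (TSV) or >=3 (SIF) fields, "
                    f"got {len(fields)}: {line!r}"
                )
            edges.append((a, b))
    return edges


def build_interaction_network(
    proteins: set[str], edge_list: str | Path
) -> InteractionGraph:
    """Build the interaction graph restricted to ``proteins``.

    Edges touching a protein outside the set are dropped (counted in
    ``n_dropped_edges``). Components are computed over nodes of degree
    >= 1; isolated proteins are reported as singletons.
    """
    edges = read_edge_list(edge_list)
    graph = nx.Graph()
    graph.add_nodes_from(proteins)
    dropped = 0
    for a, b in edges:
        if a in proteins and b in proteins and a != b:
            graph.add_edge(a, b)
        else:
            dropped += 1
    connected = {n for n, d in graph.degree() if d >= 1}
    components = [set(c) for c in nx.connected_components(graph.subgraph(connected))]
    return InteractionGraph(
        graph=graph,
        proteins=set(proteins),
        components=components,
        singletons=set(proteins) - connected,
        n_dropped_edges=dropped,
    )
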