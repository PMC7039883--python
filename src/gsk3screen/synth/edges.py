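"""Synthetic protein–protein interaction edge lists with planted structure."""

from __future__ import annotations

from pathlib import Path

import numpy as np


def plant_interaction_edges(
    proteins: list[str],
    n_connected: int,
    n_components: int = 3,
    seed: int = 0,
) -> list[tuple[str, str]]:
    """Plant edges so exactly ``n_connected`` proteins have degree >= 1.

    The connected proteins are split into ``n_components`` groups, each
    wired as a random spanning tree (so every member has at least one
    interaction and the groups are maximal components).
    """
    if n_connected > len(proteins):
        raise ValueError("n_connected exceeds the number of proteins")
    if n_connected > 0 and n_components > n_connected // 2 + 1:
        raise ValueError("too many components for the connected set")
    rng = np.random.default_rng(seed)
    chosen = list(rng.choice(proteins, size=n_connected, replace=False))
    groups = np.array_split(chosen, n_components) if n_connected else []
    edges = []
    for group in groups:
        members = list(group)
        for i in range(1, len(members)):
            j = int(rng.integers(0, i))
            edges.append((members[j], members[i]))
    return edges


def write_edge_list(edges: list[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for a, b in edges:
            fh.write(f"{a}\t{b}\n")
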