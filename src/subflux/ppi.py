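"""Protein-interaction sub-networks induced by a significant gene set.

The interaction network is treated as a plain undirected, unweighted graph:
duplicate edges collapse, self-loops drop, and an optional confidence-score
cutoff filters the edge list.  The induced subgraph on a gene set keeps
isolated genes (degree 0); reporting covers connected components (largest
first) and hubs, the nodes whose degree reaches a threshold within their
component.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import pandas as pd

__all__ = [
    "read_edge_list",
    "induced_subgraph",
    "components_and_hubs",
    "component_report",
]


def read_edge_list(path: str | Path, min_score: float | None = None) -> list[tuple[str, str]]:
    """Read a TSV edge list (gene1, gene2[, score]); header optional."""
    df = pd.read_csv(path, sep="\t", dtype=str, header=None, comment="#")
    first = df.iloc[0]
    if str(first[0]).lower() in {"gene1", "protein1", "source"}:
        df = df.iloc[1:]
    if min_score is not None:
        if df.shape[1] < 3:
            raise ValueError("edge list has no score column to filter on")
        df = df[df[2].astype(float) >= min_score]
    return [(str(a), str(b)) for a, b in zip(df[0], df[1])]


def induced_subgraph(edges: list[tuple[str, str]], genes: set[str]) -> nx.Graph:
    """Undirected graph on ``genes`` keeping only both-endpoint edges."""
    g = nx.Graph()
    g.add_nodes_from(sorted(genes))
    for a, b in edges:
        if a != b and a in genes and b in genes:
            g.add_edge(a, b)
    return g


def components_and_hubs(
    g: nx.Graph, k_hub: int = 5
) -> tuple[list[frozenset[str]], pd.DataFrame]:
    """Connected components (size-descending) and a per-node degree table.

    Hubs are nodes of degree ≥ ``k_hub``; the table records each node's
    component index, degree and hub flag.
    """
    if k_hub < 1:
        raise ValueError("k_hub must be >= 1")
    comps = sorted(
        (frozenset(c) for c in nx.connected_components(g)),
        key=lambda c: (-len(c), min(c)),
    )
    rows = []
    for ci, comp in enumerate(comps):
        for node in sorted(comp):
            deg = g.degree[node]
            rows.append((node, ci, deg, deg >= k_hub))
    table = pd.DataFrame(rows, columns=["gene", "component", "degree", "is_hub"])
    return comps, table


def component_report(
    g: nx.Graph, k_hub: int = 5, path: str | Path | None = None
) -> str:
    comps, table = components_and_hubs(g, k_hub=k_hub)
    text = table.to_csv(sep="\t", index=False)
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text


def write_graphml(g: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(g, str(path))
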