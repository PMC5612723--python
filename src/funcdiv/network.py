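"""Confidence-filtered protein-interaction networks over the selected genes.

Mirrors a STRING-style workflow: keep edges whose confidence score reaches the
high-confidence level (0.700, inclusive) with both endpoints in the selected
set, then report connected components of at least three genes and per-gene
degrees.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd

from funcdiv.data_model import ValidationError

HIGH_CONFIDENCE = 0.700


@dataclass
class InteractionGraph:
    """Score-filtered undirected graph; no self-loops, max score on duplicates."""

    graph: nx.Graph

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[tuple[str, str]]:
        return {tuple(sorted(e)) for e in self.graph.edges}

    def score(self, a: str, b: str) -> float:
        return self.graph.edges[a, b]["score"]


def filter_edges(
    edges: pd.DataFrame,
    selected: set[str],
    min_score: float = HIGH_CONFIDENCE,
) -> InteractionGraph:
    """Build the graph from an edge list (gene_a, gene_b, score).

    Keeps edges with score >= min_score and both endpoints in ``selected``;
    self-loops are dropped, and duplicate pairs (in either orientation) keep
    the maximum score.
    """
    bad = edges.index[(edges["score"] < 0) | (edges["score"] > 1)]
    if len(bad):
        raise ValidationError(
            f"edge score outside [0, 1] at row(s) {[int(i) + 2 for i in bad[:5]]}"
        )
    g = nx.Graph()
    for row in edges.itertuples(index=False):
        a, b, score = str(row.gene_a), str(row.gene_b), float(row.score)
        if a == b or score < min_score:
            continue
        if a not in selected or b not in selected:
            continue
        if g.has_edge(a, b):
            g.edges[a, b]["score"] = max(g.edges[a, b]["score"], score)
        else:
            g.add_edge(a, b, score=score)
    return InteractionGraph(graph=g)


def components_above(graph: InteractionGraph, min_size: int = 3) -> list[set[str]]:
    """Connected components with >= min_size nodes.

    Sorted by descending size, then by the lexicographically smallest member.
    """
    comps = [set(c) for c in nx.connected_components(graph.graph) if len(c) >= min_size]
    comps.sort(key=lambda c: (-len(c), min(c)))
    return comps


def degree_report(graph: InteractionGraph) -> pd.DataFrame:
    """Per-gene degrees, descending; ties broken lexicographically."""
    rows = [{"gene": node, "degree": deg} for node, deg in graph.graph.degree]
    rows.sort(key=lambda r: (-r["degree"], r["gene"]))
    return pd.DataFrame(rows, columns=["gene", "degree"])


def write_components_table(components: list[set[str]], path) -> None:
    rows = [
        {"component_id": i + 1, "gene": gene}
        for i, comp in enumerate(components)
        for gene in sorted(comp)
    ]
    pd.DataFrame(rows, columns=["component_id", "gene"]).to_csv(path, sep="\t", index=False)


def write_degrees_table(degrees: pd.DataFrame, path) -> None:
    degrees.to_csv(path, sep="\t", index=False)


def export_graph(graph: InteractionGraph, path) -> None:
    """Plain edge-list export (gene_a, gene_b, score) for external drawing tools."""
    rows = [
        {"gene_a": a, "gene_b": b, "score": f"{graph.score(a, b):.6f}"}
        for a, b in sorted(graph.edges)
    ]
    pd.DataFrame(rows, columns=["gene_a", "gene_b", "score"]).to_csv(path, sep="\t", index=False)
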