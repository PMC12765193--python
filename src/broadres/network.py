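"""Integrative gene-regulator / drug-gene network assembly from edge tables.

Edges come from three sources — protein-protein interactions, transcription
factor -> target regulatory links and drug -> gene interactions — and are
stored undirected for distance and degree statistics (the semantic
direction of regulatory and drug edges is retained as metadata).  Nodes are
annotated with differential-expression and mutation-skew flags so the
emitted tables can be loaded straight into a graph viewer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from .errors import ValidationError
from .io import EDGE_TYPES
from .mutations import SkewResult

__all__ = ["DrugGeneNetwork", "build_network", "ego_subnetwork", "degree_table"]


@dataclass
class DrugGeneNetwork:
    """Undirected annotated graph; parallel edges collapse, types accumulate."""

    graph: nx.Graph
    errors: list[str] = field(default_factory=list)

    @property
    def nodes(self):
        return self.graph.nodes

    @property
    def edges(self):
        return self.graph.edges

    def node_table(self) -> pd.DataFrame:
        rows = []
        for node, attrs in sorted(self.graph.nodes(data=True)):
            rows.append(
                {
                    "node": node,
                    "kind": attrs.get("kind", "gene"),
                    "is_deg_up": attrs.get("is_deg_up", False),
                    "is_deg_down": attrs.get("is_deg_down", False),
                    "is_mutated_skewed": attrs.get("is_mutated_skewed", False),
                    "skew_value": attrs.get("skew_value", float("nan")),
                }
            )
        return pd.DataFrame(rows)

    def edge_table(self) -> pd.DataFrame:
        rows = []
        for u, v, attrs in self.graph.edges(data=True):
            a, b = sorted((u, v))
            rows.append(
                {
                    "source": a,
                    "target": b,
                    "edge_types": "|".join(sorted(attrs["edge_types"])),
                }
            )
        return pd.DataFrame(rows).sort_values(["source", "target"]).reset_index(drop=True)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.node_table().to_csv(out / "nodes.tsv", sep="\t", index=False)
        self.edge_table().to_csv(out / "edges.tsv", sep="\t", index=False)


def build_network(
    edge_table: pd.DataFrame,
    deg_up: set[str] = frozenset(),
    deg_down: set[str] = frozenset(),
    skew: SkewResult | None = None,
    drug_targets: dict[str, set[str]] | None = None,
    row_errors: list[str] | None = None,
) -> DrugGeneNetwork:
    """Assemble the annotated network from a validated edge table.

    Self-loops are dropped, duplicate edges collapse into one edge whose
    ``edge_types`` attribute accumulates the contributing types.  Node kinds
    are inferred from edge semantics: the source of a drug-gene edge is a
    drug, the source of a tf-target edge a transcription factor, everything
    else a gene (drug > tf > gene on conflicts).  ``drug_targets``
    optionally contributes extra drug-gene edges.
    """
    errors = list(row_errors or [])
    g = nx.Graph()
    skew_map = {}
    if skew is not None:
        skew_map = dict(zip(skew.table["gene"], skew.table["skew"]))
        skewed = set(skew.top_resistant) | set(skew.top_sensitive)
    else:
        skewed = set()

    def add_edge(src: str, tgt: str, etype: str):
        if src == tgt:
            return
        for node in (src, tgt):
            if node not in g:
                g.add_node(node, kind="gene")
        if etype == "drug_gene":
            g.nodes[src]["kind"] = "drug"
        elif etype == "tf_target" and g.nodes[src]["kind"] != "drug":
            g.nodes[src]["kind"] = "tf"
        if g.has_edge(src, tgt):
            g[src][tgt]["edge_types"].add(etype)
        else:
            g.add_edge(src, tgt, edge_types={etype})

    for i, row in enumerate(edge_table.itertuples(index=False), start=1):
        src, tgt, etype = str(row.source).strip(), str(row.target).strip(), str(row.edge_type)
        if not src or not tgt:
            errors.append(f"row {i}: empty endpoint")
            continue
        if etype not in EDGE_TYPES:
            errors.append(f"row {i}: unknown edge_type {etype!r}")
            continue
        add_edge(src, tgt, etype)
    if drug_targets:
        for drug in sorted(drug_targets):
            for gene in sorted(drug_targets[drug]):
                add_edge(drug, gene, "drug_gene")

    for node in g.nodes:
        g.nodes[node]["is_deg_up"] = node in deg_up
        g.nodes[node]["is_deg_down"] = node in deg_down
        g.nodes[node]["is_mutated_skewed"] = node in skewed
        g.nodes[node]["skew_value"] = float(skew_map.get(node, float("nan")))
    return DrugGeneNetwork(graph=g, errors=errors)


def ego_subnetwork(net: DrugGeneNetwork, hub: str, radius: int = 1) -> DrugGeneNetwork:
    """Induced subgraph of nodes within graph distance ``radius`` of ``hub``."""
    if hub not in net.graph:
        raise ValidationError(f"hub {hub!r} not in network")
    sub = nx.ego_graph(net.graph, hub, radius=radius)
    return DrugGeneNetwork(graph=sub.copy())


def degree_table(net: DrugGeneNetwork) -> pd.DataFrame:
    """Per-node degree split by edge type, sorted by total degree descending."""
    rows = []
    for node in net.graph.nodes:
        by_type = dict.fromkeys(EDGE_TYPES, 0)
        for _, _, attrs in net.graph.edges(node, data=True):
            for etype in attrs["edge_types"]:
                by_type[etype] += 1
        rows.append(
            {
                "node": node,
                **{f"degree_{t}": by_type[t] for t in EDGE_TYPES},
                "total_degree": net.graph.degree(node),
            }
        )
    out = pd.DataFrame(rows)
    return out.sort_values(
        ["total_degree", "node"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
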