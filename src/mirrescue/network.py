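"""Regulatory-network assembly: miRNA->target edges plus PPI overlay.

Nodes are miRNAs (role "mirna") and genes (role "gene"); edges are
typed ``mirna_target`` (from retained anti-correlation records) or
``ppi`` (gene-gene, from a BioGrid-style tab file, expanded one hop
from the target genes). Each node carries two log2 expression ratios,
disease over treated disease (D vs D+P) and disease over control
(D vs C), stored as differences of group means.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .mirtarget import MiRTargetRecord

log = logging.getLogger(__name__)

DEFAULT_SYMBOL_COLUMNS = ("Official Symbol Interactor A",
                          "Official Symbol Interactor B")


class NetworkError(ValueError):
    pass


def load_ppi(edge_file: str | Path,
             symbol_columns: tuple[str, str] = DEFAULT_SYMBOL_COLUMNS
             ) -> list[tuple[str, str]]:
    """Undirected, deduplicated gene-symbol pairs; self-loops dropped."""
    df = pd.read_csv(edge_file, sep="\t")
    a_col, b_col = symbol_columns
    missing = [c for c in symbol_columns if c not in df.columns]
    if missing:
        raise NetworkError(
            f"PPI file lacks columns {missing}; expected headers "
            f"{list(symbol_columns)}")
    seen = set()
    edges = []
    for a, b in zip(df[a_col], df[b_col]):
        a, b = str(a), str(b)
        if a == b:
            continue
        key = (a, b) if a <= b else (b, a)
        if key not in seen:
            seen.add(key)
            edges.append(key)
    return edges


def build_network(retained_records: list[MiRTargetRecord],
                  ppi_edges: list[tuple[str, str]],
                  group_means: pd.DataFrame | None = None,
                  ppi_hops: int = 1) -> nx.Graph:
    """Assemble the typed miRNA-target / PPI graph with ratio attributes.

    ``group_means`` is a genes/miRNAs x groups table (any union of the
    two expression spaces); nodes absent from it keep NA attributes
    with a logged warning.
    """
    g = nx.Graph()
    for rec in retained_records:
        if rec.mirna == rec.gene:
            continue  # no mirna_target self-loops
        g.add_node(rec.mirna, role="mirna")
        g.add_node(rec.gene, role="gene")
        g.add_edge(rec.mirna, rec.gene, interaction="mirna_target")
    targets = {rec.gene for rec in retained_records}
    frontier = set(targets)
    for _ in range(ppi_hops):
        added = set()
        for a, b in ppi_edges:
            if a in frontier or b in frontier:
                for n in (a, b):
                    if n not in g:
                        g.add_node(n, role="gene")
                        added.add(n)
                if not g.has_edge(a, b):
                    g.add_edge(a, b, interaction="ppi")
        frontier = added
        if not frontier:
            break
    for node in g.nodes:
        r_dp = r_c = float("nan")
        if group_means is not None and node in group_means.index:
            row = group_means.loc[node]
            r_dp = float(row["D"] - row["D+P"])
            r_c = float(row["D"] - row["C"])
        else:
            log.warning("node %r has no expression data; ratios set NA",
                        node)
        g.nodes[node]["log2ratio_D_vs_DP"] = r_dp
        g.nodes[node]["log2ratio_D_vs_C"] = r_c
    return g


def export_network(net: nx.Graph, path: str | Path,
                   fmt: str = "graphml") -> Path:
    """Write the network as GraphML or SIF (source TAB type TAB target)."""
    path = Path(path)
    if fmt == "graphml":
        nx.write_graphml(net, path, named_key_ids=True)
    elif fmt == "sif":
        lines = [f"{a}\t{d['interaction']}\t{b}"
                 for a, b, d in sorted(net.edges(data=True))]
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
    else:
        raise NetworkError(f"unknown format: {fmt!r}")
    return path


def read_network(path: str | Path) -> nx.Graph:
    return nx.read_graphml(path)


def node_attribute_table(net: nx.Graph) -> pd.DataFrame:
    rows = [{"node": n, **d} for n, d in sorted(net.nodes(data=True))]
    return pd.DataFrame(rows, columns=["node", "role", "log2ratio_D_vs_DP",
                                       "log2ratio_D_vs_C"])
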