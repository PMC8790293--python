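"""Merged pathway gene-interaction network, degree statistics and hub genes.

Per-pathway edge lists are merged into one simple undirected graph whose
edges remember which pathways contributed them.  Hub genes are nodes whose
degree (number of distinct neighbours) strictly exceeds a threshold —
the operative rule is degree > 30.  A least-squares log-log fit of the
binned degree density provides the usual scale-free diagnostic for
biomolecular networks.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "GeneNetwork",
    "PowerLawFit",
    "merge_networks",
    "degree_table",
    "powerlaw_diagnostic",
    "hub_genes",
    "top_fraction_hubs",
    "write_edge_list",
    "write_graphml",
    "write_degree_table",
]


@dataclass
class GeneNetwork:
    """Simple undirected gene graph with per-edge pathway provenance.

    Nodes enter only through edges, so isolated nodes cannot occur.  Edge
    attributes: ``pathways`` (set of contributing pathway ids) and
    ``relation_types`` (set of KGML relation types observed for the pair).
    """

    graph: nx.Graph

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_provenance(self, a: str, b: str) -> set[str]:
        return self.graph.edges[a, b]["pathways"]


def merge_networks(
    pathway_edge_lists: Mapping[str, Iterable[tuple[str, str, str]]],
) -> GeneNetwork:
    """Merge per-pathway edge lists into one simple undirected network.

    Parameters
    ----------
    pathway_edge_lists
        Mapping pathway id -> iterable of ``(geneA, geneB, relation_type)``
        tuples (as produced by :func:`pathmarker.kgml.pathway_edges`).

    Duplicate gene pairs collapse to a single edge whose provenance is the
    union of contributing pathway ids.  Self-pairs are dropped.  Merging is
    idempotent: re-merging a merged network's edges changes nothing.
    """
    g: nx.Graph = nx.Graph()
    for pathway_id, edges in pathway_edge_lists.items():
        for a, b, rtype in edges:
            if a == b:
                continue
            if g.has_edge(a, b):
                g.edges[a, b]["pathways"].add(pathway_id)
                g.edges[a, b]["relation_types"].add(rtype)
            else:
                g.add_edge(a, b, pathways={pathway_id}, relation_types={rtype})
    if g.number_of_edges() == 0:
        raise ValueError("no edges: cannot build an empty gene network")
    return GeneNetwork(graph=g)


def degree_table(net: GeneNetwork) -> pd.DataFrame:
    """Per-node degree table, sorted by decreasing degree then symbol.

    Degree counts distinct neighbours; the handshake identity
    sum(degree) == 2 * |edges| holds exactly.
    """
    if net.n_nodes == 0:
        raise ValueError("empty network")
    rows = [(node, deg) for node, deg in net.graph.degree()]
    df = pd.DataFrame(rows, columns=["gene", "degree"])
    return df.sort_values(
        ["degree", "gene"], ascending=[False, True], ignore_index=True
    )


@dataclass
class PowerLawFit:
    """Result of the log-log degree-density diagnostic."""

    applicable: bool
    exponent: float = float("nan")
    r_squared: float = float("nan")
    n_bins_used: int = 0
    reason: str = ""


def powerlaw_diagnostic(degrees: pd.DataFrame, n_bins: int = 20) -> PowerLawFit:
    """Least-squares fit of log density against log degree.

    Degrees are aggregated into logarithmically spaced bins (to tame the
    noisy tail) before regressing log10(density) on log10(degree).  The
    exponent is reported as minus the slope.  Needs at least 10 distinct
    degree values; degenerate distributions yield an inapplicable result
    rather than an error.
    """
    k = np.asarray(degrees["degree"], dtype=float)
    if np.unique(k).size < 10:
        return PowerLawFit(applicable=False, reason="fewer than 10 distinct degrees")

    kmin, kmax = k.min(), k.max()
    edges = np.logspace(np.log10(kmin), np.log10(kmax), n_bins + 1)
    edges[0] *= 1 - 1e-9
    edges[-1] *= 1 + 1e-9
    counts, edges = np.histogram(k, bins=edges)
    widths = np.diff(edges)
    centers = np.sqrt(edges[:-1] * edges[1:])  # geometric bin centre
    density = counts / (widths * k.size)

    keep = counts > 0
    if keep.sum() < 3:
        return PowerLawFit(applicable=False, reason="too few occupied bins")
    x = np.log10(centers[keep])
    y = np.log10(density[keep])
    slope, intercept = np.polyfit(x, y, 1)
    fitted = slope * x + intercept
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        return PowerLawFit(applicable=False, reason="zero variance in binned density")
    return PowerLawFit(
        applicable=True,
        exponent=float(-slope),
        r_squared=1.0 - ss_res / ss_tot,
        n_bins_used=int(keep.sum()),
    )


def hub_genes(degrees: pd.DataFrame, min_degree: int = 30) -> set[str]:
    """Nodes with degree strictly greater than ``min_degree``.

    The threshold is exclusive: a node of degree exactly ``min_degree`` is
    not a hub.  Raising the threshold never adds members.
    """
    if degrees.empty:
        raise ValueError("empty degree table")
    mask = degrees["degree"] > min_degree
    return set(degrees.loc[mask, "gene"])


def top_fraction_hubs(degrees: pd.DataFrame, fraction: float = 0.10) -> set[str]:
    """Alternative hub rule: the top ``fraction`` of nodes by degree.

    Ties at the cut-off degree are all included, so the returned set may be
    larger than ``fraction * n``.
    """
    if degrees.empty:
        raise ValueError("empty degree table")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    n_keep = max(1, int(np.ceil(fraction * len(degrees))))
    ordered = degrees.sort_values(
        ["degree", "gene"], ascending=[False, True], ignore_index=True
    )
    cutoff = int(ordered.loc[n_keep - 1, "degree"])
    return set(ordered.loc[ordered["degree"] >= cutoff, "gene"])


def write_edge_list(net: GeneNetwork, path: str | Path) -> None:
    """Edge-list TSV: geneA, geneB, relation types, contributing pathways."""
    rows = []
    for a, b, data in sorted(net.graph.edges(data=True)):
        rows.append(
            "\t".join(
                [
                    a,
                    b,
                    ",".join(sorted(data["relation_types"])),
                    ",".join(sorted(data["pathways"])),
                ]
            )
        )
    header = "geneA\tgeneB\trelation_types\tpathways"
    Path(path).write_text("\n".join([header, *rows]) + "\n")


def write_graphml(net: GeneNetwork, path: str | Path) -> None:
    """GraphML export (Cytoscape-importable); set attributes serialized."""
    g = nx.Graph()
    for node, deg in net.graph.degree():
        g.add_node(node, degree=int(deg))
    for a, b, data in net.graph.edges(data=True):
        g.add_edge(
            a,
            b,
            pathways=",".join(sorted(data["pathways"])),
            relation_types=",".join(sorted(data["relation_types"])),
        )
    nx.write_graphml(g, str(path))


def write_degree_table(degrees: pd.DataFrame, path: str | Path) -> None:
    degrees.to_csv(path, sep="\t", index=False)
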