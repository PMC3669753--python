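"""Pearson-threshold co-expression graphs, modules, bait-prey networks.

An edge joins two genes whenever their Pearson correlation across the
compendium reaches the cutoff (0.7 by default, on signed r: positive
co-expression only — an ``use_abs`` flag admits strong anticorrelation
too).  A *module* is a connected component with no edges to the rest of
the graph, i.e. exactly a connected component of the thresholded graph.

The bait-prey construction seeds the network with a set of bait genes
(differentially expressed kinases/phosphatases) against a prey set (the
other Fe-responsive genes): edges between two preys are discarded, then
any node left without an edge is dropped, so every surviving node is
connected to a bait.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .io_formats import ExpressionTable, normalize_gene_id

__all__ = [
    "NetworkConfig",
    "Module",
    "pearson_matrix",
    "build_network",
    "extract_modules",
    "bait_prey_network",
]


@dataclass
class NetworkConfig:
    """Thresholding parameters for co-expression graphs."""

    r_cutoff: float = 0.7
    min_arrays: int = 10
    drop_isolated: bool = True
    use_abs: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.r_cutoff <= 1:
            raise ValueError("r_cutoff must lie in (0, 1]")
        if self.min_arrays < 2:
            raise ValueError("min_arrays must be >= 2")


def pearson_matrix(
    compendium: ExpressionTable,
    genes,
    cfg: NetworkConfig | None = None,
) -> pd.DataFrame:
    """Symmetric product-moment correlation matrix over the compendium.

    Zero-variance genes get NaN against every partner (undefined r is
    recorded as missing, never thresholded into an edge); the diagonal
    is 1 by convention.
    """
    cfg = cfg or NetworkConfig()
    wanted = [normalize_gene_id(g) for g in genes]
    missing = [g for g in wanted if g not in compendium.values.index]
    if missing:
        raise KeyError(f"genes absent from compendium: {missing[:5]}")
    if len(compendium.sample_ids) < cfg.min_arrays:
        raise ValueError(
            f"compendium has {len(compendium.sample_ids)} arrays, "
            f"fewer than min_arrays={cfg.min_arrays}"
        )
    x = compendium.values.loc[wanted].to_numpy(dtype=float)
    sd = x.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x)
    r = np.atleast_2d(r)
    r[sd == 0, :] = np.nan
    r[:, sd == 0] = np.nan
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=wanted, columns=wanted)


def _threshold_edges(r: pd.DataFrame, cfg: NetworkConfig):
    vals = r.to_numpy()
    genes = list(r.index)
    iu, ju = np.triu_indices(len(genes), k=1)
    pair = vals[iu, ju]
    crit = np.abs(pair) if cfg.use_abs else pair
    keep = ~np.isnan(pair) & (crit >= cfg.r_cutoff)
    for i, j, v in zip(iu[keep], ju[keep], pair[keep]):
        a, b = sorted((genes[i], genes[j]))
        yield a, b, float(v)


def build_network(
    compendium: ExpressionTable,
    genes,
    node_attrs: dict[str, dict] | None = None,
    cfg: NetworkConfig | None = None,
) -> nx.Graph:
    """Thresholded co-expression graph over *genes*.

    Node attributes (role, direction) are attached from *node_attrs*;
    degree-0 nodes are removed when cfg.drop_isolated.
    """
    cfg = cfg or NetworkConfig()
    r = pearson_matrix(compendium, genes, cfg)
    g = nx.Graph()
    g.add_nodes_from(r.index)
    for a, b, rv in _threshold_edges(r, cfg):
        g.add_edge(a, b, r=rv)
    if cfg.drop_isolated:
        g.remove_nodes_from([n for n, d in g.degree() if d == 0])
    _attach_attrs(g, node_attrs)
    return g


def _attach_attrs(g: nx.Graph, node_attrs: dict[str, dict] | None) -> None:
    attrs = {normalize_gene_id(k): v for k, v in (node_attrs or {}).items()}
    for n in g.nodes:
        a = attrs.get(n, {})
        g.nodes[n]["role"] = a.get("role", "prey")
        g.nodes[n]["direction"] = a.get("direction", "none")


@dataclass
class Module:
    """A connected component with no edges to any other component."""

    name: str
    members: set[str]
    n_edges: int
    summary: dict[str, int] = field(default_factory=dict)


def extract_modules(graph: nx.Graph) -> list[Module]:
    """Connected components with >= 2 nodes, named M1, M2, ... by
    decreasing size, ties broken by smallest member ID."""
    comps = [c for c in nx.connected_components(graph) if len(c) >= 2]
    comps.sort(key=lambda c: (-len(c), min(c)))
    modules = []
    for k, comp in enumerate(comps, start=1):
        sub = graph.subgraph(comp)
        roles = [graph.nodes[n].get("role", "prey") for n in comp]
        summary = {
            "n_kinase": sum(r in ("kinase", "both") for r in roles),
            "n_phosphatase": sum(r in ("phosphatase", "both") for r in roles),
            "n_prey": sum(r == "prey" for r in roles),
        }
        modules.append(
            Module(name=f"M{k}", members=set(comp), n_edges=sub.number_of_edges(), summary=summary)
        )
    return modules


def bait_prey_network(
    compendium: ExpressionTable,
    baits,
    preys,
    node_attrs: dict[str, dict] | None = None,
    cfg: NetworkConfig | None = None,
) -> nx.Graph:
    """Bait-seeded network: threshold edges over baits + preys, drop every
    prey-prey edge, then drop every node left with degree 0.  Bait-bait
    edges are retained; every surviving node touches a bait."""
    cfg = cfg or NetworkConfig()
    bait_set = {normalize_gene_id(g) for g in baits}
    prey_set = {normalize_gene_id(g) for g in preys}
    overlap = bait_set & prey_set
    if overlap:
        raise ValueError(f"genes listed as both bait and prey: {sorted(overlap)}")
    all_genes = sorted(bait_set | prey_set)
    r = pearson_matrix(compendium, all_genes, cfg)
    g = nx.Graph()
    g.add_nodes_from(all_genes)
    for a, b, rv in _threshold_edges(r, cfg):
        if a in prey_set and b in prey_set:
            continue  # edges linked to two preys are excluded
        g.add_edge(a, b, r=rv)
    g.remove_nodes_from([n for n, d in g.degree() if d == 0])
    _attach_attrs(g, node_attrs)
    for n in g.nodes:
        if n in prey_set:
            g.nodes[n]["role"] = "prey"
    return g
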