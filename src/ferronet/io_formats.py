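"""Readers and writers for every file the pipeline touches.

All tabular files are plain TSV.  Expression tables carry their sample
metadata in two extra header rows (``condition`` and ``replicate``)
directly under the sample-ID header, so a dataset is a single file.
Ontologies use a deliberately tiny OBO-like grammar ([Term] stanzas with
``id``, ``name``, optional ``namespace`` and ``is_a`` lines).  Networks
export as SIF or as an edge-attribute table plus a node-attribute table,
both of which Cytoscape imports directly.

Gene identifiers are compared case-insensitively and stored upper-cased
(AGI codes appear in mixed case in the literature).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .go_enrichment import GoDag, GoDagError

__all__ = [
    "ExpressionTable",
    "GeneAnnotationTable",
    "normalize_gene_id",
    "read_expression_table",
    "write_expression_table",
    "read_annotation_table",
    "write_annotation_table",
    "read_obo_lite",
    "write_obo_lite",
    "read_gene2term",
    "write_gene2term",
    "write_network",
    "read_edge_table",
]

SCALES = ("rpkm", "log2")


class FormatError(ValueError):
    """Raised when an input file violates the documented grammar."""


def normalize_gene_id(gene_id: str) -> str:
    return str(gene_id).strip().upper()


@dataclass
class ExpressionTable:
    """Genes x samples numeric matrix with per-sample condition/replicate.

    ``values`` is indexed by upper-cased gene IDs with sample IDs as
    columns; ``sample_meta`` is indexed by the same sample IDs and has
    columns ``condition`` (free label) and ``replicate`` (positive int).
    ``scale`` tags the unit: raw "rpkm" (non-negative) or "log2".
    """

    values: pd.DataFrame
    scale: str
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ValueError(f"scale must be one of {SCALES}: {self.scale!r}")
        self.values.index = pd.Index(
            [normalize_gene_id(g) for g in self.values.index], name="gene_id"
        )
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise FormatError(f"duplicate gene ID {dup!r}")
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise FormatError(f"duplicate sample ID {dup!r}")
        if not np.issubdtype(self.values.to_numpy().dtype, np.number):
            raise FormatError("expression matrix contains non-numeric values")
        if self.scale == "rpkm" and (self.values.to_numpy() < 0).any():
            r, c = np.argwhere(self.values.to_numpy() < 0)[0]
            raise FormatError(
                f"negative value under scale='rpkm' at gene "
                f"{self.values.index[r]!r}, sample {self.values.columns[c]!r}"
            )
        if list(self.sample_meta.index) != list(self.values.columns):
            raise FormatError("sample_meta index must equal the sample columns")
        if (self.sample_meta["replicate"].astype(int) < 1).any():
            raise FormatError("replicate numbers must be positive integers")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_for(self, condition: str) -> pd.DataFrame:
        """Sub-matrix of samples with the given condition, replicate-sorted."""
        meta = self.sample_meta[self.sample_meta["condition"] == condition]
        meta = meta.sort_values("replicate")
        return self.values[list(meta.index)]

    def subset(self, genes) -> "ExpressionTable":
        wanted = [normalize_gene_id(g) for g in genes]
        missing = [g for g in wanted if g not in self.values.index]
        if missing:
            raise KeyError(f"genes absent from table: {missing[:5]}")
        return ExpressionTable(self.values.loc[wanted].copy(), self.scale, self.sample_meta.copy())


def read_expression_table(path, scale: str) -> ExpressionTable:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        cond_row = fh.readline().rstrip("\n").split("\t")
        rep_row = fh.readline().rstrip("\n").split("\t")
        if cond_row[0] != "condition" or rep_row[0] != "replicate":
            raise FormatError(
                f"{path}: rows 2-3 must start with 'condition' and 'replicate'"
            )
        sample_ids = header[1:]
        body = pd.read_csv(fh, sep="\t", header=None, index_col=0, dtype=str)
    if len(cond_row) - 1 != len(sample_ids) or len(rep_row) - 1 != len(sample_ids):
        raise FormatError(f"{path}: metadata rows do not match the sample header")
    body.columns = sample_ids
    values = pd.DataFrame(index=body.index, columns=sample_ids, dtype=float)
    for j, col in enumerate(sample_ids):
        parsed = pd.to_numeric(body[col], errors="coerce")
        bad = parsed.isna() & body[col].notna()
        if bad.any():
            gene = body.index[bad.argmax()]
            raise FormatError(
                f"{path}: non-numeric cell at gene {gene!r}, sample {col!r}"
            )
        if parsed.isna().any():
            gene = body.index[parsed.isna().argmax()]
            raise FormatError(f"{path}: missing value at gene {gene!r}, sample {col!r}")
        values[col] = parsed.to_numpy(dtype=float)
    meta = pd.DataFrame(
        {"condition": cond_row[1:], "replicate": [int(r) for r in rep_row[1:]]},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return ExpressionTable(values, scale, meta)


def write_expression_table(table: ExpressionTable, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("gene_id\t" + "\t".join(table.sample_ids) + "\n")
        fh.write(
            "condition\t"
            + "\t".join(str(c) for c in table.sample_meta["condition"])
            + "\n"
        )
        fh.write(
            "replicate\t"
            + "\t".join(str(int(r)) for r in table.sample_meta["replicate"])
            + "\n"
        )
        for gene, row in table.values.iterrows():
            fh.write(gene + "\t" + "\t".join(format(v, ".10g") for v in row) + "\n")


@dataclass
class GeneAnnotationTable:
    """Per-gene functional annotation: free-text function, enzyme class
    (kinase / phosphatase / both / other) and subfamily label."""

    df: pd.DataFrame = field(repr=False)

    COLUMNS = ("gene_id", "function", "class", "subfamily")

    def __post_init__(self) -> None:
        df = self.df.copy()
        for col in self.COLUMNS:
            if col not in df.columns:
                raise FormatError(f"annotation table missing column {col!r}")
        df["gene_id"] = df["gene_id"].map(normalize_gene_id)
        if df["gene_id"].duplicated().any():
            dup = df["gene_id"][df["gene_id"].duplicated()].iloc[0]
            raise FormatError(f"duplicate gene ID {dup!r} in annotation table")
        bad = ~df["class"].isin(["kinase", "phosphatase", "both", "other"])
        if bad.any():
            raise FormatError(f"invalid class label {df['class'][bad].iloc[0]!r}")
        df["subfamily"] = df["subfamily"].fillna("")
        self.df = df.reset_index(drop=True)

    @property
    def gene_ids(self) -> set[str]:
        return set(self.df["gene_id"])

    def subfamily_of(self, gene_id: str) -> str:
        gene_id = normalize_gene_id(gene_id)
        hit = self.df[self.df["gene_id"] == gene_id]
        if hit.empty:
            raise KeyError(f"gene {gene_id!r} not in annotation table")
        return hit["subfamily"].iloc[0]


def read_annotation_table(path) -> GeneAnnotationTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return GeneAnnotationTable(df)


def write_annotation_table(table: GeneAnnotationTable, path) -> None:
    table.df.to_csv(path, sep="\t", index=False)


def read_obo_lite(path) -> GoDag:
    """Parse the restricted OBO grammar: [Term] stanzas with ``id:``,
    ``name:``, optional ``namespace:`` and zero or more ``is_a:`` lines."""
    terms: list[str] = []
    names: dict[str, str] = {}
    namespaces: dict[str, str] = {}
    edges: list[tuple[str, str]] = []
    cur: str | None = None
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("!"):
                continue
            if line == "[Term]":
                cur = None
                continue
            if line.startswith("[") and line.endswith("]"):
                cur = None  # foreign stanza type: skip its body
                continue
            if ":" not in line:
                raise FormatError(f"unparseable line: {line!r}")
            key, _, val = line.partition(":")
            val = val.strip().split("!")[0].strip()
            if key == "id":
                cur = val
                terms.append(cur)
            elif key == "name" and cur is not None:
                names[cur] = val
            elif key == "namespace" and cur is not None:
                namespaces[cur] = val
            elif key == "is_a" and cur is not None:
                edges.append((cur, val))
    declared = set(terms)
    for child, parent in edges:
        if parent not in declared:
            raise GoDagError(f"is_a references undeclared term {parent!r}")
    return GoDag.from_edges(terms, edges, names, namespaces)


def write_obo_lite(dag: GoDag, path) -> None:
    with open(path, "w") as fh:
        for t in sorted(dag.terms):
            fh.write("[Term]\n")
            fh.write(f"id: {t}\n")
            if t in dag.names:
                fh.write(f"name: {dag.names[t]}\n")
            if t in dag.namespaces:
                fh.write(f"namespace: {dag.namespaces[t]}\n")
            for parent in sorted(dag.parents(t)):
                fh.write(f"is_a: {parent}\n")
            fh.write("\n")


def read_gene2term(path) -> dict[str, frozenset[str]]:
    """Two-column TSV (gene, term) -> gene -> set of directly annotated terms."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for i, raw in enumerate(fh):
            line = raw.rstrip("\n")
            if not line or (i == 0 and line.lower().startswith("gene")):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"gene2term line {i + 1}: expected 2 columns")
            out.setdefault(normalize_gene_id(parts[0]), set()).add(parts[1])
    return {g: frozenset(ts) for g, ts in out.items()}


def write_gene2term(annotations: dict[str, frozenset[str] | set[str]], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tterm\n")
        for g in sorted(annotations):
            for t in sorted(annotations[g]):
                fh.write(f"{g}\t{t}\n")


def _canonical_edges(graph: nx.Graph):
    for a, b, data in graph.edges(data=True):
        a, b = (a, b) if a <= b else (b, a)
        yield a, b, data


def write_network(graph: nx.Graph, path, dialect: str = "edge_table") -> None:
    """Export an undirected co-expression graph.

    ``sif`` writes one "A <tab> co <tab> B" line per edge; ``edge_table``
    writes source/target/r rows with r at >= 6 significant digits.  A
    companion node-attribute table (<stem>.nodes.tsv with node, role,
    direction) is always written next to the edge file.
    """
    if dialect not in ("sif", "edge_table"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    edges = sorted(_canonical_edges(graph))
    with open(path, "w") as fh:
        if dialect == "sif":
            for a, b, _ in edges:
                fh.write(f"{a}\tco\t{b}\n")
        else:
            fh.write("source\ttarget\tr\n")
            for a, b, data in edges:
                fh.write(f"{a}\t{b}\t{data.get('r', float('nan')):.6g}\n")
    node_path = path.with_suffix(path.suffix + ".nodes.tsv")
    with open(node_path, "w") as fh:
        fh.write("node\trole\tdirection\n")
        for n in sorted(graph.nodes):
            attrs = graph.nodes[n]
            fh.write(f"{n}\t{attrs.get('role', 'prey')}\t{attrs.get('direction', 'none')}\n")


def read_edge_table(path) -> nx.Graph:
    g = nx.Graph()
    df = pd.read_csv(path, sep="\t")
    for _, row in df.iterrows():
        g.add_edge(
            normalize_gene_id(row["source"]),
            normalize_gene_id(row["target"]),
            r=float(row["r"]),
        )
    node_path = Path(path).with_suffix(Path(path).suffix + ".nodes.tsv")
    if node_path.exists():
        nodes = pd.read_csv(node_path, sep="\t")
        for _, row in nodes.iterrows():
            n = normalize_gene_id(row["node"])
            if n not in g:
                g.add_node(n)
            g.nodes[n]["role"] = row["role"]
            g.nodes[n]["direction"] = row["direction"]
    return g
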