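"""Bipartite gene↔term networks built from enrichment results.

The network has one node per enriched term and one per member gene, and one
edge per (term, member gene) pair; gene degree > 1 flags multifunctional
genes.  Edge lists and node tables export to TSV for Cytoscape/Gephi, and a
term×condition count matrix with hierarchical clustering supports
cross-condition heatmaps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

from .enrichment import EnrichmentReport
from .exceptions import ValidationError


@dataclass
class TermNodeInfo:
    name: str
    p_value: float
    p_adjusted: float
    x: int


@dataclass
class GeneNodeInfo:
    value: float | None
    degree: int


@dataclass
class BipartiteNetwork:
    """Term nodes, gene nodes and the term→gene edges linking them.

    Edges are directed term→gene in the serialized form, but consumers may
    treat them as undirected.  Invariants: every edge endpoint exists in its
    node table, no duplicate edges, gene degree equals incident edge count.
    """

    edges: list[tuple[str, str]] = field(default_factory=list)
    term_nodes: dict[str, TermNodeInfo] = field(default_factory=dict)
    gene_nodes: dict[str, GeneNodeInfo] = field(default_factory=dict)

    def validate(self) -> None:
        seen = set()
        degrees: dict[str, int] = {g: 0 for g in self.gene_nodes}
        for src, dst in self.edges:
            if src not in self.term_nodes:
                raise ValidationError(f"edge source {src!r} missing from term nodes")
            if dst not in self.gene_nodes:
                raise ValidationError(f"edge target {dst!r} missing from gene nodes")
            if (src, dst) in seen:
                raise ValidationError(f"duplicate edge ({src}, {dst})")
            seen.add((src, dst))
            degrees[dst] += 1
        for gid, info in self.gene_nodes.items():
            if info.degree != degrees[gid]:
                raise ValidationError(f"gene {gid} degree {info.degree} != incident edges {degrees[gid]}")

    def to_networkx(self):
        """Export to a :mod:`networkx` graph with a ``bipartite`` attribute."""
        import networkx as nx

        g = nx.Graph()
        for tid, info in self.term_nodes.items():
            g.add_node(tid, bipartite="term", name=info.name, p_value=info.p_value,
                       p_adjusted=info.p_adjusted, x=info.x)
        for gid, info in self.gene_nodes.items():
            g.add_node(gid, bipartite="gene", value=info.value, degree=info.degree)
        g.add_edges_from(self.edges)
        return g


def build_bipartite_network(
    report: EnrichmentReport,
    values: Mapping[str, float] | None = None,
    significant_only: bool = True,
) -> BipartiteNetwork:
    """One edge per (term, member gene) pair of the (optionally significance-
    filtered) report; gene values attached when provided."""
    results = report.significant_results if significant_only else report.results
    if not results:
        raise ValidationError(
            "no significant term at alpha="
            f"{report.alpha:g}; loosen alpha or pass significant_only=False"
        )
    net = BipartiteNetwork()
    for r in results:
        net.term_nodes[r.term_id] = TermNodeInfo(
            name=r.term_name, p_value=r.p_value, p_adjusted=r.p_adjusted, x=r.counts.x
        )
        for gid in sorted(r.member_genes):
            if gid not in net.gene_nodes:
                val = values.get(gid) if values is not None else None
                net.gene_nodes[gid] = GeneNodeInfo(value=val, degree=0)
            net.gene_nodes[gid].degree += 1
            net.edges.append((r.term_id, gid))
    net.validate()
    return net


# ---------------------------------------------------------------------------
# Serialization

EDGES_HEADER = "Source\tTarget"
NODES_HEADER = "id\tkind\tvalue\tp_value\tp_adjusted\tdegree\tname"


def export_edges(net: BipartiteNetwork, path: str | Path) -> None:
    """Two-column edge list (header ``Source\\tTarget``) for Cytoscape/Gephi."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(EDGES_HEADER + "\n")
        for src, dst in sorted(net.edges):
            fh.write(f"{src}\t{dst}\n")


def export_nodes(net: BipartiteNetwork, path: str | Path) -> None:
    """Node table: term rows first, then gene rows, each block sorted by id.
    Missing gene values serialize as the empty string (missing ≠ zero)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(NODES_HEADER + "\n")
        for tid in sorted(net.term_nodes):
            t = net.term_nodes[tid]
            fh.write(f"{tid}\tterm\t\t{t.p_value!r}\t{t.p_adjusted!r}\t{t.x}\t{t.name}\n")
        for gid in sorted(net.gene_nodes):
            g = net.gene_nodes[gid]
            val = "" if g.value is None else repr(g.value)
            fh.write(f"{gid}\tgene\t{val}\t\t\t{g.degree}\t\n")


def import_network(edges_path: str | Path, nodes_path: str | Path) -> BipartiteNetwork:
    """Reconstruct a :class:`BipartiteNetwork` from its TSV exports."""
    net = BipartiteNetwork()
    with open(nodes_path, encoding="utf-8", newline=None) as fh:
        header = fh.readline().rstrip("\n")
        if header != NODES_HEADER:
            raise ValidationError(f"unexpected nodes header {header!r}")
        for raw in fh:
            nid, kind, value, p_value, p_adjusted, degree, name = raw.rstrip("\n").split("\t")
            if kind == "term":
                net.term_nodes[nid] = TermNodeInfo(
                    name=name, p_value=float(p_value),
                    p_adjusted=float(p_adjusted), x=int(degree),
                )
            else:
                net.gene_nodes[nid] = GeneNodeInfo(
                    value=float(value) if value else None, degree=int(degree)
                )
    with open(edges_path, encoding="utf-8", newline=None) as fh:
        header = fh.readline().rstrip("\n")
        if header != EDGES_HEADER:
            raise ValidationError(f"unexpected edges header {header!r}")
        for raw in fh:
            src, dst = raw.rstrip("\n").split("\t")
            net.edges.append((src, dst))
    net.validate()
    return net


# ---------------------------------------------------------------------------
# Term similarity


def term_jaccard(report: EnrichmentReport, significant_only: bool = True) -> pd.DataFrame:
    """Pairwise Jaccard similarity between term member-gene sets."""
    results = report.significant_results if significant_only else report.results
    if len(results) < 2:
        raise ValidationError("term_jaccard requires at least two terms")
    tids = [r.term_id for r in results]
    sets = {r.term_id: r.member_genes for r in results}
    mat = np.eye(len(tids))
    for i, a in enumerate(tids):
        for j in range(i + 1, len(tids)):
            b = tids[j]
            union = len(sets[a] | sets[b])
            mat[i, j] = mat[j, i] = len(sets[a] & sets[b]) / union if union else 0.0
    return pd.DataFrame(mat, index=tids, columns=tids)


# ---------------------------------------------------------------------------
# Term × condition matrix


@dataclass
class TermConditionMatrix:
    """Member-gene counts of enriched terms (rows) across conditions (cols),
    with row/column orders from agglomerative hierarchical clustering on
    log10(count + 1) (Euclidean distance, average linkage)."""

    row_terms: list[str]
    col_conditions: list[str]
    cells: np.ndarray  # int counts, shape (rows, cols), in input (sorted) order
    row_order: list[int]
    col_order: list[int]
    term_names: dict[str, str] = field(default_factory=dict)
    row_linkage: np.ndarray | None = None
    col_linkage: np.ndarray | None = None

    def to_frame(self, clustered: bool = True) -> pd.DataFrame:
        df = pd.DataFrame(self.cells, index=self.row_terms, columns=self.col_conditions)
        if clustered:
            df = df.iloc[self.row_order, self.col_order]
        return df

    def export_tsv(self, path: str | Path, clustered: bool = True) -> None:
        self.to_frame(clustered).to_csv(path, sep="\t")


def _cluster_order(values: np.ndarray) -> tuple[list[int], np.ndarray | None]:
    n = values.shape[0]
    if n < 2:
        return list(range(n)), None
    link = linkage(pdist(values, metric="euclidean"), method="average")
    return leaves_list(link).tolist(), link


def build_term_condition_matrix(
    reports: Mapping[str, EnrichmentReport], min_genes: int = 1
) -> TermConditionMatrix:
    """Cross-condition count matrix of significantly enriched terms.

    Rows are the union of significant terms across conditions whose maximum
    cell reaches ``min_genes``; each cell is that term's member-gene count x
    in the condition (0 where the term is not enriched there).  Rows are
    pre-sorted lexicographically (and columns taken in sorted label order) so
    the clustered ordering does not depend on input order.
    """
    if not reports:
        raise ValidationError("at least one condition is required")
    conditions = sorted(reports)
    counts: dict[str, dict[str, int]] = {}
    names: dict[str, str] = {}
    for cond in conditions:
        for r in reports[cond].significant_results:
            counts.setdefault(r.term_id, {})[cond] = r.counts.x
            if r.term_name:
                names[r.term_id] = r.term_name
    terms = sorted(t for t, row in counts.items() if max(row.values()) >= min_genes)
    if not terms:
        raise ValidationError(
            f"no enriched term reaches min_genes={min_genes} in any condition"
        )
    cells = np.array(
        [[counts[t].get(c, 0) for c in conditions] for t in terms], dtype=int
    )
    logged = np.log10(cells + 1.0)
    row_order, row_link = _cluster_order(logged)
    col_order, col_link = _cluster_order(logged.T)
    return TermConditionMatrix(
        row_terms=terms,
        col_conditions=conditions,
        cells=cells,
        row_order=row_order,
        col_order=col_order,
        term_names=names,
        row_linkage=row_link,
        col_linkage=col_link,
    )
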