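"""Static visualizations of enrichment results: annotated bipartite networks
(circular or seeded force-directed layout with a −log10(p) bar panel), chord
diagrams, UpSet plots of term-membership intersections, and clustered
term×condition heatmaps.

All renderers are pure functions of (data, config): with a fixed seed the
emitted SVG is byte-identical across runs.  Each plot writes its plotted
table as a TSV sidecar (``<image>.tsv``) so every quantitative channel can be
checked by machine, and bar geometry in the network panel carries stable SVG
ids plus two calibration lines so bar lengths can be read back in data units.
"""

from __future__ import annotations

import math
import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from matplotlib import colormaps
from matplotlib.colors import Normalize, TwoSlopeNorm
from matplotlib.patches import PathPatch, Wedge
from matplotlib.path import Path as MplPath
from scipy.cluster.hierarchy import dendrogram

from .enrichment import EnrichmentReport
from .exceptions import ValidationError
from .network import BipartiteNetwork
from .term_index import TermGeneIndex  # noqa: F401  (re-exported for type hints)

_SVG_HASHSALT = "oranet"


@dataclass
class PlotConfig:
    """Rendering options shared by all plot types."""

    fmt: str = "svg"
    dpi: int = 150
    diverging_cmap: str = "RdBu_r"
    sequential_cmap: str = "viridis"
    ref_p: float = 0.05
    seed: int = 0
    max_chord_sectors: int = 30

    def __post_init__(self) -> None:
        if self.fmt not in ("png", "svg"):
            raise ValidationError(f"unsupported output format {self.fmt!r}")
        if self.dpi < 72:
            raise ValidationError("dpi must be >= 72")
        if not 0 < self.ref_p < 1:
            raise ValidationError("reference p-value must lie in (0, 1)")


def _save(fig, path: str | Path, config: PlotConfig) -> None:
    path = Path(path)
    with plt.rc_context({"svg.hashsalt": _SVG_HASHSALT}):
        if path.suffix.lower() == ".svg":
            fig.savefig(path, format="svg", metadata={"Date": None}, dpi=config.dpi)
        else:
            fig.savefig(path, dpi=config.dpi)
    plt.close(fig)


def _gene_norm_and_cmap(values: Mapping[str, float] | None, config: PlotConfig):
    cmap = colormaps[config.diverging_cmap]
    if not values:
        return None, cmap
    vmax = max(abs(v) for v in values.values())
    vmax = vmax if vmax > 0 else 1.0
    return TwoSlopeNorm(vmin=-vmax, vcenter=0.0, vmax=vmax), cmap


# ---------------------------------------------------------------------------
# Network + bar panel


def render_network(
    net: BipartiteNetwork,
    report: EnrichmentReport,
    config: PlotConfig,
    layout: str = "circular",
    path: str | Path = "network.svg",
) -> Path:
    """Bipartite network plus a −log10(p) bar panel.

    Gene nodes are colored by their user-supplied value on a zero-centered
    diverging map; each term's bar is annotated with its member count, and
    reference lines mark −log10(0.05) (black) and −log10(alpha) (blue).  The
    ``random`` layout is a force-directed embedding seeded from the config.
    """
    import networkx as nx

    if not net.edges:
        raise ValidationError("cannot render an empty network")
    if layout not in ("circular", "random"):
        raise ValidationError(f"unknown layout {layout!r}")

    g = net.to_networkx()
    pos = nx.circular_layout(g) if layout == "circular" else nx.spring_layout(g, seed=config.seed)

    terms = [r for r in report.results if r.term_id in net.term_nodes]
    fig, (ax_net, ax_bar) = plt.subplots(
        1, 2, figsize=(13, 7), gridspec_kw={"width_ratios": [1.6, 1.0]}
    )

    values = {
        gid: info.value for gid, info in net.gene_nodes.items() if info.value is not None
    }
    norm, cmap = _gene_norm_and_cmap(values, config)

    term_cmap = colormaps["tab20"]
    term_color = {r.term_id: term_cmap(i % 20) for i, r in enumerate(terms)}

    nx.draw_networkx_edges(g, pos, ax=ax_net, alpha=0.4, width=0.8)
    term_list = sorted(net.term_nodes)
    nx.draw_networkx_nodes(
        g, pos, nodelist=term_list, node_shape="s", node_size=350,
        node_color=[term_color.get(t, (0.7, 0.7, 0.7, 1.0)) for t in term_list],
        ax=ax_net, linewidths=0.5, edgecolors="black",
    )
    gene_list = sorted(net.gene_nodes)
    if norm is not None:
        gene_colors = [
            cmap(norm(values[gid])) if gid in values else (0.85, 0.85, 0.85, 1.0)
            for gid in gene_list
        ]
    else:
        gene_colors = ["#cccccc"] * len(gene_list)
    nx.draw_networkx_nodes(
        g, pos, nodelist=gene_list, node_shape="o", node_size=160,
        node_color=gene_colors, ax=ax_net, linewidths=0.3, edgecolors="black",
    )
    nx.draw_networkx_labels(g, pos, ax=ax_net, font_size=5)
    ax_net.set_axis_off()
    if norm is not None:
        sm = plt.cm.ScalarMappable(norm=norm, cmap=cmap)
        fig.colorbar(sm, ax=ax_net, shrink=0.5, label="value (e.g. log2 fold-change)")

    heights = [-math.log10(r.p_value) for r in terms]
    ys = np.arange(len(terms))[::-1]
    bars = ax_bar.barh(
        ys, heights, color=[term_color[r.term_id] for r in terms], height=0.7
    )
    for i, (rect, r) in enumerate(zip(bars, terms)):
        rect.set_gid(f"bar-{i:04d}")
        ax_bar.text(
            rect.get_width(), rect.get_y() + rect.get_height() / 2,
            f" {r.counts.x}", va="center", fontsize=6,
        )
    ax_bar.set_yticks(ys)
    ax_bar.set_yticklabels([r.term_id for r in terms], fontsize=6)
    line = ax_bar.axvline(-math.log10(config.ref_p), color="black", lw=1.0)
    line.set_gid("refline-fixed")
    line = ax_bar.axvline(-math.log10(report.alpha), color="tab:blue", lw=1.0, ls="--")
    line.set_gid("refline-alpha")
    cal0 = ax_bar.axvline(0.0, color="0.8", lw=0.6)
    cal0.set_gid("cal-x0")
    cal1 = ax_bar.axvline(1.0, color="0.9", lw=0.6, ls=":")
    cal1.set_gid("cal-x1")
    ax_bar.set_xlabel(r"$-\log_{10}(p)$")
    fig.tight_layout()

    path = Path(path)
    _write_sidecar(
        path,
        header=["bar_index", "term_id", "name", "x", "p_value", "neglog10_p"],
        rows=[
            [i, r.term_id, r.term_name, r.counts.x, repr(r.p_value), repr(-math.log10(r.p_value))]
            for i, r in enumerate(terms)
        ],
    )
    _save(fig, path, config)
    return path


_NUM_RE = re.compile(r"[-+]?\d*\.?\d+(?:[eE][-+]?\d+)?")


def _element_xs(elem: ET.Element) -> list[float]:
    for node in elem.iter():
        d = node.attrib.get("d")
        if d:
            nums = [float(t) for t in _NUM_RE.findall(d)]
            return nums[0::2]
    raise ValidationError("no path geometry under SVG element")


def svg_bar_values(svg_path: str | Path) -> list[float]:
    """Read bar lengths back from a :func:`render_network` SVG, in data units.

    Uses the two calibration lines (x = 0 and x = 1 in data coordinates) to
    convert pixel geometry back to −log10(p) values; returns the values in
    bar-index order, matching the sidecar TSV rows.
    """
    tree = ET.parse(svg_path)
    by_id: dict[str, ET.Element] = {}
    for elem in tree.getroot().iter():
        eid = elem.attrib.get("id")
        if eid:
            by_id[eid] = elem
    try:
        x0 = float(np.mean(_element_xs(by_id["cal-x0"])))
        x1 = float(np.mean(_element_xs(by_id["cal-x1"])))
    except KeyError:
        raise ValidationError("calibration lines missing from SVG") from None
    scale = x1 - x0
    out: list[tuple[int, float]] = []
    for eid, elem in by_id.items():
        if eid.startswith("bar-"):
            xs = _element_xs(elem)
            out.append((int(eid[4:]), (max(xs) - x0) / scale))
    return [v for _, v in sorted(out)]


# ---------------------------------------------------------------------------
# Chord diagram


def render_chord(
    net: BipartiteNetwork,
    report: EnrichmentReport,
    config: PlotConfig,
    path: str | Path = "chord.svg",
) -> Path:
    """Chord diagram: one sector per term and per gene, one ribbon per edge.

    Terms are ordered by p-value ascending, genes by value descending (genes
    without values last); when values are present an outer strip beside each
    gene sector encodes them on the diverging map, otherwise the strip is
    omitted.  Sector width is proportional to node degree.
    """
    n_sectors = len(net.term_nodes) + len(net.gene_nodes)
    if n_sectors > config.max_chord_sectors:
        raise ValidationError(
            f"{n_sectors} sectors exceed the legibility limit of "
            f"{config.max_chord_sectors}; restrict to significant terms or a top-n subset"
        )
    if not net.edges:
        raise ValidationError("cannot render an empty network")

    terms = [r.term_id for r in report.results if r.term_id in net.term_nodes]
    values = {g: i.value for g, i in net.gene_nodes.items() if i.value is not None}

    def gene_sort_key(gid: str):
        v = values.get(gid)
        return (0, -v, gid) if v is not None else (1, 0.0, gid)

    genes = sorted(net.gene_nodes, key=gene_sort_key)
    order = terms + genes
    degree = {t: net.term_nodes[t].x for t in terms}
    degree.update({g: net.gene_nodes[g].degree for g in genes})

    pad = 2.0  # degrees between sectors
    total_units = sum(degree[n] for n in order)
    avail = 360.0 - pad * len(order)
    spans: dict[str, tuple[float, float]] = {}
    angle = 0.0
    for node in order:
        width = avail * degree[node] / total_units
        spans[node] = (angle, angle + width)
        angle += width + pad

    # Slot assignment: each incident edge occupies an equal slice of its
    # node's sector, in the deterministic order of the opposite endpoint.
    slot_counter: dict[str, int] = {n: 0 for n in order}
    pos_index = {n: i for i, n in enumerate(order)}

    def next_slot(node: str) -> float:
        a0, a1 = spans[node]
        d = degree[node]
        i = slot_counter[node]
        slot_counter[node] += 1
        return a0 + (a1 - a0) * (i + 0.5) / d

    term_cmap = colormaps["tab20"]
    term_color = {t: term_cmap(i % 20) for i, t in enumerate(terms)}
    norm, cmap = _gene_norm_and_cmap(values, config)

    fig, ax = plt.subplots(figsize=(8, 8))
    ax.set_xlim(-1.45, 1.45)
    ax.set_ylim(-1.45, 1.45)
    ax.set_aspect("equal")
    ax.set_axis_off()

    for node in order:
        a0, a1 = spans[node]
        is_term = node in net.term_nodes
        color = term_color[node] if is_term else (0.75, 0.75, 0.75, 1.0)
        ax.add_patch(Wedge((0, 0), 1.08, a0, a1, width=0.08, facecolor=color,
                           edgecolor="white", lw=0.3))
        if not is_term and norm is not None and node in values:
            ax.add_patch(Wedge((0, 0), 1.16, a0, a1, width=0.05,
                               facecolor=cmap(norm(values[node])),
                               edgecolor="white", lw=0.3))
        mid = math.radians((a0 + a1) / 2)
        ax.text(1.22 * math.cos(mid), 1.22 * math.sin(mid), node,
                ha="center", va="center", fontsize=5,
                rotation=(a0 + a1) / 2 if math.cos(mid) >= 0 else (a0 + a1) / 2 + 180,
                rotation_mode="anchor")

    edges = sorted(net.edges, key=lambda e: (pos_index[e[0]], pos_index[e[1]]))
    for term_id, gene_id in edges:
        a = math.radians(next_slot(term_id))
        b = math.radians(next_slot(gene_id))
        p0 = (math.cos(a), math.sin(a))
        p1 = (math.cos(b), math.sin(b))
        curve = MplPath(
            [p0, (0.0, 0.0), p1],
            [MplPath.MOVETO, MplPath.CURVE3, MplPath.CURVE3],
        )
        ax.add_patch(PathPatch(curve, fill=False, lw=1.4,
                               edgecolor=term_color[term_id], alpha=0.6))

    path = Path(path)
    _write_sidecar(
        path,
        header=["id", "kind", "start_deg", "end_deg", "degree", "value"],
        rows=[
            [
                node,
                "term" if node in net.term_nodes else "gene",
                f"{spans[node][0]:.4f}",
                f"{spans[node][1]:.4f}",
                degree[node],
                "" if node not in values else repr(values[node]),
            ]
            for node in order
        ],
    )
    _save(fig, path, config)
    return path


# ---------------------------------------------------------------------------
# UpSet plot


def exclusive_intersections(
    sets: Mapping[str, Iterable[str]]
) -> list[tuple[tuple[str, ...], int]]:
    """Exclusive membership patterns: each element is counted once, under the
    exact combination of sets containing it.

    Patterns are ordered by count descending, ties broken lexicographically
    on the pattern tuple; set names inside a pattern follow the size-
    descending (then lexicographic) set order used for plotting.
    """
    materialized = {name: set(s) for name, s in sets.items()}
    set_order = sorted(materialized, key=lambda n: (-len(materialized[n]), n))
    rank = {n: i for i, n in enumerate(set_order)}
    patterns: dict[tuple[str, ...], int] = {}
    for element in set().union(*materialized.values()):
        pat = tuple(sorted((n for n in materialized if element in materialized[n]),
                           key=lambda n: rank[n]))
        patterns[pat] = patterns.get(pat, 0) + 1
    return sorted(patterns.items(), key=lambda kv: (-kv[1], kv[0]))


def _sets_from(data) -> dict[str, set[str]]:
    if isinstance(data, BipartiteNetwork):
        out: dict[str, set[str]] = {t: set() for t in data.term_nodes}
        for src, dst in data.edges:
            out[src].add(dst)
        return out
    if isinstance(data, EnrichmentReport):
        return {r.term_id: set(r.member_genes) for r in data.significant_results}
    return {name: set(s) for name, s in data.items()}


def render_upset(
    data,
    config: PlotConfig,
    path: str | Path = "upset.svg",
) -> Path:
    """UpSet plot of exclusive intersections between term member-gene sets.

    Accepts a :class:`BipartiteNetwork`, an :class:`EnrichmentReport`
    (significant terms), or a mapping of set name → members.  Sets are
    ordered by size descending; intersection bars by exclusive size
    descending with lexicographic tie-break.
    """
    sets = _sets_from(data)
    if len(sets) < 2:
        raise ValidationError("an UpSet plot requires at least two sets")
    inter = exclusive_intersections(sets)
    set_order = sorted(sets, key=lambda n: (-len(sets[n]), n))

    fig = plt.figure(figsize=(max(6, 0.45 * len(inter) + 3), 6))
    gs = fig.add_gridspec(2, 2, width_ratios=[1, 3], height_ratios=[2, 1.4],
                          hspace=0.05, wspace=0.05)
    ax_bars = fig.add_subplot(gs[0, 1])
    ax_mat = fig.add_subplot(gs[1, 1], sharex=ax_bars)
    ax_sets = fig.add_subplot(gs[1, 0], sharey=ax_mat)

    xs = np.arange(len(inter))
    counts = [c for _, c in inter]
    ax_bars.bar(xs, counts, color="0.2", width=0.6)
    for x, c in zip(xs, counts):
        ax_bars.text(x, c, str(c), ha="center", va="bottom", fontsize=7)
    ax_bars.set_ylabel("exclusive intersection size")
    ax_bars.tick_params(labelbottom=False)

    n_sets = len(set_order)
    ys = {name: n_sets - 1 - i for i, name in enumerate(set_order)}
    for x, (pat, _) in enumerate(inter):
        member_ys = [ys[n] for n in pat]
        ax_mat.scatter([x] * n_sets, list(range(n_sets)), s=30, color="0.85", zorder=1)
        ax_mat.scatter([x] * len(member_ys), member_ys, s=30, color="0.2", zorder=2)
        if len(member_ys) > 1:
            ax_mat.plot([x, x], [min(member_ys), max(member_ys)], color="0.2", lw=1.5)
    ax_mat.set_yticks([ys[n] for n in set_order])
    ax_mat.set_yticklabels(set_order, fontsize=7)
    ax_mat.set_xticks(xs)
    ax_mat.tick_params(labelbottom=False)
    ax_mat.set_ylim(-0.5, n_sets - 0.5)

    ax_sets.barh([ys[n] for n in set_order], [len(sets[n]) for n in set_order],
                 color="0.5", height=0.6)
    ax_sets.invert_xaxis()
    ax_sets.set_xlabel("set size")
    ax_sets.tick_params(labelleft=False)

    path = Path(path)
    _write_sidecar(
        path,
        header=["sets", "exclusive_count"],
        rows=[["&".join(pat), c] for pat, c in inter],
    )
    _save(fig, path, config)
    return path


# ---------------------------------------------------------------------------
# Clustered heatmap


def heatmap_transform(count) -> np.ndarray:
    """The heatmap color transform: log10(count + 1), so empty cells map to 0."""
    return np.log10(np.asarray(count, dtype=float) + 1.0)


def render_heatmap(matrix, config: PlotConfig, path: str | Path = "heatmap.svg") -> Path:
    """Clustered term×condition heatmap; cell color = log10(count + 1).

    Rows/columns appear in the hierarchical-clustering order carried by the
    matrix, with dendrograms drawn whenever a dimension has at least two
    entries.  An all-zero matrix is rejected.
    """
    cells = np.asarray(matrix.cells)
    if not cells.any():
        raise ValidationError("all-zero matrix: nothing to plot")
    data = heatmap_transform(cells)[np.ix_(matrix.row_order, matrix.col_order)]
    row_labels = [matrix.row_terms[i] for i in matrix.row_order]
    col_labels = [matrix.col_conditions[j] for j in matrix.col_order]

    fig = plt.figure(figsize=(max(4, 0.6 * len(col_labels) + 3),
                              max(4, 0.25 * len(row_labels) + 2)))
    gs = fig.add_gridspec(2, 2, width_ratios=[0.18, 1], height_ratios=[0.18, 1],
                          hspace=0.02, wspace=0.02)
    ax = fig.add_subplot(gs[1, 1])
    im = ax.imshow(data, aspect="auto", cmap=config.sequential_cmap,
                   norm=Normalize(vmin=0.0))
    ax.set_xticks(range(len(col_labels)))
    ax.set_xticklabels(col_labels, rotation=90, fontsize=7)
    ax.set_yticks(range(len(row_labels)))
    ax.set_yticklabels(row_labels, fontsize=6)
    ax.yaxis.tick_right()
    fig.colorbar(im, ax=ax, shrink=0.6, pad=0.15, label="log10(count + 1)")

    if matrix.row_linkage is not None:
        ax_r = fig.add_subplot(gs[1, 0])
        dendrogram(matrix.row_linkage, orientation="left", ax=ax_r, no_labels=True,
                   color_threshold=-1, above_threshold_color="0.3")
        ax_r.invert_yaxis()
        ax_r.set_axis_off()
    if matrix.col_linkage is not None:
        ax_c = fig.add_subplot(gs[0, 1])
        dendrogram(matrix.col_linkage, orientation="top", ax=ax_c, no_labels=True,
                   color_threshold=-1, above_threshold_color="0.3")
        ax_c.set_axis_off()

    path = Path(path)
    _write_sidecar(
        path,
        header=["term_id"] + col_labels,
        rows=[[row_labels[i]] + [repr(float(v)) for v in data[i]] for i in range(len(row_labels))],
    )
    _save(fig, path, config)
    return path


# ---------------------------------------------------------------------------


def _write_sidecar(image_path: Path, header: Sequence, rows: Iterable[Sequence]) -> None:
    sidecar = image_path.with_suffix(image_path.suffix + ".tsv")
    with open(sidecar, "w", encoding="utf-8") as fh:
        fh.write("\t".join(str(h) for h in header) + "\n")
        for row in rows:
            fh.write("\t".join(str(c) for c in row) + "\n")
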