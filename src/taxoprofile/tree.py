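"""Presence-annotated taxonomy trees with combination-coded pie charts.

The tree topology is the reference taxonomy's, never inferred from the hit
sequences: the union of lineages of every organism carrying at least one of
the (up to three) proteins. Each organism contributes a combination code — a
bitmask over the configured protein order — and every node accumulates the
per-code organism counts of its subtree, so pie charts can show which
protein combinations occur where and how many organisms they cover.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Mapping, Sequence

import pandas as pd

from .qc_filter import ConfigurationError
from .taxonomy import TaxonomyDB

logger = logging.getLogger(__name__)

__all__ = [
    "combo_code",
    "combo_label",
    "AnnotatedTaxTree",
    "TreeNode",
    "annotate_tree",
    "PruneConfig",
    "prune_tree",
    "TreeStyle",
    "render_tree",
    "write_newick",
    "write_counts_tsv",
]


def combo_code(flags: Sequence[bool]) -> int | None:
    """Bitmask code of a presence-flag vector (protein k ↔ bit k).

    Returns ``None`` for an all-false vector — the organism is simply not on
    the tree. More than three flags is an error: with p proteins the codes
    run 1 .. 2^p − 1, and seven categories (p = 3) is the ceiling a pie
    chart's color coding stays readable at.
    """
    if not 1 <= len(flags) <= 3:
        raise ValueError(f"expected 1..3 presence flags, got {len(flags)}")
    code = sum(1 << k for k, present in enumerate(flags) if present)
    return code or None


def combo_label(code: int, proteins: Sequence[str]) -> str:
    """Human-readable label of a code, e.g. ``protA+protC``."""
    return "+".join(p for k, p in enumerate(proteins) if code >> k & 1)


@dataclass
class TreeNode:
    """One tree node: taxonomy identity plus aggregated combination counts."""

    taxid: int
    scientific_name: str
    rank: str
    children: list[int] = field(default_factory=list)
    #: this node's own organism code (None unless the node is an organism)
    own_code: int | None = None
    #: aggregated over the subtree, own organism included
    counts: Counter = field(default_factory=Counter)

    @property
    def total_organisms(self) -> int:
        return sum(self.counts.values())

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class AnnotatedTaxTree:
    """Taxonomy subtree annotated with per-combination organism counts."""

    root_taxid: int
    nodes: dict[int, TreeNode]
    proteins: list[str]

    def node(self, taxid: int) -> TreeNode:
        return self.nodes[taxid]

    @property
    def root(self) -> TreeNode:
        return self.nodes[self.root_taxid]

    def walk(self, taxid: int | None = None):
        """Depth-first (pre-order) iteration over nodes, children by taxid."""
        taxid = self.root_taxid if taxid is None else taxid
        node = self.nodes[taxid]
        yield node
        for child in sorted(node.children):
            yield from self.walk(child)

    def codes_in_use(self) -> set[int]:
        return {c for n in self.nodes.values() for c in n.counts if n.counts[c]}


def annotate_tree(
    db: TaxonomyDB, presence: Mapping[str, set[int]]
) -> AnnotatedTaxTree:
    """Map per-protein organism sets onto the taxonomy.

    ``presence`` maps 1–3 protein names (order defines the bit positions) to
    species-collapsed organism taxid sets. The tree is the union of lineages
    of organisms present for at least one protein; counts are aggregated
    bottom-up so every internal node's counts equal the sum over its
    children (plus its own organism, if it is one). Organisms missing from
    the taxonomy are attached directly under the root with a warning.
    """
    proteins = list(presence)
    if not 1 <= len(proteins) <= 3:
        raise ValueError(f"expected 1..3 proteins, got {len(proteins)}")
    codes: dict[int, int] = {}
    for organism in set().union(*presence.values()):
        code = combo_code([organism in presence[p] for p in proteins])
        if code is not None:
            codes[organism] = code
    if not codes:
        raise ValueError("no hits to map: every presence set is empty")

    root_taxid = db.root.taxid
    nodes: dict[int, TreeNode] = {}

    def ensure(taxid: int, name: str, rank: str) -> TreeNode:
        if taxid not in nodes:
            nodes[taxid] = TreeNode(taxid=taxid, scientific_name=name, rank=rank)
        return nodes[taxid]

    ensure(root_taxid, db.root.scientific_name, db.root.rank)
    for organism, code in sorted(codes.items()):
        if organism in db:
            lineage = db.lineage(organism)
            for parent, child in zip(lineage, lineage[1:]):
                ensure(parent.taxid, parent.scientific_name, parent.rank)
                ensure(child.taxid, child.scientific_name, child.rank)
                if child.taxid not in nodes[parent.taxid].children:
                    nodes[parent.taxid].children.append(child.taxid)
            nodes[organism].own_code = code
        else:
            logger.warning(
                "organism taxid %d absent from taxonomy; attaching to root",
                organism,
            )
            stray = ensure(organism, f"unknown taxid {organism}", "no rank")
            stray.own_code = code
            if organism not in nodes[root_taxid].children:
                nodes[root_taxid].children.append(organism)

    tree = AnnotatedTaxTree(root_taxid=root_taxid, nodes=nodes, proteins=proteins)
    _aggregate(tree, root_taxid)
    return tree


def _aggregate(tree: AnnotatedTaxTree, taxid: int) -> Counter:
    node = tree.nodes[taxid]
    counts: Counter = Counter()
    if node.own_code is not None:
        counts[node.own_code] += 1
    for child in node.children:
        counts.update(_aggregate(tree, child))
    node.counts = counts
    return counts


# -- pruning ---------------------------------------------------------------

@dataclass(frozen=True)
class PruneConfig:
    """Parsed tree_to_prune.txt: taxa to collapse, optional subtree partition."""

    collapse: tuple = ()  # taxids or scientific names
    partition: int | str | None = None

    @classmethod
    def from_file(cls, source: str | Path | IO[str]) -> "PruneConfig":
        """One taxid-or-name per line; an optional ``partition:`` line."""
        if isinstance(source, (str, Path)):
            text = Path(source).read_text()
        else:
            text = source.read()
        collapse: list = []
        partition: int | str | None = None
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.lower().startswith("partition:"):
                value = line.partition(":")[2].strip()
                partition = int(value) if value.isdigit() else value
            else:
                collapse.append(int(line) if line.isdigit() else line)
        return cls(collapse=tuple(collapse), partition=partition)


def _resolve_in_tree(tree: AnnotatedTaxTree, entry: int | str) -> int | None:
    if isinstance(entry, int):
        return entry if entry in tree.nodes else None
    for node in tree.nodes.values():
        if node.scientific_name == entry:
            return node.taxid
    return None


def prune_tree(tree: AnnotatedTaxTree, config: PruneConfig) -> AnnotatedTaxTree:
    """Collapse named taxa into terminal nodes and/or restrict to a partition.

    Collapsed nodes keep their aggregated counts, so count conservation
    still holds. The partition re-roots the result at the named taxon (as
    when rendering one superkingdom at a time). Entries that resolve
    nowhere are warned about and skipped; pruning away everything is an
    error. An empty config returns an equivalent copy.
    """
    import copy

    root_taxid = tree.root_taxid
    if config.partition is not None:
        resolved = _resolve_in_tree(tree, config.partition)
        if resolved is None:
            raise ValueError(f"partition {config.partition!r} not in tree")
        root_taxid = resolved

    keep: dict[int, TreeNode] = {}
    collapse_ids = set()
    for entry in config.collapse:
        resolved = _resolve_in_tree(tree, entry)
        if resolved is None:
            logger.warning("prune entry %r not in tree; skipped", entry)
        else:
            collapse_ids.add(resolved)

    def copy_subtree(taxid: int):
        node = copy.deepcopy(tree.nodes[taxid])
        if taxid in collapse_ids:
            node.children = []
        keep[taxid] = node
        for child in node.children:
            copy_subtree(child)

    copy_subtree(root_taxid)
    pruned = AnnotatedTaxTree(
        root_taxid=root_taxid, nodes=keep, proteins=list(tree.proteins)
    )
    if pruned.root.total_organisms == 0:
        raise ValueError("pruning removed every organism from the tree")
    return pruned


# -- rendering -------------------------------------------------------------

@dataclass(frozen=True)
class TreeStyle:
    """Rendering options: protein-order colors, pie radius clamps, suppression.

    ``colors`` must have 2^p − 1 entries for p proteins (7 at p = 3), one per
    combination code in ascending code order. Pie radius grows with the
    square root of the organism count (area ∝ organisms), clamped to the
    ``radius_min``/``radius_max`` display range. Nodes with fewer organisms
    than ``min_total`` get no pie.
    """

    colors: tuple[str, ...]
    radius_min: float = 4.0
    radius_max: float = 40.0
    min_total: int = 1


def pie_fractions(node: TreeNode) -> list[tuple[int, float]]:
    """(code, angular fraction) pairs; fractions sum to exactly 1."""
    total = node.total_organisms
    return [
        (code, node.counts[code] / total)
        for code in sorted(node.counts)
        if node.counts[code]
    ]


def pie_radius(total: int, style: TreeStyle, max_total: int) -> float:
    """Radius ∝ sqrt(total), scaled so the largest node hits radius_max."""
    if total < 1:
        return 0.0
    scale = style.radius_max / math.sqrt(max(max_total, 1))
    return min(style.radius_max, max(style.radius_min, scale * math.sqrt(total)))


def _leaf_positions(tree: AnnotatedTaxTree):
    """Rectangular layout: leaves on integer y, internals centered; x = depth."""
    pos: dict[int, tuple[float, float]] = {}
    next_y = [0.0]

    def place(taxid: int, depth: int) -> float:
        node = tree.nodes[taxid]
        if node.is_leaf:
            y = next_y[0]
            next_y[0] += 1.0
        else:
            ys = [place(c, depth + 1) for c in sorted(node.children)]
            y = (min(ys) + max(ys)) / 2
        pos[taxid] = (float(depth), y)
        return y

    place(tree.root_taxid, 0)
    return pos


def render_tree(
    tree: AnnotatedTaxTree,
    style: TreeStyle,
    image_path: str | Path | None = None,
    newick_path: str | Path | None = None,
    counts_path: str | Path | None = None,
    title: str | None = None,
):
    """Render the annotated tree: pie-chart graphic, Newick text, counts TSV."""
    expected = 2 ** len(tree.proteins) - 1
    if len(style.colors) != expected:
        raise ConfigurationError(
            f"{len(tree.proteins)} protein(s) need {expected} color(s), "
            f"got {len(style.colors)}"
        )
    if newick_path is not None:
        with open(newick_path, "w") as fh:
            fh.write(write_newick(tree))
    if counts_path is not None:
        write_counts_tsv(tree, counts_path)
    if image_path is None:
        return

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Wedge

    pos = _leaf_positions(tree)
    n_leaves = sum(1 for n in tree.nodes.values() if n.is_leaf)
    depth = max(x for x, _ in pos.values())
    fig, ax = plt.subplots(figsize=(max(6.0, 1.6 * depth + 4), max(4.0, 0.3 * n_leaves + 2)))
    for node in tree.walk():
        x, y = pos[node.taxid]
        for child in sorted(node.children):
            cx, cy = pos[child]
            ax.plot([x, x, cx], [y, cy, cy], color="#888888", linewidth=0.8,
                    zorder=1)
    max_total = max(n.total_organisms for n in tree.nodes.values())
    # pie radius is specified in display points; convert to data units
    fig.canvas.draw()
    pt_per_data = ax.transData.transform((1, 0))[0] - ax.transData.transform((0, 0))[0]
    for node in tree.walk():
        x, y = pos[node.taxid]
        total = node.total_organisms
        if total >= style.min_total and total > 0:
            r = pie_radius(total, style, max_total) / max(pt_per_data, 1e-9)
            theta = 90.0
            for code, frac in pie_fractions(node):
                span = 360.0 * frac
                ax.add_patch(
                    Wedge((x, y), r, theta - span, theta,
                          facecolor=style.colors[code - 1],
                          edgecolor="white", linewidth=0.3, zorder=3)
                )
                theta -= span
        label = node.scientific_name
        if node.is_leaf:
            ax.annotate(f" {label}", (x, y), fontsize=7, va="center",
                        xytext=(6, 0), textcoords="offset points")
    handles = [
        plt.Rectangle((0, 0), 1, 1, facecolor=style.colors[code - 1])
        for code in range(1, expected + 1)
    ]
    labels = [combo_label(code, tree.proteins) for code in range(1, expected + 1)]
    ax.legend(handles, labels, loc="lower left", fontsize=7, title="presence")
    ax.set_axis_off()
    if title:
        ax.set_title(title)
    fig.savefig(image_path, metadata={"Date": None}, bbox_inches="tight")
    plt.close(fig)


def _newick_name(node: TreeNode) -> str:
    name = node.scientific_name.replace(" ", "_")
    for ch in "();:,'[]":
        name = name.replace(ch, "_")
    return f"{name}_{node.taxid}"


def write_newick(tree: AnnotatedTaxTree) -> str:
    """Newick text; leaf labels are scientific names with taxids appended."""

    def fmt(taxid: int) -> str:
        node = tree.nodes[taxid]
        if node.is_leaf:
            return _newick_name(node)
        inner = ",".join(fmt(c) for c in sorted(node.children))
        return f"({inner}){_newick_name(node)}"

    return fmt(tree.root_taxid) + ";\n"


def write_counts_tsv(tree: AnnotatedTaxTree, sink: str | Path | IO[str]) -> None:
    """Per-node counts table: one row per node, one column per combination."""
    expected = 2 ** len(tree.proteins) - 1
    rows = []
    for node in tree.walk():
        row = {
            "taxid": node.taxid,
            "scientific_name": node.scientific_name,
            "rank": node.rank,
            "total_organisms": node.total_organisms,
        }
        for code in range(1, expected + 1):
            row[combo_label(code, tree.proteins)] = node.counts.get(code, 0)
        rows.append(row)
    pd.DataFrame(rows).to_csv(sink, sep="\t", index=False, lineterminator="\n")
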