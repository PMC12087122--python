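"""NCBI-taxonomy-style store: load dump files, answer lineage and rank queries.

The store is deliberately strict: unknown taxids raise :class:`UnknownTaxidError`
here, and the tolerant soft-handling (mapping stray taxids to the root with a
warning) lives one layer up, in the tree- and heatmap-building code. Merged or
deleted taxids are not resolved; a miniature dump in the same pipe-and-tab
dialect is enough for every query the pipeline makes.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator

logger = logging.getLogger(__name__)

__all__ = [
    "TaxNode",
    "TaxonomyDB",
    "TaxonomyError",
    "TaxonomyParseError",
    "TaxonomyStructureError",
    "UnknownTaxidError",
    "load_taxonomy",
    "write_taxdump",
]


class TaxonomyError(Exception):
    """Base class for taxonomy store errors."""


class TaxonomyParseError(TaxonomyError):
    """A dump line could not be parsed; carries the 1-based line number."""

    def __init__(self, source: str, lineno: int, line: str):
        self.source = source
        self.lineno = lineno
        super().__init__(f"{source}: malformed line {lineno}: {line!r}")


class TaxonomyStructureError(TaxonomyError):
    """The node set violates tree structure (orphans, missing root, cycles)."""

    def __init__(self, message: str, taxids: Iterable[int] = ()):
        self.taxids = sorted(taxids)
        if self.taxids:
            message = f"{message}: {self.taxids}"
        super().__init__(message)


class UnknownTaxidError(TaxonomyError, KeyError):
    """Query for a taxid absent from the store."""

    def __init__(self, taxid: int):
        self.taxid = taxid
        super().__init__(f"unknown taxid {taxid}")


@dataclass(frozen=True)
class TaxNode:
    """One taxon: identifier, parent link, rank and scientific name."""

    taxid: int
    parent_taxid: int
    rank: str
    scientific_name: str

    @property
    def is_root(self) -> bool:
        return self.taxid == self.parent_taxid


class TaxonomyDB:
    """In-memory taxonomy with taxid and scientific-name lookup.

    Ambiguous scientific names (one name, several taxids) resolve to the
    lowest taxid; the loader logs a warning for each collision.
    """

    def __init__(self, nodes: dict[int, TaxNode]):
        self._nodes = nodes
        self._root = self._validate()
        self._name_index: dict[str, int] = {}
        for taxid in sorted(nodes):
            name = nodes[taxid].scientific_name
            if name in self._name_index:
                logger.warning(
                    "ambiguous scientific name %r: keeping taxid %d, ignoring %d",
                    name, self._name_index[name], taxid,
                )
            else:
                self._name_index[name] = taxid

    def _validate(self) -> TaxNode:
        roots = [n for n in self._nodes.values() if n.is_root]
        if len(roots) != 1:
            raise TaxonomyStructureError(
                f"expected exactly one self-parented root, found {len(roots)}",
                [n.taxid for n in roots],
            )
        orphans = [
            n.taxid
            for n in self._nodes.values()
            if n.parent_taxid not in self._nodes
        ]
        if orphans:
            raise TaxonomyStructureError("orphan nodes (parent absent)", orphans)
        # Walking parents from every node must reach the root (no cycles).
        root = roots[0]
        ok: set[int] = {root.taxid}
        for start in self._nodes:
            path = []
            taxid = start
            while taxid not in ok:
                path.append(taxid)
                taxid = self._nodes[taxid].parent_taxid
                if taxid in path:
                    raise TaxonomyStructureError("cycle detected", path)
            ok.update(path)
        return root

    # -- basic access ------------------------------------------------------

    def __len__(self) -> int:
        return len(self._nodes)

    def __contains__(self, taxid: int) -> bool:
        return taxid in self._nodes

    def __iter__(self) -> Iterator[int]:
        return iter(sorted(self._nodes))

    @property
    def root(self) -> TaxNode:
        return self._root

    @property
    def name_index(self) -> dict[str, int]:
        return dict(self._name_index)

    def node(self, taxid: int) -> TaxNode:
        try:
            return self._nodes[taxid]
        except KeyError:
            raise UnknownTaxidError(taxid) from None

    def name(self, taxid: int) -> str:
        return self.node(taxid).scientific_name

    def rank(self, taxid: int) -> str:
        return self.node(taxid).rank

    def taxid_of_name(self, name: str) -> int | None:
        """Lowest taxid bearing this scientific name, or None."""
        return self._name_index.get(name)

    # -- lineage queries ---------------------------------------------------

    def lineage(self, taxid: int) -> list[TaxNode]:
        """Chain of nodes from the root down to *taxid* (inclusive)."""
        node = self.node(taxid)
        chain = [node]
        while not node.is_root:
            node = self._nodes[node.parent_taxid]
            chain.append(node)
        chain.reverse()
        return chain

    def species_of(self, taxid: int) -> int:
        """Collapse to the nearest ancestor-or-self of rank "species".

        Strain- and subspecies-level taxids thereby count as one organism.
        If no species rank occurs on the path to the root, the input taxid
        is returned unchanged (e.g. genus-level hits stay genus-level).
        """
        node = self.node(taxid)
        while True:
            if node.rank == "species":
                return node.taxid
            if node.is_root:
                return taxid
            node = self._nodes[node.parent_taxid]

    def depth(self) -> int:
        """Length of the longest root-to-node path."""
        return max(len(self.lineage(t)) for t in self._nodes)


def _iter_dump_lines(source: str | Path | IO[str]) -> tuple[str, list[list[str]]]:
    """Split an NCBI-dialect dump into per-line field lists.

    Fields are separated by ``\\t|\\t`` and each line ends with ``\\t|``.
    Returns (source label, rows); raises TaxonomyParseError on short rows.
    """
    if isinstance(source, (str, Path)):
        label = str(source)
        text = Path(source).read_text(encoding="utf-8")
    else:
        label = getattr(source, "name", "<stream>")
        text = source.read()
    rows = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        stripped = line.rstrip()
        if stripped.endswith("\t|"):
            stripped = stripped[:-2]
        fields = stripped.split("\t|\t")
        rows.append((lineno, line, fields))
    return label, rows


def load_taxonomy(
    nodes_source: str | Path | IO[str],
    names_source: str | Path | IO[str],
) -> TaxonomyDB:
    """Load a taxonomy from nodes/names dump files.

    ``nodes`` rows are ``taxid | parent | rank``; ``names`` rows are
    ``taxid | name | unique name | name class`` and only rows whose class is
    ``scientific name`` are indexed. Unknown ranks are preserved verbatim.
    """
    nodes_label, node_rows = _iter_dump_lines(nodes_source)
    names_label, name_rows = _iter_dump_lines(names_source)

    parsed: dict[int, tuple[int, str]] = {}
    for lineno, raw, fields in node_rows:
        if len(fields) < 3:
            raise TaxonomyParseError(nodes_label, lineno, raw)
        try:
            taxid = int(fields[0])
            parent = int(fields[1])
        except ValueError:
            raise TaxonomyParseError(nodes_label, lineno, raw) from None
        parsed[taxid] = (parent, fields[2].strip())

    names: dict[int, str] = {}
    for lineno, raw, fields in name_rows:
        if len(fields) < 4:
            raise TaxonomyParseError(names_label, lineno, raw)
        try:
            taxid = int(fields[0])
        except ValueError:
            raise TaxonomyParseError(names_label, lineno, raw) from None
        if fields[3].strip() == "scientific name":
            names[taxid] = fields[1].strip()

    nodes = {
        taxid: TaxNode(taxid, parent, rank, names.get(taxid, f"taxid {taxid}"))
        for taxid, (parent, rank) in parsed.items()
    }
    return TaxonomyDB(nodes)


def write_taxdump(db: TaxonomyDB, nodes_sink: IO[str], names_sink: IO[str]) -> None:
    """Serialise a store back to the dump dialect (round-trip companion)."""
    for taxid in db:
        node = db.node(taxid)
        nodes_sink.write(f"{node.taxid}\t|\t{node.parent_taxid}\t|\t{node.rank}\t|\n")
        names_sink.write(
            f"{node.taxid}\t|\t{node.scientific_name}\t|\t\t|\tscientific name\t|\n"
        )
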