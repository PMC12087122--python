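"""Merge filtered per-seed result tables and derive organism listings.

Organism identity is the species-collapsed taxid by default, so strain-level
hits never inflate organism counts; raw-taxid identity is available via
``collapse_species=False``. Identical accessions hit by different seeds are
deduplicated before any counting — one accession contributes one record, the
occurrence with the lowest e-value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

import pandas as pd

from .blast_io import HitRecord, ResultTable, _record_order
from .taxonomy import TaxonomyDB, UnknownTaxidError

logger = logging.getLogger(__name__)

__all__ = [
    "CombinedTable",
    "combine_protein",
    "unique_organisms",
    "write_combined_table",
    "write_listings",
]


@dataclass
class CombinedTable:
    """All surviving hits of one protein, pooled over its seed queries."""

    protein: str
    records: list[HitRecord] = field(default_factory=list)
    #: organism taxid (species-collapsed unless disabled) per record
    organisms: list[int] = field(default_factory=list)
    #: organism taxid → index of its best (minimum-e-value) record
    best_by_organism: dict[int, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def organism_set(self) -> set[int]:
        return set(self.best_by_organism)

    def best_evalue(self, organism: int) -> float:
        return self.records[self.best_by_organism[organism]].evalue


def _organism_of(db: TaxonomyDB, taxid: int, collapse_species: bool) -> int:
    if taxid not in db:
        logger.warning("taxid %d absent from taxonomy; kept as-is", taxid)
        return taxid
    return db.species_of(taxid) if collapse_species else taxid


def combine_protein(
    tables: Sequence[ResultTable],
    db: TaxonomyDB,
    collapse_species: bool = True,
) -> CombinedTable:
    """Pool filtered tables of one protein into a :class:`CombinedTable`.

    Records are deduplicated by accession (keeping the best occurrence),
    re-sorted by ascending e-value, and mapped to organisms via species
    collapse. Mixing tables of different proteins is an error.
    """
    if not tables:
        raise ValueError("no tables to combine")
    proteins = {t.protein for t in tables}
    if len(proteins) > 1:
        raise ValueError(f"mixed protein names: {sorted(proteins)}")
    best_by_accession: dict[str, HitRecord] = {}
    for table in tables:
        for rec in table.records:
            cur = best_by_accession.get(rec.subject_accession)
            if cur is None or _record_order(rec) < _record_order(cur):
                best_by_accession[rec.subject_accession] = rec
    records = sorted(best_by_accession.values(), key=_record_order)
    organisms = [
        _organism_of(db, rec.subject_taxid, collapse_species) for rec in records
    ]
    best: dict[int, int] = {}
    for i, org in enumerate(organisms):
        # records are e-value sorted, so the first index per organism is best
        if org not in best:
            best[org] = i
    return CombinedTable(
        protein=proteins.pop(),
        records=records,
        organisms=organisms,
        best_by_organism=best,
    )


def _display_name(db: TaxonomyDB, taxid: int) -> str:
    try:
        return db.name(taxid)
    except UnknownTaxidError:
        logger.warning("taxid %d has no taxonomy entry", taxid)
        return f"unknown taxid {taxid}"


def unique_organisms(
    combined: Iterable[CombinedTable], db: TaxonomyDB
) -> tuple[dict[str, list[tuple[int, str]]], list[tuple[int, str]]]:
    """Non-redundant organism listings, per protein and overall.

    Returns (per_protein, overall); each listing is a taxid-sorted list of
    (taxid, scientific_name) pairs. Taxids missing from the taxonomy are
    listed as ``unknown taxid <n>``.
    """
    per_protein: dict[str, list[tuple[int, str]]] = {}
    union: set[int] = set()
    for table in combined:
        taxids = sorted(table.organism_set())
        union.update(taxids)
        per_protein[table.protein] = [(t, _display_name(db, t)) for t in taxids]
    overall = [(t, _display_name(db, t)) for t in sorted(union)]
    return per_protein, overall


def write_combined_table(
    table: CombinedTable, db: TaxonomyDB, sink: str | Path | IO[str]
) -> int:
    """Write a combined table as TSV (result-table dialect + organism column)."""
    rows = []
    for rec, org in zip(table.records, table.organisms):
        rows.append(
            {
                "protein": rec.protein,
                "seed_id": rec.seed_id,
                "subject_accession": rec.subject_accession,
                "subject_taxid": rec.subject_taxid,
                "organism_taxid": org,
                "organism_name": _display_name(db, org),
                "evalue": repr(rec.evalue),
                "bitscore": repr(rec.bitscore),
                "query_start": rec.query_start,
                "query_end": rec.query_end,
                "subject_length": rec.subject_length,
            }
        )
    pd.DataFrame(
        rows,
        columns=[
            "protein", "seed_id", "subject_accession", "subject_taxid",
            "organism_taxid", "organism_name", "evalue", "bitscore",
            "query_start", "query_end", "subject_length",
        ],
    ).to_csv(sink, sep="\t", index=False, lineterminator="\n")
    return len(rows)


def write_listings(
    per_protein: Mapping[str, list[tuple[int, str]]],
    overall: list[tuple[int, str]],
    outdir: str | Path,
) -> list[Path]:
    """Write names_/taxids_ text files per protein plus the overall union."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    def _write(stub: str, listing: list[tuple[int, str]]):
        names_path = outdir / f"names_{stub}.txt"
        taxids_path = outdir / f"taxids_{stub}.txt"
        names_path.write_text("".join(f"{name}\n" for _, name in listing))
        taxids_path.write_text("".join(f"{taxid}\n" for taxid, _ in listing))
        written.extend([names_path, taxids_path])

    for protein, listing in per_protein.items():
        _write(protein, listing)
    _write("all", overall)
    return written
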