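"""BLAST result I/O: XML2 parsing, TSV result tables, hit-FASTA extraction.

One :class:`HitRecord` per HSP, ordered by ascending e-value. Coordinates are
1-based inclusive, exactly as BLAST reports them, and are converted nowhere
downstream. An e-value of 0.0 is kept as 0.0 here; capping to a finite
significance score happens only when the heatmap matrix is built.
"""

from __future__ import annotations

import logging
import math
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Iterable, Sequence

import pandas as pd
from Bio import Blast
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

logger = logging.getLogger(__name__)

__all__ = [
    "HitRecord",
    "ResultTable",
    "BlastFormatError",
    "TableFormatError",
    "parse_blast_xml",
    "write_result_table",
    "read_result_table",
    "blast2fasta",
    "BlastParams",
    "run_blastp",
]


class BlastFormatError(ValueError):
    """Input is not a parseable single-query BLAST XML2 document."""


class TableFormatError(ValueError):
    """A TSV result table violates the documented column contract."""


@dataclass(frozen=True)
class HitRecord:
    """One HSP-level homology hit for a seed query.

    ``query_start``/``query_end`` are 1-based inclusive positions on the seed;
    ``subject_length`` is the full subject sequence length in amino acids;
    ``aligned_subject_seq`` is the gapped aligned segment and may be empty when
    the record came from a TSV written without sequences.
    """

    protein: str
    seed_id: str
    subject_accession: str
    subject_taxid: int
    evalue: float
    bitscore: float
    query_start: int
    query_end: int
    subject_length: int
    aligned_subject_seq: str = ""

    def __post_init__(self):
        if self.evalue < 0:
            raise ValueError(f"negative e-value {self.evalue}")
        if not (1 <= self.query_start <= self.query_end):
            raise ValueError(
                f"bad query span {self.query_start}..{self.query_end}"
            )
        if self.subject_length < 1:
            raise ValueError(f"subject_length {self.subject_length} < 1")


#: Sort key giving the canonical record order: ascending e-value, ties broken
#: by descending bit score, then accession lexicographically.
def _record_order(rec: HitRecord):
    return (rec.evalue, -rec.bitscore, rec.subject_accession)


@dataclass
class ResultTable:
    """Ordered hits of one seed query; the unit stored in resulttables/."""

    protein: str
    seed_id: str
    seed_length: int
    records: list[HitRecord] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def sorted(self) -> "ResultTable":
        return replace(self, records=sorted(self.records, key=_record_order))


def parse_blast_xml(source: str | Path | IO[bytes], protein: str) -> ResultTable:
    """Parse a single-query BLAST XML2 document into a :class:`ResultTable`.

    Hits lacking a taxid are skipped with a warning; the skip count is kept in
    ``table.metadata["skipped_no_taxid"]``. Records come back sorted by
    ascending e-value (ties: descending bit score, then accession).
    """
    try:
        if isinstance(source, (str, Path)):
            with open(source, "rb") as fh:
                records = list(Blast.parse(fh))
        else:
            records = list(Blast.parse(source))
    except Exception as exc:  # Bio.Blast raises assorted parse errors
        raise BlastFormatError(f"not a parseable BLAST XML document: {exc}") from exc
    if len(records) != 1:
        raise BlastFormatError(
            f"expected a single-query document, found {len(records)} queries"
        )
    record = records[0]
    seed_id = record.query.description.split()[0] if record.query.description else record.query.id
    seed_length = len(record.query.seq)

    hits: list[HitRecord] = []
    skipped = 0
    for hit in record:
        target = hit.target
        taxid = target.annotations.get("taxid") if hasattr(target, "annotations") else None
        if taxid is None:
            skipped += 1
            logger.warning(
                "hit %s has no taxid; skipping %d HSP(s)", target.id, len(hit)
            )
            continue
        accession = target.name or target.id
        subject_length = len(target.seq)
        for hsp in hit:
            # alignment rows: 0 = subject (hseq), 1 = query; coords are 0-based
            qstart = int(hsp.coordinates[1].min()) + 1
            qend = int(hsp.coordinates[1].max())
            hits.append(
                HitRecord(
                    protein=protein,
                    seed_id=seed_id,
                    subject_accession=str(accession),
                    subject_taxid=int(taxid),
                    evalue=float(hsp.annotations["evalue"]),
                    bitscore=float(hsp.annotations["bit score"]),
                    query_start=qstart,
                    query_end=qend,
                    subject_length=subject_length,
                    aligned_subject_seq=str(hsp[0]),
                )
            )
    hits.sort(key=_record_order)
    return ResultTable(
        protein=protein,
        seed_id=seed_id,
        seed_length=seed_length,
        records=hits,
        metadata={"skipped_no_taxid": skipped},
    )


_BASE_COLUMNS = [
    "protein",
    "seed_id",
    "seed_length",
    "subject_accession",
    "subject_taxid",
    "evalue",
    "bitscore",
    "query_start",
    "query_end",
    "subject_length",
]
_SEQ_COLUMN = "aligned_subject_seq"


def write_result_table(table: ResultTable, sink: str | Path | IO[str]) -> int:
    """Write a TSV result table; returns the number of data rows written.

    The aligned-sequence column is present only when at least one record
    carries a sequence, so sequence-free tables stay compact.
    """
    with_seq = any(r.aligned_subject_seq for r in table.records)
    columns = _BASE_COLUMNS + ([_SEQ_COLUMN] if with_seq else [])
    rows = []
    for r in table.records:
        row = {
            "protein": r.protein,
            "seed_id": r.seed_id,
            "seed_length": table.seed_length,
            "subject_accession": r.subject_accession,
            "subject_taxid": r.subject_taxid,
            "evalue": repr(r.evalue),  # shortest exact repr → lossless round trip
            "bitscore": repr(r.bitscore),
            "query_start": r.query_start,
            "query_end": r.query_end,
            "subject_length": r.subject_length,
        }
        if with_seq:
            row[_SEQ_COLUMN] = r.aligned_subject_seq
        rows.append(row)
    df = pd.DataFrame(rows, columns=columns)
    df.to_csv(sink, sep="\t", index=False, lineterminator="\n")
    return len(rows)


def read_result_table(source: str | Path | IO[str]) -> ResultTable:
    """Read a TSV result table written by :func:`write_result_table`."""
    try:
        df = pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)
    except Exception as exc:
        raise TableFormatError(f"unreadable result table: {exc}") from exc
    missing = [c for c in _BASE_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"missing required column(s): {missing}")
    extra = [c for c in df.columns if c not in _BASE_COLUMNS + [_SEQ_COLUMN]]
    if extra:
        raise TableFormatError(f"unexpected column(s): {extra}")
    records = []
    for i, row in df.iterrows():
        try:
            records.append(
                HitRecord(
                    protein=row["protein"],
                    seed_id=row["seed_id"],
                    subject_accession=row["subject_accession"],
                    subject_taxid=int(row["subject_taxid"]),
                    evalue=float(row["evalue"]),
                    bitscore=float(row["bitscore"]),
                    query_start=int(row["query_start"]),
                    query_end=int(row["query_end"]),
                    subject_length=int(row["subject_length"]),
                    aligned_subject_seq=row.get(_SEQ_COLUMN, ""),
                )
            )
        except ValueError as exc:
            raise TableFormatError(f"row {i + 1}: {exc}") from exc
    if len(df):
        protein = df["protein"].iloc[0]
        seed_id = df["seed_id"].iloc[0]
        try:
            seed_length = int(df["seed_length"].iloc[0])
        except ValueError as exc:
            raise TableFormatError(f"column seed_length: {exc}") from exc
    else:
        protein, seed_id, seed_length = "", "", 0
    return ResultTable(protein=protein, seed_id=seed_id, seed_length=seed_length,
                       records=records)


def blast2fasta(
    tables: Iterable[ResultTable],
    dedupe: bool = True,
    strict: bool = False,
) -> str:
    """Collect hit sequences from result tables into FASTA text.

    Gap characters are stripped. Headers are ``accession taxid protein``.
    With ``dedupe`` on, an accession occurring in several tables keeps only
    its lowest-e-value occurrence. Records without a stored aligned sequence
    are skipped with a warning, or rejected when ``strict`` is set.
    """
    best: dict[str, HitRecord] = {}
    order: list[str] = []
    for table in tables:
        for rec in table.records:
            if not rec.aligned_subject_seq:
                if strict:
                    raise ValueError(
                        f"record {rec.subject_accession} has no aligned sequence"
                    )
                logger.warning(
                    "skipping %s: no aligned sequence stored", rec.subject_accession
                )
                continue
            key = rec.subject_accession if dedupe else f"{rec.subject_accession}/{rec.protein}/{rec.seed_id}"
            if key not in best:
                best[key] = rec
                order.append(key)
            elif rec.evalue < best[key].evalue:
                best[key] = rec
    out = []
    for key in order:
        rec = best[key]
        seq = rec.aligned_subject_seq.replace("-", "")
        out.append(
            SeqRecord(
                Seq(seq),
                id=rec.subject_accession,
                description=f"{rec.subject_taxid} {rec.protein}",
            )
        )
    import io as _io

    buf = _io.StringIO()
    SeqIO.write(out, buf, "fasta")
    return buf.getvalue()


@dataclass(frozen=True)
class BlastParams:
    """blastp parameter set; defaults follow common protein-search practice."""

    matrix: str = "BLOSUM62"
    word_size: int = 6
    gapopen: int = 11
    gapextend: int = 1
    evalue: float = 1e-3
    max_target_seqs: int = 20000


def run_blastp(
    seed_fasta: str | Path,
    database: str,
    mode: str = "local",
    params: BlastParams | None = None,
    outdir: str | Path = "blastresults",
) -> Path:
    """Run a blastp search and store its XML2 output under *outdir*.

    This is an invocation wrapper around BLAST+ (local) or the NCBI web
    service (remote); it is exercised only when a search backend is actually
    available. Output is written atomically: on failure no partial file is
    left behind.
    """
    if not database:
        raise ValueError("database must be non-empty")
    if mode not in ("local", "remote"):
        raise ValueError(f"mode must be 'local' or 'remote', got {mode!r}")
    seed_fasta = Path(seed_fasta)
    if not seed_fasta.exists():
        raise FileNotFoundError(seed_fasta)
    params = params or BlastParams()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    out_path = outdir / (seed_fasta.stem + ".xml")
    logger.info(
        "blastp %s vs %s (%s): matrix=%s word_size=%d gapopen=%d gapextend=%d "
        "evalue=%g max_target_seqs=%d",
        seed_fasta, database, mode, params.matrix, params.word_size,
        params.gapopen, params.gapextend, params.evalue, params.max_target_seqs,
    )
    if mode == "local":
        exe = shutil.which("blastp")
        if exe is None:
            raise OSError("blastp executable not found on PATH")
        cmd = [
            exe, "-query", str(seed_fasta), "-db", database,
            "-outfmt", "16",  # single-file XML2
            "-matrix", params.matrix,
            "-word_size", str(params.word_size),
            "-gapopen", str(params.gapopen),
            "-gapextend", str(params.gapextend),
            "-evalue", str(params.evalue),
            "-max_target_seqs", str(params.max_target_seqs),
        ]
        with tempfile.NamedTemporaryFile(
            "w", dir=outdir, suffix=".part", delete=False
        ) as tmp:
            tmp_path = Path(tmp.name)
        try:
            subprocess.run(cmd + ["-out", str(tmp_path)], check=True)
            tmp_path.replace(out_path)
        except Exception:
            tmp_path.unlink(missing_ok=True)
            raise
        return out_path
    # remote: delegate to NCBI qblast with XML2 download
    try:
        with open(seed_fasta) as fh:
            seq = fh.read()
        handle = Blast.qblast(
            "blastp", database, seq, format_type="XML2",
            expect=params.evalue, hitlist_size=params.max_target_seqs,
            matrix_name=params.matrix, word_size=params.word_size,
            gapcosts=f"{params.gapopen} {params.gapextend}",
        )
        data = handle.read()
    except Exception as exc:
        raise OSError(f"remote BLAST unavailable: {exc}") from exc
    tmp_path = out_path.with_suffix(".part")
    tmp_path.write_bytes(data)
    tmp_path.replace(out_path)
    return out_path
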