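"""Quality control and filtering of homology-search hits.

Covers the two visual QC aids (hit-length histogram, six-interval coverage
profile), the e-value/length cutoff filter, and the cross-hit similarity
matrix used to detect paralog confusion between query proteins.

Boundary semantics are inclusive on both cutoffs: a hit is kept when
``evalue <= cutoff`` and ``subject_length >= min_length``. The length tested
is the full subject sequence length, not the aligned span, since the cutoff
screens out hits that are too short relative to the seed protein.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .blast_io import ResultTable, HitRecord

logger = logging.getLogger(__name__)

__all__ = [
    "Limits",
    "CoverageProfile",
    "CrossHitMatrix",
    "ConfigurationError",
    "DEFAULT_EVALUE_CUTOFF",
    "DEFAULT_MIN_LENGTH",
    "length_histogram",
    "plot_length_histogram",
    "coverage_profile",
    "plot_coverage",
    "apply_limits",
    "cross_hit_matrix",
    "accession_evalues",
]

DEFAULT_EVALUE_CUTOFF = 1e-30
DEFAULT_MIN_LENGTH = 50

#: search-time e-value ceiling; upper edge of the default coverage intervals
SEARCH_EVALUE_DEFAULT = 1e-3
#: most significant bound of the default coverage intervals
COVERAGE_FLOOR = 1e-180


class ConfigurationError(ValueError):
    """A configuration file or value is invalid."""


@dataclass(frozen=True)
class Limits:
    """Per-protein e-value and minimum-length cutoffs with global defaults."""

    default_evalue: float = DEFAULT_EVALUE_CUTOFF
    default_min_length: int = DEFAULT_MIN_LENGTH
    overrides: Mapping[str, tuple[float, int]] = field(default_factory=dict)

    def __post_init__(self):
        if self.default_evalue <= 0:
            raise ConfigurationError("default e-value cutoff must be > 0")
        if self.default_min_length < 0:
            raise ConfigurationError("default min length must be >= 0")
        for protein, (ev, ln) in self.overrides.items():
            if ev <= 0 or ln < 0:
                raise ConfigurationError(
                    f"invalid limits for {protein!r}: evalue={ev}, min_length={ln}"
                )

    def resolve(self, protein: str) -> tuple[float, int]:
        """(evalue_cutoff, min_length) for a protein, override or default."""
        if protein in self.overrides:
            return self.overrides[protein]
        return (self.default_evalue, self.default_min_length)

    @classmethod
    def from_file(cls, source: str | Path | IO[str]) -> "Limits":
        """Parse limits.txt: whitespace-separated ``protein evalue min_length``.

        Lines starting with ``#`` are comments. A line for protein ``*``
        replaces the global defaults.
        """
        if isinstance(source, (str, Path)):
            text = Path(source).read_text()
            label = str(source)
        else:
            text = source.read()
            label = getattr(source, "name", "<stream>")
        overrides: dict[str, tuple[float, int]] = {}
        default = (DEFAULT_EVALUE_CUTOFF, DEFAULT_MIN_LENGTH)
        for lineno, line in enumerate(text.splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ConfigurationError(
                    f"{label}:{lineno}: expected 'protein evalue min_length', got {line!r}"
                )
            try:
                entry = (float(parts[1]), int(parts[2]))
            except ValueError as exc:
                raise ConfigurationError(f"{label}:{lineno}: {exc}") from None
            if parts[0] == "*":
                default = entry
            else:
                overrides[parts[0]] = entry
        return cls(default_evalue=default[0], default_min_length=int(default[1]),
                   overrides=overrides)


# -- length histogram ------------------------------------------------------

def length_histogram(
    tables: Iterable[ResultTable], bin_width: int = 50
) -> tuple[np.ndarray, np.ndarray]:
    """Bin subject sequence lengths; returns (bin_edges, counts).

    Bins are ``[k*bin_width, (k+1)*bin_width)`` covering 0 up to the largest
    observed length; counts sum to the number of input records. With no
    records both arrays are empty.
    """
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    lengths = np.array(
        [r.subject_length for t in tables for r in t.records], dtype=int
    )
    if lengths.size == 0:
        return np.array([], dtype=int), np.array([], dtype=int)
    n_bins = int(lengths.max() // bin_width) + 1
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(lengths, bins=edges)
    return edges, counts


def plot_length_histogram(
    tables: Sequence[ResultTable],
    bin_width: int = 50,
    image_path: str | Path | None = None,
    table_path: str | Path | None = None,
    title: str = "Hit length distribution",
):
    """Render the histogram as an image and a two-column companion TSV."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    edges, counts = length_histogram(tables, bin_width)
    fig, ax = plt.subplots(figsize=(8, 4.5))
    if counts.size:
        ax.bar(edges[:-1], counts, width=bin_width, align="edge",
               color="#4878a8", edgecolor="white")
    else:
        ax.annotate("no hits", xy=(0.5, 0.5), xycoords="axes fraction",
                    ha="center", fontsize=14)
    ax.set_xlabel("subject length (aa)")
    ax.set_ylabel("hits")
    ax.set_title(title)
    if image_path is not None:
        fig.savefig(image_path, metadata={"Date": None})
    if table_path is not None:
        pd.DataFrame(
            {"bin_start": edges[:-1] if counts.size else [], "count": counts}
        ).to_csv(table_path, sep="\t", index=False, lineterminator="\n")
    plt.close(fig)
    return edges, counts


# -- coverage profile ------------------------------------------------------

def default_interval_edges(
    threshold: float = SEARCH_EVALUE_DEFAULT, floor: float = COVERAGE_FLOOR
) -> np.ndarray:
    """Seven descending e-value bounds, log-uniform in the exponent.

    They delimit six intervals of increasing significance between the
    search-time e-value ceiling and a practical floor below which BLAST
    e-values are effectively zero.
    """
    return 10.0 ** np.linspace(math.log10(threshold), math.log10(floor), 7)


@dataclass
class CoverageProfile:
    """Hits grouped into six e-value intervals, spans on the query axis."""

    interval_edges: np.ndarray  # 7 descending bounds
    intervals: list[list[tuple[int, int]]]  # six lists of (start, end) spans
    query_length: int

    @property
    def counts(self) -> list[int]:
        return [len(iv) for iv in self.intervals]


def coverage_profile(
    table: ResultTable, interval_edges: Sequence[float] | None = None
) -> CoverageProfile:
    """Assign each hit's aligned span to one of six e-value intervals.

    Interval ``i`` holds hits with ``edges[i+1] < evalue <= edges[i]``; hits
    more significant than the last edge (including e-value 0) fall into the
    most significant interval, hits above the first edge into the least
    significant one. Within an interval spans are ordered by ascending
    e-value (most significant first).
    """
    edges = (
        np.asarray(interval_edges, dtype=float)
        if interval_edges is not None
        else default_interval_edges()
    )
    if edges.shape != (7,) or not np.all(np.diff(edges) < 0):
        raise ValueError("interval_edges must be 7 strictly descending bounds")
    buckets: list[list[tuple[float, int, int]]] = [[] for _ in range(6)]
    for rec in table.records:
        if rec.query_end > table.seed_length:
            raise ValueError(
                f"hit {rec.subject_accession}: span {rec.query_start}.."
                f"{rec.query_end} exceeds query length {table.seed_length}"
            )
        idx = 5
        for i in range(6):
            if rec.evalue > edges[i + 1]:
                idx = i
                break
        buckets[idx].append((rec.evalue, rec.query_start, rec.query_end))
    intervals = [
        [(s, e) for _, s, e in sorted(bucket)] for bucket in buckets
    ]
    return CoverageProfile(
        interval_edges=edges, intervals=intervals, query_length=table.seed_length
    )


def plot_coverage(
    profile: CoverageProfile,
    image_path: str | Path | None = None,
    table_path: str | Path | None = None,
    title: str = "Hit coverage by e-value interval",
):
    """Render the coverage profile: one band per interval, one bar per hit."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 6))
    y = 0
    yticks, ylabels = [], []
    cmap = plt.get_cmap("viridis")
    for i, spans in enumerate(profile.intervals):
        y0 = y
        for (start, end) in spans:
            ax.hlines(y, start, end, colors=cmap(i / 5), linewidth=2)
            y += 1
        yticks.append((y0 + y) / 2)
        hi, lo = profile.interval_edges[i], profile.interval_edges[i + 1]
        ylabels.append(f"{hi:.0e} .. {lo:.0e} ({len(spans)})")
        y += 2  # gap between bands
    ax.set_yticks(yticks, ylabels, fontsize=7)
    ax.set_xlim(0, profile.query_length + 1)
    ax.invert_yaxis()
    ax.set_xlabel("query position (aa)")
    ax.set_title(title)
    if image_path is not None:
        fig.savefig(image_path, metadata={"Date": None})
    if table_path is not None:
        rows = [
            {
                "interval": i + 1,
                "evalue_high": profile.interval_edges[i],
                "evalue_low": profile.interval_edges[i + 1],
                "query_start": s,
                "query_end": e,
            }
            for i, spans in enumerate(profile.intervals)
            for s, e in spans
        ]
        pd.DataFrame(
            rows,
            columns=["interval", "evalue_high", "evalue_low", "query_start", "query_end"],
        ).to_csv(table_path, sep="\t", index=False, lineterminator="\n")
    plt.close(fig)
    return profile


# -- cutoff filtering ------------------------------------------------------

def apply_limits(table: ResultTable, limits: Limits) -> ResultTable:
    """Keep records passing both cutoffs (inclusive); order preserved.

    The returned table's metadata records the filtering arithmetic:
    ``parsed == kept + removed_by_evalue + removed_by_length`` (a record
    failing both cutoffs is counted under the e-value removal).
    """
    cutoff, min_length = limits.resolve(table.protein)
    kept: list[HitRecord] = []
    removed_ev = removed_len = 0
    for rec in table.records:
        if rec.evalue > cutoff:
            removed_ev += 1
        elif rec.subject_length < min_length:
            removed_len += 1
        else:
            kept.append(rec)
    logger.info(
        "%s/%s: %d parsed, %d kept, %d removed by e-value>%g, %d removed by length<%d",
        table.protein, table.seed_id, len(table.records), len(kept),
        removed_ev, cutoff, removed_len, min_length,
    )
    meta = dict(table.metadata)
    meta.update(
        parsed=len(table.records),
        kept=len(kept),
        removed_by_evalue=removed_ev,
        removed_by_length=removed_len,
        evalue_cutoff=cutoff,
        min_length=min_length,
    )
    return replace(table, records=kept, metadata=meta)


# -- cross-hit matrix ------------------------------------------------------

#: floor substituted for true e-value 0.0 inside the matrix, so the value 0
#: can keep its meaning of "no cross-hit found"
ZERO_EVALUE_FLOOR = 1e-200


def accession_evalues(tables: Iterable[ResultTable]) -> dict[str, float]:
    """Best (minimum) e-value per subject accession over a set of tables."""
    best: dict[str, float] = {}
    for table in tables:
        for rec in table.records:
            cur = best.get(rec.subject_accession)
            if cur is None or rec.evalue < cur:
                best[rec.subject_accession] = rec.evalue
    return best


@dataclass
class CrossHitMatrix:
    """Symmetric protein × protein matrix of best shared-accession e-values.

    An entry of 0 means the two proteins share no hit accession. True
    e-values of 0.0 are floored to ``ZERO_EVALUE_FLOOR`` before entry so
    they stay distinguishable from the no-cross-hit sentinel.
    """

    proteins: list[str]
    values: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.proteins, columns=self.proteins)

    def write_csv(self, sink: str | Path | IO[str]) -> None:
        df = self.to_dataframe()
        header = (
            "# cross-hit similarity matrix: entry = best e-value of accessions "
            "shared by the two proteins; 0 = no cross-hit; true e-values of 0.0 "
            f"are floored to {ZERO_EVALUE_FLOOR:g}\n"
        )
        if isinstance(sink, (str, Path)):
            with open(sink, "w") as fh:
                fh.write(header)
                df.to_csv(fh, lineterminator="\n")
        else:
            sink.write(header)
            df.to_csv(sink, lineterminator="\n")


def cross_hit_matrix(
    hits_by_protein: Mapping[str, Mapping[str, float] | Iterable[ResultTable]],
) -> CrossHitMatrix:
    """Cross-hit check over ≥2 proteins' accession→best-e-value sets.

    Accepts either precomputed accession→e-value mappings or iterables of
    result tables per protein. Entry (i, j) is the minimum e-value over all
    occurrences, in either protein's set, of accessions the two share.
    """
    resolved: dict[str, dict[str, float]] = {}
    for protein, hits in hits_by_protein.items():
        if isinstance(hits, Mapping):
            resolved[protein] = dict(hits)
        else:
            resolved[protein] = accession_evalues(hits)
    proteins = list(resolved)
    if len(proteins) < 2:
        raise ValueError("cross-hit check requires at least two proteins")
    n = len(proteins)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = resolved[proteins[i]], resolved[proteins[j]]
            shared = a.keys() & b.keys()
            if shared:
                ev = min(min(a[acc], b[acc]) for acc in shared)
                values[i, j] = values[j, i] = max(ev, ZERO_EVALUE_FLOOR)
    return CrossHitMatrix(proteins=proteins, values=values)
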