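"""Workspace layout, configuration parsing, and pipeline orchestration.

A workspace is a directory with four working subfolders (blastresults/,
fastas/, resulttables/, combinedtables/) and five plain-text configuration
files. Initialisation is idempotent: re-running it never clobbers files the
user has edited. The pipeline runs in a fixed stage order — parse, qc,
filter, combine, heatmap, tree — and each stage can be re-run on its own
once its upstream outputs exist, so cutoffs can be iterated on without
re-parsing everything.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Sequence

from . import blast_io, combine as combine_mod, qc_filter, heatmap as heatmap_mod
from . import tree as tree_mod
from .qc_filter import ConfigurationError, Limits
from .heatmap import HeatmapConfig
from .taxonomy import TaxonomyDB, load_taxonomy

logger = logging.getLogger(__name__)

__all__ = [
    "Workspace",
    "ProteinList",
    "TreeConfig",
    "ConfigBundle",
    "DependencyError",
    "STAGES",
    "init_workspace",
    "parse_configs",
    "run_pipeline",
    "RunReport",
]

STAGES = ("parse", "qc", "filter", "combine", "heatmap", "tree")

SUBFOLDERS = ("blastresults", "fastas", "resulttables", "combinedtables")

CONFIG_TEMPLATES = {
    "proteinlist.txt": """\
# One protein per line: <protein name> <seed FASTA file under fastas/>.
# The FASTA file may contain several seed sequences for the protein; each
# gets its own BLAST query and result table.
# Example:
#   NAMPT\tnampt.fa
""",
    "limits.txt": """\
# Per-protein cutoffs: <protein> <e-value cutoff> <minimum subject length (aa)>.
# A line with protein '*' replaces the global defaults (1e-30 and 50 aa).
# Hits are kept when evalue <= cutoff AND subject length >= minimum length.
# Example:
#   NAPRT\t1e-120\t200
""",
    "heatmap_config.txt": """\
# key = value settings for the interactive heatmap.
#   organisms      = comma-separated taxids or scientific names (rows);
#                    empty means every organism with a combined hit
#   linkage        = hierarchical clustering linkage (default: centroid)
#   color          = dark endpoint of the relative-view ramp (default #000000)
#   slider_default = initial absolute-view e-value exponent (default 30)
""",
    "tree_config.txt": """\
# key = value settings for the presence tree.
#   proteins = comma-separated protein names (at most 3); their order sets
#              the combination-code bit positions and the legend order
#   colors   = 2^p - 1 comma-separated colors, one per combination code
""",
    "tree_to_prune.txt": """\
# One taxid or scientific name per line: that taxon is collapsed into a
# terminal node keeping its aggregated counts.
# An optional line 'partition: <taxid or name>' restricts the rendered tree
# to that subtree (e.g. one superkingdom).
""",
}


class DependencyError(RuntimeError):
    """A requested stage is missing the outputs of an upstream stage."""


@dataclass(frozen=True)
class Workspace:
    """Paths of one analysis workspace."""

    root: Path

    @property
    def blastresults(self) -> Path:
        return self.root / "blastresults"

    @property
    def fastas(self) -> Path:
        return self.root / "fastas"

    @property
    def resulttables(self) -> Path:
        return self.root / "resulttables"

    @property
    def combinedtables(self) -> Path:
        return self.root / "combinedtables"

    @property
    def qc_dir(self) -> Path:
        return self.root / "qc"

    @property
    def trees_dir(self) -> Path:
        return self.root / "trees"

    @property
    def taxonomy_dir(self) -> Path:
        return self.root / "taxonomy"

    def config_path(self, name: str) -> Path:
        return self.root / name


def init_workspace(root: str | Path) -> Workspace:
    """Create the folder structure and config templates; never overwrite.

    Pre-existing folders and files are left untouched, so a second
    invocation is a logged no-op.
    """
    root = Path(root)
    if root.exists() and not root.is_dir():
        raise NotADirectoryError(f"{root} exists and is not a directory")
    root.mkdir(parents=True, exist_ok=True)
    created = []
    for sub in SUBFOLDERS:
        path = root / sub
        if not path.exists():
            path.mkdir()
            created.append(sub)
    for name, template in CONFIG_TEMPLATES.items():
        path = root / name
        if not path.exists():
            path.write_text(template)
            created.append(name)
    if created:
        logger.info("initialised workspace %s: created %s", root, ", ".join(created))
    else:
        logger.info("workspace %s already initialised; nothing to do", root)
    return Workspace(root=root)


@dataclass(frozen=True)
class ProteinList:
    """Ordered (protein name, seed FASTA filename) records."""

    records: tuple[tuple[str, str], ...]

    @property
    def proteins(self) -> list[str]:
        return [p for p, _ in self.records]

    def fasta_for(self, protein: str) -> str:
        for p, f in self.records:
            if p == protein:
                return f
        raise KeyError(protein)

    @classmethod
    def from_file(cls, source: str | Path | IO[str]) -> "ProteinList":
        if isinstance(source, (str, Path)):
            text = Path(source).read_text()
            label = str(source)
        else:
            text = source.read()
            label = getattr(source, "name", "<stream>")
        records: list[tuple[str, str]] = []
        seen: set[str] = set()
        for lineno, line in enumerate(text.splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ConfigurationError(
                    f"{label}:{lineno}: expected '<protein> <fasta file>'"
                )
            if parts[0] in seen:
                raise ConfigurationError(
                    f"{label}:{lineno}: duplicate protein {parts[0]!r}"
                )
            seen.add(parts[0])
            records.append((parts[0], parts[1]))
        return cls(records=tuple(records))


@dataclass(frozen=True)
class TreeConfig:
    """Parsed tree_config.txt: ordered proteins (≤3) and combination colors."""

    proteins: tuple[str, ...] = ()
    colors: tuple[str, ...] = ()

    @classmethod
    def from_file(cls, source: str | Path | IO[str]) -> "TreeConfig":
        if isinstance(source, (str, Path)):
            text = Path(source).read_text()
            label = str(source)
        else:
            text = source.read()
            label = getattr(source, "name", "<stream>")
        proteins: tuple[str, ...] = ()
        colors: tuple[str, ...] = ()
        for lineno, line in enumerate(text.splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ConfigurationError(f"{label}:{lineno}: expected key = value")
            key, _, value = line.partition("=")
            items = tuple(v.strip() for v in value.split(",") if v.strip())
            if key.strip() == "proteins":
                proteins = items
            elif key.strip() == "colors":
                colors = items
            else:
                raise ConfigurationError(
                    f"{label}:{lineno}: unknown key {key.strip()!r}"
                )
        if len(proteins) > 3:
            raise ConfigurationError(
                f"{label}: at most 3 tree proteins are supported, got {len(proteins)}"
            )
        return cls(proteins=proteins, colors=colors)


@dataclass
class ConfigBundle:
    """All five configuration files, parsed and cross-validated."""

    protein_list: ProteinList
    limits: Limits
    heatmap: HeatmapConfig
    tree: TreeConfig
    prune: tree_mod.PruneConfig


def parse_configs(ws: Workspace) -> ConfigBundle:
    """Parse and validate every configuration file; collect all errors.

    Cross-file consistency is enforced: limits overrides and tree proteins
    must be subsets of proteinlist.txt, and every referenced seed FASTA must
    exist under fastas/. All violations are reported together.
    """
    errors: list[str] = []

    def attempt(parser, path, default):
        try:
            return parser(path)
        except ConfigurationError as exc:
            errors.append(str(exc))
            return default

    protein_list = attempt(
        ProteinList.from_file, ws.config_path("proteinlist.txt"),
        ProteinList(records=()),
    )
    limits = attempt(Limits.from_file, ws.config_path("limits.txt"), Limits())
    hm_config = attempt(
        HeatmapConfig.from_file, ws.config_path("heatmap_config.txt"),
        HeatmapConfig(),
    )
    tree_config = attempt(
        TreeConfig.from_file, ws.config_path("tree_config.txt"), TreeConfig()
    )
    prune = tree_mod.PruneConfig.from_file(ws.config_path("tree_to_prune.txt"))

    known = set(protein_list.proteins)
    for protein in limits.overrides:
        if protein not in known:
            errors.append(
                f"limits.txt: protein {protein!r} not listed in proteinlist.txt"
            )
    for protein in tree_config.proteins:
        if protein not in known:
            errors.append(
                f"tree_config.txt: protein {protein!r} not listed in proteinlist.txt"
            )
    for protein, fasta in protein_list.records:
        if not (ws.fastas / fasta).exists():
            errors.append(
                f"proteinlist.txt: seed FASTA {fasta!r} for {protein!r} "
                f"missing under fastas/"
            )
    if errors:
        raise ConfigurationError(
            "configuration errors:\n  " + "\n  ".join(errors)
        )
    return ConfigBundle(
        protein_list=protein_list, limits=limits, heatmap=hm_config,
        tree=tree_config, prune=prune,
    )


@dataclass
class RunReport:
    """Per-stage record counts of one pipeline run."""

    stages_run: list[str] = field(default_factory=list)
    #: (protein, seed_id) → filtering arithmetic of that seed's table
    seed_counts: dict[tuple[str, str], dict[str, int]] = field(default_factory=dict)
    #: protein → number of unique organisms after combining
    organisms_per_protein: dict[str, int] = field(default_factory=dict)
    overall_organisms: int = 0

    def to_text(self) -> str:
        lines = [f"stages run: {', '.join(self.stages_run) or 'none'}"]
        for (protein, seed), c in sorted(self.seed_counts.items()):
            lines.append(
                f"  {protein}/{seed}: parsed={c.get('parsed', 0)} "
                f"kept={c.get('kept', 0)} "
                f"removed_by_evalue={c.get('removed_by_evalue', 0)} "
                f"removed_by_length={c.get('removed_by_length', 0)}"
            )
        for protein, n in sorted(self.organisms_per_protein.items()):
            lines.append(f"  {protein}: {n} unique organism(s)")
        if self.overall_organisms:
            lines.append(f"  overall: {self.overall_organisms} unique organism(s)")
        return "\n".join(lines)


def _load_taxonomy(ws: Workspace, taxonomy_dir: Path | None) -> TaxonomyDB:
    tax_dir = Path(taxonomy_dir) if taxonomy_dir else ws.taxonomy_dir
    nodes, names = tax_dir / "nodes.dmp", tax_dir / "names.dmp"
    if not nodes.exists() or not names.exists():
        raise DependencyError(
            f"taxonomy dump not found under {tax_dir} (need nodes.dmp and names.dmp)"
        )
    return load_taxonomy(nodes, names)


def _result_xmls(ws: Workspace, protein: str) -> list[Path]:
    found = sorted(ws.blastresults.glob(f"{protein}.*.xml"))
    single = ws.blastresults / f"{protein}.xml"
    if single.exists():
        found.append(single)
    return found


def _parsed_tables(ws: Workspace, protein: str) -> list[Path]:
    return sorted(
        p for p in ws.resulttables.glob(f"{protein}.*.tsv")
        if not p.name.endswith(".filtered.tsv")
    )


def _filtered_tables(ws: Workspace, protein: str) -> list[Path]:
    return sorted(ws.resulttables.glob(f"{protein}.*.filtered.tsv"))


def run_pipeline(
    ws: Workspace,
    stages: Sequence[str] | None = None,
    taxonomy_dir: str | Path | None = None,
) -> RunReport:
    """Execute the requested stages in canonical order.

    Every stage logs its inputs, outputs and parameter values to the
    workspace run log. Missing upstream outputs raise
    :class:`DependencyError` naming the stage that must run first.
    """
    requested = list(STAGES) if stages is None else [s for s in STAGES if s in stages]
    unknown = set(stages or ()) - set(STAGES)
    if unknown:
        raise ConfigurationError(
            f"unknown stage(s) {sorted(unknown)}; valid: {', '.join(STAGES)}"
        )
    bundle = parse_configs(ws)
    report = RunReport()

    log_handler = logging.FileHandler(ws.root / "run.log")
    log_handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    pkg_logger = logging.getLogger("taxoprofile")
    pkg_logger.addHandler(log_handler)
    previous_level = pkg_logger.level
    if pkg_logger.getEffectiveLevel() > logging.INFO:
        pkg_logger.setLevel(logging.INFO)
    try:
        for stage in requested:
            _STAGE_IMPLS[stage](ws, bundle, report, Path(taxonomy_dir) if taxonomy_dir else None)
            report.stages_run.append(stage)
            logger.info("stage %s complete", stage)
    finally:
        pkg_logger.setLevel(previous_level)
        pkg_logger.removeHandler(log_handler)
        log_handler.close()
    return report


# -- stage implementations -------------------------------------------------

def _stage_parse(ws, bundle, report, taxonomy_dir):
    for protein in bundle.protein_list.proteins:
        xmls = _result_xmls(ws, protein)
        if not xmls:
            logger.warning(
                "no XML results for %s under %s (expected %s.<seed>.xml)",
                protein, ws.blastresults, protein,
            )
        for xml in xmls:
            table = blast_io.parse_blast_xml(xml, protein)
            out = ws.resulttables / f"{protein}.{table.seed_id}.tsv"
            n = blast_io.write_result_table(table, out)
            logger.info("parsed %s: %d record(s) -> %s", xml.name, n, out.name)


def _require_parsed(ws, bundle):
    tables = {
        protein: _parsed_tables(ws, protein)
        for protein in bundle.protein_list.proteins
    }
    if not any(tables.values()):
        raise DependencyError("no parsed result tables found; run the parse stage first")
    return tables


def _stage_qc(ws, bundle, report, taxonomy_dir):
    import matplotlib

    matplotlib.rcParams["svg.hashsalt"] = "taxoprofile"
    paths = _require_parsed(ws, bundle)
    ws.qc_dir.mkdir(exist_ok=True)
    by_protein: dict[str, list] = {}
    for protein, table_paths in paths.items():
        tables = [blast_io.read_result_table(p) for p in table_paths]
        by_protein[protein] = tables
        if tables:
            qc_filter.plot_length_histogram(
                tables,
                image_path=ws.qc_dir / f"{protein}_lengths.svg",
                table_path=ws.qc_dir / f"{protein}_lengths.tsv",
                title=f"{protein}: hit length distribution",
            )
            for table in tables:
                profile = qc_filter.coverage_profile(table)
                qc_filter.plot_coverage(
                    profile,
                    image_path=ws.qc_dir / f"{protein}.{table.seed_id}_coverage.svg",
                    table_path=ws.qc_dir / f"{protein}.{table.seed_id}_coverage.tsv",
                    title=f"{protein}/{table.seed_id}: coverage by e-value interval",
                )
    if len([p for p, t in by_protein.items() if t]) >= 2:
        matrix = qc_filter.cross_hit_matrix(
            {p: t for p, t in by_protein.items() if t}
        )
        matrix.write_csv(ws.root / "matrix.csv")
        logger.info("cross-hit matrix written to matrix.csv")
    else:
        logger.info("fewer than two proteins with hits; cross-hit check skipped")


def _stage_filter(ws, bundle, report, taxonomy_dir):
    paths = _require_parsed(ws, bundle)
    for protein, table_paths in paths.items():
        for path in table_paths:
            table = blast_io.read_result_table(path)
            filtered = qc_filter.apply_limits(table, bundle.limits)
            out = path.parent / (path.stem + ".filtered.tsv")
            blast_io.write_result_table(filtered, out)
            report.seed_counts[(protein, table.seed_id)] = {
                k: filtered.metadata[k]
                for k in ("parsed", "kept", "removed_by_evalue", "removed_by_length")
            }


def _stage_combine(ws, bundle, report, taxonomy_dir):
    db = _load_taxonomy(ws, taxonomy_dir)
    combined = []
    for protein in bundle.protein_list.proteins:
        paths = _filtered_tables(ws, protein)
        if not paths:
            raise DependencyError(
                f"no filtered tables for {protein!r}; run the filter stage first"
            )
        tables = [blast_io.read_result_table(p) for p in paths]
        table = combine_mod.combine_protein(tables, db)
        combined.append(table)
        combine_mod.write_combined_table(
            table, db, ws.combinedtables / f"{protein}.tsv"
        )
        report.organisms_per_protein[protein] = len(table.organism_set())
    per_protein, overall = combine_mod.unique_organisms(combined, db)
    combine_mod.write_listings(per_protein, overall, ws.combinedtables)
    report.overall_organisms = len(overall)


def _read_combined(ws, bundle, db) -> list[combine_mod.CombinedTable]:
    combined = []
    for protein in bundle.protein_list.proteins:
        path = ws.combinedtables / f"{protein}.tsv"
        if not path.exists():
            raise DependencyError(
                f"combined table for {protein!r} missing; run the combine stage first"
            )
        import pandas as pd

        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        records = [
            blast_io.HitRecord(
                protein=row["protein"],
                seed_id=row["seed_id"],
                subject_accession=row["subject_accession"],
                subject_taxid=int(row["subject_taxid"]),
                evalue=float(row["evalue"]),
                bitscore=float(row["bitscore"]),
                query_start=int(row["query_start"]),
                query_end=int(row["query_end"]),
                subject_length=int(row["subject_length"]),
            )
            for _, row in df.iterrows()
        ]
        organisms = [int(v) for v in df["organism_taxid"]] if len(df) else []
        best: dict[int, int] = {}
        for i, org in enumerate(organisms):
            if org not in best:
                best[org] = i
        combined.append(
            combine_mod.CombinedTable(
                protein=protein, records=records, organisms=organisms,
                best_by_organism=best,
            )
        )
    return combined


def _stage_heatmap(ws, bundle, report, taxonomy_dir):
    db = _load_taxonomy(ws, taxonomy_dir)
    combined = _read_combined(ws, bundle, db)
    config = bundle.heatmap
    if not config.organisms:
        union = sorted(set().union(*(t.organism_set() for t in combined)))
        config = HeatmapConfig(
            organisms=tuple(union), linkage=config.linkage,
            color=config.color, slider_default=config.slider_default,
        )
        logger.info("heatmap organisms defaulted to all %d hit organisms", len(union))
    matrix = heatmap_mod.build_score_matrix(combined, config, db)
    row_order, col_order, _, _ = heatmap_mod.cluster_axes(matrix, config.linkage)
    heatmap_mod.render_heatmap(
        matrix, (row_order, col_order), config, ws.root / "heatmap.html"
    )
    matrix.write_tsv(ws.root / "heatmap_scores.tsv")
    logger.info(
        "heatmap: %d organism(s) x %d protein(s), linkage=%s",
        len(matrix.names), len(matrix.proteins), config.linkage,
    )


_DEFAULT_COMBO_COLORS = (
    "#e41a1c", "#377eb8", "#4daf4a", "#984ea3", "#ff7f00", "#ffff33", "#a65628",
)


def _stage_tree(ws, bundle, report, taxonomy_dir):
    import matplotlib

    matplotlib.rcParams["svg.hashsalt"] = "taxoprofile"
    db = _load_taxonomy(ws, taxonomy_dir)
    combined = _read_combined(ws, bundle, db)
    by_protein = {t.protein: t for t in combined}
    tree_proteins = list(bundle.tree.proteins) or list(by_protein)[:3]
    ws.trees_dir.mkdir(exist_ok=True)

    def render(proteins: list[str], stub: str, colors: tuple[str, ...]):
        presence = {p: by_protein[p].organism_set() for p in proteins}
        if not any(presence.values()):
            logger.warning("no organisms for tree %s; skipped", stub)
            return
        annotated = tree_mod.annotate_tree(db, presence)
        pruned = tree_mod.prune_tree(annotated, bundle.prune)
        style = tree_mod.TreeStyle(colors=colors)
        tree_mod.render_tree(
            pruned, style,
            image_path=ws.trees_dir / f"tree_{stub}.svg",
            newick_path=ws.trees_dir / f"tree_{stub}.nwk",
            counts_path=ws.trees_dir / f"tree_{stub}.tsv",
            title=f"presence tree: {', '.join(proteins)}",
        )
        logger.info("tree %s: %d node(s)", stub, len(pruned.nodes))

    n = 2 ** len(tree_proteins) - 1
    colors = bundle.tree.colors or _DEFAULT_COMBO_COLORS[:n]
    if len(tree_proteins) > 1:
        render(tree_proteins, "combined", colors)
    for protein in tree_proteins:
        render([protein], protein, (colors[0],))


_STAGE_IMPLS = {
    "parse": _stage_parse,
    "qc": _stage_qc,
    "filter": _stage_filter,
    "combine": _stage_combine,
    "heatmap": _stage_heatmap,
    "tree": _stage_tree,
}
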