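"""Synthetic-data generation: miniature taxonomy dumps and BLAST XML2 documents.

The generator plants a known presence-absence structure (which organisms carry
which proteins, at which e-values and subject lengths) and emits the same file
formats the real pipeline consumes, so every stage can be tested end-to-end
against planted truth without any downloads. Only the *structure* of search
results is emulated — hit sequences are random amino-acid strings, not
evolved homologs.

A fixed random seed makes every emitted byte reproducible: the same
:class:`PresenceSpec` always produces identical taxonomy dumps and XML
documents.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .taxonomy import load_taxonomy, TaxonomyDB

__all__ = [
    "PresenceRule",
    "CladeSpec",
    "PresenceSpec",
    "make_taxonomy",
    "planted_presence",
    "make_blast_results",
    "write_workspace_fixture",
    "small_spec",
]

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


def _child_seed(base: int, *parts: str) -> int:
    """Stable sub-seed derived from a base seed and string labels (< 2^31)."""
    h = zlib.crc32("/".join(parts).encode()) & 0x7FFFFFFF
    return (base * 1_000_003 + h) % (2**31 - 1)


@dataclass(frozen=True)
class PresenceRule:
    """How one protein behaves within one clade.

    fraction: probability that a clade organism carries the protein.
    evalue_range: (low, high) bounds for log-uniform e-value sampling; the
        log-uniform draw lets any coverage-plot interval be populated.
    length_modes: mixture of (mean, sd, weight) normal components for the
        subject sequence length, so bimodal length histograms can be planted.
    hit_strains: report the hit under a strain-level taxid (when the organism
        has strains) to exercise species-level collapsing.
    """

    fraction: float = 1.0
    evalue_range: tuple[float, float] = (1e-120, 1e-40)
    length_modes: tuple[tuple[float, float, float], ...] = ((450.0, 40.0, 1.0),)
    hit_strains: bool = False

    def __post_init__(self):
        if not (0.0 <= self.fraction <= 1.0):
            raise ValueError(f"fraction {self.fraction} outside [0, 1]")
        lo, hi = self.evalue_range
        if not (0 < lo <= hi):
            raise ValueError(f"e-value range must be positive: {self.evalue_range}")


@dataclass(frozen=True)
class CladeSpec:
    """A named clade: one phylum with one genus holding the species."""

    name: str
    superkingdom: str
    n_species: int
    strains_per_species: int = 0


@dataclass
class PresenceSpec:
    """Full layout of a synthetic study: taxonomy plus per-protein presence."""

    clades: list[CladeSpec]
    proteins: dict[str, dict[str, PresenceRule]]
    seeds_per_protein: dict[str, list[str]] = field(default_factory=dict)
    query_length: int = 450
    seed: int = 42
    #: optionally plant one shared accession between two proteins
    cross_hit: tuple[str, str] | None = None
    cross_hit_evalues: tuple[float, float] = (1e-60, 1e-45)

    def __post_init__(self):
        if not self.clades:
            raise ValueError("at least one clade required")
        if any(c.n_species < 1 for c in self.clades) or not any(
            c.n_species > 0 for c in self.clades
        ):
            raise ValueError("every clade needs at least one organism")

    def seeds_for(self, protein: str) -> list[str]:
        return self.seeds_per_protein.get(protein, ["seed1"])


# -- taxonomy layout -------------------------------------------------------
#
# Taxids are assigned deterministically: root=1, superkingdoms from 2 up, then
# sequential ids for each clade's phylum, genus, species, and strains.

def _layout(spec: PresenceSpec):
    """Enumerate (taxid, parent, rank, name) rows plus species/strain maps."""
    rows = [(1, 1, "no rank", "root")]
    sk_ids: dict[str, int] = {}
    next_id = 2
    for clade in spec.clades:
        if clade.superkingdom not in sk_ids:
            sk_ids[clade.superkingdom] = next_id
            rows.append((next_id, 1, "superkingdom", clade.superkingdom))
            next_id += 1
    species_by_clade: dict[str, list[int]] = {}
    strains_by_species: dict[int, list[int]] = {}
    next_id = 10
    for clade in spec.clades:
        phylum = next_id
        rows.append((phylum, sk_ids[clade.superkingdom], "phylum", clade.name))
        genus = next_id + 1
        rows.append((genus, phylum, "genus", f"{clade.name} genus"))
        next_id += 2
        species_by_clade[clade.name] = []
        for j in range(clade.n_species):
            sp = next_id
            rows.append((sp, genus, "species", f"{clade.name} species {j + 1}"))
            species_by_clade[clade.name].append(sp)
            next_id += 1
            strains_by_species[sp] = []
            for k in range(clade.strains_per_species):
                st = next_id
                rows.append(
                    (st, sp, "no rank", f"{clade.name} species {j + 1} strain {k + 1}")
                )
                strains_by_species[sp].append(st)
                next_id += 1
    return rows, species_by_clade, strains_by_species


def make_taxonomy(spec: PresenceSpec) -> tuple[str, str]:
    """Emit (nodes_text, names_text) in the pipe-and-tab dump dialect."""
    rows, _, _ = _layout(spec)
    nodes = "".join(f"{t}\t|\t{p}\t|\t{r}\t|\n" for t, p, r, _ in rows)
    names = "".join(
        f"{t}\t|\t{n}\t|\t\t|\tscientific name\t|\n" for t, _, _, n in rows
    )
    return nodes, names


def taxonomy_db(spec: PresenceSpec) -> TaxonomyDB:
    """Convenience: the spec's taxonomy loaded into a store."""
    import io

    nodes, names = make_taxonomy(spec)
    return load_taxonomy(io.StringIO(nodes), io.StringIO(names))


def planted_presence(spec: PresenceSpec, protein: str) -> set[int]:
    """Ground-truth species taxids carrying *protein* under the spec's draw.

    The draw depends only on (seed, protein, clade), never on how many seeds
    are queried, so it is the reference for known-truth recovery tests.
    """
    rules = spec.proteins[protein]
    present: set[int] = set()
    _, species_by_clade, _ = _layout(spec)
    for clade in spec.clades:
        rule = rules.get(clade.name)
        if rule is None or rule.fraction == 0.0:
            continue
        rng = np.random.RandomState(_child_seed(spec.seed, "presence", protein, clade.name))
        draws = rng.random_sample(clade.n_species)
        for sp, u in zip(species_by_clade[clade.name], draws):
            if u < rule.fraction:
                present.add(sp)
    return present


# -- BLAST XML2 emission ---------------------------------------------------

_XML_HEADER = """<?xml version="1.0" encoding="UTF-8"?>
<BlastXML2
    xmlns="http://www.ncbi.nlm.nih.gov"
    xmlns:xs="http://www.w3.org/2001/XMLSchema-instance"
    xs:schemaLocation="http://www.ncbi.nlm.nih.gov http://www.ncbi.nlm.nih.gov/data_specs/schema_alt/NCBI_BlastOutput2.xsd"
>
<BlastOutput2>
  <report>
    <Report>
      <program>blastp</program>
      <version>BLASTP 2.17.0+</version>
      <search-target>
        <Target>
          <db>synthetic</db>
        </Target>
      </search-target>
      <params>
        <Parameters>
          <matrix>BLOSUM62</matrix>
          <expect>0.001</expect>
          <gap-open>11</gap-open>
          <gap-extend>1</gap-extend>
          <filter>F</filter>
        </Parameters>
      </params>
      <results>
        <Results>
          <search>
            <Search>
              <query-id>Query_1</query-id>
              <query-title>{seed_id} synthetic seed for {protein}</query-title>
              <query-len>{query_len}</query-len>
              <hits>
"""

_XML_FOOTER = """              </hits>
              <stat>
                <Statistics>
                  <db-num>1000</db-num>
                  <db-len>450000</db-len>
                  <hsp-len>120</hsp-len>
                  <eff-space>100000000</eff-space>
                  <kappa>0.041</kappa>
                  <lambda>0.267</lambda>
                  <entropy>0.14</entropy>
                </Statistics>
              </stat>
            </Search>
          </search>
        </Results>
      </results>
    </Report>
  </report>
</BlastOutput2>
</BlastXML2>
"""

_HIT_TEMPLATE = """                <Hit>
                  <num>{num}</num>
                  <description>
                    <HitDescr>
                      <id>{accession}</id>
                      <accession>{accession}</accession>
                      <title>synthetic subject {accession}</title>
                      <taxid>{taxid}</taxid>
                    </HitDescr>
                  </description>
                  <len>{subject_len}</len>
                  <hsps>
                    <Hsp>
                      <num>1</num>
                      <bit-score>{bitscore}</bit-score>
                      <score>{score}</score>
                      <evalue>{evalue}</evalue>
                      <identity>{alen}</identity>
                      <positive>{alen}</positive>
                      <query-from>{qfrom}</query-from>
                      <query-to>{qto}</query-to>
                      <hit-from>1</hit-from>
                      <hit-to>{alen}</hit-to>
                      <align-len>{alen}</align-len>
                      <gaps>0</gaps>
                      <qseq>{qseq}</qseq>
                      <hseq>{hseq}</hseq>
                      <midline>{midline}</midline>
                    </Hsp>
                  </hsps>
                </Hit>
"""


def _random_protein(rng: np.random.RandomState, length: int) -> str:
    return "".join(rng.choice(_AA, size=length))


def accession_for(taxid: int, protein: str) -> str:
    """Deterministic synthetic accession for an organism/protein pair."""
    tag = "".join(ch for ch in protein.upper() if ch.isalnum())
    return f"SYN{taxid:05d}{tag}"


def _draw_hits(spec: PresenceSpec, protein: str, seed_id: str):
    """One planned hit per present organism: (taxid, accession, evalue, length)."""
    _, species_by_clade, strains_by_species = _layout(spec)
    present = planted_presence(spec, protein)
    hits = []
    for clade in spec.clades:
        rule = spec.proteins[protein].get(clade.name)
        if rule is None:
            continue
        rng = np.random.RandomState(
            _child_seed(spec.seed, "hits", protein, seed_id, clade.name)
        )
        for sp in species_by_clade[clade.name]:
            if sp not in present:
                continue
            lo, hi = rule.evalue_range
            u = rng.random_sample()
            evalue = 10 ** (np.log10(lo) + u * (np.log10(hi) - np.log10(lo)))
            weights = np.array([w for _, _, w in rule.length_modes], dtype=float)
            mode = rng.choice(len(weights), p=weights / weights.sum())
            mean, sd, _ = rule.length_modes[mode]
            length = max(30, int(round(rng.normal(mean, sd))))
            taxid = sp
            if rule.hit_strains and strains_by_species.get(sp):
                taxid = strains_by_species[sp][0]
            hits.append((taxid, accession_for(sp, protein), float(evalue), length))
    return hits


def make_blast_results(spec: PresenceSpec, protein: str, seed_id: str) -> str:
    """Emit one synthetic single-query BLAST XML2 document as text."""
    if protein not in spec.proteins:
        raise ValueError(f"protein {protein!r} has no presence rules")
    qlen = spec.query_length
    hits = _draw_hits(spec, protein, seed_id)
    if spec.cross_hit and protein in spec.cross_hit:
        # planted shared accession between the two cross-hit proteins
        first_clade = spec.clades[0]
        _, species_by_clade, _ = _layout(spec)
        taxid = species_by_clade[first_clade.name][0]
        idx = spec.cross_hit.index(protein)
        hits.append(
            (taxid, "XHIT00001", spec.cross_hit_evalues[idx], spec.query_length)
        )
    hits.sort(key=lambda h: (h[2], h[1]))  # ascending e-value like real BLAST
    rng = np.random.RandomState(_child_seed(spec.seed, "seqs", protein, seed_id))
    chunks = [
        _XML_HEADER.format(seed_id=seed_id, protein=protein, query_len=qlen)
    ]
    for num, (taxid, accession, evalue, length) in enumerate(hits, start=1):
        alen = min(qlen, length)
        qfrom = 1 + int(rng.randint(0, qlen - alen + 1))
        qto = qfrom + alen - 1
        hseq = _random_protein(rng, alen)
        qseq = _random_protein(rng, alen)
        bitscore = round(max(25.0, -0.7 * np.log10(max(evalue, 1e-300)) * 10 / 3), 4)
        chunks.append(
            _HIT_TEMPLATE.format(
                num=num,
                accession=accession,
                taxid=taxid,
                subject_len=length,
                bitscore=bitscore,
                score=int(bitscore * 2),
                evalue=f"{evalue:.6e}",
                alen=alen,
                qfrom=qfrom,
                qto=qto,
                qseq=qseq,
                hseq=hseq,
                midline=" " * alen,
            )
        )
    chunks.append(_XML_FOOTER)
    return "".join(chunks)


def small_spec(seed: int = 42) -> PresenceSpec:
    """A 12-node, two-superkingdom taxonomy with three proteins.

    Node count: 1 root + 2 superkingdoms + 2 phyla + 2 genera + (3 + 2)
    species = 12. Protein presences are planted with fraction 1 or 0 so
    every downstream count is enumerable by hand.
    """
    clades = [
        CladeSpec("Alphabacteria", "Bacteria", n_species=3),
        CladeSpec("Betamycota", "Eukaryota", n_species=2),
    ]
    proteins = {
        "protA": {
            "Alphabacteria": PresenceRule(fraction=1.0),
            "Betamycota": PresenceRule(fraction=1.0),
        },
        "protB": {"Alphabacteria": PresenceRule(fraction=1.0)},
        "protC": {"Betamycota": PresenceRule(fraction=1.0)},
    }
    return PresenceSpec(clades=clades, proteins=proteins, seed=seed)


def write_workspace_fixture(spec: PresenceSpec, root: str | Path) -> Path:
    """Materialise a complete, runnable workspace for the spec.

    Initialises the folder structure, then writes the taxonomy dump, one
    multi-record seed FASTA per protein, one XML2 result file per
    (protein, seed) and a filled-in proteinlist.txt. Config templates keep
    their documented defaults; the heatmap organism selection is set to all
    species so the full planted structure is visible.
    """
    from .workspace import init_workspace

    root = Path(root)
    ws = init_workspace(root)
    tax_dir = root / "taxonomy"
    tax_dir.mkdir(exist_ok=True)
    nodes, names = make_taxonomy(spec)
    (tax_dir / "nodes.dmp").write_text(nodes)
    (tax_dir / "names.dmp").write_text(names)

    rows, species_by_clade, _ = _layout(spec)
    species_names = [
        name for _, _, rank, name in rows if rank == "species"
    ]

    proteinlist_lines = []
    for protein in spec.proteins:
        rng = np.random.RandomState(_child_seed(spec.seed, "seedfasta", protein))
        fasta_name = f"{protein}.fa"
        with open(root / "fastas" / fasta_name, "w") as fh:
            for seed_id in spec.seeds_for(protein):
                fh.write(f">{seed_id} synthetic seed for {protein}\n")
                fh.write(_random_protein(rng, spec.query_length) + "\n")
        proteinlist_lines.append(f"{protein}\t{fasta_name}")
        for seed_id in spec.seeds_for(protein):
            xml = make_blast_results(spec, protein, seed_id)
            (root / "blastresults" / f"{protein}.{seed_id}.xml").write_text(xml)

    (root / "proteinlist.txt").write_text("\n".join(proteinlist_lines) + "\n")
    (root / "heatmap_config.txt").write_text(
        "# synthetic fixture heatmap settings\n"
        "linkage = centroid\n"
        "slider_default = 30\n"
        "organisms = " + ", ".join(species_names) + "\n"
    )
    tree_proteins = list(spec.proteins)[:3]
    colors = ["#1b9e77", "#d95f02", "#7570b3", "#e7298a", "#66a61e", "#e6ab02", "#a6761d"]
    n_colors = 2 ** len(tree_proteins) - 1
    (root / "tree_config.txt").write_text(
        "# synthetic fixture tree settings\n"
        "proteins = " + ", ".join(tree_proteins) + "\n"
        "colors = " + ", ".join(colors[:n_colors]) + "\n"
    )
    return root
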