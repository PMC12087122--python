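import io

import pytest
from hypothesis import settings

from taxoprofile import fixtures as fx
from taxoprofile import load_taxonomy
from taxoprofile.blast_io import HitRecord, ResultTable

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_spec():
    """Two superkingdoms, 12 taxonomy nodes, three fully-planted proteins."""
    return fx.small_spec(seed=42)


@pytest.fixture(scope="session")
def small_db(small_spec):
    nodes, names = fx.make_taxonomy(small_spec)
    return load_taxonomy(io.StringIO(nodes), io.StringIO(names))


@pytest.fixture(scope="session")
def strain_spec():
    """One clade whose species each carry a strain; hits land on strains."""
    clades = [
        fx.CladeSpec("Gammaphyta", "Bacteria", n_species=2, strains_per_species=1),
        fx.CladeSpec("Deltamonada", "Eukaryota", n_species=2),
    ]
    proteins = {
        "protX": {
            "Gammaphyta": fx.PresenceRule(fraction=1.0, hit_strains=True),
            "Deltamonada": fx.PresenceRule(fraction=1.0),
        },
    }
    return fx.PresenceSpec(clades=clades, proteins=proteins, seed=7)


@pytest.fixture(scope="session")
def strain_db(strain_spec):
    nodes, names = fx.make_taxonomy(strain_spec)
    return load_taxonomy(io.StringIO(nodes), io.StringIO(names))


def make_record(**kwargs) -> HitRecord:
    """HitRecord with sensible defaults, overridable per test."""
    defaults = dict(
        protein="protA",
        seed_id="seed1",
        subject_accession="ACC00001",
        subject_taxid=12,
        evalue=1e-50,
        bitscore=120.0,
        query_start=1,
        query_end=100,
        subject_length=400,
        aligned_subject_seq="",
    )
    defaults.update(kwargs)
    return HitRecord(**defaults)


def make_table(records, protein="protA", seed_id="seed1", seed_length=450):
    return ResultTable(
        protein=protein, seed_id=seed_id, seed_length=seed_length,
        records=list(records),
    )


def build_xml(hits, query_len=450, protein="protA", seed_id="seed1"):
    """Craft a BLAST XML2 document from (accession, taxid, evalue, bitscore,
    qfrom, qto, subject_len, hseq) tuples; taxid None omits the taxid tag."""
    chunks = [fx._XML_HEADER.format(seed_id=seed_id, protein=protein,
                                    query_len=query_len)]
    for num, (acc, taxid, evalue, bitscore, qfrom, qto, slen, hseq) in enumerate(
        hits, start=1
    ):
        hit = fx._HIT_TEMPLATE.format(
            num=num, accession=acc, taxid=taxid if taxid is not None else 0,
            subject_len=slen, bitscore=bitscore, score=int(bitscore * 2),
            evalue=f"{evalue:.6e}", alen=qto - qfrom + 1, qfrom=qfrom, qto=qto,
            qseq="A" * (qto - qfrom + 1), hseq=hseq,
            midline=" " * (qto - qfrom + 1),
        )
        if taxid is None:
            hit = hit.replace(f"<taxid>0</taxid>\n                    ", "")
        chunks.append(hit)
    chunks.append(fx._XML_FOOTER)
    return "".join(chunks)


def parse_xml_text(text, protein="protA"):
    from taxoprofile import parse_blast_xml

    return parse_blast_xml(io.BytesIO(text.encode()), protein)
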