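"""Formats, genetic codes and coordinate conventions."""

import pytest
from hypothesis import given, settings, strategies as st

from organnot.seq_io import (
    AnnotationDoc,
    Contig,
    FastaError,
    Feature,
    GeneticCodeError,
    MasterfileError,
    load_genetic_code,
    parse_masterfile,
    read_fasta,
    read_gff3,
    revcomp,
    write_feature_table,
    write_gff3,
    write_masterfile,
)

# Published NCBI translation tables, frozen here as independent fixtures:
# 64-character amino-acid strings in TTT-first codon order plus start strings
# (M marks a start codon).  Transcribed from the NCBI genetic-code listing.
_BASES = "TCAG"
_CODON_ORDER = [a + b + c for a in _BASES for b in _BASES for c in _BASES]
NCBI_TABLES = {
    1: ("FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG",
        "---M------**--*----M---------------M----------------------------"),
    4: ("FFLLSSSSYY**CCWWLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG",
        "--MM------**-------M------------MMMM---------------M------------"),
    5: ("FFLLSSSSYY**CCWWLLLLPPPPHHQQRRRRIIMMTTTTNNKKSSSSVVVVAAAADDEEGGGG",
        "---M------**--------------------MMMM---------------M------------"),
    11: ("FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG",
         "---M------**--*----M------------MMMM---------------M------------"),
}


@pytest.mark.parametrize("table_id", sorted(NCBI_TABLES))
def test_genetic_code_matches_published_ncbi_table(table_id):
    aa_line, start_line = NCBI_TABLES[table_id]
    gc = load_genetic_code(table_id)
    for codon, aa, s in zip(_CODON_ORDER, aa_line, start_line):
        assert gc.codon_map[codon] == aa, (table_id, codon)
        if s == "M":
            assert gc.is_start(codon), (table_id, codon)


def test_genetic_code_stop_reassignment():
    assert load_genetic_code(1).codon_map["TGA"] == "*"
    assert load_genetic_code(4).codon_map["TGA"] == "W"


def test_custom_code_requires_64_entries():
    gc1 = load_genetic_code(1)
    partial = dict(gc1.codon_map)
    del partial["AAA"]
    with pytest.raises(GeneticCodeError):
        load_genetic_code(partial)
    with pytest.raises(GeneticCodeError):
        load_genetic_code({**gc1.codon_map, "AAA": "!"})
    custom = load_genetic_code(dict(gc1.codon_map), start_codons=["GTG"])
    assert custom.start_codons == ("GTG",)


def test_n_codons_translate_to_x_and_are_never_start_or_stop(code1):
    assert code1.translate_codon("ANA") == "X"
    assert not code1.is_start("ATN") and not code1.is_stop("TNA")


def test_read_fasta_folds_case_and_u_and_reads_topology():
    contigs = read_fasta(">c1 circular\nacgu\n>b\nGGCC\n")
    assert contigs[0].seq == "ACGT" and contigs[0].topology == "circular"
    assert contigs[1].id == "b" and contigs[1].topology == "linear"


def test_read_fasta_rejects_illegal_characters_with_position():
    with pytest.raises(FastaError, match="position 3"):
        read_fasta(">c\nAC!T\n")
    with pytest.raises(FastaError):
        read_fasta("")


@pytest.fixture()
def two_gene_doc():
    contig = Contig("c1", "ACGT" * 60)
    return AnnotationDoc(contig, [
        Feature("CDS", "cox1", "+", [(9, 60), (99, 150)],
                {"product": 'oxidase "1"'}, ["frameshift flagged"]),
        Feature("tRNA", "trnM", "-", [(179, 190)]),
    ]).validate()


def test_masterfile_round_trip_and_layout(two_gene_doc):
    text = write_masterfile(two_gene_doc)
    # the start comment precedes the sequence line containing position 10
    lines = text.splitlines()
    start_idx = next(i for i, l in enumerate(lines) if l.startswith("; >>> cox1"))
    assert lines[start_idx + 2].lstrip().startswith(";") or "1  " in lines[start_idx + 2]
    assert any("frameshift flagged" in l for l in lines if l.startswith(";"))
    doc2 = parse_masterfile(text)
    assert doc2.contig.seq == two_gene_doc.contig.seq
    assert [(f.kind, f.gene, f.strand, f.exons, f.qualifiers, f.comments)
            for f in doc2.features] == \
           [(f.kind, f.gene, f.strand, f.exons, f.qualifiers, f.comments)
            for f in two_gene_doc.features]


def test_masterfile_orphan_end_marker_rejected(two_gene_doc):
    text = write_masterfile(two_gene_doc)
    with pytest.raises(MasterfileError, match="without start"):
        parse_masterfile(text.replace("; <<< cox1", "; <<< ghost"))


def test_feature_table_dialect(two_gene_doc):
    tbl = write_feature_table(two_gene_doc)
    lines = tbl.splitlines()
    assert lines[0] == ">Feature c1"
    assert "10\t60\tCDS" in lines       # key on first exon, 1-based inclusive
    assert "100\t150" in lines          # continuation exon without key
    assert "190\t180\ttRNA" in lines    # reverse strand written end < start
    assert any(l == "\t\t\tgene\tcox1" for l in lines)
    assert any("note\tframeshift flagged" in l for l in lines)


def test_gff3_round_trip_and_coordinate_agreement(two_gene_doc):
    gff = write_gff3(two_gene_doc)
    doc2 = read_gff3(gff, two_gene_doc.contig)
    assert [(f.kind, f.gene, f.strand, f.exons) for f in doc2.features] == \
           [(f.kind, f.gene, f.strand, f.exons) for f in two_gene_doc.features]
    # all writers agree on 1-based inclusive spans
    tbl = write_feature_table(two_gene_doc)
    assert "10\t60\tCDS" in tbl
    assert "\tgene\t10\t150\t" in gff.replace("organnot", "\t".join(["organnot"]))


feature_strategy = st.builds(
    lambda kind, gene, strand, starts, lens, qual, comments: Feature(
        kind=kind, gene=gene, strand=strand,
        exons=sorted(
            [(s, s + l) for s, l in zip(starts, lens)],
            reverse=strand == "-",
        ),
        qualifiers=qual, comments=comments,
    ),
    kind=st.sampled_from(["CDS", "tRNA", "rRNA", "ncRNA"]),
    gene=st.from_regex(r"[a-z][a-z0-9]{1,6}", fullmatch=True),
    strand=st.sampled_from("+-"),
    starts=st.lists(st.integers(0, 50), min_size=1, max_size=3, unique=True),
    lens=st.lists(st.integers(1, 5), min_size=3, max_size=3),
    qual=st.dictionaries(st.sampled_from(["product", "note"]),
                         st.text(alphabet="abc \"\\", max_size=8), max_size=2),
    comments=st.lists(st.text(alphabet="abc d", min_size=1, max_size=10).map(str.strip)
                      .filter(bool), max_size=2),
)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.lists(feature_strategy, max_size=4))
def test_masterfile_and_gff3_round_trips_are_lossless(features):
    # exons may touch between features; spans stay within the contig
    fixed = []
    for f in features:
        spans = sorted((s * 3, s * 3 + 3 * (e - s)) for s, e in f.exons)
        merged = [spans[0]]
        for s, e in spans[1:]:
            if s < merged[-1][1]:
                continue
            merged.append((s, e))
        fixed.append(Feature(f.kind, f.gene, f.strand,
                             sorted(merged, reverse=f.strand == "-"),
                             f.qualifiers, f.comments))
    doc = AnnotationDoc(Contig("z", "ACGT" * 60), fixed).validate()

    def key(f):
        return (f.kind, f.gene, f.strand, tuple(f.exons),
                tuple(sorted(f.qualifiers.items())), tuple(f.comments))

    # both dialects are position-ordered, so compare as multisets
    rt_master = parse_masterfile(write_masterfile(doc))
    assert sorted(map(key, rt_master.features)) == sorted(map(key, doc.features))
    rt_gff = read_gff3(write_gff3(doc), doc.contig)
    assert sorted((f.kind, f.gene, f.strand, tuple(f.exons)) for f in rt_gff.features) \
        == sorted((f.kind, f.gene, f.strand, tuple(f.exons)) for f in doc.features)


def test_wrapped_feature_split_by_writers():
    contig = Contig("c", "ACGT" * 30, topology="circular")
    doc = AnnotationDoc(contig, [Feature("CDS", "wrap", "+", [(110, 130)])]).validate()
    tbl = write_feature_table(doc)
    assert "111\t120\tCDS" in tbl and "1\t10" in tbl
    assert any("wraps origin" in line for line in tbl.splitlines())


def test_revcomp():
    assert revcomp("ACGTN") == "NACGT"
    assert revcomp(revcomp("GATTACA")) == "GATTACA"
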