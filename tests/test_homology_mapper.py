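"""ORF-to-reference search, locus calling and pathology flags."""

import numpy as np
import pytest

import organnot.homology_mapper as hm
import organnot.synth_genome as sg
from organnot.orf_translate import extract_orfs
from organnot.seq_io import Contig, revcomp


@pytest.fixture(scope="module")
def refs():
    return hm.parse_reference_fasta(sg.reference_protein_fasta())


def make_orf(seq, start=0, strand="+", contig_len=None):
    from organnot.orf_translate import Orf
    end = start + 3 * len(seq)
    return Orf("c", strand, start % 3, start, end, seq)


def test_reference_fasta_header_parsing(refs):
    assert refs[0].gene == "cox1" and refs[0].id == "cox1_a"
    tagged = hm.parse_reference_fasta(">pol|pol_1 plasmid-origin polymerase\nMKLW\n")
    assert tagged[0].tags == ("plasmid-origin",)


def test_identity_orf_gives_full_coverage(refs):
    ref = refs[0]
    orf = make_orf(ref.seq)
    hits = hm.search_orfs([orf], [ref])
    assert len(hits) == 1
    assert hits[0].coverage == pytest.approx(100.0)
    loci = hm.cluster_loci(hits)
    hm.call_full_genes(loci)
    assert loci[0].status == "full"


def test_partial_orf_coverage_and_status(refs):
    ref = refs[0]
    orf = make_orf(ref.seq[:40])
    hits = hm.search_orfs([orf], [ref])
    assert hits and hits[0].coverage == pytest.approx(100 * 40 / len(ref.seq), abs=1.0)
    loci = hm.call_full_genes(hm.cluster_loci(hits))
    assert loci[0].status == "partial"


def test_scrambled_orf_scores_below_threshold(refs, rng):
    ref = refs[0]
    scrambled = "".join(rng.permutation(list(ref.seq)))
    assert hm.search_orfs([make_orf(scrambled)], [ref]) == []


def test_search_requires_references(refs):
    with pytest.raises(ValueError):
        hm.search_orfs([], [])


def test_opposite_strand_genes_called_with_correct_strands(code4, refs):
    rng = np.random.default_rng(2)
    cds1 = sg.back_translate(sg.make_protein_family("atp6", 160)[0], code4, rng)
    cds2 = sg.back_translate(sg.make_protein_family("rps3", 140)[0], code4, rng)
    seq = sg.random_dna(rng, 300) + cds1 + sg.random_dna(rng, 300) + revcomp(cds2) + sg.random_dna(rng, 300)
    contig = Contig("c", seq)
    orfs = extract_orfs(contig, code4, 40)
    loci = hm.call_full_genes(hm.cluster_loci(hm.search_orfs(orfs, refs)))
    by_gene = {l.gene: l for l in loci}
    assert by_gene["atp6"].strand == "+" and by_gene["rps3"].strand == "-"


def test_reverse_complement_yields_mirrored_loci(code4, refs):
    contig, _ = sg.generate(sg.default_genome_spec(seed=4))
    n = len(contig)

    def loci_of(c):
        orfs = extract_orfs(c, code4, 40)
        loci = hm.cluster_loci(hm.search_orfs(orfs, refs))
        hm.call_full_genes(loci)
        return {(l.gene, l.status) for l in loci}, \
               {(l.gene, l.strand, l.start, l.end) for l in loci}

    st_f, sp_f = loci_of(contig)
    st_r, sp_r = loci_of(Contig(contig.id, revcomp(contig.seq)))
    assert st_f == st_r
    mirrored = {(g, "+" if s == "-" else "-", n - e, n - a)
                for g, s, a, e in sp_r}
    assert sp_f == mirrored


def test_frameshift_mutant_is_flagged_never_repaired(code4, refs):
    rng = np.random.default_rng(7)
    cds = sg.back_translate(sg.make_protein_family("cox1", 320)[0], code4, rng)
    mid = len(cds) // 2
    broken = cds[:mid] + cds[mid + 1 :]  # 1-nt deletion
    contig = Contig("c", sg.random_dna(rng, 200) + broken + sg.random_dna(rng, 200))
    orfs = extract_orfs(contig, code4, 40)
    loci = hm.flag_frameshift(hm.cluster_loci(hm.search_orfs(orfs, refs)))
    cox = [l for l in loci if l.gene == "cox1"][0]
    assert cox.status == "frameshift-suspect"
    assert any("not repaired" in c for c in cox.comments)


def test_intact_gene_not_flagged_as_frameshift(code4, refs):
    rng = np.random.default_rng(8)
    cds = sg.back_translate(sg.make_protein_family("cox1", 320)[0], code4, rng)
    contig = Contig("c", sg.random_dna(rng, 200) + cds + sg.random_dna(rng, 200))
    orfs = extract_orfs(contig, code4, 40)
    loci = hm.flag_frameshift(hm.cluster_loci(hm.search_orfs(orfs, refs)))
    assert [l for l in loci if l.gene == "cox1"][0].status != "frameshift-suspect"


def test_distant_same_frame_partials_are_intron_candidates_not_frameshift(code4, refs):
    rng = np.random.default_rng(9)
    prot = sg.make_protein_family("cob", 260)[0]
    cds = sg.back_translate(prot, code4, rng)
    # split by a 2 kb spacer, same frame (spacer length multiple of 3)
    contig = Contig("c", sg.random_dna(rng, 150) + cds[:390]
                    + sg.random_dna(rng, 2001) + cds[390:] + sg.random_dna(rng, 150))
    orfs = extract_orfs(contig, code4, 40)
    loci = hm.cluster_loci(hm.search_orfs(orfs, refs))
    hm.flag_frameshift(loci)
    hm.flag_trans_splicing(loci)
    cob = [l for l in loci if l.gene == "cob"]
    assert len(cob) == 1 and cob[0].status == "partial"  # cis-intron candidate


def test_trans_splice_flag_for_opposite_strand_halves(code4, refs):
    rng = np.random.default_rng(10)
    prot = sg.make_protein_family("nad5", 290)[0]
    half = len(prot) // 2
    c1 = sg.back_translate(prot[:half], code4, rng)
    c2 = sg.back_translate(prot[half:], code4, rng)
    contig = Contig("c", sg.random_dna(rng, 150) + c1 + sg.random_dna(rng, 1000)
                    + revcomp(c2) + sg.random_dna(rng, 150))
    orfs = extract_orfs(contig, code4, 40)
    loci = hm.cluster_loci(hm.search_orfs(orfs, refs))
    hm.flag_trans_splicing(loci)
    nad5 = [l for l in loci if l.gene == "nad5"]
    assert len(nad5) == 2
    assert all(l.status == "trans-splice-suspect" for l in nad5)
    assert any("different strands" in c for l in nad5 for c in l.comments)


def test_trans_splice_flag_for_multi_contig_halves(code4, refs):
    rng = np.random.default_rng(11)
    prot = sg.make_protein_family("nad5", 290)[0]
    half = len(prot) // 2
    all_loci = []
    for i, piece in enumerate((prot[:half], prot[half:])):
        cds = sg.back_translate(piece, code4, rng)
        contig = Contig(f"c{i}", sg.random_dna(rng, 120) + cds + sg.random_dna(rng, 120))
        orfs = extract_orfs(contig, code4, 40)
        all_loci.extend(hm.cluster_loci(hm.search_orfs(orfs, refs)))
    hm.flag_trans_splicing(all_loci)
    nad5 = [l for l in all_loci if l.gene == "nad5"]
    assert len(nad5) == 2 and all(l.status == "trans-splice-suspect" for l in nad5)
    assert any("different contigs" in c for l in nad5 for c in l.comments)


def test_nearby_same_strand_partials_not_trans_splice(code4, refs):
    rng = np.random.default_rng(12)
    prot = sg.make_protein_family("cob", 260)[0]
    cds = sg.back_translate(prot, code4, rng)
    contig = Contig("c", sg.random_dna(rng, 150) + cds[:390]
                    + sg.random_dna(rng, 5000) + cds[390:] + sg.random_dna(rng, 150))
    orfs = extract_orfs(contig, code4, 40)
    loci = hm.flag_trans_splicing(hm.cluster_loci(hm.search_orfs(orfs, refs)))
    assert all(l.status != "trans-splice-suspect" for l in loci if l.gene == "cob")


def test_sw_calibration_gumbel(refs):
    calib = hm.calibrate_sw(refs[0], n_samples=100, seed=1)
    mu, lam = calib
    assert lam > 0
    # identical query scores far beyond the null location
    aligner = hm.make_aligner()
    assert aligner.score(refs[0].seq, refs[0].seq) > mu + 10 / lam
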