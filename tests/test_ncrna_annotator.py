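"""tRNA, rRNA and structured ncRNA detection."""

import numpy as np
import pytest

import organnot.synth_genome as sg
from organnot.ncrna_annotator import (
    RrnaModel,
    find_rrna,
    find_trnas,
    load_structure_profile,
    predict_codon_read,
    refine_rnl_termini,
    search_structure,
)
from organnot.profile_hmm import build_profile
from organnot.seq_io import Contig, revcomp


@pytest.fixture(scope="module")
def rnl_model():
    prof = build_profile(sg.make_rna_family("rnl", 300), name="rnl", alphabet="nt")
    return RrnaModel("rnl", prof, flank5=120, flank3=120, terminus_uncertainty=50)


@pytest.fixture(scope="module")
def rns_model():
    prof = build_profile(sg.make_rna_family("rns", 250), name="rns", alphabet="nt")
    return RrnaModel("rns", prof)


# ---------------------------------------------------------------------------
# tRNAs
# ---------------------------------------------------------------------------


def test_planted_trna_identity_under_table4(code4, rng):
    seq, _ = sg.make_trna(rng, "CAT", 7)
    genome = sg.random_dna(rng, 800) + seq + sg.random_dna(rng, 800)
    calls = find_trnas(Contig("g", genome), code4)
    assert len(calls) == 1
    c = calls[0]
    assert (c.start, c.end) == (800, 800 + len(seq))
    assert c.anticodon == "CAT" and c.amino_acid == "M" and c.loop_len == 7
    assert genome[c.anticodon_span[0] : c.anticodon_span[1]] == "CAT"


def test_eight_nt_anticodon_loop_detected_and_flagged(code4, rng):
    seq, _ = sg.make_trna(rng, "TAG", 8)
    genome = sg.random_dna(rng, 600) + seq + sg.random_dna(rng, 600)
    calls = find_trnas(Contig("g", genome), code4)
    assert len(calls) == 1
    c = calls[0]
    assert c.loop_len == 8
    assert any("unusual anticodon loop" in m for m in c.comments)
    # the identity stays the supplied-code translation (here Leu); any
    # reassignment is the caller's responsibility via a custom code
    assert c.amino_acid == "L"


def test_identity_always_translation_of_reverse_complemented_anticodon(code4, rng):
    for ac in ("CAT", "GAA", "TTC", "TGG"):
        seq, _ = sg.make_trna(rng, ac, 7)
        genome = sg.random_dna(rng, 400) + seq + sg.random_dna(rng, 400)
        for c in find_trnas(Contig("g", genome), code4):
            assert c.amino_acid == code4.translate_codon(revcomp(c.anticodon))


def test_acceptor_stem_identity_elements_are_ignored(code4, rng):
    """A planted G3:U70-style alanine determinant must not change the
    reported identity: only the anticodon and the supplied code decide."""
    seq, _ = sg.make_trna(rng, "CAT", 7)
    # force a G at acceptor position 3 and T at its pairing partner (70)
    s = list(seq)
    s[2] = "G"
    s[-2 - 2] = "T"  # acceptor 3' stem mirror of position 3, before NCCA end
    genome = sg.random_dna(rng, 500) + "".join(s) + sg.random_dna(rng, 500)
    calls = find_trnas(Contig("g", genome), code4)
    if calls:  # the weakened stem may or may not still pass the pair minima
        assert all(c.amino_acid == "M" for c in calls if c.anticodon == "CAT")


def test_trna_reverse_complement_symmetry(code4, rng):
    seq, _ = sg.make_trna(rng, "GAA", 7)
    genome = sg.random_dna(rng, 700) + seq + sg.random_dna(rng, 700)
    n = len(genome)
    fw = find_trnas(Contig("g", genome), code4)
    rc = find_trnas(Contig("g", revcomp(genome)), code4)
    assert sorted((n - c.end, n - c.start, c.anticodon) for c in rc) == \
        sorted((c.start, c.end, c.anticodon) for c in fw)


def test_no_trna_calls_on_random_sequence(code4):
    hits = 0
    for seed in range(100):
        r = np.random.default_rng(5000 + seed)
        g = Contig("x", "".join(r.choice(list("ACGT"), size=2000)))
        if find_trnas(g, code4):
            hits += 1
    assert hits <= 5  # >= 95% of draws are clean


@pytest.mark.parametrize("anticodon,mode,expected", [
    ("UAC", "superwobble", {"GUA", "GUG", "GUU", "GUC"}),
    ("GAA", "standard", {"UUC", "UUU"}),
    ("CAU", "standard", {"AUG"}),
    ("UAC", "standard", {"GUA", "GUG"}),
])
def test_wobble_rules(anticodon, mode, expected):
    assert predict_codon_read(anticodon, mode) == expected


def test_wobble_rejects_bad_input():
    with pytest.raises(ValueError):
        predict_codon_read("AC")
    with pytest.raises(ValueError):
        predict_codon_read("UAC", "sideways")


# ---------------------------------------------------------------------------
# rRNAs
# ---------------------------------------------------------------------------


def test_rns_termini_exact(rns_model, rng):
    gene = sg.make_rns(rng)
    genome = sg.random_dna(rng, 700) + gene + sg.random_dna(rng, 700)
    call, introns = find_rrna(Contig("g", genome), rns_model)
    assert (call.start, call.end) == (700, 700 + len(gene))
    assert call.uncertainty5 == 0 and not introns


def test_rnl_termini_within_50_then_refined_to_helix(rnl_model, rng):
    gene, core_off, core_len = sg.make_rnl(rng)
    genome = sg.random_dna(rng, 600) + gene + sg.random_dna(rng, 600)
    truth = (600, 600 + len(gene))
    contig = Contig("g", genome)
    rough, _ = find_rrna(contig, rnl_model)
    assert abs(rough.start - truth[0]) <= 50 and abs(rough.end - truth[1]) <= 50
    assert rough.uncertainty5 == 50
    refined = refine_rnl_termini(contig, rough)
    assert abs(refined.start - truth[0]) <= 3 and abs(refined.end - truth[1]) <= 3
    assert refined.uncertainty5 == 3


def test_rnl_refinement_no_op_without_helix(rnl_model, rng):
    core = sg.make_rna_family("rnl", 300)[0]
    gene = sg.random_dna(rng, 120, gc=0.0) + core + sg.random_dna(rng, 120, gc=0.0)
    # all-AT flanks of identical composition cannot form a >=6 bp GC-anchored
    # duplex scoring above threshold... they can pair A-T; build unpairable
    gene = "A" * 120 + core + "A" * 120
    genome = "C" * 300 + gene + "C" * 300
    contig = Contig("g", genome)
    rough, _ = find_rrna(contig, rnl_model)
    out = refine_rnl_termini(contig, rough)
    assert (out.start, out.end) == (rough.start, rough.end)
    assert out.uncertainty5 == 50
    assert any("no terminal helix" in c for c in out.comments)


def test_rnl_minus_strand(rnl_model, rng):
    gene, *_ = sg.make_rnl(rng)
    genome = sg.random_dna(rng, 500) + gene + sg.random_dna(rng, 500)
    truth = (500, 500 + len(gene))
    n = len(genome)
    contig = Contig("g", revcomp(genome))
    call, _ = find_rrna(contig, rnl_model)
    refined = refine_rnl_termini(contig, call)
    assert refined.strand == "-"
    assert abs((n - refined.end) - truth[0]) <= 3
    assert abs((n - refined.start) - truth[1]) <= 3


def test_rnl_with_intron_reported_without_exon_model(rnl_model, splice_models, rng):
    gene, core_off, core_len = sg.make_rnl(rng)
    intron = sg.make_group2_intron(rng, 300)
    split = gene[: core_off + 150] + intron + gene[core_off + 150 :]
    genome = sg.random_dna(rng, 500) + split + sg.random_dna(rng, 500)
    call, introns = find_rrna(Contig("g", genome), rnl_model,
                              intron_models=splice_models)
    assert "intron present; exon model not inferred" in call.comments
    assert abs(call.start - 500) <= 50 and abs(call.end - (500 + len(split))) <= 50
    itruth = (500 + core_off + 150, 500 + core_off + 150 + 300)
    assert introns and introns[0].group == "II"
    assert abs(introns[0].start - itruth[0]) <= 6
    assert abs(introns[0].end - itruth[1]) <= 6


# ---------------------------------------------------------------------------
# structure profiles (ssrA, rrn5)
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def ssra_profile():
    sp = load_structure_profile("ssrA")
    from organnot.ncrna_annotator import calibrate_structure_profile
    calibrate_structure_profile(sp, seed=151)
    return sp


@pytest.fixture(scope="module")
def rrn5_profile():
    sp = load_structure_profile("rrn5")
    from organnot.ncrna_annotator import calibrate_structure_profile
    calibrate_structure_profile(sp, seed=150)
    return sp


def test_planted_ssra_found_below_threshold(ssra_profile, rng):
    gene = sg.make_ssra(rng)
    genome = sg.random_dna(rng, 900) + gene + sg.random_dna(rng, 900)
    calls = search_structure(Contig("g", genome), ssra_profile)
    assert any(c.start == 900 and c.end == 900 + len(gene) for c in calls)
    assert all(c.evalue <= 1e-3 for c in calls)


def test_gac_motif_is_a_hard_constraint(ssra_profile, rng):
    gene = sg.make_ssra(rng)
    genome = sg.random_dna(rng, 900) + gene + sg.random_dna(rng, 900)
    idx = genome.find(sg.SSRA_STRAND)
    mutated = genome[: idx + sg.SSRA_GAC_OFFSET] + "GAG" + genome[idx + sg.SSRA_GAC_OFFSET + 3 :]
    calls = search_structure(Contig("g", mutated), ssra_profile)
    assert not any(abs(c.start - 900) < 20 for c in calls)


def test_planted_rrn5_found(rrn5_profile, rng):
    gene = sg.make_rrn5(rng)
    genome = sg.random_dna(rng, 800) + gene + sg.random_dna(rng, 800)
    calls = search_structure(Contig("g", genome), rrn5_profile)
    assert any(c.start == 800 and c.end == 800 + len(gene) for c in calls)


def test_structure_search_reverse_complement_symmetry(ssra_profile, rng):
    gene = sg.make_ssra(rng)
    genome = sg.random_dna(rng, 600) + gene + sg.random_dna(rng, 600)
    n = len(genome)
    fw = search_structure(Contig("g", genome), ssra_profile)
    rc = search_structure(Contig("g", revcomp(genome)), ssra_profile)
    assert sorted((n - c.end, n - c.start) for c in rc) == \
        sorted((c.start, c.end) for c in fw)


def test_no_structure_calls_on_random_genomes(ssra_profile, rrn5_profile):
    hits = 0
    for seed in range(100):
        r = np.random.default_rng(7000 + seed)
        g = Contig("x", "".join(r.choice(list("ACGT"), size=2000)))
        if search_structure(g, ssra_profile) or search_structure(g, rrn5_profile):
            hits += 1
    assert hits <= 5
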