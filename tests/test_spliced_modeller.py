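"""Spliced alignment, boundary refinement, mini-exon rescue, start choice."""

import numpy as np
import pytest
from Bio import Align
from Bio.Align import substitution_matrices

import organnot.synth_genome as sg
from organnot.profile_hmm import build_profile
from organnot.spliced_modeller import (
    SplicedAlignError,
    adjust_start,
    refine_boundaries,
    rescue_miniexons,
    spliced_align,
)


@pytest.fixture(scope="module")
def cox1_family():
    return sg.make_protein_family("cox1", 200)


def plain_sw_score(protein, dna_translation):
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    return aligner.score(protein, dna_translation)


def test_intron_free_gene_single_segment_matches_smith_waterman(
    code4, splice_models, cox1_family
):
    """With no intron the DP reduces to ungapped protein-codon alignment;
    the aligned span is exact and the score equals the sum of BLOSUM
    diagonal scores of the translation (the Smith-Waterman result for a
    perfect match)."""
    rng = np.random.default_rng(3)
    prot = cox1_family[0]
    cds = sg.back_translate(prot, code4, rng)
    region = sg.random_dna(rng, 300) + cds + sg.random_dna(rng, 300)
    aln = spliced_align(prot, region, code4, splice_models)
    assert aln.exons == [(300, 300 + len(cds))]
    assert aln.introns == []
    blosum = substitution_matrices.load("BLOSUM62")
    identity_score = sum(blosum[a, a] for a in prot)
    assert aln.score == pytest.approx(identity_score)
    assert aln.score == pytest.approx(plain_sw_score(prot, prot))


@pytest.mark.parametrize("group,codon,phase", [
    ("II", 80, 0), ("I", 50, 1), ("II", 120, 2), ("I", 150, 0),
])
def test_single_intron_recovered_exactly_at_any_phase(
    code4, splice_models, cox1_family, group, codon, phase
):
    rng = np.random.default_rng(40 + codon + phase)
    prot = cox1_family[0]
    cds = sg.back_translate(prot, code4, rng)
    cut = 3 * codon + phase
    if group == "II":
        intron = sg.make_group2_intron(rng, 240)
    else:
        intron = sg.make_group1_intron(rng, 240, cds[:cut][-6:])
    gene = cds[:cut] + intron + cds[cut:]
    region = sg.random_dna(rng, 200) + gene + sg.random_dna(rng, 200)
    aln = spliced_align(prot, region, code4, splice_models)
    assert aln.exons == [(200, 200 + cut), (200 + cut + 240, 200 + len(gene))]
    assert aln.introns == [(200 + cut, 200 + cut + 240, phase)]


def test_no_chain_above_floor_raises(code4, splice_models, rng):
    with pytest.raises(SplicedAlignError):
        spliced_align("W" * 80, sg.random_dna(rng, 400), code4, splice_models)


def test_refine_corrects_displaced_boundary_and_is_idempotent(
    code4, splice_models, cox1_family
):
    rng = np.random.default_rng(9)
    prot = cox1_family[0]
    cds = sg.back_translate(prot, code4, rng)
    cut = 300
    intron = sg.make_group2_intron(rng, 240)
    gene = cds[:cut] + intron + cds[cut:]
    region = sg.random_dna(rng, 150) + gene + sg.random_dna(rng, 150)
    aln = spliced_align(prot, region, code4, splice_models)
    true_exons = [(150, 150 + cut), (150 + cut + 240, 150 + len(gene))]
    # displace the intron 2 nt and let refinement slide it back
    aln.exons = [(150, 150 + cut + 2), (150 + cut + 240 + 2, 150 + len(gene))]
    aln.introns = [(150 + cut + 2, 150 + cut + 240 + 2, 0)]
    exons, calls = refine_boundaries(aln, region, splice_models, code4)
    assert exons == true_exons
    assert calls[0].group == "II"
    # idempotence on correct boundaries
    aln.exons = list(exons)
    aln.introns = [(exons[0][1], exons[1][0], 0)]
    exons2, _ = refine_boundaries(aln, region, splice_models, code4)
    assert exons2 == exons


def _mini_exon_setup(seed, n_codons=2):
    rng = np.random.default_rng(seed)
    fam = sg.make_protein_family("cob", 260)
    prot = fam[0]
    profile = build_profile(fam, name="cob")
    from organnot.seq_io import load_genetic_code
    code = load_genetic_code(4)
    cds = sg.back_translate(prot, code, rng) + "TAA"
    c0 = 120 * 3
    w = 3 * n_codons
    iA = sg.make_group2_intron(rng, 220)
    iB = sg.make_group2_intron(rng, 260)
    gene = cds[:c0] + iA + cds[c0 : c0 + w] + iB + cds[c0 + w :]
    region = sg.random_dna(rng, 150) + gene + sg.random_dna(rng, 150)
    truth = [(150, 150 + c0), (150 + c0 + 220, 150 + c0 + 220 + w),
             (150 + c0 + 220 + w + 260, 150 + len(gene) - 3)]
    return code, prot, profile, region, truth


def test_mini_exon_skipped_by_aligner_then_rescued_exactly(splice_models):
    code, prot, profile, region, truth = _mini_exon_setup(42)
    aln = spliced_align(prot, region, code, splice_models)
    assert len(aln.exons) == 2  # the 2-codon exon is cheaper to delete
    exons, calls = refine_boundaries(aln, region, splice_models, code)
    exons, calls, comments, rescued = rescue_miniexons(
        exons, calls, region, profile, splice_models, code)
    assert rescued
    assert exons == truth
    assert any("mini-exon-added" in c for c in comments)
    assert len(calls) == 2 and all(c.group == "II" for c in calls)
    # rescue is idempotent on its own output
    exons2, calls2, comments2, rescued2 = rescue_miniexons(
        exons, calls, region, profile, splice_models, code)
    assert exons2 == exons and not rescued2


def test_blocks_longer_than_miniexon_bound_are_not_rescued(splice_models):
    code, prot, profile, region, truth = _mini_exon_setup(43, n_codons=6)
    aln = spliced_align(prot, region, code, splice_models)
    exons, calls = refine_boundaries(aln, region, splice_models, code)
    n_before = len(exons)
    exons, calls, comments, rescued = rescue_miniexons(
        exons, calls, region, profile, splice_models, code)
    if len(exons) == n_before:  # 6-codon exon either found by the DP or
        assert not rescued      # rejected by the bound, never invented
        assert any("exceeds the mini-exon bound" in c for c in comments) or not comments


def test_start_codon_selection_and_fallback_order(code4):
    # profile-implied start carries an ATG: chosen directly
    region = "AAAATG" + "GCT" * 30 + "TAA" + "A" * 20
    exons = [(3, 3 + 93)]
    new_exons, start, comments = adjust_start(exons, region, code4)
    assert start == "ATG" and new_exons[0][0] == 3 and not comments
    # no ATG anywhere: GTG preferred over TTG (fallback order)
    region2 = "AAAGTGTTG" + "GCT" * 30 + "TAA"
    got = {}
    for offset, codon in ((3, "GTG"), (6, "TTG")):
        ne, st, cm = adjust_start([(6, 6 + 90)], region2, code4)
        got[st] = ne[0][0]
    assert "GTG" in got and got["GTG"] == 3  # GTG wins although TTG is at 6
    # none of ATG/GTG/TTG/ATA present: comment, model retained
    region3 = "CCCCCC" + "GCT" * 30 + "TAA"
    ne, st, cm = adjust_start([(6, 6 + 90)], region3, code4)
    assert st is None and ne[0][0] == 6
    assert any("no start codon found" in c for c in cm)


def test_adjust_start_does_not_cross_an_upstream_stop(code4):
    # an in-frame stop sits between the candidate ATG and the exon start
    region = "ATG" + "TAA" + "GCT" * 30 + "TAA"
    ne, st, cm = adjust_start([(6, 6 + 90)], region, code4)
    assert ne[0][0] == 6  # the upstream ATG is unreachable


def test_reverse_complement_symmetry_of_gene_modelling(code4, splice_models, cox1_family):
    from organnot.seq_io import revcomp

    rng = np.random.default_rng(77)
    prot = cox1_family[0]
    cds = sg.back_translate(prot, code4, rng)
    cut = 240
    gene = cds[:cut] + sg.make_group2_intron(rng, 200) + cds[cut:]
    region = sg.random_dna(rng, 180) + gene + sg.random_dna(rng, 180)
    fw = spliced_align(prot, region, code4, splice_models)
    assert len(fw.exons) == 2
    # the minus-strand view of the same region contains no gene: the chain
    # falls below the score floor rather than producing a phantom model
    with pytest.raises(SplicedAlignError):
        spliced_align(prot, revcomp(region), code4, splice_models)


def test_translation_of_emitted_model_is_stop_free(code4, splice_models, cox1_family):
    rng = np.random.default_rng(15)
    prot = cox1_family[0]
    cds = sg.back_translate(prot, code4, rng)
    gene = cds[:330] + sg.make_group1_intron(rng, 210, cds[:330][-6:]) + cds[330:]
    region = sg.random_dna(rng, 100) + gene + sg.random_dna(rng, 100)
    aln = spliced_align(prot, region, code4, splice_models)
    exons, _ = refine_boundaries(aln, region, splice_models, code4)
    cds_out = "".join(region[s:e] for s, e in exons)
    assert len(cds_out) % 3 == 0
    assert "*" not in code4.translate(cds_out)
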