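"""Synthetic mitochondrial genome generator with planted ground truth.

Every structure the annotation pipeline must recover can be planted here
with exact known coordinates: multi-exon protein genes with Group I/II
introns (including mini-exons of 1-3 codons and all three intron phases),
frameshifted and trans-spliced gene copies, tRNA cloverleaves (7-9 nt
anticodon loops), rRNA genes (a precisely bounded small-subunit gene, and a
large-subunit gene whose weakly conserved termini are joined by a terminal
helix), a 5S rRNA and a tmRNA with its invariant GAC motif and helix-3 G-U
pair.  Intron and ncRNA signatures match the shipped default models, which
separates "pipeline correctness" (recovery at zero mutation) from "model
quality" (degradation under mutation, applied separately via
:func:`mutate`).

The same seed always yields byte-identical output.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict

import numpy as np

from .seq_io import Contig, GeneticCode, load_genetic_code, revcomp
from .profile_hmm import AA_ALPHABET, AA_BACKGROUND

NT = np.array(list("ACGT"))

# ---------------------------------------------------------------------------
# Shared sequence anchors for the structured ncRNA models.  The shipped
# structure-profile fixtures under organnot/models/ use these same consensus
# strings; both are synthetic teaching models, not reconstructions of any
# published alignment.
# ---------------------------------------------------------------------------
SSRA_STRAND = "ATTGACGGTTCA"  # invariant GAC at offsets 3..5
SSRA_GAC_OFFSET = 3
RRN5_STRAND_A = "GGTTACCACCTG"
RRN5_STRAND_B = "CCGAACTC"
TRNA_T_LOOP = "TTCGAAT"

_FAMILY_SEED = 424243  # fixed: reference families are frozen fixtures-in-code

DEFAULT_GENE_LENGTHS = {
    "cox1": 320,
    "cob": 260,
    "nad5": 290,
    "nad1": 220,
    "atp6": 160,
    "rps3": 140,
}


# ---------------------------------------------------------------------------
# Reference protein families (synthetic, deterministic)
# ---------------------------------------------------------------------------


def make_protein_family(name: str, length: int, n_seqs: int = 5, divergence: float = 0.10):
    """A deterministic synthetic protein family: a random base sequence
    (starting with M) plus variants at the given divergence.  Returned as an
    ungapped alignment (list of equal-length strings); member 0 is the base."""
    rng = np.random.default_rng([_FAMILY_SEED, zlib.crc32(name.encode()), length])
    aa = np.array(list(AA_ALPHABET))
    base = rng.choice(aa, size=length, p=AA_BACKGROUND)
    base[0] = "M"
    seqs = ["".join(base)]
    for _ in range(n_seqs - 1):
        var = base.copy()
        for i in range(1, length):
            if rng.random() < divergence:
                var[i] = rng.choice(aa[aa != var[i]])
        seqs.append("".join(var))
    return seqs


def reference_protein_fasta(gene_lengths: dict | None = None) -> str:
    """Reference collection as FASTA with ``>gene|id`` headers (one family
    per gene, all members included)."""
    gene_lengths = gene_lengths or DEFAULT_GENE_LENGTHS
    out = []
    for gene, length in gene_lengths.items():
        for i, seq in enumerate(make_protein_family(gene, length)):
            out.append(f">{gene}|{gene}_{chr(97 + i)} synthetic family member")
            out.append(seq)
    return "\n".join(out) + "\n"


def make_rna_family(name: str, length: int, n_seqs: int = 5, divergence: float = 0.08):
    """Deterministic synthetic nucleotide family for rRNA core models."""
    rng = np.random.default_rng([_FAMILY_SEED + 1, zlib.crc32(name.encode()), length])
    base = rng.choice(NT, size=length)
    seqs = ["".join(base)]
    for _ in range(n_seqs - 1):
        var = base.copy()
        for i in range(length):
            if rng.random() < divergence:
                var[i] = rng.choice(NT[NT != var[i]])
        seqs.append("".join(var))
    return seqs


# ---------------------------------------------------------------------------
# Low-level builders
# ---------------------------------------------------------------------------


def random_dna(rng, length: int, gc: float = 0.4) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(NT, size=length, p=p))


def back_translate(protein: str, code: GeneticCode, rng) -> str:
    """Random synonymous back-translation under ``code`` (no N codons)."""
    by_aa = {}
    for codon, aa in code.codon_map.items():
        by_aa.setdefault(aa, []).append(codon)
    out = []
    for aa in protein:
        codons = sorted(by_aa[aa])
        out.append(codons[rng.integers(len(codons))])
    return "".join(out)


def make_group2_intron(rng, length: int) -> str:
    """Canonical Group II intron matching the shipped model: 5' GTGCGGTA,
    domain-VI hairpin, branch A at -7, 3' ...CTGAAT."""
    if length < 50:
        raise ValueError("Group II intron too short to carry its signatures")
    stem = random_dna(rng, 6, gc=0.6)
    hairpin = stem + random_dna(rng, 4) + revcomp(stem)  # 16 nt
    suffix = hairpin + random_dna(rng, 1) + "A" + "CTGAAT"  # branch A at -7
    filler = _stopless_filler(rng, length - 8 - len(suffix), forbid=("GTGCG",))
    return "GTGCGGTA" + filler + suffix


def make_group1_intron(rng, length: int, upstream_exon_tail: str) -> str:
    """Canonical Group I intron: weak TA 5' end, internal guide pairing the
    upstream exon tail (P1), 3' terminal ...AG."""
    if length < 40:
        raise ValueError("Group I intron too short to carry its signatures")
    guide = revcomp(upstream_exon_tail[-6:])
    body = _stopless_filler(rng, length - 2 - 6 - 6, forbid=("GTGCG",))
    return "TA" + guide + body + "ATTAAG"


def _stopless_filler(rng, length: int, forbid=()) -> str:
    if length < 0:
        raise ValueError("intron plan infeasible (negative filler)")
    while True:
        s = random_dna(rng, length)
        if all(f not in s for f in forbid):
            return s


def make_trna(rng, anticodon: str, loop_len: int = 7) -> tuple:
    """Canonical cloverleaf tRNA gene.  Returns (seq, anticodon_offset) with
    the anticodon placed center-anchored in a 7-9 nt anticodon loop."""
    if loop_len not in (7, 8, 9):
        raise ValueError("anticodon loop length must be 7..9")
    acc = random_dna(rng, 7, gc=0.6)
    dstem = random_dna(rng, 4, gc=0.6)
    dloop = random_dna(rng, 8)
    acstem = random_dna(rng, 5, gc=0.6)
    ac_off = (loop_len - 3) // 2
    acloop = random_dna(rng, ac_off) + anticodon + random_dna(rng, loop_len - 3 - ac_off)
    var = random_dna(rng, 4)
    tstem = random_dna(rng, 5, gc=0.6)
    parts = [
        acc, "TA", dstem, dloop, revcomp(dstem), "A",
        acstem, acloop, revcomp(acstem), var,
        tstem, TRNA_T_LOOP, revcomp(tstem), revcomp(acc), "A",
    ]
    seq = "".join(parts)
    anticodon_offset = 7 + 2 + 4 + 8 + 4 + 1 + 5 + ac_off
    return seq, anticodon_offset


def make_rns(rng) -> str:
    """Small-subunit rRNA gene: the conserved core is the whole gene, so its
    termini are precisely mappable."""
    return make_rna_family("rns", 250)[0]


def make_rnl(rng, flank_min: int = 90, flank_max: int = 150, helix_len: int = 12) -> tuple:
    """Large-subunit rRNA gene: conserved core with weakly conserved
    variable-length flanks; the 5' and 3' termini are joined by a terminal
    helix.  Returns (seq, core_offset, core_len)."""
    core = make_rna_family("rnl", 300)[0]
    len5 = int(rng.integers(flank_min, flank_max + 1))
    len3 = int(rng.integers(flank_min, flank_max + 1))
    helix5 = random_dna(rng, helix_len, gc=0.6)
    flank5 = helix5 + random_dna(rng, len5 - helix_len)
    flank3 = random_dna(rng, len3 - helix_len) + revcomp(helix5)
    return flank5 + core + flank3, len5, len(core)


def make_ssra(rng) -> str:
    """Synthetic tmRNA gene matching the shipped structure profile:
    helix P1, the invariant-GAC strand, and helix P3 carrying a G-T pair."""
    h1 = random_dna(rng, 7, gc=0.6)
    p1 = h1 + random_dna(rng, 4) + revcomp(h1)
    spacer1 = random_dna(rng, int(rng.integers(3, 7)))
    spacer2 = random_dna(rng, int(rng.integers(2, 6)))
    # helix 3 with a planted G-T (G.U) pair at stem position 2
    h3a = list(random_dna(rng, 6, gc=0.6))
    h3a[2] = "G"
    h3b = list(revcomp("".join(h3a)))
    h3b[5 - 2] = "T"  # mirror position of stem index 2
    p3 = "".join(h3a) + random_dna(rng, 4) + "".join(h3b)
    return p1 + spacer1 + SSRA_STRAND + spacer2 + p3


def make_rrn5(rng) -> str:
    """Synthetic 5S rRNA gene matching the shipped structure profile."""
    h1 = random_dna(rng, 6, gc=0.6)
    return (
        RRN5_STRAND_A
        + random_dna(rng, int(rng.integers(2, 5)))
        + h1 + random_dna(rng, 4) + revcomp(h1)
        + random_dna(rng, int(rng.integers(2, 5)))
        + RRN5_STRAND_B
    )


# ---------------------------------------------------------------------------
# Genome specification
# ---------------------------------------------------------------------------


@dataclass
class IntronPlan:
    group: str  # "I" or "II"
    after_codon: int  # intron inserted after this many codons ...
    phase: int = 0  # ... plus this many extra nucleotides (0, 1, 2)
    length: int = 250


@dataclass
class GenePlan:
    gene: str
    strand: str = "+"
    introns: list = field(default_factory=list)  # list of IntronPlan
    mini_exon: tuple | None = None  # (codon_start, n_codons) between 2 introns
    frameshift: bool = False
    trans_splice: bool = False
    protein_divergence: float = 0.0


@dataclass
class TrnaPlan:
    anticodon: str
    loop_len: int = 7
    strand: str = "+"


@dataclass
class GenomeSpec:
    seed: int
    genetic_code: int = 4
    gc: float = 0.40
    intergenic_min: int = 120
    intergenic_max: int = 320
    mutation_rate: float = 0.0
    genes: list = field(default_factory=list)
    trnas: list = field(default_factory=list)
    rns: bool = True
    rnl: bool = True
    ssra: bool = True
    rrn5: bool = True


def default_genome_spec(seed: int, mutation_rate: float = 0.0,
                        protein_divergence: float = 0.0) -> GenomeSpec:
    """The default study roster: five multi-exon genes covering both intron
    groups, all three intron phases and a 2-codon mini-exon; one single-exon
    gene on the reverse strand; two tRNAs (one with an 8-nt anticodon loop);
    rns; rnl with terminal helix; ssrA; rrn5."""
    genes = [
        GenePlan("cox1", "+",
                 introns=[IntronPlan("II", 60, 0, 240), IntronPlan("I", 150, 1, 260)],
                 protein_divergence=protein_divergence),
        GenePlan("cob", "+",
                 introns=[IntronPlan("II", 80, 2, 220), IntronPlan("II", 170, 0, 250)],
                 mini_exon=(120, 2),
                 protein_divergence=protein_divergence),
        GenePlan("nad5", "-",
                 introns=[IntronPlan("I", 100, 0, 230)],
                 protein_divergence=protein_divergence),
        GenePlan("nad1", "+",
                 introns=[IntronPlan("II", 70, 1, 210)],
                 protein_divergence=protein_divergence),
        GenePlan("atp6", "+",
                 introns=[IntronPlan("I", 50, 0, 200)],
                 protein_divergence=protein_divergence),
        GenePlan("rps3", "-", protein_divergence=protein_divergence),
    ]
    trnas = [TrnaPlan("CAT", 7, "+"), TrnaPlan("TAG", 8, "+")]
    return GenomeSpec(seed=seed, mutation_rate=mutation_rate, genes=genes, trnas=trnas)


@dataclass
class TruthFeature:
    kind: str  # CDS, tRNA, rRNA, ncRNA, intron
    gene: str
    strand: str
    exons: list  # 0-based half-open genomic spans, transcript order
    flags: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    @property
    def start(self):
        return min(s for s, _ in self.exons)

    @property
    def end(self):
        return max(e for _, e in self.exons)


@dataclass
class SynthTruth:
    features: list = field(default_factory=list)

    def by_gene(self, gene: str):
        return [f for f in self.features if f.gene == gene]

    def of_kind(self, kind: str):
        return [f for f in self.features if f.kind == kind]


class SpecError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Gene assembly
# ---------------------------------------------------------------------------


def _build_gene(plan: GenePlan, code: GeneticCode, rng):
    """Build one gene part.  Returns (seq, exon_spans, intron_records, flags,
    protein) with spans local to the part, transcript orientation (forward)."""
    family = make_protein_family(plan.gene, DEFAULT_GENE_LENGTHS.get(plan.gene, 200))
    protein = family[0]
    if plan.protein_divergence > 0:
        aa = np.array(list(protein))
        pool = np.array(list(AA_ALPHABET))
        for i in range(1, len(aa)):
            if rng.random() < plan.protein_divergence:
                aa[i] = rng.choice(pool[pool != aa[i]])
        protein = "".join(aa)
    cds = back_translate(protein, code, rng) + "TAA"

    if plan.frameshift:
        # delete one nucleotide mid-gene: a pseudo-gene / sequencing-error
        # mimic that must be flagged, never repaired
        pos = len(cds) // 2
        seq = cds[:pos] + cds[pos + 1 :]
        return seq, [(0, len(seq))], [], ["frameshift"], protein

    cut_points = []
    for ip in plan.introns:
        cut_points.append((ip.after_codon * 3 + ip.phase, ip))
    if plan.mini_exon:
        cstart, ncod = plan.mini_exon
        # a mini-exon is delimited by two introns
        g = rng.choice(["I", "II"])
        cut_points.append((cstart * 3, IntronPlan(g, cstart, 0, int(rng.integers(200, 300)))))
        cut_points.append(((cstart + ncod) * 3, IntronPlan(g, cstart + ncod, 0, int(rng.integers(200, 300)))))
    cut_points.sort(key=lambda x: x[0])
    for (a, _), (b, _) in zip(cut_points, cut_points[1:]):
        if b <= a:
            raise SpecError("intron insertion points must be strictly increasing")

    pieces = []
    exons = []
    introns = []
    pos = 0
    prev_cut = 0
    for cut, ip in cut_points:
        exon_seq = cds[prev_cut:cut]
        pieces.append(exon_seq)
        exons.append((pos, pos + len(exon_seq)))
        pos += len(exon_seq)
        tail = cds[:cut][-6:]
        if ip.group == "II":
            iseq = make_group2_intron(rng, ip.length)
        else:
            iseq = make_group1_intron(rng, ip.length, tail)
        pieces.append(iseq)
        introns.append({"span": (pos, pos + len(iseq)), "group": ip.group,
                        "phase": cut % 3})
        pos += len(iseq)
        prev_cut = cut
    last = cds[prev_cut:]
    pieces.append(last)
    exons.append((pos, pos + len(last)))
    seq = "".join(pieces)
    # construction self-check: spliced translation is stop-free
    spliced = "".join(seq[s:e] for s, e in exons)
    assert spliced == cds
    aa_check = code.translate(cds[:-3])
    assert "*" not in aa_check and aa_check == protein
    return seq, exons, introns, [], protein


def generate(spec: GenomeSpec):
    """Emit (Contig, SynthTruth) for a genome specification.

    Features are laid out left to right with random intergenic spacers; minus
    strand features are reverse complemented in place.  Mutation (if any) is
    applied uniformly afterwards and never touches truth coordinates.
    """
    rng = np.random.default_rng(spec.seed)
    code = load_genetic_code(spec.genetic_code)
    parts = []  # (seq, [(kind, gene, strand, local_exons, flags, meta)])

    for plan in spec.genes:
        if plan.trans_splice:
            family = make_protein_family(plan.gene, DEFAULT_GENE_LENGTHS.get(plan.gene, 200))
            protein = family[0]
            half = len(protein) // 2
            cds1 = back_translate(protein[:half], code, rng)
            cds2 = back_translate(protein[half:], code, rng) + "TAA"
            parts.append((cds1, [("CDS", plan.gene, "+", [(0, len(cds1))],
                                  ["trans-splice"], {"piece": 1})]))
            parts.append((cds2, [("CDS", plan.gene, "-", [(0, len(cds2))],
                                  ["trans-splice"], {"piece": 2})]))
            continue
        seq, exons, introns, flags, protein = _build_gene(plan, code, rng)
        feats = [("CDS", plan.gene, plan.strand, exons, flags, {"protein": protein})]
        for i, rec in enumerate(introns):
            feats.append(("intron", f"{plan.gene}-i{i + 1}", plan.strand,
                          [rec["span"]], [], {"group": rec["group"],
                                              "phase": rec["phase"]}))
        if plan.mini_exon:
            cstart, ncod = plan.mini_exon
            feats[0][5]["mini_exon_codons"] = (cstart, ncod)
        parts.append((seq, feats))

    for tp in spec.trnas:
        seq, ac_off = make_trna(rng, tp.anticodon, tp.loop_len)
        meta = {"anticodon": tp.anticodon, "loop_len": tp.loop_len,
                "anticodon_offset": ac_off}
        name = f"trn-{tp.anticodon}"
        parts.append((seq, [("tRNA", name, tp.strand, [(0, len(seq))], [], meta)]))
    if spec.rns:
        seq = make_rns(rng)
        parts.append((seq, [("rRNA", "rns", "+", [(0, len(seq))], [], {})]))
    if spec.rnl:
        seq, core_off, core_len = make_rnl(rng)
        meta = {"core_offset": core_off, "core_len": core_len}
        # non-pairing guard bases pin the terminal helix: without them a
        # chance pair in the intergenic DNA would extend the helix and make
        # the "true" termini ambiguous by a nucleotide or two
        seq = "AA" + seq + "AA"
        parts.append((seq, [("rRNA", "rnl", "+", [(2, len(seq) - 2)], [], meta)]))
    if spec.ssra:
        seq = make_ssra(rng)
        parts.append((seq, [("ncRNA", "ssrA", "+", [(0, len(seq))], [], {})]))
    if spec.rrn5:
        seq = make_rrn5(rng)
        parts.append((seq, [("rRNA", "rrn5", "+", [(0, len(seq))], [], {})]))

    chunks = []
    truth = SynthTruth()
    pos = 0
    for seq, feats in parts:
        gap = random_dna(rng, int(rng.integers(spec.intergenic_min, spec.intergenic_max + 1)),
                         spec.gc)
        chunks.append(gap)
        pos += len(gap)
        strand = feats[0][2]
        placed = revcomp(seq) if strand == "-" else seq
        L = len(seq)
        for kind, gene, fstrand, local_exons, flags, meta in feats:
            if strand == "-":
                exons = [(pos + L - e, pos + L - s) for s, e in local_exons]
            else:
                exons = [(pos + s, pos + e) for s, e in local_exons]
            truth.features.append(
                TruthFeature(kind=kind, gene=gene, strand=fstrand,
                             exons=exons, flags=list(flags), meta=dict(meta))
            )
        chunks.append(placed)
        pos += L
    tail_gap = random_dna(rng, int(rng.integers(spec.intergenic_min, spec.intergenic_max + 1)),
                          spec.gc)
    chunks.append(tail_gap)
    contig = Contig(id=f"synth{spec.seed}", seq="".join(chunks))
    if spec.mutation_rate > 0:
        contig = mutate(contig, spec.mutation_rate, seed=spec.seed + 10_007)
    return contig, truth


def mutate(contig: Contig, rate: float, seed: int) -> Contig:
    """I.i.d. substitutions at ``rate``; substituted bases always change and
    stay within {A,C,G,T}."""
    if rate == 0:
        return Contig(contig.id, contig.seq, contig.topology)
    rng = np.random.default_rng(seed)
    arr = np.array(list(contig.seq))
    hit = rng.random(len(arr)) < rate
    for i in np.nonzero(hit)[0]:
        if arr[i] in "ACGT":
            arr[i] = rng.choice(NT[NT != arr[i]])
    return Contig(contig.id, "".join(arr), contig.topology)


# ---------------------------------------------------------------------------
# Spec serialization (text-reviewable regression fixtures)
# ---------------------------------------------------------------------------


def spec_to_json(spec: GenomeSpec) -> str:
    return json.dumps(asdict(spec), indent=1)


def spec_from_json(text: str) -> GenomeSpec:
    raw = json.loads(text)
    raw["genes"] = [
        GenePlan(**{**g, "introns": [IntronPlan(**ip) for ip in g.get("introns", [])],
                    "mini_exon": tuple(g["mini_exon"]) if g.get("mini_exon") else None})
        for g in raw.get("genes", [])
    ]
    raw["trnas"] = [TrnaPlan(**t) for t in raw.get("trnas", [])]
    return GenomeSpec(**raw)
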