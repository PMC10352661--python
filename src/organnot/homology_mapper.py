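"""ORF-to-reference homology mapping and locus calling.

Predicted ORFs are searched against a curated collection of organellar
proteins by exhaustive Smith-Waterman local alignment (BLOSUM62, affine gaps
11/1).  At mitogenome scale — a few hundred ORFs against a few hundred
references — exhaustive alignment is fast enough that no heuristic seeding
step is needed.

Full-length matches become single-exon gene calls directly.  Partial
matches are clustered into gene loci and handed to the spliced modeller;
along the way, pairs of partial hits diagnostic of frameshifts (same strand,
different reading frames, near-adjacent) or of trans-splicing (different
strands or contigs, or implausibly distant) are flagged — flagged, never
auto-repaired, since they may equally indicate pseudogenes or sequencing
errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from scipy.stats import gumbel_r

from .orf_translate import Orf
from .profile_hmm import AA_ALPHABET, AA_BACKGROUND

DEFAULT_SCORE_THRESHOLD = 50.0
DEFAULT_FULL_COVERAGE = 90.0
DEFAULT_MAX_FS_GAP = 45
DEFAULT_MAX_INTRON = 20_000


@dataclass
class ReferenceProtein:
    gene: str
    id: str
    seq: str
    tags: tuple = ()


def parse_reference_fasta(text: str) -> list:
    """Parse a reference set with ``>gene|id description`` headers; the gene
    name is the first pipe-delimited token.  A ``plasmid-origin`` token in
    the description becomes a tag."""
    refs = []
    name = None
    desc = ""
    chunks = []

    def flush():
        if name is None:
            return
        gene, _, rid = name.partition("|")
        tags = tuple(t for t in ("plasmid-origin",) if t in desc)
        refs.append(ReferenceProtein(gene=gene, id=rid or gene, seq="".join(chunks), tags=tags))

    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            head = line[1:].split(None, 1)
            name = head[0]
            desc = head[1] if len(head) > 1 else ""
            chunks = []
        else:
            chunks.append(line.upper())
    flush()
    return refs


def make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


@dataclass
class ProteinHit:
    orf: Orf
    ref: ReferenceProtein
    orf_span: tuple  # residue span on the ORF, 0-based half-open
    ref_span: tuple  # residue span on the reference
    score: float
    coverage: float  # percent of the reference covered, in (0, 100]
    evalue: float | None = None

    def __post_init__(self):
        if not (0 < self.coverage <= 100):
            raise ValueError("coverage must lie in (0, 100]")

    @property
    def gene(self):
        return self.ref.gene

    @property
    def strand(self):
        return self.orf.strand

    @property
    def genomic_span(self):
        """Genomic span of the aligned ORF residues (forward coordinates)."""
        a, b = self.orf_span
        if self.orf.strand == "+":
            return (self.orf.start + 3 * a, self.orf.start + 3 * b)
        return (self.orf.end - 3 * b, self.orf.end - 3 * a)

    @property
    def frame(self):
        return self.orf.frame


def calibrate_sw(ref: ReferenceProtein, n_samples: int = 100, seed: int = 0,
                 sample_len: int = 200) -> tuple:
    """Gumbel null for Smith-Waterman scores against ``ref`` (same machinery
    as the profile-HMM calibration: MLE fit to scores of background
    sequences)."""
    rng = np.random.default_rng(seed)
    aligner = make_aligner()
    letters = list(AA_ALPHABET)
    scores = np.empty(n_samples)
    for i in range(n_samples):
        q = "".join(rng.choice(letters, size=sample_len, p=AA_BACKGROUND))
        scores[i] = aligner.score(q, ref.seq)
    mu, beta = gumbel_r.fit(scores)
    return (float(mu), float(1.0 / beta))


def search_orfs(
    orfs: list,
    references: list,
    score_threshold: float = DEFAULT_SCORE_THRESHOLD,
    calibrations: dict | None = None,
) -> list:
    """Best local alignment of every ORF against every reference; hits below
    ``score_threshold`` (raw BLOSUM62 score) are dropped.  If ``calibrations``
    maps reference ids to (mu, lambda), E-values are attached."""
    if not references:
        raise ValueError("reference set is empty")
    aligner = make_aligner()
    hits = []
    for orf in orfs:
        q = orf.aa_seq
        if not q:
            continue
        for ref in references:
            score = aligner.score(q, ref.seq)
            if score < score_threshold:
                continue
            aln = aligner.align(q, ref.seq)[0]
            qs, qe = int(aln.aligned[0][0][0]), int(aln.aligned[0][-1][1])
            rs, re_ = int(aln.aligned[1][0][0]), int(aln.aligned[1][-1][1])
            cov = 100.0 * (re_ - rs) / len(ref.seq)
            ev = None
            if calibrations and ref.id in calibrations:
                mu, lam = calibrations[ref.id]
                ev = float(-np.expm1(-np.exp(-lam * (score - mu))))
            hits.append(ProteinHit(orf, ref, (qs, qe), (rs, re_), float(score), cov, ev))
    hits.sort(key=lambda h: (h.genomic_span[0], -h.score))
    return hits


@dataclass
class GeneLocus:
    gene: str
    contig_id: str
    strand: str
    hits: list
    status: str = "partial"  # full | partial | frameshift-suspect | trans-splice-suspect
    comments: list = field(default_factory=list)

    @property
    def start(self):
        return min(h.genomic_span[0] for h in self.hits)

    @property
    def end(self):
        return max(h.genomic_span[1] for h in self.hits)

    @property
    def score(self):
        return sum(h.score for h in self.hits)

    @property
    def plasmid_origin(self):
        return all("plasmid-origin" in h.ref.tags for h in self.hits)


def _dedup_hits(hits):
    """Keep, per gene/strand, the best-scoring hit among hits whose genomic
    spans overlap (family members all hit the same exon).

    Hits overlapping genomically but covering mostly disjoint reference
    intervals are complementary pieces (for example the two halves of a
    frameshifted gene) and are both kept."""
    chosen = []
    for h in sorted(hits, key=lambda h: -h.score):
        s, e = h.genomic_span
        clash = False
        for c in chosen:
            if c.gene == h.gene and c.strand == h.strand and c.orf.contig_id == h.orf.contig_id:
                cs, ce = c.genomic_span
                if s < ce and cs < e:
                    r_olap = min(c.ref_span[1], h.ref_span[1]) - max(c.ref_span[0], h.ref_span[0])
                    shorter = min(c.ref_span[1] - c.ref_span[0], h.ref_span[1] - h.ref_span[0])
                    if r_olap > 0.5 * shorter:
                        clash = True
                        break
        if not clash:
            chosen.append(h)
    chosen.sort(key=lambda h: h.genomic_span[0])
    return chosen


def cluster_loci(hits: list, max_intron: int = DEFAULT_MAX_INTRON) -> list:
    """Group hits into candidate gene loci by gene name, contig, strand and
    genomic proximity (gaps <= ``max_intron``).

    Before clustering, overlapping hits of *different* genes compete and
    only the strongest survives — a weak cross-family match inside another
    gene's exon would otherwise stitch its gene's cluster across foreign
    territory.  Overlapping loci of different genes are then resolved by
    higher summed score, then leftmost."""
    hits = _dedup_hits(hits)
    kept_spans = []
    filtered = []
    for h in sorted(hits, key=lambda h: -h.score):
        s, e = h.genomic_span
        clash = any(
            cid == h.orf.contig_id and s < ce and cs < e
            and (g != h.gene or st != h.strand)
            for g, cid, st, cs, ce in kept_spans
        )
        if not clash:
            kept_spans.append((h.gene, h.orf.contig_id, h.strand, s, e))
            filtered.append(h)
    hits = sorted(filtered, key=lambda h: h.genomic_span[0])
    groups = {}
    for h in hits:
        groups.setdefault((h.gene, h.orf.contig_id, h.strand), []).append(h)
    loci = []
    for (gene, cid, strand), ghits in sorted(groups.items()):
        ghits.sort(key=lambda h: h.genomic_span[0])
        current = [ghits[0]]
        for h in ghits[1:]:
            if h.genomic_span[0] - current[-1].genomic_span[1] <= max_intron:
                current.append(h)
            else:
                loci.append(GeneLocus(gene, cid, strand, current))
                current = [h]
        loci.append(GeneLocus(gene, cid, strand, current))
    # resolve overlaps between loci of different genes
    loci.sort(key=lambda l: (-l.score, l.start))
    kept = []
    for loc in loci:
        overlap = any(
            loc.contig_id == k.contig_id
            and loc.start < k.end and k.start < loc.end
            and loc.gene != k.gene
            for k in kept
        )
        if not overlap:
            kept.append(loc)
    kept.sort(key=lambda l: (l.contig_id, l.start))
    return kept


def call_full_genes(loci: list, full_coverage_min: float = DEFAULT_FULL_COVERAGE) -> list:
    """Mark loci carried by a single (near-)full-length hit as ``full``;
    they can be annotated directly as single-exon genes."""
    for loc in loci:
        best = max(loc.hits, key=lambda h: h.coverage)
        if best.coverage >= full_coverage_min and len(loc.hits) == 1:
            loc.status = "full"
    return loci


def flag_frameshift(loci: list, max_fs_gap: int = DEFAULT_MAX_FS_GAP) -> list:
    """Two same-strand hits of one gene in different reading frames covering
    adjacent reference intervals and separated by at most ``max_fs_gap`` nt
    indicate a frameshift (pseudogene or sequencing error): flag, never
    repair."""
    for loc in loci:
        if len(loc.hits) < 2:
            continue
        hs = sorted(loc.hits, key=lambda h: h.genomic_span[0])
        for a, b in zip(hs, hs[1:]):
            gap_nt = b.genomic_span[0] - a.genomic_span[1]
            if a.frame == b.frame:
                continue
            # local alignments of the two halves may overrun the frameshift
            # point in the wrong frame, so a genomic overlap up to the same
            # bound is tolerated
            if not (-max_fs_gap <= gap_nt <= max_fs_gap):
                continue
            ra, rb = (a, b) if a.strand == "+" else (b, a)
            ref_gap = rb.ref_span[0] - ra.ref_span[1]
            if -15 <= ref_gap <= 15:
                loc.status = "frameshift-suspect"
                loc.comments.append(
                    f"potential frameshift between {ra.genomic_span} and "
                    f"{rb.genomic_span} (pseudogene or sequencing error); not repaired"
                )
                break
    return loci


def flag_trans_splicing(loci: list, max_intron: int = DEFAULT_MAX_INTRON) -> list:
    """Partial loci of one gene on different strands or contigs, or farther
    apart than any plausible intron, are trans-splicing candidates."""
    by_gene = {}
    for loc in loci:
        by_gene.setdefault(loc.gene, []).append(loc)
    for gene, group in by_gene.items():
        if len(group) < 2:
            continue
        partials = [l for l in group if l.status in ("partial", "full")]
        if len(partials) < 2:
            continue
        # a marginal stray hit must not drag a solid gene into
        # trans-splice status: pieces must carry comparable evidence
        best = max(l.score for l in partials)
        partials = [l for l in partials if l.score >= max(100.0, 0.1 * best)]
        if len(partials) < 2:
            continue
        reasons = []
        strands = {l.strand for l in partials}
        contigs = {l.contig_id for l in partials}
        if len(strands) > 1:
            reasons.append("exons on different strands")
        if len(contigs) > 1:
            reasons.append("exons on different contigs")
        if len(contigs) == 1 and len(strands) == 1:
            spans = sorted((l.start, l.end) for l in partials)
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                if s2 - e1 > max_intron:
                    reasons.append(
                        f"distance {s2 - e1} nt exceeds the maximum intron length"
                    )
        if reasons:
            for l in partials:
                l.status = "trans-splice-suspect"
                l.comments.append("possible trans-spliced gene: " + "; ".join(reasons))
    return loci
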