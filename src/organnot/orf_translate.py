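"""Conceptual translation and ORF extraction.

The first annotation step translates the genome in all six reading frames
under the user-supplied genetic code and cuts each frame into maximal
stop-to-stop segments.  ORFs are deliberately stop-bounded rather than
ATG-bounded: mitochondrial codes use several alternative start codons and
start selection is deferred to the start-adjustment step, so a maximal
segment policy loses no candidates.  The default minimum length is 40 amino
acids.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .seq_io import Contig, GeneticCode, revcomp

DEFAULT_MIN_AA = 40


@dataclass
class Orf:
    """A maximal stop-free reading-frame segment.

    ``start``/``end`` are 0-based half-open forward-strand genomic
    coordinates of the coding span (terminal stop codon excluded); on
    circular contigs ``end`` may exceed the contig length to denote origin
    wrapping.  ``frame`` is the 0..2 offset on the reading strand.
    """

    contig_id: str
    strand: str
    frame: int
    start: int
    end: int
    aa_seq: str
    flags: list = field(default_factory=list)

    def __len__(self):
        return len(self.aa_seq)


def six_frame_translate(contig: Contig, code: GeneticCode) -> list:
    """Translations of frames +0, +1, +2, -0, -1, -2 (stops as ``*``;
    trailing partial codons dropped).  Frame -f is frame +f of the reverse
    complement."""
    if len(contig) < 3:
        raise ValueError(f"contig {contig.id!r} shorter than one codon")
    seq = contig.seq
    rc = revcomp(seq)
    return [code.translate(s[f:]) for s in (seq, rc) for f in range(3)]


def _frame_segments(aa: str, min_aa: int):
    """Yield (residue_start, residue_end) of maximal stop-free runs with at
    least ``min_aa`` residues."""
    start = 0
    for i, ch in enumerate(aa + "*"):
        if ch == "*":
            if i - start >= min_aa:
                yield start, i
            start = i + 1


def extract_orfs(contig: Contig, code: GeneticCode, min_aa: int = DEFAULT_MIN_AA) -> list:
    """All ORFs of at least ``min_aa`` residues across the six frames.

    On circular contigs each frame is read around the origin (up to three
    passes, which covers every frame/length combination); a stop-free circle
    is truncated at one genome length and flagged.
    """
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    n = len(contig)
    orfs = []
    seen = set()
    for strand in "+-":
        seq = contig.seq if strand == "+" else revcomp(contig.seq)
        passes = 3 if contig.circular else 1
        ext = seq * passes
        for frame in range(3):
            aa = code.translate(ext[frame:])
            for ra, rb in _frame_segments(aa, min_aa):
                s = frame + 3 * ra
                e = frame + 3 * rb
                flags = []
                if contig.circular:
                    stop_bounded = ra > 0
                    if not stop_bounded:
                        if "*" in aa:
                            # truncated view of a segment whose true start
                            # (after a stop) appears later in the extension
                            continue
                        # stop-free circular frame: truncate at one genome
                        # length
                        e = s + 3 * (n // 3)
                        rb = ra + (e - s) // 3
                        flags = ["truncated: no stop codon on circular frame"]
                    elif e - s > n:
                        e = s + 3 * (n // 3)
                        rb = ra + (e - s) // 3
                        flags = ["truncated: no stop codon on circular frame"]
                    fs, fe = _map_span(s, e, n, strand)
                    key = (strand, fs % n, fe - fs)
                    if key in seen:
                        continue
                    seen.add(key)
                    orfs.append(
                        Orf(contig.id, strand, fs % 3 if strand == "+" else frame,
                            fs, fe, aa[ra:rb], flags)
                    )
                else:
                    if strand == "+":
                        fs, fe = s, e
                    else:
                        fs, fe = n - e, n - s
                    orfs.append(Orf(contig.id, strand, frame, fs, fe, aa[ra:rb]))
    orfs.sort(key=lambda o: (o.start, o.end, o.strand, o.frame))
    return orfs


def _map_span(s: int, e: int, n: int, strand: str):
    """Map a span on the (possibly tripled) reading strand back to
    forward-strand circle coordinates, wrapping as start < n <= end."""
    length = e - s
    if strand == "+":
        fs = s % n
    else:
        fs = (n - e) % n
    return fs, fs + length
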