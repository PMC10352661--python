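"""Exon/intron gene modelling by spliced alignment.

A reference protein is aligned to a genomic region by a dynamic program over
(protein position x genomic position x {codon-phase exon states, intron
states}).  Introns may interrupt a codon at any phase; intron states carry
the nucleotides of the interrupted codon so that split codons are scored
exactly when the intron closes.  Intron openings pay a fixed penalty plus
splice-signal log-odds from the Group I/II models (each class scored with
its own matrices — never a merged one).

Alignment alone reproduces the well-known failure mode of pairwise spliced
aligners: exons shorter than ~4 codons are usually cheaper to delete than to
open a second intron for.  Those mini-exons are recovered afterwards by
``rescue_miniexons``: conserved profile positions that the model traverses
as deletions mark a missing block, candidate windows of the right size are
enumerated inside the flanking intron, each candidate is merged in frame
with the upstream exon, translated, and re-scored against the profile HMM,
and the best candidate is accepted if it clears a bit-score gain threshold.

Alignment scores are in half-bits (BLOSUM62 units); splice-signal log-odds
(bits) are folded in with a weight of 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from Bio.Align import substitution_matrices

from .seq_io import GeneticCode, revcomp
from .profile_hmm import ProfileHMM, viterbi, find_missing_blocks
from .intron_classifier import (
    IntronCall,
    SpliceModel,
    classify,
    score_intron,
    MIN_INTRON_LEN,
)

DEFAULT_MAX_INTRON = 20_000
DEFAULT_MINIEXON_MAX_CODONS = 4
DEFAULT_MIN_GAIN = 2.0  # bits of profile-score gain required to accept a mini-exon
DEFAULT_START_WINDOW = 10  # codons searched around the profile-implied start
# Splice-signal log-odds are weighted up when folded into the alignment so
# that a true acceptor a few nt away always beats absorbing stray residues
# against a random intron edge.
SPLICE_WEIGHT = 3.0  # bits -> half-bits, with emphasis
# The intron-open penalty is set so that, like pairwise spliced aligners,
# exons shorter than ~4 codons are cheaper to delete than to open a second
# intron for — those mini-exons are the rescue step's job.
INTRON_OPEN = -140.0  # half-bits
GAP_RES = -9.0  # unmatched protein residue (half-bits)
GAP_CODON = -9.0  # unmatched in-frame genomic codon (half-bits)
START_FALLBACK_ORDER = ("GTG", "TTG", "ATA")

_NT_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


class SplicedAlignError(ValueError):
    pass


@dataclass
class SplicedAlignment:
    """Colinear chain of exon-aligned segments with intron gaps, in local
    region coordinates (forward orientation of the aligned strand)."""

    protein: str
    score: float
    exons: list  # (start, end) region spans, 5'->3'
    introns: list  # (start, end, phase) region spans
    protein_span: tuple  # residues of the reference covered (0-based, half-open)


@dataclass
class GeneModel:
    gene: str
    contig_id: str
    strand: str
    exons: list  # genomic forward-strand spans, transcript order
    introns: list  # IntronCall objects (genomic coordinates)
    start_codon: str | None
    stop_codon: str | None
    translation: str
    score: float = 0.0
    flags: list = field(default_factory=list)
    comments: list = field(default_factory=list)

    def cds_length(self):
        return sum(e - s for s, e in self.exons)


# ---------------------------------------------------------------------------
# scoring tables
# ---------------------------------------------------------------------------

_BLOSUM = substitution_matrices.load("BLOSUM62")


def _codon_score_table(protein: str, code: GeneticCode) -> np.ndarray:
    """(m, 64) table of BLOSUM62 scores of each protein residue against the
    translation of each codon; stop codons score an effective -infinity so
    exons can never read through a stop."""
    m = len(protein)
    tab = np.empty((m, 64), dtype=np.float64)
    aa_of = []
    for idx in range(64):
        codon = "ACGT"[idx >> 4] + "ACGT"[(idx >> 2) & 3] + "ACGT"[idx & 3]
        aa_of.append(code.translate_codon(codon))
    alpha = _BLOSUM.alphabet
    for i, res in enumerate(protein):
        r = res if res in alpha else "X"
        for idx, aa in enumerate(aa_of):
            if aa == "*":
                tab[i, idx] = -1e9
            else:
                a = aa if aa in alpha else "X"
                tab[i, idx] = float(_BLOSUM[r, a])
    return tab


def splice_signal_arrays(region: str, splice_models: dict):
    """Per-position donor (intron starts here) and acceptor (intron ends
    here, inclusive) log-odds, taken as the best over the intron classes.

    Positional structural terms are folded in alongside the PWMs — the
    Group I P1 pairing between the internal guide and the upstream exon
    tail and the 3' terminal G, and the Group II branch adenosine — because
    for weakly conserved matrices the PWM alone cannot anchor a boundary
    against chance codon matches at the intron edge."""
    from .intron_classifier import count_pairs

    n = len(region)
    d_best = np.full(n, -np.inf)
    a_best = np.full(n, -np.inf)
    for model in splice_models.values():
        d = model.pwm5_scan(region)
        a = model.pwm3_scan(region)
        p = model.params
        if model.group == "I":
            gs, gl = int(p["p1_guide_start"]), int(p["p1_guide_len"])
            bonus = np.zeros(n)
            for j in range(gl, n - gs - gl):
                bonus[j] = count_pairs(region[j - gl : j],
                                       region[j + gs : j + gs + gl]) * p["p1_bonus_per_pair"]
            d = d + bonus
            term = np.zeros(n)
            for j in range(n):
                if region[j] == "G":
                    term[j] = p["terminal_g_bonus"]
            a = a + term
        else:
            lo, hi = int(p["branch_min"]), int(p["branch_max"])
            br = np.zeros(n)
            for j in range(-lo, n):
                if "A" in region[j + lo + 1 : j + hi + 2]:
                    br[j] = p["branch_bonus"]
            a = a + br
        d_best = np.maximum(d_best, d)
        a_best = np.maximum(a_best, a)
    return d_best, a_best


def _encode_dna(seq: str) -> np.ndarray:
    out = np.full(len(seq), -1, dtype=np.int8)
    for ch, v in _NT_CODE.items():
        out[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(ch)] = v
    return out


# ---------------------------------------------------------------------------
# the DP kernel
# ---------------------------------------------------------------------------


@njit(cache=True)
def _spliced_kernel(bl, genc, donor, accep, min_intron, gap_res, gap_codon,
                    intron_open):
    """Semiglobal (full protein) / local (genome) spliced alignment.

    bl: (m, 64) codon score table; genc: (n,) nt codes (-1 for N);
    donor[j]: splice score of an intron *starting* at 0-based position j;
    accep[j]: splice score of an intron *ending* (inclusive) at j.
    Returns E matrix, backpointer and aux (intron entry) matrices.
    """
    m = bl.shape[0]
    n = genc.shape[0]
    NEG = -1e15
    E = np.full((m + 1, n + 1), NEG)
    ptr = np.zeros((m + 1, n + 1), dtype=np.int8)
    aux = np.full((m + 1, n + 1), -1, dtype=np.int32)
    for j in range(n + 1):
        E[0, j] = 0.0  # free local start at any codon boundary
    # phase-1/2 entry values recorded per row for use by the next row
    e1 = np.full((4, n + 1), NEG)
    e2 = np.full((16, n + 1), NEG)
    e1_new = np.full((4, n + 1), NEG)
    e2_new = np.full((16, n + 1), NEG)

    for i in range(0, m + 1):
        # running maxima for intron exits landing in this row
        r0 = NEG
        r0_arg = -1
        r1 = np.full(4, NEG)
        r1_arg = np.full(4, -1, dtype=np.int32)
        r2 = np.full(16, NEG)
        r2_arg = np.full(16, -1, dtype=np.int32)
        for x in range(4):
            e1_new[x, :] = NEG
        for x in range(16):
            e2_new[x, :] = NEG
        for j in range(0, n + 1):
            # admit phase-0 entries from this row at je = j - min_intron
            je = j - min_intron
            if i > 0 and je >= 0 and je + 1 <= n:
                v = E[i, je] + intron_open + donor[je]
                # donor[je] scores an intron starting at genome index je
                # (0-based); entry after consuming je nts means the intron
                # occupies positions je .. ja-1
                if v > r0:
                    r0 = v
                    r0_arg = je
            # admit phase-1/2 entries from the previous row
            jp = j - min_intron - 3
            if i > 0 and jp >= 0:
                x = genc[jp] if jp < n else -1
                if x >= 0 and e1[x, jp] > r1[x]:
                    r1[x] = e1[x, jp]
                    r1_arg[x] = jp
                xy_ok = jp + 1 < n
                if xy_ok:
                    a = genc[jp]
                    b = genc[jp + 1]
                    if a >= 0 and b >= 0:
                        xy = a * 4 + b
                        if e2[xy, jp] > r2[xy]:
                            r2[xy] = e2[xy, jp]
                            r2_arg[xy] = jp
            if i == 0:
                # record phase entries for row 0 too (introns before residue 1
                # are not meaningful, so skip)
                continue
            best = NEG
            bp = 0
            barg = -1
            # match: contiguous codon ending at j
            if j >= 3:
                a = genc[j - 3]
                b = genc[j - 2]
                c = genc[j - 1]
                if a >= 0 and b >= 0 and c >= 0:
                    sc = E[i - 1, j - 3] + bl[i - 1, a * 16 + b * 4 + c]
                else:
                    sc = E[i - 1, j - 3] - 2.0  # codon containing N scores as X
                if sc > best:
                    best = sc
                    bp = 1
            # protein residue deleted
            sc = E[i - 1, j] + gap_res
            if sc > best:
                best = sc
                bp = 2
            # genomic codon inserted
            if j >= 3:
                sc = E[i, j - 3] + gap_codon
                if sc > best:
                    best = sc
                    bp = 3
            # phase-0 intron exit: intron ends at j-1 (acceptor), resume here
            if j >= 1 and r0 > NEG / 2:
                sc = r0 + accep[j - 1]
                if sc > best:
                    best = sc
                    bp = 4
                    barg = r0_arg
            # phase-1 exit: acceptor at j-3; codon = G[je] + G[j-2] + G[j-1]
            if j >= 3:
                b = genc[j - 2]
                c = genc[j - 1]
                if b >= 0 and c >= 0:
                    for x in range(4):
                        if r1[x] > NEG / 2:
                            sc = r1[x] + accep[j - 3] + bl[i - 1, x * 16 + b * 4 + c]
                            if sc > best:
                                best = sc
                                bp = 5
                                barg = r1_arg[x]
            # phase-2 exit: acceptor at j-2; codon = G[je] G[je+1] + G[j-1]
            if j >= 2:
                c = genc[j - 1]
                if c >= 0:
                    for xy in range(16):
                        if r2[xy] > NEG / 2:
                            sc = r2[xy] + accep[j - 2] + bl[i - 1, xy * 4 + c]
                            if sc > best:
                                best = sc
                                bp = 6
                                barg = r2_arg[xy]
            E[i, j] = best
            ptr[i, j] = bp
            aux[i, j] = barg
            # record phase-1/2 entries from this row (entry after E[i, j])
            if j + 1 <= n and j < n:
                x = genc[j]
                if x >= 0 and j + 1 < n:
                    e1_new[x, j] = E[i, j] + intron_open + donor[j + 1]
                if j + 2 < n:
                    a = genc[j]
                    b = genc[j + 1]
                    if a >= 0 and b >= 0:
                        e2_new[a * 4 + b, j] = E[i, j] + intron_open + donor[j + 2]
        for x in range(4):
            for j in range(n + 1):
                e1[x, j] = e1_new[x, j]
        for x in range(16):
            for j in range(n + 1):
                e2[x, j] = e2_new[x, j]
    return E, ptr, aux


def spliced_align(
    reference_protein: str,
    genomic_region: str,
    code: GeneticCode,
    splice_models: dict,
    max_intron: int = DEFAULT_MAX_INTRON,
    min_intron: int = MIN_INTRON_LEN,
    score_floor: float = 40.0,
) -> SplicedAlignment:
    """Best colinear exon chain aligning the full reference protein to the
    region (local in the genome, global in the protein).

    Raises :class:`SplicedAlignError` when no chain reaches ``score_floor``.
    """
    m = len(reference_protein)
    n = len(genomic_region)
    if n < 3:
        raise SplicedAlignError("region shorter than one codon")
    if n > max_intron + 3 * m + 2000:
        raise SplicedAlignError(
            f"region of {n} nt exceeds the maximum intron length budget"
        )
    bl = _codon_score_table(reference_protein, code)
    genc = _encode_dna(genomic_region)
    donor = np.full(n + 1, -1e9)
    accep = np.full(n + 1, -1e9)
    d_best, a_best = splice_signal_arrays(genomic_region, splice_models)
    donor[:n] = SPLICE_WEIGHT * d_best
    accep[:n] = SPLICE_WEIGHT * a_best
    E, ptr, aux = _spliced_kernel(
        bl, genc, donor, accep, min_intron, GAP_RES, GAP_CODON, INTRON_OPEN
    )
    j_end = int(np.argmax(E[m]))
    score = float(E[m, j_end])
    if score < score_floor:
        raise SplicedAlignError(f"no spliced chain above score floor ({score:.1f})")
    # traceback
    i, j = m, j_end
    boundaries = []  # intron spans (start, end, phase) in region coords
    first_j = j
    while i > 0:
        bp = ptr[i, j]
        if bp == 1:
            i, j = i - 1, j - 3
        elif bp == 2:
            i = i - 1
        elif bp == 3:
            j = j - 3
        elif bp == 4:
            je = int(aux[i, j])
            boundaries.append((je, j - 1, 0))
            j = je
        elif bp == 5:
            je = int(aux[i, j])
            boundaries.append((je + 1, j - 3, 1))
            i, j = i - 1, je
        elif bp == 6:
            je = int(aux[i, j])
            boundaries.append((je + 2, j - 2, 2))
            i, j = i - 1, je
        else:
            break
        first_j = j
    prot_start = i
    boundaries.reverse()
    introns = [(s, e + 1, ph) for s, e, ph in boundaries]
    exons = []
    cur = first_j
    for s, e, _ in introns:
        exons.append((cur, s))
        cur = e
    exons.append((cur, j_end))
    exons = [(s, e) for s, e in exons if e > s]
    return SplicedAlignment(
        protein=reference_protein,
        score=score,
        exons=exons,
        introns=introns,
        protein_span=(prot_start, m),
    )


# ---------------------------------------------------------------------------
# gene-model construction helpers (region coordinates, forward orientation)
# ---------------------------------------------------------------------------


def _spliced_cds(region: str, exons) -> str:
    return "".join(region[s:e] for s, e in exons)


def refine_boundaries(
    alignment: SplicedAlignment,
    region: str,
    models: dict,
    code: GeneticCode,
    jitter: int = 6,
) -> tuple:
    """Re-optimize each intron's boundaries within a +-``jitter`` nt window
    using the classified group's own splice model.

    Donor and acceptor slide together (preserving reading frame); a shift is
    legal only if the spliced translation stays stop-free.  The
    highest-scoring legal shift wins, ties break leftmost.  Returns
    (exons, intron_calls) in region coordinates.  Idempotent when the
    current boundaries already score best.
    """
    exons = list(alignment.exons)
    calls = []
    for k, (istart, iend, phase) in enumerate(alignment.introns):
        # each legal shift is classified afresh; the winner is the shift
        # whose best class model gives the smallest calibrated E-value, so a
        # slightly displaced boundary can recover both its position and its
        # group assignment in one move
        best = None
        for delta in range(-jitter, jitter + 1):
            s, e = istart + delta, iend + delta
            if s <= exons[k][0] or e >= exons[k + 1][1]:
                continue
            cand_exons = list(exons)
            cand_exons[k] = (exons[k][0], s)
            cand_exons[k + 1] = (e, exons[k + 1][1])
            cds = _spliced_cds(region, cand_exons)
            if "*" in code.translate(cds[: len(cds) - len(cds) % 3]):
                continue
            call = classify(region[s:e], region[max(0, s - 8) : s], models, start=s)
            # deltas ascend, so the first minimum is the leftmost tie
            if best is None or call.evalue < best[0].evalue:
                best = (call, delta)
        if best is None:
            call = classify(region[istart:iend],
                            region[max(0, istart - 8) : istart], models,
                            start=istart)
        else:
            call, delta = best
            if delta != 0:
                s, e = istart + delta, iend + delta
                exons[k] = (exons[k][0], s)
                exons[k + 1] = (e, exons[k + 1][1])
                call.comments.append(f"boundary adjusted by {delta:+d} nt")
        calls.append(call)
    return exons, calls


def rescue_miniexons(
    exons: list,
    intron_calls: list,
    region: str,
    profile: ProfileHMM,
    models: dict,
    code: GeneticCode,
    max_codons: int = DEFAULT_MINIEXON_MAX_CODONS,
    min_gain: float = DEFAULT_MIN_GAIN,
    min_intron: int = MIN_INTRON_LEN,
):
    """Recover mini-exons the aligner deleted.

    Conserved profile match states traversed as deletions mark missing
    blocks; genomic windows of 3b +- 3 nt inside the bracketing intron whose
    edges admit legal splice signals are merged in frame with the upstream
    exon, translated and scored against the profile; the top candidate is
    accepted iff it beats the no-mini-exon score by ``min_gain`` bits.

    A skipped mini-exon does not always leave deletions behind: the aligner
    may instead absorb its residues against the intron edge as (poor)
    matches, hiding the block.  When no block is found directly, boundary
    trims of up to 3 codons on either side of each intron are tried; a trim
    is committed only if it exposes a block whose rescue then succeeds and
    raises the overall profile score.

    Returns (exons, intron_calls, comments, rescued_flag).
    """
    exons, intron_calls, comments, rescued = _rescue_pass(
        exons, intron_calls, region, profile, models, code,
        max_codons, min_gain, min_intron,
    )
    if rescued:
        return exons, intron_calls, comments, rescued
    base_cds = _spliced_cds(region, exons)
    base_score = viterbi(
        profile, code.translate(base_cds[: len(base_cds) - len(base_cds) % 3])
    ).score
    for k in range(len(exons) - 1):
        for side in ("donor", "acceptor"):
            for t in (1, 2, 3):
                trial = [list(x) for x in exons]
                if side == "donor":
                    trial[k][1] -= 3 * t
                    if trial[k][1] - trial[k][0] < 9:
                        continue
                else:
                    trial[k + 1][0] += 3 * t
                    if trial[k + 1][1] - trial[k + 1][0] < 9:
                        continue
                trial = [tuple(x) for x in trial]
                t_exons, t_calls, t_comments, t_rescued = _rescue_pass(
                    trial, intron_calls, region, profile, models, code,
                    max_codons, min_gain, min_intron,
                )
                if not t_rescued:
                    continue
                t_cds = _spliced_cds(region, t_exons)
                t_score = viterbi(
                    profile,
                    code.translate(t_cds[: len(t_cds) - len(t_cds) % 3]),
                ).score
                if t_score >= base_score + min_gain:
                    new_calls = []
                    for (s1, e1), (s2, e2) in zip(t_exons, t_exons[1:]):
                        new_calls.append(classify(
                            region[e1:s2], region[max(0, e1 - 8) : e1],
                            models, start=e1,
                        ))
                    comments.extend(t_comments)
                    comments.append(
                        f"intron boundary trimmed by {t} codon(s) on the "
                        f"{side} side to expose a hidden mini-exon"
                    )
                    return t_exons, new_calls, comments, True
    return exons, intron_calls, comments, rescued


def _rescue_pass(
    exons: list,
    intron_calls: list,
    region: str,
    profile: ProfileHMM,
    models: dict,
    code: GeneticCode,
    max_codons: int,
    min_gain: float,
    min_intron: int,
):
    comments = []
    rescued = False
    cds = _spliced_cds(region, exons)
    translation = code.translate(cds[: len(cds) - len(cds) % 3])
    hit = viterbi(profile, translation)
    blocks = find_missing_blocks(hit, profile)
    if not blocks:
        return exons, intron_calls, comments, rescued
    # map profile states to translation residues to exon positions
    state_to_res = {}
    for op, k, t in hit.trace:
        if op == "M":
            state_to_res[k] = t
    for first_state, last_state in blocks:
        b = last_state - first_state + 1
        if b > max_codons:
            comments.append(
                f"missing conserved block of {b} residues exceeds the mini-exon bound"
            )
            continue
        # residues flanking the block in the current translation
        left_res = max(
            (state_to_res[k] for k in range(first_state - 1, 0, -1) if k in state_to_res),
            default=None,
        )
        if left_res is None:
            comments.append("missing block at the protein N-terminus; no upstream exon to merge")
            continue
        # locate the intron bracketing the block: the one following the exon
        # that contains the codon of left_res
        cds_pos = 3 * (left_res + 1)  # nt offset just after the left residue
        acc = 0
        host = None
        for idx, (s, e) in enumerate(exons[:-1]):
            acc += e - s
            if cds_pos <= acc:
                host = idx
                break
        if host is None:
            comments.append("missing block not bracketed by an intron; not rescued")
            continue
        istart, iend = exons[host][1], exons[host + 1][0]
        group = intron_calls[host].group if host < len(intron_calls) else "unknown"
        group_model = models.get(group) or next(iter(models.values()))
        # merge candidates with the upstream flanking exon (plus its in-frame
        # upstream context, so translation stays in the CDS frame)
        up_part = _spliced_cds(region, exons[: host + 1])
        base_hit = viterbi(profile, code.translate(up_part[: len(up_part) - len(up_part) % 3]))
        candidates = []
        for w in sorted({3 * b - 3, 3 * b, 3 * b + 3}):
            if w <= 0:
                continue
            for s in range(istart + min_intron, iend - min_intron - w + 1):
                e = s + w
                # both child introns need legal splice signals
                acc_sc = group_model.score_3p(region[s - group_model.w3 : s])
                don_sc = group_model.score_5p(region[e : e + group_model.w5])
                if acc_sc < 0 or don_sc < 0:
                    continue
                merged = up_part + region[s:e]
                aa = code.translate(merged[: len(merged) - len(merged) % 3])
                if "*" in aa:
                    continue
                sc = viterbi(profile, aa).score
                gain = sc - base_hit.score
                candidates.append((gain, s, e, acc_sc + don_sc))
        if not candidates:
            comments.append(
                f"no mini-exon candidate with legal splice signals for missing "
                f"block {first_state}-{last_state}; model unchanged"
            )
            continue
        candidates.sort(key=lambda c: (-c[0], -c[3], c[1]))
        gain, s, e, _ = candidates[0]
        if gain < min_gain:
            comments.append(
                f"best mini-exon candidate gain {gain:.1f} bits below threshold; "
                f"model unchanged"
            )
            continue
        ties = [c for c in candidates if c[0] == gain and c[3] == candidates[0][3]]
        if len(ties) > 1:
            alts = ", ".join(f"{c[1]}-{c[2]}" for c in ties[1:])
            comments.append(f"equal-scoring mini-exon alternatives at {alts}")
        tail1 = region[max(0, istart - 8) : istart]
        call1 = classify(region[istart:s], tail1, models, start=istart)
        call2 = classify(region[e:iend], region[s:e][-8:], models, start=e)
        exons = exons[: host + 1] + [(s, e)] + exons[host + 1 :]
        intron_calls = intron_calls[:host] + [call1, call2] + intron_calls[host + 1 :]
        comments.append(f"mini-exon-added: {b}-codon exon restored at {s}-{e}")
        rescued = True
        # recompute the translation context for any further blocks
        cds = _spliced_cds(region, exons)
        translation = code.translate(cds[: len(cds) - len(cds) % 3])
        hit = viterbi(profile, translation)
        state_to_res = {k: t for op, k, t in hit.trace if op == "M"}
    return exons, intron_calls, comments, rescued


def adjust_start(
    exons: list,
    region: str,
    code: GeneticCode,
    window_codons: int = DEFAULT_START_WINDOW,
):
    """Choose the translation start nearest the profile-implied position.

    In-frame ATG codons within +-``window_codons`` of the implied start are
    preferred (nearest first); failing that, the alternative starts are
    tried in the fixed order GTG, TTG, ATA.  If none is present the implied
    start is kept and a comment records the absence.  Returns
    (exons, start_codon, comments).
    """
    comments = []
    s0, e0 = exons[0]
    limit = exons[0][1]

    def codon_at(pos):
        if pos < 0 or pos + 3 > limit:
            return None
        return region[pos : pos + 3]

    def stop_free(pos):
        # moving the start must not expose an in-frame stop before the exon end
        if pos >= s0:
            return True
        seg = region[pos:s0]
        return "*" not in code.translate(seg)

    candidates = []
    for t in range(-window_codons, window_codons + 1):
        pos = s0 + 3 * t
        c = codon_at(pos)
        if c is None or not stop_free(pos):
            continue
        candidates.append((abs(t), t, pos, c))
    candidates.sort()
    for target in ("ATG",) + START_FALLBACK_ORDER:
        for _, t, pos, c in candidates:
            if c == target:
                if t != 0:
                    comments.append(f"start codon moved by {t:+d} codons to {target}")
                if target != "ATG":
                    comments.append(f"alternative start codon {target}")
                return [(pos, e0)] + exons[1:], target, comments
    comments.append("no start codon found (ATG/GTG/TTG/ATA); profile-implied start kept")
    return exons, None, comments
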