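"""Non-coding RNA gene detection.

Three detector families live here:

* **tRNAs** — a geometric cloverleaf search (acceptor stem, D-arm,
  anticodon arm with a 7-9 nt loop, T-arm anchored on the T-loop motif).
  The anticodon is read center-anchored from the loop; tRNA identity is the
  translation of the reverse-complemented anticodon under the user's
  genetic code, with predicted codon reading derived from wobble or
  superwobble rules.  Acceptor-stem identity elements (such as a G3:U70
  pair) are deliberately not consulted, so rare synthetase-driven codon
  reassignments will be missed — by design, the genetic code is the user's
  responsibility.

* **rRNAs** — nucleotide profile HMMs over conserved cores.  The
  small-subunit gene (rns) is core-complete, so its termini are precise;
  the large-subunit gene (rnl) has weakly conserved termini that are first
  placed at nominal offsets from the core with +-50 nt uncertainty, then
  optionally refined by locating the terminal helix that joins the 5' and
  3' ends.  Introns inside rRNA genes are detected and reported separately,
  without exon modelling.

* **Structured ncRNAs** (rrn5, ssrA, optionally rnpB) — ordered
  structure-profile search: precisely delimited helix/strand elements are
  evaluated in a configurable order starting from an anchor element, with
  hard sequence constraints (the tmRNA model requires the invariant GAC
  motif and a G-U pair in helix 3).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .seq_io import Contig, GeneticCode, revcomp
from .profile_hmm import ProfileHMM, viterbi
from .intron_classifier import can_pair, count_pairs, classify, MIN_INTRON_LEN, pwm_logodds

TLOOP_ANCHOR = "TTCGA"
TRNA_MIN_TOTAL_PAIRS = 20


@dataclass
class TrnaCall:
    start: int
    end: int
    strand: str
    anticodon: str  # DNA letters, gene orientation
    anticodon_span: tuple  # genomic span of the anticodon
    loop_len: int
    acceptor_pairs: int  # of 7
    amino_acid: str
    codons_read: set
    score: float
    comments: list = field(default_factory=list)

    def __post_init__(self):
        if not (7 <= self.loop_len <= 9):
            raise ValueError("anticodon loop length must lie in [7, 9]")


@dataclass
class NcrnaCall:
    gene: str
    start: int
    end: int
    strand: str
    score: float
    evalue: float
    uncertainty5: int = 0  # +- nt uncertainty of each terminus
    uncertainty3: int = 0
    comments: list = field(default_factory=list)

    def __post_init__(self):
        if self.evalue < 0:
            raise ValueError("E-value must be >= 0")


# ---------------------------------------------------------------------------
# tRNA cloverleaf search
# ---------------------------------------------------------------------------

#: cloverleaf geometry: stem lengths are canonical; spacer/loop ranges admit
#: the common structural variation (including 8-9 nt anticodon loops)
TRNA_GEOMETRY = {
    "acc_stem": 7, "acc_min_pairs": 5,
    "spacer1": (1, 3),
    "d_stem": 4, "d_min_pairs": 3, "d_loop": (5, 12),
    "spacer2": (0, 2),
    "ac_stem": 5, "ac_min_pairs": 4, "ac_loop": (7, 9),
    "var_loop": (3, 23),
    "t_stem": 5, "t_min_pairs": 4, "t_loop": 7,
    "discriminator": 1,
}


def _trna_candidates_at(seq: str, p: int, geo: dict):
    """Enumerate cloverleaf geometries with the T-loop starting at ``p``;
    yield (start, end, total_pairs, parts) for structures passing the
    per-arm minima."""
    n = len(seq)
    ts = geo["t_stem"]
    tl = geo["t_loop"]
    if p - ts < 0 or p + tl + ts + geo["acc_stem"] + geo["discriminator"] > n:
        return
    tstem5 = seq[p - ts : p]
    tstem3 = seq[p + tl : p + tl + ts]
    t_pairs = count_pairs(tstem5, tstem3)
    if t_pairs < geo["t_min_pairs"]:
        return
    acc3 = seq[p + tl + ts : p + tl + ts + geo["acc_stem"]]
    end = p + tl + ts + geo["acc_stem"] + geo["discriminator"]
    acs = geo["ac_stem"]
    ds = geo["d_stem"]
    for var in range(geo["var_loop"][0], geo["var_loop"][1] + 1):
        ac3_end = p - ts - var
        if ac3_end - acs < 0:
            continue
        ac_stem3 = seq[ac3_end - acs : ac3_end]
        for loop in range(geo["ac_loop"][0], geo["ac_loop"][1] + 1):
            ac5_start = ac3_end - acs - loop - acs
            if ac5_start < 0:
                continue
            ac_stem5 = seq[ac5_start : ac5_start + acs]
            ac_pairs = count_pairs(ac_stem5, ac_stem3)
            if ac_pairs < geo["ac_min_pairs"]:
                continue
            for sp2 in range(geo["spacer2"][0], geo["spacer2"][1] + 1):
                d3_end = ac5_start - sp2
                if d3_end - ds < 0:
                    continue
                d_stem3 = seq[d3_end - ds : d3_end]
                for dloop in range(geo["d_loop"][0], geo["d_loop"][1] + 1):
                    d5_start = d3_end - ds - dloop - ds
                    if d5_start < 0:
                        continue
                    d_stem5 = seq[d5_start : d5_start + ds]
                    d_pairs = count_pairs(d_stem5, d_stem3)
                    if d_pairs < geo["d_min_pairs"]:
                        continue
                    for sp1 in range(geo["spacer1"][0], geo["spacer1"][1] + 1):
                        start = d5_start - sp1 - geo["acc_stem"]
                        if start < 0:
                            continue
                        acc5 = seq[start : start + geo["acc_stem"]]
                        acc_pairs = count_pairs(acc5, acc3)
                        if acc_pairs < geo["acc_min_pairs"]:
                            continue
                        total = acc_pairs + d_pairs + ac_pairs + t_pairs
                        yield (
                            start, end, total,
                            {
                                "acc_pairs": acc_pairs,
                                "anticodon_loop_start": ac5_start + acs,
                                "loop_len": loop,
                            },
                        )


def find_trnas(contig: Contig, code: GeneticCode, geometry: dict | None = None,
               min_total_pairs: int = TRNA_MIN_TOTAL_PAIRS) -> list:
    """Cloverleaf scan of both strands.

    Candidates are anchored on the T-loop motif; arms must satisfy the
    per-arm pairing minima and the summed stem pairing must reach
    ``min_total_pairs`` (of 21).  Identity is always the active-code
    translation of the reverse-complemented anticodon."""
    geo = geometry or TRNA_GEOMETRY
    n = len(contig)
    calls = []
    for strand in "+-":
        seq = contig.seq if strand == "+" else revcomp(contig.seq)
        p = seq.find(TLOOP_ANCHOR)
        while p != -1:
            best = None
            for start, end, total, parts in _trna_candidates_at(seq, p, geo):
                if total < min_total_pairs:
                    continue
                if best is None or total > best[2]:
                    best = (start, end, total, parts)
            if best is not None:
                start, end, total, parts = best
                loop_len = parts["loop_len"]
                ls = parts["anticodon_loop_start"]
                ac_off = (loop_len - 3) // 2
                anticodon = seq[ls + ac_off : ls + ac_off + 3]
                aa = code.translate_codon(revcomp(anticodon))
                if strand == "+":
                    gs, ge = start, end
                    a_span = (ls + ac_off, ls + ac_off + 3)
                else:
                    gs, ge = n - end, n - start
                    a_span = (n - (ls + ac_off + 3), n - (ls + ac_off))
                comments = []
                if loop_len != 7:
                    comments.append(
                        f"unusual anticodon loop ({loop_len} nt); decoding may be "
                        f"reassigned — identity follows the supplied genetic code"
                    )
                calls.append(
                    TrnaCall(
                        start=gs, end=ge, strand=strand,
                        anticodon=anticodon, anticodon_span=a_span,
                        loop_len=loop_len, acceptor_pairs=parts["acc_pairs"],
                        amino_acid=aa,
                        codons_read=predict_codon_read(anticodon, "standard"),
                        score=float(total), comments=comments,
                    )
                )
            p = seq.find(TLOOP_ANCHOR, p + 1)
    # greedy non-overlap, higher score first
    calls.sort(key=lambda c: (-c.score, c.start))
    chosen = []
    for c in calls:
        if all(c.end <= o.start or c.start >= o.end for o in chosen):
            chosen.append(c)
    chosen.sort(key=lambda c: c.start)
    return chosen


_WOBBLE_34 = {
    # anticodon position 34 (first base) -> codon third-position bases read
    "G": "CU",
    "U": "AG",
    "C": "G",
    "A": "U",
}


def predict_codon_read(anticodon: str, wobble_mode: str = "standard") -> set:
    """Codons readable by a tRNA with the given anticodon (RNA letters).

    Standard wobble follows the position-34 pairing rules (G reads C/U; U
    reads A/G; C reads G only; A reads U); in superwobble mode an unmodified
    U34 reads all four codons of its family box."""
    ac = anticodon.upper().replace("T", "U")
    if len(ac) != 3:
        raise ValueError("anticodon must be 3 nt")
    comp = {"A": "U", "U": "A", "G": "C", "C": "G"}
    stem = comp[ac[2]] + comp[ac[1]]
    w = ac[0]
    if wobble_mode == "superwobble" and w == "U":
        thirds = "ACGU"
    elif wobble_mode in ("standard", "superwobble"):
        thirds = _WOBBLE_34[w]
    else:
        raise ValueError(f"unknown wobble mode {wobble_mode!r}")
    return {stem + t for t in thirds}


# ---------------------------------------------------------------------------
# rRNA genes
# ---------------------------------------------------------------------------


@dataclass
class RrnaModel:
    """A core nucleotide profile plus the terminus convention around it."""

    gene: str
    profile: ProfileHMM
    flank5: int = 0  # nominal nt between gene 5' terminus and core start
    flank3: int = 0
    terminus_uncertainty: int = 0  # +- window on each terminus


def _best_hit_both_strands(profile: ProfileHMM, contig: Contig):
    hit_f = viterbi(profile, contig.seq, target_id=contig.id)
    hit_r = viterbi(profile, revcomp(contig.seq), target_id=contig.id)
    if hit_f.score >= hit_r.score:
        return hit_f, "+"
    return hit_r, "-"


def find_rrna(
    contig: Contig,
    model: RrnaModel,
    intron_models: dict | None = None,
    max_rrna_intron: int = 3000,
    min_score: float = 50.0,
) -> tuple:
    """Locate an rRNA gene via its core profile.

    Returns (NcrnaCall or None, [IntronCall...]).  Core termini are
    extrapolated to the model ends, then extended by the model's nominal
    flank lengths with the model's terminus uncertainty.  If the core is
    split in two by an intron, the pieces are chained, the gene call covers
    both, and the intervening intron is reported separately with a comment —
    no exon model is inferred for rRNA genes.
    """
    profile = model.profile
    hit, strand = _best_hit_both_strands(profile, contig)
    if hit.score < min_score or not hit.trace:
        return None, []
    n = len(contig)
    seq = contig.seq if strand == "+" else revcomp(contig.seq)
    M = profile.M
    intron_calls = []
    comments = []
    core_start = hit.target_start - (hit.model_start - 1)
    core_end = hit.target_end + (M - hit.model_end)
    model_cov = (hit.model_end - hit.model_start + 1) / M
    # an intron short enough to bridge shows up as a long insert run
    run_start = None
    prev_t = None
    insert_runs = []
    for op, k, t in hit.trace + [("M", -1, -1)]:
        if op == "I":
            if run_start is None:
                run_start = t
            prev_t = t
        else:
            if run_start is not None and prev_t - run_start + 1 >= MIN_INTRON_LEN:
                insert_runs.append((run_start, prev_t + 1))
            run_start = None
    for gs, ge in insert_runs:
        if ge - gs <= max_rrna_intron:
            comments.append("intron present; exon model not inferred")
            if intron_models:
                # alignment places the insert run only approximately; slide
                # the window a few nt to find the best splice-signal fit
                best = None
                for delta in range(-6, 7):
                    s, e = gs + delta, ge + delta
                    if s < 0 or e > len(seq):
                        continue
                    c = classify(seq[s:e], seq[max(0, s - 8) : s],
                                 intron_models, start=s)
                    if best is None or c.evalue < best.evalue:
                        best = c
                intron_calls.append(best)
    if model_cov < 0.9:
        # look for the rest of the core on either side (intron-split gene)
        def _register_gap(gap_start, gap_end):
            gap_len = gap_end - gap_start
            if MIN_INTRON_LEN <= gap_len <= max_rrna_intron:
                comments.append("intron present; exon model not inferred")
                if intron_models:
                    intron_calls.append(classify(
                        seq[gap_start:gap_end],
                        seq[max(0, gap_start - 8) : gap_start],
                        intron_models,
                        start=gap_start,
                    ))
                return True
            return False

        if hit.model_end < M - 10 and hit.target_end < len(seq):
            right = viterbi(profile, seq[hit.target_end :], target_id=contig.id)
            if (right.score >= min_score / 2 and right.trace
                    and right.model_start > hit.model_end):
                gap_end = hit.target_end + right.target_start
                if _register_gap(hit.target_end, gap_end):
                    core_end = (hit.target_end + right.target_end
                                + (M - right.model_end))
        if hit.model_start > 10 and hit.target_start > 0:
            left = viterbi(profile, seq[: hit.target_start], target_id=contig.id)
            if (left.score >= min_score / 2 and left.trace
                    and left.model_end < hit.model_start):
                if _register_gap(left.target_end, hit.target_start):
                    core_start = left.target_start - (left.model_start - 1)
    start = core_start - model.flank5
    end = core_end + model.flank3
    if strand == "+":
        gs, ge = start, end
    else:
        gs, ge = n - end, n - start
        for ic in intron_calls:
            ic.start, ic.end = n - ic.end, n - ic.start
            ic.strand = "-"
    gs = max(0, gs)
    ge = min(n, ge)
    calib = profile.calibration
    if calib:
        mu, lam = calib
        ev = -math.expm1(-math.exp(-lam * (hit.score - mu)))
    else:
        ev = 0.0
    call = NcrnaCall(
        gene=model.gene,
        start=gs,
        end=ge,
        strand=strand,
        score=hit.score,
        evalue=max(ev, 0.0),
        uncertainty5=model.terminus_uncertainty,
        uncertainty3=model.terminus_uncertainty,
        comments=comments,
    )
    return call, intron_calls


def refine_rnl_termini(
    contig: Contig,
    rough_call: NcrnaCall,
    min_pairs: int = 6,
    max_stem: int = 14,
    window: int | None = None,
    score_threshold: float = 8.0,
) -> NcrnaCall:
    """Sharpen rnl termini by locating the terminal helix.

    The two +-window terminus regions are scanned for the maximal-scoring
    complementary duplex (Watson-Crick + G-U, up to one looped-out
    position); if one scores at least ``score_threshold`` paired positions
    the termini are placed adjacent to the duplex ends and the uncertainty
    shrinks; otherwise the rough call is returned with a comment.  Ties
    break toward the longer duplex, then more G-C pairs, then leftmost.
    """
    w = window if window is not None else max(rough_call.uncertainty5, 1)
    n = len(contig)
    seq = contig.seq if rough_call.strand == "+" else revcomp(contig.seq)
    if rough_call.strand == "+":
        s0, e0 = rough_call.start, rough_call.end
    else:
        s0, e0 = n - rough_call.end, n - rough_call.start
    w5_lo = max(0, s0 - w)
    w5_hi = min(n, s0 + w + max_stem)
    w3_lo = max(0, e0 - w - max_stem)
    w3_hi = min(n, e0 + w)
    best = None  # (score, length, gc, -i), i, j, L
    for L in range(min_pairs, max_stem + 1):
        for i in range(w5_lo, w5_hi - L + 1):
            left = seq[i : i + L]
            for j in range(w3_lo, w3_hi - L + 1):
                if j < i + L:
                    continue
                right = seq[j : j + L]
                pairs = count_pairs(left, right)
                if pairs < L - 1 or pairs < min_pairs:
                    continue  # at most one looped-out/mismatched position
                gc = wc = 0
                for a, b in zip(left, right[::-1]):
                    if {a, b} == {"G", "C"}:
                        gc += 1
                        wc += 1
                    elif {a, b} in ({"A", "T"},):
                        wc += 1
                # Watson-Crick pairs carry full weight, G-U wobbles less:
                # chance duplexes lean on wobbles, real terminal helices on
                # WC.  Ties prefer more G-C, then the better-paired (more
                # compact) duplex, then leftmost.
                score = wc + 0.4 * (pairs - wc)
                key = (score, gc, -L, -i)
                if best is None or key > best[0]:
                    best = (key, i, j, L)
    if best is None or best[0][0] < score_threshold:
        out = _copy_call(rough_call)
        out.comments = rough_call.comments + [
            "no terminal helix found; termini remain +-"
            f"{rough_call.uncertainty5} nt"
        ]
        return out
    _, i, j, L = best
    new_s, new_e = i, j + L
    if rough_call.strand == "+":
        gs, ge = new_s, new_e
    else:
        gs, ge = n - new_e, n - new_s
    out = _copy_call(rough_call)
    out.start, out.end = gs, ge
    out.uncertainty5 = out.uncertainty3 = 3
    out.comments = rough_call.comments + [
        f"termini refined to the terminal helix ({L} bp)"
    ]
    return out


def _copy_call(call: NcrnaCall) -> NcrnaCall:
    return NcrnaCall(
        gene=call.gene, start=call.start, end=call.end, strand=call.strand,
        score=call.score, evalue=call.evalue,
        uncertainty5=call.uncertainty5, uncertainty3=call.uncertainty3,
        comments=list(call.comments),
    )


# ---------------------------------------------------------------------------
# Ordered structure-profile search (5S rRNA, tmRNA, ...)
# ---------------------------------------------------------------------------


@dataclass
class StrandElement:
    pwm: np.ndarray  # (w, 4) probabilities, columns A C G T
    hard: list = field(default_factory=list)  # (offset, base) required exactly

    @property
    def width(self):
        return self.pwm.shape[0]


@dataclass
class HelixElement:
    stem: int
    loop_min: int
    loop_max: int
    min_pairs: int
    require_gu: bool = False

    @property
    def min_width(self):
        return 2 * self.stem + self.loop_min

    @property
    def max_width(self):
        return 2 * self.stem + self.loop_max


@dataclass
class StructureProfile:
    """Ordered helix/strand elements with spacer ranges and a search
    strategy (a permutation of element indices; the first is the anchor
    scanned genome-wide, the rest are placed within their spacer ranges)."""

    name: str
    elements: list
    spacers: list  # (min, max) between consecutive elements
    strategy: list
    calibration: tuple | None = None
    pair_bonus: float = 1.0
    gu_bonus: float = 1.0

    def __post_init__(self):
        if sorted(self.strategy) != list(range(len(self.elements))):
            raise ValueError("strategy must be a permutation of element indices")
        if len(self.spacers) != len(self.elements) - 1:
            raise ValueError("need one spacer range between each element pair")


def _score_strand(el: StrandElement, seq: str, pos: int):
    if pos < 0 or pos + el.width > len(seq):
        return None
    window = seq[pos : pos + el.width]
    for off, base in el.hard:
        if window[off] != base:
            return None
    return pwm_logodds(el.pwm, window)


def _best_helix(el: HelixElement, seq: str, lo: int, hi: int, pb, gub,
                soft: bool = False):
    """Best helix placement with 5' strand start in [lo, hi]; returns
    (score, start, width) or None.  ``soft`` relaxes the pairing minimum and
    the G-U requirement (null calibration)."""
    best = None
    for start in range(max(0, lo), hi + 1):
        for loop in range(el.loop_min, el.loop_max + 1):
            width = 2 * el.stem + loop
            if start + width > len(seq):
                continue
            left = seq[start : start + el.stem]
            right = seq[start + el.stem + loop : start + width]
            pairs = count_pairs(left, right)
            if not soft and pairs < el.min_pairs:
                continue
            has_gu = any(
                {a, b} == {"G", "T"} for a, b in zip(left, right[::-1])
            )
            if not soft and el.require_gu and not has_gu:
                continue
            wc = sum(
                1 for a, b in zip(left, right[::-1])
                if {a, b} in ({"G", "C"}, {"A", "T"})
            )
            # Watson-Crick pairs outweigh wobbles so chance wobble-heavy
            # windows cannot tie a genuine stem
            score = (wc + 0.4 * (pairs - wc)) * pb + (gub if has_gu else 0.0)
            if best is None or score > best[0]:
                best = (score, start, width)
    return best


def search_structure(
    contig: Contig,
    profile: StructureProfile,
    threshold: float = 1e-3,
    anchor_floor: float = 8.0,
) -> list:
    """Scan both strands with an ordered-element structure profile.

    The anchor element (first in the search strategy) must be a strand; it
    is scanned genome-wide and every position above ``anchor_floor`` (and
    satisfying its hard constraints) seeds placement of the remaining
    elements within their spacer ranges.  Calls pass if the calibrated
    E-value is <= ``threshold``."""
    anchor_idx = profile.strategy[0]
    anchor = profile.elements[anchor_idx]
    if not isinstance(anchor, StrandElement):
        raise ValueError("the anchor element of the search strategy must be a strand")
    n = len(contig)
    hits = []
    for strand in "+-":
        seq = contig.seq if strand == "+" else revcomp(contig.seq)
        for pos in range(0, n - anchor.width + 1):
            sc = _score_strand(anchor, seq, pos)
            if sc is None or sc < anchor_floor:
                continue
            placed = _place_elements(profile, seq, anchor_idx, pos, sc)
            if placed is None:
                continue
            total, span = placed
            if strand == "+":
                gs, ge = span
            else:
                gs, ge = n - span[1], n - span[0]
            hits.append((total, gs, ge, strand))
    calls = []
    if profile.calibration is None:
        calibrate_structure_profile(profile)
    mu, lam = profile.calibration
    hits.sort(key=lambda h: (-h[0], h[1]))
    chosen = []
    for total, gs, ge, strand in hits:
        if any(gs < e and s < ge for _, s, e, _ in chosen):
            continue
        chosen.append((total, gs, ge, strand))
    for total, gs, ge, strand in chosen:
        ev = -math.expm1(-math.exp(-lam * (total - mu)))
        if ev <= threshold:
            calls.append(
                NcrnaCall(
                    gene=profile.name, start=gs, end=ge, strand=strand,
                    score=float(total), evalue=max(float(ev), 0.0),
                )
            )
    calls.sort(key=lambda c: c.start)
    return calls


def _place_elements(profile: StructureProfile, seq: str, anchor_idx: int,
                    anchor_pos: int, anchor_score: float, soft: bool = False):
    """Place the non-anchor elements around a fixed anchor placement,
    greedily outward per the element order; returns (total_score,
    (start, end)) or None if any element cannot be placed."""
    strand_score = _score_strand_soft if soft else _score_strand
    anchor = profile.elements[anchor_idx]
    total = anchor_score
    left_edge = anchor_pos
    right_edge = anchor_pos + anchor.width
    # rightward elements
    cursor = right_edge
    for k in range(anchor_idx + 1, len(profile.elements)):
        smin, smax = profile.spacers[k - 1]
        el = profile.elements[k]
        if isinstance(el, StrandElement):
            best = None
            for sp in range(smin, smax + 1):
                sc = strand_score(el, seq, cursor + sp)
                if sc is not None and (best is None or sc > best[0]):
                    best = (sc, cursor + sp, el.width)
        else:
            best = _best_helix(el, seq, cursor + smin, cursor + smax,
                               profile.pair_bonus, profile.gu_bonus, soft)
        if best is None:
            return None
        total += best[0]
        cursor = best[1] + best[2]
        right_edge = cursor
    # leftward elements
    cursor = left_edge
    for k in range(anchor_idx - 1, -1, -1):
        smin, smax = profile.spacers[k]
        el = profile.elements[k]
        if isinstance(el, StrandElement):
            best = None
            for sp in range(smin, smax + 1):
                start = cursor - sp - el.width
                sc = strand_score(el, seq, start)
                if sc is not None and (best is None or sc > best[0]):
                    best = (sc, start, el.width)
        else:
            best = None
            for sp in range(smin, smax + 1):
                for loop in range(el.loop_min, el.loop_max + 1):
                    width = 2 * el.stem + loop
                    start = cursor - sp - width
                    if start < 0:
                        continue
                    cand = _best_helix(el, seq, start, start,
                                       profile.pair_bonus, profile.gu_bonus, soft)
                    if cand is not None and (best is None or cand[0] > best[0]):
                        best = cand
        if best is None:
            return None
        total += best[0]
        cursor = best[1]
        left_edge = cursor
    return total, (left_edge, right_edge)


def calibrate_structure_profile(
    profile: StructureProfile,
    n_samples: int = 100,
    seed: int = 0,
    sample_len: int = 2000,
    tail_quantile: float = 0.8,
) -> tuple:
    """Null calibration on random uniform sequences.

    Per sample, the strongest anchor positions are evaluated with *soft*
    placement (hard constraints and pairing minima relaxed) so every sample
    yields a best achievable score; the exceedances over the
    ``tail_quantile`` are fitted with an exponential tail
    (peaks-over-threshold) and expressed as Gumbel (mu, lambda).  The
    resulting E-values are therefore per random sequence of
    ``sample_len`` nt."""
    rng = np.random.default_rng(seed)
    anchor_idx = profile.strategy[0]
    anchor = profile.elements[anchor_idx]
    scores = np.empty(n_samples)
    for it in range(n_samples):
        seq = "".join(rng.choice(list("ACGT"), size=sample_len))
        anchor_scores = np.array([
            _score_strand_soft(anchor, seq, p)
            for p in range(sample_len - anchor.width + 1)
        ])
        best = -1e9
        for pos in np.argsort(anchor_scores)[-10:]:
            placed = _place_elements(profile, seq, anchor_idx, int(pos),
                                     float(anchor_scores[pos]), soft=True)
            if placed is not None:
                best = max(best, placed[0])
        scores[it] = best
    u = float(np.quantile(scores, tail_quantile))
    exc = scores[scores > u] - u
    if exc.size < 5 or float(exc.mean()) <= 0:
        raise ValueError("degenerate structure-score distribution")
    lam = 1.0 / float(exc.mean())
    mu = u + math.log(1.0 - tail_quantile) / lam
    profile.calibration = (float(mu), float(lam))
    return profile.calibration


def _score_strand_soft(el: StrandElement, seq: str, pos: int):
    """PWM score ignoring hard constraints (for null calibration, where hard
    constraints would zero out nearly every sample)."""
    if pos < 0 or pos + el.width > len(seq):
        return None
    return pwm_logodds(el.pwm, seq[pos : pos + el.width])


# ---------------------------------------------------------------------------
# Structure-profile fixture format
# ---------------------------------------------------------------------------


def structure_profile_from_text(text: str) -> StructureProfile:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    name = None
    elements = []
    spacers = []
    strategy = None
    i = 0
    while i < len(lines):
        tok = lines[i].split()
        if tok[0] == "StructureProfile":
            i += 1
        elif tok[0] == "name":
            name = tok[1]
            i += 1
        elif tok[0] == "strategy":
            strategy = [int(v) for v in tok[1:]]
            i += 1
        elif tok[0] == "spacer":
            spacers.append((int(tok[1]), int(tok[2])))
            i += 1
        elif tok[0] == "element" and tok[1] == "strand":
            w = int(tok[2])
            rows = [[float(v) for v in lines[i + 1 + r].split()] for r in range(w)]
            pwm = np.array(rows)
            pwm /= pwm.sum(axis=1, keepdims=True)
            elements.append(StrandElement(pwm=pwm))
            i += 1 + w
        elif tok[0] == "hard":
            elements[-1].hard.append((int(tok[1]), tok[2]))
            i += 1
        elif tok[0] == "element" and tok[1] == "helix":
            elements.append(
                HelixElement(
                    stem=int(tok[2]), loop_min=int(tok[3]), loop_max=int(tok[4]),
                    min_pairs=int(tok[5]), require_gu=bool(int(tok[6])),
                )
            )
            i += 1
        else:
            raise ValueError(f"bad structure profile line: {lines[i]!r}")
    if strategy is None:
        strategy = list(range(len(elements)))
    return StructureProfile(name=name, elements=elements, spacers=spacers,
                            strategy=strategy)


def load_structure_profile(name: str) -> StructureProfile:
    from importlib import resources

    text = resources.files("organnot.models").joinpath(f"{name}.txt").read_text()
    return structure_profile_from_text(text)
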