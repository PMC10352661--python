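"""Profile hidden Markov models for protein (and nucleotide) families.

The models are classic match/insert/delete profiles with local,
Smith-Waterman-style alignment semantics: an alignment may enter the model at
any match state and leave from any match state, with free flanking sequence,
because gene segments are local matches within six-frame translations.

Scoring is additive log-odds in bits.  Match emissions are log2 odds against
a fixed background (a Robinson-Robinson-style composition for proteins,
uniform for nucleotides); insert emissions score zero; transition scores are
normalized so that the match-match continuation costs zero, which makes the
score of an all-match alignment exactly the sum of its match emission
log-odds.  E-values come from a Gumbel null fitted by maximum likelihood to
Viterbi scores of random background sequences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.stats import gumbel_r

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
NT_ALPHABET = "ACGT"

# Robinson-Robinson-style amino-acid background composition, indexed to
# AA_ALPHABET order and normalized to sum to one.
_RR = {
    "A": 0.078, "R": 0.051, "N": 0.045, "D": 0.054, "C": 0.019,
    "Q": 0.043, "E": 0.063, "G": 0.074, "H": 0.022, "I": 0.051,
    "L": 0.091, "K": 0.057, "M": 0.022, "F": 0.039, "P": 0.052,
    "S": 0.071, "T": 0.058, "W": 0.013, "Y": 0.032, "V": 0.066,
}
AA_BACKGROUND = np.array([_RR[a] for a in AA_ALPHABET])
AA_BACKGROUND /= AA_BACKGROUND.sum()
NT_BACKGROUND = np.full(4, 0.25)

TRANS_NAMES = ("MM", "MI", "MD", "IM", "II", "DM", "DD")


def _alphabet_info(alphabet: str):
    if alphabet == "aa":
        return AA_ALPHABET, AA_BACKGROUND
    if alphabet == "nt":
        return NT_ALPHABET, NT_BACKGROUND
    raise ValueError(f"unknown alphabet {alphabet!r}")


def encode_seq(seq: str, alphabet: str) -> np.ndarray:
    """Map a sequence to alphabet indices; unknown symbols (X, N, ...) get
    index -1 and score as background (log-odds 0)."""
    letters, _ = _alphabet_info(alphabet)
    lut = np.full(128, -1, dtype=np.int8)
    for i, ch in enumerate(letters):
        lut[ord(ch)] = i
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return lut[arr]


@dataclass
class ProfileHMM:
    name: str
    alphabet: str  # "aa" or "nt"
    match_probs: np.ndarray  # (M, K) emission probabilities
    transitions: np.ndarray  # (M + 1, 7) probabilities, TRANS_NAMES order
    consensus: str
    calibration: tuple | None = None  # (mu, lambda)

    def __post_init__(self):
        self.match_probs = np.asarray(self.match_probs, dtype=float)
        self.transitions = np.asarray(self.transitions, dtype=float)
        M, K = self.match_probs.shape
        letters, bg = _alphabet_info(self.alphabet)
        if K != len(letters):
            raise ValueError("emission table width does not match alphabet")
        if M < 1:
            raise ValueError("profile needs at least one match state")
        if not np.allclose(self.match_probs.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("match emission rows must sum to 1")
        for a, b in ((0, 3), (3, 5), (5, 7)):
            if not np.allclose(self.transitions[:, a:b].sum(axis=1), 1.0, atol=1e-6):
                raise ValueError("transition probabilities out of a state must sum to 1")
        self.background = bg
        self.match_logodds = np.log2(self.match_probs / bg[None, :])
        t = np.log2(self.transitions)
        tmm = t[:, 0:1]
        # normalized transition scores: match-match continuation costs zero
        self.trans_scores = (t - tmm).astype(np.float64)

    @property
    def M(self) -> int:
        return self.match_probs.shape[0]

    def information_content(self) -> np.ndarray:
        """Relative entropy (bits) of each match state vs the background."""
        return np.sum(self.match_probs * self.match_logodds, axis=1)


@dataclass
class HmmHit:
    profile_name: str
    target_id: str
    target_start: int  # 0-based half-open residue span on the target
    target_end: int
    model_start: int  # 1-based first/last match states used
    model_end: int
    score: float  # bits
    evalue: float | None
    trace: list  # list of (op, model_state, target_pos) with op in "MID"
    posterior: np.ndarray | None = None

    def __post_init__(self):
        if self.evalue is not None and self.evalue < 0:
            raise ValueError("E-value must be >= 0")


class ProfileBuildError(ValueError):
    pass


def build_profile(
    aligned_seqs,
    pseudocount_weight: float = 1.0,
    name: str = "profile",
    alphabet: str = "aa",
) -> ProfileHMM:
    """Build a profile from an aligned family.

    Columns with less than 50% gap characters become match states.  Emissions
    get Laplace-style uniform pseudocounts of total weight
    ``pseudocount_weight`` (``p = (c + w/K) / (n + w)``); transitions get an
    add-one prior.  Scores are log-odds against the fixed background.
    """
    seqs = [s.upper() for s in aligned_seqs]
    if len(seqs) < 2:
        raise ProfileBuildError("need at least two aligned sequences")
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise ProfileBuildError("ragged alignment")
    letters, bg = _alphabet_info(alphabet)
    K = len(letters)
    idx = {ch: i for i, ch in enumerate(letters)}
    n = len(seqs)
    gap_frac = [sum(s[c] == "-" for s in seqs) / n for c in range(L)]
    match_cols = [c for c in range(L) if gap_frac[c] < 0.5]
    M = len(match_cols)
    if M == 0:
        raise ProfileBuildError("alignment has no match columns")

    counts = np.zeros((M, K))
    consensus = []
    for k, c in enumerate(match_cols):
        for s in seqs:
            ch = s[c]
            if ch in idx:
                counts[k, idx[ch]] += 1
        consensus.append(letters[int(np.argmax(counts[k]))] if counts[k].sum() else letters[0])
    w = pseudocount_weight
    col_tot = counts.sum(axis=1, keepdims=True)
    match_probs = (counts + w / K) / (col_tot + w)

    # transition counts along each sequence's implied state path
    tcounts = np.ones((M + 1, 7))  # add-one prior
    is_match = np.zeros(L, dtype=bool)
    is_match[match_cols] = True
    col_to_state = np.zeros(L, dtype=int)
    for k, c in enumerate(match_cols):
        col_to_state[c] = k + 1
    for s in seqs:
        prev = "M"  # begin state behaves like a match at position 0
        prev_k = 0
        for c in range(L):
            if is_match[c]:
                cur = "M" if s[c] != "-" else "D"
                cur_k = col_to_state[c]
            else:
                if s[c] == "-":
                    continue
                cur = "I"
                cur_k = prev_k
            pair = prev + cur
            if pair == "DI":  # not representable in a plan7 topology
                pair = "MI"
            if pair in ("MM", "MI", "MD", "IM", "II", "DM", "DD"):
                tcounts[prev_k if cur == "I" or prev == "I" else prev_k,
                        TRANS_NAMES.index(pair)] += 1
            prev, prev_k = cur, cur_k
    transitions = np.empty_like(tcounts)
    transitions[:, 0:3] = tcounts[:, 0:3] / tcounts[:, 0:3].sum(axis=1, keepdims=True)
    transitions[:, 3:5] = tcounts[:, 3:5] / tcounts[:, 3:5].sum(axis=1, keepdims=True)
    transitions[:, 5:7] = tcounts[:, 5:7] / tcounts[:, 5:7].sum(axis=1, keepdims=True)
    return ProfileHMM(
        name=name,
        alphabet=alphabet,
        match_probs=match_probs,
        transitions=transitions,
        consensus="".join(consensus),
    )


# ---------------------------------------------------------------------------
# Viterbi (numba kernel with backpointers) and forward
# ---------------------------------------------------------------------------


@njit(cache=True)
def _viterbi_kernel(em, mi, ii, md, dd, im, dm):
    """Local Viterbi.  ``em`` is (L, M) emission log-odds for the target.
    Returns (best, end_i, end_k, bM, bI, bD) with 1-based i (target) and k
    (model) indices in the backpointer arrays."""
    L, M = em.shape
    NEG = -1e30
    vm_prev = np.full(M + 1, NEG)
    vi_prev = np.full(M + 1, NEG)
    vd_prev = np.full(M + 1, NEG)
    vm = np.full(M + 1, NEG)
    vi = np.full(M + 1, NEG)
    vd = np.full(M + 1, NEG)
    bM = np.zeros((L + 1, M + 1), dtype=np.int8)
    bI = np.zeros((L + 1, M + 1), dtype=np.int8)
    bD = np.zeros((L + 1, M + 1), dtype=np.int8)
    best = 0.0
    end_i = 0
    end_k = 0
    for i in range(1, L + 1):
        for k in range(M + 1):
            vm[k] = NEG
            vi[k] = NEG
            vd[k] = NEG
        for k in range(1, M + 1):
            # match state k consuming residue i
            sc = 0.0  # local entry
            ptr = 0
            if vm_prev[k - 1] > sc:
                sc = vm_prev[k - 1]
                ptr = 1
            if vi_prev[k - 1] + im[k - 1] > sc:
                sc = vi_prev[k - 1] + im[k - 1]
                ptr = 2
            if vd_prev[k - 1] + dm[k - 1] > sc:
                sc = vd_prev[k - 1] + dm[k - 1]
                ptr = 3
            vm[k] = sc + em[i - 1, k - 1]
            bM[i, k] = ptr
            # insert state after k consuming residue i
            a = vm_prev[k] + mi[k]
            b = vi_prev[k] + ii[k]
            if a >= b:
                vi[k] = a
                bI[i, k] = 0
            else:
                vi[k] = b
                bI[i, k] = 1
            # delete state k (no residue; within-column chain)
            a = vm[k - 1] + md[k - 1]
            b = vd[k - 1] + dd[k - 1]
            if a >= b:
                vd[k] = a
                bD[i, k] = 0
            else:
                vd[k] = b
                bD[i, k] = 1
            if vm[k] > best:
                best = vm[k]
                end_i = i
                end_k = k
        for k in range(M + 1):
            vm_prev[k] = vm[k]
            vi_prev[k] = vi[k]
            vd_prev[k] = vd[k]
    return best, end_i, end_k, bM, bI, bD


def viterbi(profile: ProfileHMM, target_seq: str, target_id: str = "target") -> HmmHit:
    """Best local alignment of the profile to ``target_seq`` (score in bits).

    A target with no positive-scoring alignment yields an empty hit with
    score 0 (the local-alignment floor).
    """
    if not target_seq:
        raise ValueError("empty target")
    enc = encode_seq(target_seq, profile.alphabet)
    em = np.where(
        enc[:, None] >= 0,
        profile.match_logodds[:, np.clip(enc, 0, None)].T,
        0.0,
    ).astype(np.float64)
    t = profile.trans_scores
    best, end_i, end_k, bM, bI, bD = _viterbi_kernel(
        np.ascontiguousarray(em),
        np.ascontiguousarray(t[:, 1]), np.ascontiguousarray(t[:, 4]),
        np.ascontiguousarray(t[:, 2]), np.ascontiguousarray(t[:, 6]),
        np.ascontiguousarray(t[:, 3]), np.ascontiguousarray(t[:, 5]),
    )
    if end_i == 0:
        return HmmHit(profile.name, target_id, 0, 0, 0, 0, 0.0, None, [])
    # traceback
    trace = []
    state, i, k = "M", end_i, end_k
    while True:
        if state == "M":
            trace.append(("M", k, i - 1))
            ptr = bM[i, k]
            if ptr == 0:
                break
            state = {1: "M", 2: "I", 3: "D"}[int(ptr)]
            i, k = i - 1, k - 1
        elif state == "I":
            trace.append(("I", k, i - 1))
            state = "M" if bI[i, k] == 0 else "I"
            i = i - 1
        else:  # D
            trace.append(("D", k, -1))
            state = "M" if bD[i, k] == 0 else "D"
            k = k - 1
    trace.reverse()
    t_start = trace[0][2]
    m_start = trace[0][1]
    return HmmHit(
        profile_name=profile.name,
        target_id=target_id,
        target_start=t_start,
        target_end=end_i,
        model_start=m_start,
        model_end=end_k,
        score=float(best),
        evalue=None,
        trace=trace,
    )


def _forward_matrices(profile: ProfileHMM, enc: np.ndarray):
    """Forward matrices in log2 space over all local paths (entry at any
    match state, exit from any match state)."""
    M = profile.M
    L = len(enc)
    em = np.where(
        enc[:, None] >= 0,
        profile.match_logodds[:, np.clip(enc, 0, None)].T,
        0.0,
    )
    t = profile.trans_scores
    mi, md, im, ii, dm, dd = t[:, 1], t[:, 2], t[:, 3], t[:, 4], t[:, 5], t[:, 6]
    NEG = -np.inf
    FM = np.full((L + 1, M + 1), NEG)
    FI = np.full((L + 1, M + 1), NEG)
    FD = np.full((L + 1, M + 1), NEG)
    ln2 = math.log(2.0)

    def lse(*arrays):
        out = arrays[0]
        for a in arrays[1:]:
            out = np.logaddexp(out * ln2, a * ln2) / ln2
        return out

    for i in range(1, L + 1):
        prev_m, prev_i, prev_d = FM[i - 1], FI[i - 1], FD[i - 1]
        cand = lse(
            np.zeros(M),  # local entry
            prev_m[:-1],
            prev_i[:-1] + im[:-1],
            prev_d[:-1] + dm[:-1],
        )
        FM[i, 1:] = cand + em[i - 1]
        FI[i, :] = lse(prev_m + mi, prev_i + ii)
        # delete chain along k
        base = FM[i, :-1] + md[:-1]
        cdd = np.concatenate([[0.0], np.cumsum(dd[1:M])])  # cdd[j] = sum dd[1..j]
        shifted = base - cdd
        run = np.logaddexp.accumulate(shifted * ln2) / ln2
        FD[i, 1:] = run + cdd
    return FM, FI, FD, em


def forward(profile: ProfileHMM, target_seq: str) -> float:
    """Forward bit score: log2 of the summed odds over all local paths
    (including the empty alignment), hence always >= the Viterbi score."""
    if not target_seq:
        raise ValueError("empty target")
    enc = encode_seq(target_seq, profile.alphabet)
    FM, _, _, _ = _forward_matrices(profile, enc)
    ln2 = math.log(2.0)
    ends = FM[1:, 1:].ravel()
    ends = ends[np.isfinite(ends)]
    total = np.logaddexp.reduce(np.concatenate([[0.0], ends * ln2])) / ln2
    return float(total)


def posterior_decode(profile: ProfileHMM, target_seq: str) -> np.ndarray:
    """Per-residue posterior probability that the residue is emitted by the
    model (match or insert state) under the local path ensemble.  This is the
    'PP' confidence line; values lie in [0, 1]."""
    enc = encode_seq(target_seq, profile.alphabet)
    M = profile.M
    L = len(enc)
    FM, FI, FD, em = _forward_matrices(profile, enc)
    t = profile.trans_scores
    mi, md, im, ii, dm, dd = t[:, 1], t[:, 2], t[:, 3], t[:, 4], t[:, 5], t[:, 6]
    ln2 = math.log(2.0)
    NEG = -np.inf
    BM = np.full((L + 1, M + 1), NEG)
    BI = np.full((L + 1, M + 1), NEG)
    BD = np.full((L + 1, M + 1), NEG)
    BM[:, 1:] = 0.0  # free local exit from any match state, any position

    def l2add(a, b):
        return np.logaddexp(a * ln2, b * ln2) / ln2

    for i in range(L - 1, -1, -1):
        nm, ni = BM[i + 1], BI[i + 1]
        # delete chain backwards: BD[i, k] = max over continue/exit paths
        bd = np.full(M + 1, NEG)
        for k in range(M - 1, 0, -1):
            val = nm[k + 1] + em[i, k] + dm[k] if i < L else NEG
            if k + 1 <= M:
                val = l2add(val, bd[k + 1] + dd[k])
            bd[k] = val
        BD[i] = bd
        bm = np.full(M + 1, NEG)
        bi = np.full(M + 1, NEG)
        for k in range(M, 0, -1):
            exit_sc = 0.0
            cont = NEG
            if i < L:
                if k < M:
                    cont = nm[k + 1] + em[i, k]
                cont = l2add(cont, ni[k] + mi[k])
            if k < M:
                cont = l2add(cont, BD[i][k + 1] + md[k])
            bm[k] = l2add(exit_sc, cont)
            c2 = NEG
            if i < L:
                if k < M:
                    c2 = nm[k + 1] + em[i, k] + im[k]
                c2 = l2add(c2, ni[k] + ii[k])
            bi[k] = c2
        BM[i] = bm
        BI[i] = bi
    ends = FM[1:, 1:].ravel()
    ends = ends[np.isfinite(ends)]
    total = np.logaddexp.reduce(np.concatenate([[0.0], ends * ln2])) / ln2
    post = np.zeros(L)
    for i in range(1, L + 1):
        contrib = np.concatenate([FM[i, 1:] + BM[i, 1:], FI[i, :] + BI[i, :]])
        contrib = contrib[np.isfinite(contrib)]
        if contrib.size:
            post[i - 1] = 2.0 ** (
                np.logaddexp.reduce(contrib * ln2) / ln2 - total
            )
    return np.clip(post, 0.0, 1.0)


def posterior_deciles(post: np.ndarray) -> str:
    """Render posteriors as a decile string: '0'..'9' and '*' for 1.0."""
    out = []
    for p in post:
        d = int(p * 10)
        out.append("*" if d >= 10 else str(d))
    return "".join(out)


# ---------------------------------------------------------------------------
# Calibration and E-values
# ---------------------------------------------------------------------------


class CalibrationError(ValueError):
    pass


def random_background_seq(rng: np.random.Generator, length: int, alphabet: str) -> str:
    letters, bg = _alphabet_info(alphabet)
    return "".join(rng.choice(list(letters), size=length, p=bg))


def calibrate(
    profile: ProfileHMM,
    n_samples: int = 200,
    seed: int = 0,
    sample_len: int = 400,
) -> tuple:
    """Fit Gumbel (mu, lambda) to Viterbi scores of i.i.d. background
    sequences and store it on the profile.  Deterministic given ``seed``."""
    if n_samples < 100:
        raise CalibrationError("need at least 100 calibration samples")
    rng = np.random.default_rng(seed)
    scores = np.empty(n_samples)
    for i in range(n_samples):
        seq = random_background_seq(rng, sample_len, profile.alphabet)
        scores[i] = viterbi(profile, seq).score
    if np.ptp(scores) < 1e-12:
        raise CalibrationError("degenerate score distribution (all equal)")
    mu, beta = gumbel_r.fit(scores)
    calib = (float(mu), float(1.0 / beta))
    profile.calibration = calib
    return calib


def evalue(score: float, calibration: tuple, n_targets: int = 1) -> float:
    """Expected number of chance hits at or above ``score`` among
    ``n_targets`` independent targets: E = n (1 - exp(-exp(-lambda (s - mu)))).
    Monotone decreasing in score."""
    mu, lam = calibration
    p = -math.expm1(-math.exp(-lam * (score - mu)))
    return n_targets * p


# ---------------------------------------------------------------------------
# Missing conserved blocks (mini-exon evidence)
# ---------------------------------------------------------------------------


def find_missing_blocks(
    hit: HmmHit,
    profile: ProfileHMM,
    min_block: int = 2,
    min_info: float = 1.0,
) -> list:
    """Maximal runs of >= ``min_block`` consecutive match states traversed as
    deletions whose mean information content is >= ``min_info`` bits.

    These are conserved positions the alignment failed to place — the
    footprint a skipped mini-exon leaves behind.  Returns a list of
    (first_state, last_state) 1-based inclusive model spans.
    """
    if not hit.trace:
        return []
    info = profile.information_content()
    blocks = []
    run = []
    for op, k, _ in hit.trace + [("M", -1, -1)]:
        if op == "D":
            run.append(k)
        else:
            if len(run) >= min_block and info[np.array(run) - 1].mean() >= min_info:
                blocks.append((run[0], run[-1]))
            run = []
    return blocks


# ---------------------------------------------------------------------------
# Serialization (documented plain-text format)
# ---------------------------------------------------------------------------


def profile_to_text(profile: ProfileHMM) -> str:
    lines = [
        "ProfileHMM 1",
        f"name {profile.name}",
        f"alphabet {profile.alphabet}",
        f"M {profile.M}",
        f"consensus {profile.consensus}",
    ]
    if profile.calibration:
        mu, lam = profile.calibration
        lines.append(f"calibration {mu!r} {lam!r}")
    else:
        lines.append("calibration none")
    for k in range(profile.M):
        vals = " ".join(f"{p:.6e}" for p in profile.match_probs[k])
        lines.append(f"match {k + 1} {vals}")
    for k in range(profile.M + 1):
        vals = " ".join(f"{p:.6e}" for p in profile.transitions[k])
        lines.append(f"trans {k} {vals}")
    return "\n".join(lines) + "\n"


def profile_from_text(text: str) -> ProfileHMM:
    meta = {}
    match_rows = {}
    trans_rows = {}
    for line in text.splitlines():
        if not line.strip():
            continue
        tok = line.split()
        if tok[0] == "ProfileHMM":
            continue
        if tok[0] in ("name", "alphabet", "M", "consensus"):
            meta[tok[0]] = tok[1]
        elif tok[0] == "calibration":
            meta["calibration"] = None if tok[1] == "none" else (float(tok[1]), float(tok[2]))
        elif tok[0] == "match":
            match_rows[int(tok[1])] = [float(v) for v in tok[2:]]
        elif tok[0] == "trans":
            trans_rows[int(tok[1])] = [float(v) for v in tok[2:]]
    M = int(meta["M"])
    match = np.array([match_rows[k + 1] for k in range(M)])
    # renormalize against round-off from the fixed-precision serialization
    match /= match.sum(axis=1, keepdims=True)
    trans = np.array([trans_rows[k] for k in range(M + 1)])
    trans[:, 0:3] /= trans[:, 0:3].sum(axis=1, keepdims=True)
    trans[:, 3:5] /= trans[:, 3:5].sum(axis=1, keepdims=True)
    trans[:, 5:7] /= trans[:, 5:7].sum(axis=1, keepdims=True)
    return ProfileHMM(
        name=meta["name"],
        alphabet=meta["alphabet"],
        match_probs=match,
        transitions=trans,
        consensus=meta["consensus"],
        calibration=meta.get("calibration"),
    )
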