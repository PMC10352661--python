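"""Group I / Group II intron detection and classification.

Mitochondrial genes are riddled with self-splicing introns of two classes
with distinct conserved features.  Group II introns begin with a GUGYG-like
5' motif, carry a branch-point adenosine a short, fairly fixed distance from
their 3' end (upstream of which lies the domain-VI hairpin), and end in AY.
Group I introns end in a conserved G and carry an internal guide sequence
near their 5' end that pairs with the tail of the upstream exon (the P1
duplex).  Each class gets its own position weight matrices plus structural
bonus terms; the two models are scored and calibrated separately — a single
merged splice matrix for both classes is close to uninformative and is
deliberately avoided.

Default models are shipped as editable plain-text fixtures under
``organnot/models/`` so curated matrices can be dropped in.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .seq_io import revcomp

MIN_INTRON_LEN = 30

_NT_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}


def can_pair(a: str, b: str) -> bool:
    """Watson-Crick or G-U wobble pairing (DNA letters)."""
    return (a, b) in _PAIRS


def count_pairs(a: str, b: str) -> int:
    """Pairs formed between ``a`` and the reverse of ``b`` (antiparallel)."""
    return sum(can_pair(x, y) for x, y in zip(a, b[::-1]))


def best_hairpin(seq: str, min_loop: int = 3, min_stem: int = 3) -> int:
    """Length (bp) of the best-paired perfect stem of any hairpin in ``seq``
    (0 if none reaches ``min_stem``)."""
    n = len(seq)
    best = 0
    for stem in range(min_stem, n // 2 + 1):
        for i in range(0, n - 2 * stem - min_loop + 1):
            for j in range(i + stem + min_loop, n - stem + 1):
                left = seq[i : i + stem]
                right = seq[j : j + stem]
                if count_pairs(left, right) == stem:
                    best = max(best, stem)
    return best


def pwm_logodds(pwm: np.ndarray, seq: str) -> float:
    """Log2 odds of ``seq`` under a PWM vs a uniform background."""
    total = 0.0
    for i, ch in enumerate(seq):
        j = _NT_INDEX.get(ch)
        total += math.log2(pwm[i, j] / 0.25) if j is not None else 0.0
    return total


@dataclass
class SpliceModel:
    """PWMs and structural checks for one intron class."""

    group: str  # "I" or "II"
    pwm5: np.ndarray  # (w5, 4) probabilities, columns A C G T
    pwm3: np.ndarray
    params: dict = field(default_factory=dict)
    calibration: tuple | None = None  # (mu, lambda) of the null tail
    null_scores: np.ndarray | None = None  # sorted null sample (bulk CDF)
    tail_start: float | None = None

    def __post_init__(self):
        self.pwm5 = np.asarray(self.pwm5, dtype=float)
        self.pwm3 = np.asarray(self.pwm3, dtype=float)
        for pwm in (self.pwm5, self.pwm3):
            if not np.allclose(pwm.sum(axis=1), 1.0, atol=1e-6):
                raise ValueError("PWM rows must be probability distributions")

    @property
    def w5(self):
        return self.pwm5.shape[0]

    @property
    def w3(self):
        return self.pwm3.shape[0]

    def score_5p(self, window: str) -> float:
        return pwm_logodds(self.pwm5, window)

    def score_3p(self, window: str) -> float:
        return pwm_logodds(self.pwm3, window)

    def pwm5_scan(self, seq: str) -> np.ndarray:
        """Log-odds of the 5' PWM at every start position of ``seq``."""
        return _pwm_scan(self.pwm5, seq)

    def pwm3_scan(self, seq: str) -> np.ndarray:
        """Log-odds of the 3' PWM at every *end* position (the returned value
        at index j scores the window ending at j inclusive)."""
        raw = _pwm_scan(self.pwm3, seq)
        out = np.full(len(seq), -np.inf)
        w = self.w3
        out[w - 1 :] = raw[: len(seq) - w + 1]
        return out

    def passes_gates(self, seq: str, upstream_exon_tail: str) -> bool:
        """Hard structural gates used by the standalone genome scan: the
        class-defining structure must actually be present, not just a PWM
        match."""
        p = self.params
        if self.group == "II":
            lo, hi = int(p["branch_min"]), int(p["branch_max"])
            if "A" not in seq[len(seq) + lo : len(seq) + hi + 1]:
                return False
            region = seq[max(0, len(seq) + int(p["hairpin_start"])) : len(seq) + int(p["hairpin_end"])]
            return best_hairpin(region, min_stem=int(p["hairpin_min_stem"])) > 0
        if not seq.endswith("G"):
            return False
        gs, gl = int(p["p1_guide_start"]), int(p["p1_guide_len"])
        tail = upstream_exon_tail[-gl:]
        if len(tail) < gl:
            return False
        return count_pairs(tail, seq[gs : gs + gl]) >= int(p.get("p1_min_pairs", 5))


def _pwm_scan(pwm: np.ndarray, seq: str) -> np.ndarray:
    w = pwm.shape[0]
    n = len(seq)
    enc = np.full(n, -1, dtype=np.int64)
    for ch, j in _NT_INDEX.items():
        enc[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(ch)] = j
    logp = np.log2(pwm / 0.25)
    out = np.full(n, -np.inf)
    if n < w:
        return out
    acc = np.zeros(n - w + 1)
    for i in range(w):
        col = enc[i : n - w + 1 + i]
        vals = np.where(col >= 0, logp[i, np.clip(col, 0, None)], 0.0)
        acc += vals
    out[: n - w + 1] = acc
    return out


def score_intron(seq: str, upstream_exon_tail: str, model: SpliceModel) -> float:
    """Total log-odds of ``seq`` being an intron of ``model``'s class.

    Sum of 5'/3' PWM log-odds plus the class's structural bonus terms.
    ``upstream_exon_tail`` is the exon sequence immediately 5' of the intron
    (used for the Group I P1 duplex proxy).
    """
    if len(seq) < MIN_INTRON_LEN:
        raise ValueError(f"intron candidate shorter than {MIN_INTRON_LEN} nt")
    if len(seq) < model.w5 + model.w3:
        raise ValueError("sequence shorter than combined PWM windows")
    p = model.params
    total = model.score_5p(seq[: model.w5]) + model.score_3p(seq[-model.w3 :])
    if model.group == "II":
        lo, hi = int(p["branch_min"]), int(p["branch_max"])
        window = seq[len(seq) + lo : len(seq) + hi + 1]
        if "A" in window:
            total += p["branch_bonus"]
        hs, he = int(p["hairpin_start"]), int(p["hairpin_end"])
        region = seq[max(0, len(seq) + hs) : len(seq) + he]
        stem = best_hairpin(region, min_stem=int(p["hairpin_min_stem"]))
        total += min(stem, p["hairpin_max_pairs"]) * p["hairpin_bonus_per_pair"]
    else:
        if seq.endswith("G"):
            total += p["terminal_g_bonus"]
        gs, gl = int(p["p1_guide_start"]), int(p["p1_guide_len"])
        guide = seq[gs : gs + gl]
        tail = upstream_exon_tail[-gl:] if upstream_exon_tail else ""
        if len(tail) == gl:
            total += count_pairs(tail, guide) * p["p1_bonus_per_pair"]
    return total


@dataclass
class IntronCall:
    start: int  # 0-based half-open genomic span
    end: int
    strand: str
    group: str  # "I", "II" or "unknown"
    score: float
    evalue: float
    motifs: dict = field(default_factory=dict)
    twintron: bool = False
    comments: list = field(default_factory=list)

    def __post_init__(self):
        if self.evalue < 0:
            raise ValueError("E-value must be >= 0")


def calibrate_splice_model(
    model: SpliceModel,
    n_samples: int = 1200,
    seed: int = 0,
    sample_len: int = 250,
    tail_quantile: float = 0.97,
) -> tuple:
    """Shuffle-style calibration on scores of random uniform sequences.

    The composite intron score (PWMs plus discrete structural bonuses) is
    left-skewed, so a whole-sample Gumbel MLE badly overestimates the upper
    tail.  Instead the exceedances over the ``tail_quantile`` threshold are
    fitted with an exponential (peaks-over-threshold), and the result is
    expressed as equivalent Gumbel (mu, lambda) so the usual E-value formula
    applies in the tail."""
    rng = np.random.default_rng(seed)
    scores = np.empty(n_samples)
    for i in range(n_samples):
        seq = "".join(rng.choice(["A", "C", "G", "T"], size=sample_len))
        tail = "".join(rng.choice(["A", "C", "G", "T"], size=8))
        scores[i] = score_intron(seq, tail, model)
    u = float(np.quantile(scores, tail_quantile))
    exc = scores[scores > u] - u
    if exc.size < 10 or float(exc.mean()) <= 0:
        raise ValueError("degenerate score distribution (no tail spread)")
    lam = 1.0 / float(exc.mean())
    # P(S > s) ~ (1 - q) exp(-lam (s - u)); match the Gumbel tail form
    mu = u + math.log(1.0 - tail_quantile) / lam
    model.calibration = (float(mu), float(lam))
    # the bulk of the null keeps its empirical survival function, so that
    # p-values of null sequences are uniform while the tail stays exponential
    model.null_scores = np.sort(scores)
    model.tail_start = u
    return model.calibration


def _pvalue(score: float, calibration: tuple, model: "SpliceModel | None" = None,
            smooth_rng=None) -> float:
    """Null p-value: empirical survival in the bulk, exponential in the tail.

    The composite intron score is partly discrete (pair counts and fixed
    bonuses), so the deterministic p-value is the conservative upper bound
    over ties; passing ``smooth_rng`` applies the standard randomized
    probability-integral transform instead, which makes null p-values
    exactly uniform (used when testing calibration sanity)."""
    mu, lam = calibration
    if model is not None and model.null_scores is not None and score <= model.tail_start:
        n = model.null_scores.size
        lo = int(np.searchsorted(model.null_scores, score, side="left"))
        hi = int(np.searchsorted(model.null_scores, score, side="right"))
        k_gt = n - hi
        k_eq = hi - lo
        if smooth_rng is not None:
            return (k_gt + smooth_rng.random() * (k_eq + 1)) / (n + 1)
        return (k_gt + k_eq + 1) / (n + 1)
    return -math.expm1(-math.exp(-lam * (score - mu)))


def classify(
    seq: str,
    upstream_exon_tail: str,
    models: dict,
    threshold: float = 0.01,
    start: int = 0,
    strand: str = "+",
) -> IntronCall:
    """Assign a candidate intron to Group I or II (or ``unknown``).

    The group is the model with the smaller calibrated E-value, provided it
    passes ``threshold``; exact ties break toward ``unknown``.
    """
    results = {}
    for g, model in models.items():
        if model.calibration is None:
            calibrate_splice_model(model)
        sc = score_intron(seq, upstream_exon_tail, model)
        results[g] = (sc, _pvalue(sc, model.calibration, model))
    (g1, (s1, e1)), (g2, (s2, e2)) = sorted(results.items())
    if e1 == e2 or min(e1, e2) > threshold:
        group, score, ev = "unknown", max(s1, s2), min(e1, e2)
    elif e1 < e2:
        group, score, ev = g1, s1, e1
    else:
        group, score, ev = g2, s2, e2
    model = models.get(group)
    motifs = {
        "five_prime": seq[: model.w5] if model else seq[:5],
        "three_prime": seq[-(model.w3 if model else 4) :],
    }
    return IntronCall(
        start=start,
        end=start + len(seq),
        strand=strand,
        group=group,
        score=float(score),
        evalue=float(ev),
        motifs=motifs,
    )


def scan_genome(
    contig,
    models: dict,
    threshold: float = 0.01,
    min_len: int = 100,
    max_len: int = 1000,
) -> list:
    """Standalone windowed intron scan over both strands.

    Candidate 5' sites (PWM log-odds above the model's ``scan_floor5``) are
    paired with candidate 3' sites (``scan_floor3``) within
    [min_len, max_len]; pairs must pass the class's structural gates, are
    scored in full, and E-values are the calibrated per-candidate p-value
    times the number of candidate pairs evaluated.  Surviving calls are
    reported greedily (higher score first, then leftmost) without overlap.

    Sensitivity tracks the information content of the shipped matrices:
    Group II introns carry a strong composite signature and scan reliably;
    Group I introns have weak primary-sequence signals, so the standalone
    scan (as opposed to homology-driven modelling) may require curated,
    clade-specific matrices to find them.
    """
    seq_fw = contig.seq if hasattr(contig, "seq") else str(contig)
    n = len(seq_fw)
    raw = []
    n_candidates = {g: 0 for g in models}
    for strand in "+-":
        seq = seq_fw if strand == "+" else revcomp(seq_fw)
        for g, model in models.items():
            if model.calibration is None:
                calibrate_splice_model(model)
            floor5 = float(model.params.get("scan_floor5", 2.0))
            floor3 = float(model.params.get("scan_floor3", 2.0))
            s5 = model.pwm5_scan(seq)
            s3 = model.pwm3_scan(seq)
            starts = np.nonzero(s5 >= floor5)[0]
            ends = np.nonzero(s3 >= floor3)[0]
            for a in starts:
                lo = np.searchsorted(ends, a + min_len - 1)
                hi = np.searchsorted(ends, a + max_len)
                for b in ends[lo:hi]:
                    sub = seq[a : b + 1]
                    if len(sub) < MIN_INTRON_LEN:
                        continue
                    # every floor-passing pair counts toward that model's
                    # search multiplicity, gated or not — gating correlates
                    # with score, so counting only gated pairs understates E
                    n_candidates[g] += 1
                    tail = seq[max(0, a - 8) : a]
                    if not model.passes_gates(sub, tail):
                        continue
                    sc = score_intron(sub, tail, model)
                    pv = _pvalue(sc, model.calibration, model)
                    if strand == "+":
                        gs, ge = int(a), int(b) + 1
                    else:
                        gs, ge = n - int(b) - 1, n - int(a)
                    raw.append((sc, pv, gs, ge, strand, g, sub[: model.w5], sub[-model.w3 :]))
    calls = []
    for sc, pv, gs, ge, strand, g, m5, m3 in raw:
        ev = pv * max(n_candidates[g], 1)
        if ev <= threshold:
            calls.append(
                IntronCall(
                    start=gs, end=ge, strand=strand, group=g,
                    score=float(sc), evalue=float(ev),
                    motifs={"five_prime": m5, "three_prime": m3},
                )
            )
    calls.sort(key=lambda c: (-c.score, c.start))
    chosen = []
    for c in calls:
        if all(c.end <= o.start or c.start >= o.end for o in chosen):
            chosen.append(c)
    chosen.sort(key=lambda c: c.start)
    return chosen


def detect_twintrons(calls: list) -> list:
    """Flag nested or directly abutting intron calls as twintron structures.

    A call nested inside another, or two calls on the same strand separated
    by <= 2 nt with no exon between, marks the outer/joined structure."""
    out = sorted(calls, key=lambda c: (c.start, -(c.end - c.start)))
    for i, a in enumerate(out):
        for b in out[i + 1 :]:
            if b.start >= a.end + 3:
                break
            if a.strand != b.strand:
                continue
            if b.start >= a.start and b.end <= a.end:
                a.twintron = True
                b.twintron = True
                if "nested intron (twintron)" not in a.comments:
                    a.comments.append("nested intron (twintron)")
            elif 0 <= b.start - a.end <= 2:
                a.twintron = True
                b.twintron = True
                if "adjacent introns without intervening exon (twintron)" not in a.comments:
                    a.comments.append("adjacent introns without intervening exon (twintron)")
    return out


# ---------------------------------------------------------------------------
# Fixture format
# ---------------------------------------------------------------------------


def splice_model_to_text(model: SpliceModel) -> str:
    lines = ["SpliceModel 1", f"group {model.group}"]
    for k, v in model.params.items():
        lines.append(f"param {k} {v}")
    for tag, pwm in (("pwm5", model.pwm5), ("pwm3", model.pwm3)):
        lines.append(f"{tag} {pwm.shape[0]}")
        for row in pwm:
            lines.append(" ".join(f"{p:.4f}" for p in row))
    return "\n".join(lines) + "\n"


def splice_model_from_text(text: str) -> SpliceModel:
    group = None
    params = {}
    pwms = {}
    lines = [ln for ln in text.splitlines() if ln.strip()]
    i = 0
    while i < len(lines):
        tok = lines[i].split()
        if tok[0] == "SpliceModel":
            i += 1
        elif tok[0] == "group":
            group = tok[1]
            i += 1
        elif tok[0] == "param":
            params[tok[1]] = float(tok[2])
            i += 1
        elif tok[0] in ("pwm5", "pwm3"):
            w = int(tok[1])
            rows = [[float(v) for v in lines[i + 1 + r].split()] for r in range(w)]
            pwm = np.array(rows)
            pwm /= pwm.sum(axis=1, keepdims=True)
            pwms[tok[0]] = pwm
            i += 1 + w
        else:
            raise ValueError(f"bad splice model line: {lines[i]!r}")
    return SpliceModel(group=group, pwm5=pwms["pwm5"], pwm3=pwms["pwm3"], params=params)


def default_splice_models() -> dict:
    """The shipped Group I and Group II models, keyed by group."""
    models = {}
    for g, fname in (("I", "splice_group1.txt"), ("II", "splice_group2.txt")):
        text = resources.files("organnot.models").joinpath(fname).read_text()
        models[g] = splice_model_from_text(text)
    return models
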