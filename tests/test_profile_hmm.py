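"""Profile HMM construction, alignment, calibration and E-values."""

import numpy as np
import pytest
from scipy.stats import gumbel_r, kstest

from organnot import profile_hmm as ph
from organnot.profile_hmm import (
    AA_ALPHABET,
    ProfileBuildError,
    build_profile,
    calibrate,
    evalue,
    find_missing_blocks,
    forward,
    posterior_decode,
    posterior_deciles,
    profile_from_text,
    profile_to_text,
    random_background_seq,
    viterbi,
)
from organnot.synth_genome import make_protein_family


def enumerate_best_path(prof, target):
    """Exhaustive enumeration over all legal local state paths (oracle)."""
    enc = ph.encode_seq(target, prof.alphabet)
    M, L = prof.M, len(target)
    t = prof.trans_scores
    em = lambda k, i: (prof.match_logodds[k - 1, enc[i - 1]] if enc[i - 1] >= 0 else 0.0)
    best = 0.0

    def extend(score, k, i):
        nonlocal best
        best = max(best, score)
        if k < M and i < L:
            extend(score + em(k + 1, i + 1), k + 1, i + 1)
        if i < L:
            sc = score + t[k, 1]  # M->I
            for r in range(1, L - i + 1):
                sc_r = sc + (r - 1) * t[k, 4]
                if k < M and i + r < L:
                    extend(sc_r + t[k, 3] + em(k + 1, i + r + 1), k + 1, i + r + 1)
        sc = score + t[k, 2]  # M->D chain
        kk = k + 1
        while kk <= M:
            if kk < M and i < L:
                extend(sc + t[kk, 5] + em(kk + 1, i + 1), kk + 1, i + 1)
            sc += t[kk, 6]
            kk += 1

    for k in range(1, M + 1):
        for i in range(1, L + 1):
            extend(em(k, i), k, i)
    return best


def test_build_profile_degenerate_alignment():
    prof = build_profile(["MKLVWHDA"] * 3)
    assert prof.M == 8 and prof.consensus == "MKLVWHDA"


def test_build_profile_gap_threshold_excludes_majority_gap_columns():
    aln = ["MK-A", "ML-A", "M--A", "MI-A", "M-FA"]
    prof = build_profile(aln)
    assert prof.M == 3  # column 3 (80% gaps) is not a match state


def test_build_profile_hand_computed_pseudocount_emission():
    # two sequences, one column: A and C; Laplace weight 1 over 20 symbols
    prof = build_profile(["AW", "CW"], pseudocount_weight=1.0)
    pa = (1 + 1 / 20) / (2 + 1)
    assert prof.match_probs[0, AA_ALPHABET.index("A")] == pytest.approx(pa)
    assert prof.match_probs[0, AA_ALPHABET.index("C")] == pytest.approx(pa)
    assert prof.match_probs[0, AA_ALPHABET.index("W")] == pytest.approx((1 / 20) / 3)


def test_build_profile_rejects_bad_alignments():
    with pytest.raises(ProfileBuildError):
        build_profile(["AB", "A"])
    with pytest.raises(ProfileBuildError):
        build_profile(["ACD"])
    with pytest.raises(ProfileBuildError):
        build_profile(["--", "--", "AK", "--", "--"])  # no match columns


def test_viterbi_on_consensus_equals_sum_of_match_logodds():
    prof = build_profile(["MKLVWHDA"] * 3)
    hit = viterbi(prof, "MKLVWHDA")
    expected = sum(prof.match_logodds[k, AA_ALPHABET.index(c)]
                   for k, c in enumerate("MKLVWHDA"))
    assert hit.score == pytest.approx(expected)
    assert all(op == "M" for op, _, _ in hit.trace)


def test_viterbi_local_floor_is_zero():
    prof = build_profile(["WWWW"] * 3)
    hit = viterbi(prof, "PPPP")  # nothing scores positively
    assert hit.score == 0.0 and hit.trace == []


@pytest.mark.parametrize("seed", range(40))
def test_viterbi_matches_exhaustive_enumeration(seed):
    """Small-profile Viterbi equals brute-force path enumeration."""
    rng = np.random.default_rng(seed)
    M = int(rng.integers(1, 4))
    aln = ["".join(rng.choice(list(AA_ALPHABET), size=M)) for _ in range(3)]
    prof = build_profile(aln)
    target = "".join(rng.choice(list(AA_ALPHABET), size=int(rng.integers(1, 5))))
    assert viterbi(prof, target).score == pytest.approx(
        enumerate_best_path(prof, target), abs=1e-6)


@pytest.mark.parametrize("seed", [0, 7, 21])
def test_forward_at_least_viterbi(seed):
    rng = np.random.default_rng(seed)
    aln = make_protein_family("cox1", 40)
    prof = build_profile(aln)
    target = "".join(rng.choice(list(AA_ALPHABET), size=60))
    assert forward(prof, target) >= viterbi(prof, target).score - 1e-9


def test_calibration_recovers_known_gumbel_parameters():
    rng = np.random.default_rng(0)
    scores = gumbel_r.rvs(loc=-3, scale=1 / 0.7, size=5000, random_state=rng)
    mu, beta = gumbel_r.fit(scores)
    assert mu == pytest.approx(-3, abs=0.2)
    assert 1 / beta == pytest.approx(0.7, abs=0.05)


def test_calibration_is_seed_reproducible_and_null_evalues_uniform():
    prof = build_profile(make_protein_family("cob", 100))
    calib = calibrate(prof, n_samples=200, seed=3, sample_len=150)
    assert calib == calibrate(prof, n_samples=200, seed=3, sample_len=150)
    rng = np.random.default_rng(99)
    evs = [evalue(viterbi(prof, random_background_seq(rng, 150, "aa")).score, calib)
           for _ in range(200)]
    assert kstest(evs, "uniform").pvalue > 0.01


def test_calibration_rejects_too_few_samples_and_degenerate_scores():
    prof = build_profile(make_protein_family("nad1", 60))
    with pytest.raises(ph.CalibrationError):
        calibrate(prof, n_samples=50)


def test_evalue_closed_forms():
    calib = (10.0, 0.5)
    assert evalue(10.0, calib, 1) == pytest.approx(1 - np.exp(-1))
    assert evalue(1e9, calib, 1) == pytest.approx(0.0, abs=1e-12)
    small = evalue(40.0, calib, 1)
    assert evalue(40.0, calib, 2) == pytest.approx(2 * small, rel=1e-6)
    s = np.linspace(0, 50, 40)
    ev = [evalue(x, calib) for x in s]
    assert all(a >= b for a, b in zip(ev, ev[1:]))


def test_posterior_confidence_high_on_true_family_member():
    aln = make_protein_family("atp6", 80)
    prof = build_profile(aln)
    post = posterior_decode(prof, aln[0])
    assert post.min() >= 0 and post.max() <= 1
    assert post.mean() > 0.9
    assert set(posterior_deciles(post)) <= set("0123456789*")


def test_find_missing_blocks_on_constructed_deletion():
    aln = make_protein_family("cox1", 90)
    prof = build_profile(aln)
    target = aln[0][:50] + aln[0][53:]  # delete 3 conserved residues
    hit = viterbi(prof, target)
    assert find_missing_blocks(hit, prof, min_block=2, min_info=1.0) == [(51, 53)]
    # no deletions -> no blocks
    assert find_missing_blocks(viterbi(prof, aln[0]), prof) == []


def test_find_missing_blocks_filters_low_information_states():
    rng = np.random.default_rng(5)
    # a noisy, low-information family: deletions there are not "conserved"
    base = "".join(rng.choice(list(AA_ALPHABET), size=60))
    aln = []
    for _ in range(6):
        v = list(base)
        for i in range(60):
            if rng.random() < 0.6:
                v[i] = rng.choice(list(AA_ALPHABET))
        aln.append("".join(v))
    prof = build_profile(aln)
    target = base[:30] + base[33:]
    blocks = find_missing_blocks(viterbi(prof, target), prof, min_info=1.0)
    info = prof.information_content()
    for a, b in blocks:
        assert info[a - 1 : b].mean() >= 1.0


def test_profile_text_round_trip():
    prof = build_profile(make_protein_family("rps3", 50))
    prof.calibration = (12.5, 0.44)
    prof2 = profile_from_text(profile_to_text(prof))
    assert prof2.M == prof.M and prof2.consensus == prof.consensus
    assert prof2.calibration == pytest.approx(prof.calibration)
    np.testing.assert_allclose(prof2.match_probs, prof.match_probs, atol=1e-6)
    target = make_protein_family("rps3", 50)[1]
    assert viterbi(prof2, target).score == pytest.approx(
        viterbi(prof, target).score, abs=1e-4)
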