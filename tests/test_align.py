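"""Alignment core: scoring, chain admissibility, DP optimality, traceback."""

from __future__ import annotations

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tracklink.align import (
    FULL,
    GAP_DIARY,
    GAP_GPS,
    MISMATCH,
    PARTIAL,
    ScoringScheme,
    align,
    chain_applicable,
    order_resolution_demo,
    pair_score,
)

SCHEME = ScoringScheme()
ALPHABET = ["Ab", "Ba", "Bd", "Da", "Ac", "Ca"]


def enumerate_alignment_scores(g, d, scheme=SCHEME, allow_chain=True):
    """Yield the total score of every legal alignment (no memoisation, no
    pruning) — the independent oracle for the dynamic programme."""
    if not g and not d:
        yield 0.0
        return
    if g and d:
        for rest in enumerate_alignment_scores(g[:-1], d[:-1], scheme, allow_chain):
            yield rest + pair_score(g[-1], d[-1], scheme)[0]
        if allow_chain and len(g) >= 2 and chain_applicable(g[-2], g[-1], d[-1]):
            for rest in enumerate_alignment_scores(g[:-2], d[:-1], scheme, allow_chain):
                yield rest + scheme.chain_pair
    if g:
        for rest in enumerate_alignment_scores(g[:-1], d, scheme, allow_chain):
            yield rest + scheme.gap
    if d:
        for rest in enumerate_alignment_scores(g, d[:-1], scheme, allow_chain):
            yield rest + scheme.gap


def brute_force_score(g, d, scheme=SCHEME, allow_chain=True):
    return max(enumerate_alignment_scores(list(g), list(d), scheme, allow_chain))


@pytest.mark.parametrize(
    "g,d,expected",
    [
        ("Ab", "Ab", FULL),
        ("Ac", "Ab", PARTIAL),  # shared origin only
        ("Cb", "Ab", PARTIAL),  # shared destination only
        ("Bd", "Ac", MISMATCH),
    ],
)
def test_pair_score_classification(g, d, expected):
    score, cls = pair_score(g, d, SCHEME)
    assert cls == expected
    assert score == {FULL: 2.0, PARTIAL: 1.0, MISMATCH: -1.0}[expected]


def test_pair_score_is_case_insensitive_per_position():
    assert pair_score("Ab", "ab", SCHEME)[1] == FULL
    assert pair_score("AB", "Ab", SCHEME)[1] == FULL


def test_pair_score_rejects_malformed_codes():
    with pytest.raises(ValueError):
        pair_score("A", "Ab", SCHEME)
    with pytest.raises(ValueError):
        pair_score("Aj", "Ab", SCHEME)  # letter J is never a location code


@pytest.mark.parametrize(
    "gi,gj,d,expected",
    [
        ("Bd", "Da", "Ba", True),  # School->Shops + Shops->Home vs School->Home
        ("Bd", "Ea", "Ba", False),  # chain broken: shops != open space
        ("Ab", "Ba", "Aa", True),
        ("Ab", "Ba", "Ab", False),  # outer destination mismatch
    ],
)
def test_chain_applicable(gi, gj, d, expected):
    assert chain_applicable(gi, gj, d) is expected


def test_two_gps_trips_chain_onto_one_diary_trip():
    res = align(["Bd", "Da"], ["Ba"])
    assert [p.step for p in res.pairs] == ["chain"]
    (pair,) = res.pairs
    assert pair.gps_indices == (0, 1) and pair.diary_index == 0
    assert pair.match_class == PARTIAL
    assert res.counts["unmatched_diary"] == 0 and res.counts["unmatched_gps"] == 0
    assert res.score == SCHEME.chain_pair


def test_identical_sequences_align_fully():
    res = align(["Ab", "Ba"], ["Ab", "Ba"])
    assert res.counts["full"] == 2
    assert res.score == 2 * SCHEME.full_match


def test_single_partial_pairing():
    res = align(["Ac"], ["Ab"])
    assert res.counts == {
        "full": 0, "partial": 1, "unmatched_diary": 0, "unmatched_gps": 0,
        "n_gps": 1, "n_diary": 1,
    }


def test_empty_side_becomes_gaps():
    res = align(["Ab", "Ba"], [])
    assert all(p.match_class == GAP_GPS for p in res.pairs)
    assert res.score == 2 * SCHEME.gap
    res = align([], ["Ab"])
    assert res.pairs[0].match_class == GAP_DIARY
    assert align([], []).score == 0.0


def test_dp_matches_brute_force_exhaustively_small():
    """DP optimum equals enumeration of every legal alignment for all
    sequence pairs up to 2x2 over the six-code alphabet."""
    seqs = [list(t) for n in range(3) for t in itertools.product(ALPHABET, repeat=n)]
    for g in seqs:
        for d in seqs:
            assert align(g, d).score == brute_force_score(g, d), (g, d)


def test_dp_matches_brute_force_on_longer_random_pairs():
    import random

    rng = random.Random(1234)
    for _ in range(150):
        g = [rng.choice(ALPHABET) for _ in range(rng.randint(0, 5))]
        d = [rng.choice(ALPHABET) for _ in range(rng.randint(0, 4))]
        assert align(g, d).score == brute_force_score(g, d), (g, d)


def test_chain_disabled_equals_textbook_needleman_wunsch():
    """With chains off the aligner reduces to plain global alignment;
    cross-checked against Biopython's PairwiseAligner on proxy symbols."""
    import random

    from Bio import Align as BioAlign
    from Bio.Align.substitution_matrices import Array

    proxy = {code: chr(ord("a") + i) for i, code in enumerate(ALPHABET)}
    matrix = Array("".join(proxy.values()), dims=2)
    for x in ALPHABET:
        for y in ALPHABET:
            matrix[proxy[x], proxy[y]] = pair_score(x, y, SCHEME)[0]
    aligner = BioAlign.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = SCHEME.gap
    aligner.extend_gap_score = SCHEME.gap

    rng = random.Random(99)
    for _ in range(100):
        g = [rng.choice(ALPHABET) for _ in range(rng.randint(1, 6))]
        d = [rng.choice(ALPHABET) for _ in range(rng.randint(1, 5))]
        ours = align(g, d, allow_chain=False).score
        ref = aligner.score("".join(proxy[c] for c in g), "".join(proxy[c] for c in d))
        assert ours == ref, (g, d)


@settings(deadline=None, max_examples=200)
@given(
    g=st.lists(st.sampled_from(ALPHABET), max_size=6),
    d=st.lists(st.sampled_from(ALPHABET), max_size=5),
)
def test_conservation_and_consistency_invariants(g, d):
    """Every diary trip lands in exactly one class; every GPS trip is used
    exactly once; counts agree with the pair list."""
    res = align(g, d)
    assert res.counts["full"] + res.counts["partial"] + res.counts["unmatched_diary"] == len(d)
    used_g = [i for p in res.pairs for i in p.gps_indices]
    assert sorted(used_g) == list(range(len(g)))
    used_d = [p.diary_index for p in res.pairs if p.diary_index is not None]
    assert sorted(used_d) == list(range(len(d)))


@settings(deadline=None, max_examples=100)
@given(
    g=st.lists(st.sampled_from(ALPHABET), max_size=4),
    d=st.lists(st.sampled_from(ALPHABET), max_size=3),
    extra=st.sampled_from(ALPHABET),
)
def test_appending_common_trip_never_lowers_score(g, d, extra):
    assert align(g + [extra], d + [extra]).score >= align(g, d).score


def test_traceback_is_deterministic():
    g, d = ["Ab", "Ba", "Ab", "Ba"], ["Ab", "Ba"]
    first = align(g, d)
    second = align(g, d)
    assert first.pairs == second.pairs and first.score == second.score


def test_duplicate_trips_resolved_by_sequence_order():
    """Two identical GPS candidates, one diary entry placed after an
    intervening trip: the later GPS copy must take the match."""
    gps = ["Ac", "Ca", "Ab", "Ba", "Ac"]
    diary = ["Ab", "Ba", "Ac"]
    res = order_resolution_demo(gps, diary)
    last_diary_pair = [p for p in res.pairs if p.diary_index == 2]
    assert last_diary_pair[0].gps_indices == (4,)
    assert last_diary_pair[0].match_class == FULL


def test_order_resolution_degenerate_single_pair():
    res = order_resolution_demo(["Ab"], ["Ab"])
    assert res.counts["full"] == 1


def test_scoring_scheme_invariants_enforced():
    with pytest.raises(ValueError):
        ScoringScheme(full_match=1.0, partial_match=1.0)
    with pytest.raises(ValueError):
        ScoringScheme(chain_pair=-3.0)
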