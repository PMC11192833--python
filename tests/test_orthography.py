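"""Pairwise-similarity schemes: worked examples, invariants, and
independent oracles (recursive edit distance, bipartite matching,
edlib)."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from orthomem.orthography import (
    EdgeMix,
    ExteriorWeights,
    InvalidWordError,
    OverlapParams,
    both_edges_overlap_similarity,
    both_edges_slot_similarity,
    closed_bigram_similarity,
    e_modified_similarity,
    end_based_slot_similarity,
    extract_closed_bigrams,
    extract_open_bigrams,
    levenshtein_distance,
    levenshtein_similarity,
    nearest_neighbors,
    normalize_word,
    open_bigram_similarity,
    overlap_similarity,
    sigma_schedule,
    similarity,
    slot_similarity,
)

EW = ExteriorWeights()
GOMEZ = OverlapParams(d=1.544, r=1.094)
words = st.text(alphabet="abcdefghijklmnopqrstuvwxyz", min_size=1, max_size=8)


# ---------------------------------------------------------------------------
# Worked examples
# ---------------------------------------------------------------------------


def test_normalize_word():
    assert normalize_word("Ledge") == "ledge"
    assert normalize_word("dog") == "dog"
    assert normalize_word(" Dog's! ") == "dogs"
    with pytest.raises(InvalidWordError):
        normalize_word("")
    with pytest.raises(InvalidWordError):
        normalize_word("123 !")


@pytest.mark.parametrize(
    "probe,studied,expected",
    [
        ("baseball", "based", 0.5),
        ("ledge", "ledger", 5 / 6),
        ("raided", "hamburger", 1 / 9),
    ],
)
def test_slot_worked_examples(probe, studied, expected):
    result = slot_similarity(probe, studied, EW)
    assert result.value == pytest.approx(expected)


def test_slot_match_count_raided_hamburger():
    assert slot_similarity("raided", "hamburger", EW).matches == 1


def test_end_anchored_matching_follows_positional_rule():
    """End-anchored matching counts every pair of letters sharing an
    end-anchored position.  kitten/smitten align at -1(n), -2(e),
    -3(t), -4(t), -5(i): five matches over alignment 7."""
    assert end_based_slot_similarity("kitten", "smitten", EW).value == pytest.approx(5 / 7)
    assert end_based_slot_similarity("ledge", "ledger", EW).value == 0.0


def test_both_edges_slot_mixture():
    result = both_edges_slot_similarity("ledge", "ledger", EW, EdgeMix(w=0.75))
    assert result.value == pytest.approx(0.625)
    # composition of independently computed parts
    s_start = slot_similarity("kitten", "smitten", EW).value
    s_end = end_based_slot_similarity("kitten", "smitten", EW).value
    combo = both_edges_slot_similarity("kitten", "smitten", EW, EdgeMix(w=0.75))
    assert combo.value == pytest.approx(0.75 * s_start + 0.25 * s_end)


@pytest.mark.parametrize(
    "fn,probe,studied,expected,digits",
    [
        (closed_bigram_similarity, "ledge", "ledger", 0.71, 2),
        (closed_bigram_similarity, "sustain", "sultan", 0.5, 1),
        (open_bigram_similarity, "sustain", "station", 0.59, 2),
        (open_bigram_similarity, "ledge", "ledger", 0.71, 2),
        (levenshtein_similarity, "ledge", "ledger", 0.83, 2),
    ],
)
def test_printed_bigram_and_levenshtein_values(fn, probe, studied, expected, digits):
    assert round(fn(probe, studied).value if fn is levenshtein_similarity else fn(probe, studied, EW).value, digits) == expected


def test_overlap_printed_value():
    assert round(overlap_similarity("ledge", "ledger", EW, GOMEZ).value, 1) == 0.3
    assert round(overlap_similarity("ledge", "lever", EW, GOMEZ).value, 2) == 0.26


def test_both_edges_overlap_soft_value():
    # the end-anchored sigma indexing is a convention; printed 0.28 is a
    # soft check
    value = both_edges_overlap_similarity("ledge", "ledger", EW, GOMEZ, EdgeMix(w=0.75)).value
    assert abs(value - 0.28) < 0.01


def test_levenshtein_distances():
    assert levenshtein_distance("dog", "dogs") == 1
    assert levenshtein_distance("trail", "trial") == 2
    assert levenshtein_similarity("dog", "dogs").value == pytest.approx(0.75)


def test_closed_bigram_once_only_rule():
    # without once-only matching ababab/ab would score .5
    assert closed_bigram_similarity("ababab", "ab", EW).value == pytest.approx(3 / 7)


def test_bigram_bags():
    assert extract_closed_bigrams("cat") == {"_c": 1, "ca": 1, "at": 1, "t_": 1}
    assert sum(extract_closed_bigrams("ledger").values()) == 7
    assert extract_closed_bigrams("a") == {"_a": 1, "a_": 1}
    assert sum(extract_open_bigrams("sustain").values()) == 17
    assert extract_open_bigrams("ab") == {"_a": 1, "ab": 1, "b_": 1}
    about = extract_open_bigrams("about")
    for pair in ("ab", "ao", "au"):
        assert about[pair] >= 1


def test_sigma_schedule():
    expected = 1.544 * (1 - np.exp(-0.5 / 1.094))
    assert sigma_schedule(1, GOMEZ) == pytest.approx(expected)
    sigmas = [sigma_schedule(l, GOMEZ) for l in range(1, 12)]
    assert all(a < b for a, b in zip(sigmas, sigmas[1:]))
    assert sigmas[-1] < GOMEZ.d
    with pytest.raises(ValueError):
        OverlapParams(d=-1.0, r=1.0)


def test_nearest_neighbors_ranking():
    pool = ["ledger", "ladle", "wedgie", "redeem", "midget", "ledge", "cat"]
    top = nearest_neighbors("ledge", pool, "slot", k=3)
    assert top[0] == ("ledger", pytest.approx(5 / 6))
    assert all(w != "ledge" for w, _ in top)  # probe excluded
    # k larger than pool: whole ranked pool
    assert len(nearest_neighbors("ledge", pool, "slot", k=50)) == len(pool) - 1
    # all-zero similarities rank lexicographically
    zeros = nearest_neighbors("zzz", ["cat", "bat", "art"], "slot", k=3)
    assert [w for w, _ in zeros] == ["art", "bat", "cat"]
    with pytest.raises(ValueError):
        nearest_neighbors("ledge", ["ledge"], "slot")


def test_e_modification():
    base = slot_similarity("ledge", "ledger", EW)
    # epsilon = 0 is a no-op
    assert e_modified_similarity(base, "ledge", "ledger", 0.0, EW).value == base.value
    # joint presence of 'e' raises similarity, growing with epsilon
    boosted = [
        e_modified_similarity(base, "ledge", "ledger", eps, EW).value for eps in (0.5, 1.0, 2.0)
    ]
    assert boosted[0] > base.value * base.alignment / (base.alignment + 0.5)
    assert boosted[0] < boosted[1] < boosted[2]
    # no matches and no shared 'e' -> exactly zero
    none = slot_similarity("cat", "dog", EW)
    assert e_modified_similarity(none, "cat", "dog", 1.0, EW).value == 0.0
    with pytest.raises(ValueError):
        e_modified_similarity(base, "ledge", "ledger", -0.1, EW)


# ---------------------------------------------------------------------------
# Invariants and oracles
# ---------------------------------------------------------------------------

ALL_SCHEMES = ["slot", "both-slot", "overlap", "both-overlap", "closed-bigram", "open-bigram", "levenshtein"]


@pytest.mark.parametrize("scheme", ALL_SCHEMES)
def test_bounds_and_self_similarity(scheme, random_word_pairs):
    """All schemes stay in [0, 1]; every scheme except the overlap
    models scores a word against itself at exactly 1.  Positional
    uncertainty makes overlap self-similarity fall short of 1 (it only
    reaches 1 in the sigma -> 0 limit, covered separately)."""
    for w1, w2 in random_word_pairs[:60]:
        value = similarity(w1, w2, scheme, ew=EW, op=GOMEZ).value
        assert 0.0 <= value <= 1.0
        self_value = similarity(w1, w1, scheme, ew=EW, op=GOMEZ).value
        if scheme in ("overlap", "both-overlap"):
            assert self_value <= 1.0 + 1e-12
        else:
            assert self_value == pytest.approx(1.0, abs=1e-9)


@pytest.mark.parametrize(
    "scheme", [s for s in ALL_SCHEMES if s not in ("overlap", "both-overlap")]
)
def test_symmetry_for_equal_length_pairs(scheme, random_word_pairs):
    """With alpha = omega = 1 the position-exact schemes are symmetric
    for equal-length pairs and Levenshtein unconditionally.  The
    overlap models are not asserted here: their uncertainty lives in
    the studied word and grows with serial position, so swapping probe
    and studied words changes which letters carry the uncertainty."""
    for w1, w2 in random_word_pairs:
        if scheme != "levenshtein" and len(w1) != len(w2):
            continue
        a = similarity(w1, w2, scheme, ew=EW, op=GOMEZ).value
        b = similarity(w2, w1, scheme, ew=EW, op=GOMEZ).value
        assert a == pytest.approx(b, abs=1e-12)


def test_overlap_reverts_to_slot_as_uncertainty_vanishes(random_word_pairs):
    tiny = OverlapParams(d=1e-6, r=1.0)
    for w1, w2 in random_word_pairs[:60]:
        ov = overlap_similarity(w1, w2, EW, tiny).value
        sl = slot_similarity(w1, w2, EW).value
        assert abs(ov - sl) < 1e-6


def test_both_edges_reduce_to_forward_at_w1(random_word_pairs):
    one = EdgeMix(w=1.0)
    for w1, w2 in random_word_pairs[:40]:
        assert both_edges_slot_similarity(w1, w2, EW, one).value == pytest.approx(
            slot_similarity(w1, w2, EW).value
        )
        assert both_edges_overlap_similarity(w1, w2, EW, GOMEZ, one).value == pytest.approx(
            overlap_similarity(w1, w2, EW, GOMEZ).value
        )


@given(words)
@settings(max_examples=60, deadline=None, derandomize=True)
def test_bigram_bag_sizes(word):
    w = len(word)
    assert sum(extract_closed_bigrams(word).values()) == w + 1
    expected_open = max(w - 1, 0) + max(w - 2, 0) + max(w - 3, 0) + 2
    assert sum(extract_open_bigrams(word).values()) == expected_open


def _bipartite_matching_size(bag_i, bag_j):
    """Independent once-only-matching oracle: maximum bipartite
    matching over token instances with equality edges."""
    import networkx as nx

    graph = nx.Graph()
    left, right = [], []
    for token, count in bag_i.items():
        left.extend((("i", token, c)) for c in range(count))
    for token, count in bag_j.items():
        right.extend((("j", token, c)) for c in range(count))
    graph.add_nodes_from(left, bipartite=0)
    graph.add_nodes_from(right, bipartite=1)
    for u in left:
        for v in right:
            if u[1] == v[1]:
                graph.add_edge(u, v)
    matching = nx.bipartite.maximum_matching(graph, top_nodes=left)
    return len(matching) // 2


@given(st.tuples(words, words))
@settings(max_examples=40, deadline=None, derandomize=True)
def test_once_only_matching_equals_bipartite_oracle(pair):
    w1, w2 = pair
    for extract in (extract_closed_bigrams, extract_open_bigrams):
        bag_i, bag_j = extract(w1), extract(w2)
        greedy = sum((bag_i & bag_j).values())
        assert greedy == _bipartite_matching_size(bag_i, bag_j)


def _lev_recursive(a, b):
    if not a:
        return len(b)
    if not b:
        return len(a)
    return min(
        _lev_recursive(a[1:], b) + 1,
        _lev_recursive(a, b[1:]) + 1,
        _lev_recursive(a[1:], b[1:]) + (a[0] != b[0]),
    )


@given(st.tuples(st.text(alphabet="abcde", min_size=1, max_size=6),
                 st.text(alphabet="abcde", min_size=1, max_size=6)))
@settings(max_examples=50, deadline=None, derandomize=True)
def test_levenshtein_dp_equals_recursive_oracle(pair):
    a, b = pair
    assert levenshtein_distance(a, b) == _lev_recursive(a, b)


def test_levenshtein_matches_edlib(random_word_pairs):
    edlib = pytest.importorskip("edlib")
    for w1, w2 in random_word_pairs:
        assert levenshtein_distance(w1, w2) == edlib.align(w1, w2)["editDistance"]


def test_exterior_weight_validation():
    with pytest.raises(ValueError):
        ExteriorWeights(alpha=-0.5)
    with pytest.raises(ValueError):
        EdgeMix(w=1.5)
    with pytest.raises(ValueError):
        similarity("cat", "dog", "trigram")
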