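import math
import random

import pytest
from hypothesis import given, settings, strategies as st

from bgcmine.compare import (Blosum62Aligner, QueryCluster, ReferenceEntry,
                             best_hit_pairing, compare, compare_one,
                             components_part, final_score, identity_part,
                             load_reference_db, synteny_part,
                             write_reference_db)

from ._oracles import EqualityAligner, brute_force_lis

PROT = {
    "p1": "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ",
    "p2": "MSDNKQLVAALREAGIEVHTTPEGVRAIEALGG",
    "p3": "MALWMRLLPLLALLALWGPDPAAAFVNQHLCGS",
    "p4": "MENFKHLPEPFRIRVIEPVKRTTAYREGQIVKG",
}


def ref_entry(entry_id, names, components=("tag1",)):
    return ReferenceEntry(entry_id,
                          tuple((f"r_{n}", PROT[n], tuple(components))
                                for n in names))


# --------------------------------------------------------------------------
# Pairing


def test_identical_sets_pair_fully_at_100():
    proteins = [(n, PROT[n]) for n in ("p1", "p2", "p3")]
    pairing = best_hit_pairing(proteins, [(f"r{n}", PROT[n]) for n in ("p1", "p2", "p3")],
                               Blosum62Aligner())
    assert len(pairing) == 3
    assert all(identity == 100.0 for _, _, identity in pairing)
    assert {(q, r) for q, r, _ in pairing} == {("p1", "rp1"), ("p2", "rp2"),
                                              ("p3", "rp3")}


def test_greedy_pairing_prefers_higher_identity():
    def aligner(a, b):
        table = {("Q", "X"): 90.0, ("Q", "Y"): 70.0}
        return table.get((a, b), 0.0), 1.0

    pairing = best_hit_pairing([("q", "Q")], [("x", "X"), ("y", "Y")], aligner)
    assert pairing == [("q", "x", 90.0)]


def test_pairing_discards_below_thresholds():
    def weak(a, b):
        return 25.0, 1.0  # below 30% identity

    assert best_hit_pairing([("q", "Q")], [("r", "R")], weak) == []

    def shallow(a, b):
        return 90.0, 0.1  # below 25% coverage

    assert best_hit_pairing([("q", "Q")], [("r", "R")], shallow) == []


def test_empty_query_gives_empty_pairing():
    assert best_hit_pairing([], [("r", PROT["p1"])], Blosum62Aligner()) == []


# --------------------------------------------------------------------------
# Score parts


def test_identity_part_mean_over_query():
    pairing = [("q1", "r1", 80.0), ("q2", "r2", 40.0)]
    assert identity_part(pairing, 3) == pytest.approx(0.4)
    assert identity_part([("q", "r", 100.0)], 1) == 1.0
    assert identity_part([], 5) == 0.0
    with pytest.raises(ValueError):
        identity_part(pairing, 0)


@pytest.mark.parametrize("ref_indices,expected", [
    ([1, 2, 3, 4, 5], 1.0),
    ([5, 4, 3, 2, 1], 1.0),   # reverse orientation
    ([2, 1, 3, 4], 3 / 4),
])
def test_synteny_part_examples(ref_indices, expected):
    query_order = [f"q{i}" for i in range(len(ref_indices))]
    ref_order = [f"r{i}" for i in range(max(ref_indices) + 1)]
    pairing = [(f"q{i}", f"r{idx}", 90.0) for i, idx in enumerate(ref_indices)]
    assert synteny_part(pairing, query_order, ref_order) == pytest.approx(expected)


@pytest.mark.parametrize("seed", range(25))
def test_synteny_lis_matches_brute_force(seed):
    rng = random.Random(seed)
    n = rng.randint(1, 8)
    indices = rng.sample(range(12), n)
    query_order = [f"q{i}" for i in range(n)]
    ref_order = [f"r{i}" for i in range(12)]
    pairing = [(f"q{i}", f"r{idx}", 90.0) for i, idx in enumerate(indices)]
    expected = max(brute_force_lis(indices),
                   brute_force_lis([-x for x in indices])) / n
    assert synteny_part(pairing, query_order, ref_order) == pytest.approx(expected)


def test_synteny_no_pairs_is_zero():
    assert synteny_part([], ["q1"], ["r1"]) == 0.0


@pytest.mark.parametrize("a,b,expected", [
    ({"A", "B"}, {"A", "B"}, 1.0),
    ({"A"}, {"B"}, 0.0),
    ({"A", "B"}, {"B", "C"}, 1 / 3),
    (set(), set(), 0.0),
])
def test_components_jaccard(a, b, expected):
    assert components_part(a, b) == pytest.approx(expected)


@pytest.mark.parametrize("parts,expected", [
    ([1.0, 1.0, 1.0], 1.0),
    ([0.5, 0.5, 0.5], 0.5),
    ([0.9, 0.4, 0.0], 0.0),
])
def test_final_score_geometric_mean(parts, expected):
    assert final_score(parts) == pytest.approx(expected)


def test_final_score_validates_input():
    with pytest.raises(ValueError):
        final_score([])
    with pytest.raises(ValueError):
        final_score([1.2])


@given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=6))
@settings(max_examples=300, deadline=None)
def test_final_score_within_geometric_mean_envelope(parts):
    score = final_score(parts)
    assert 0.0 <= score <= 1.0
    if 0.0 in parts:
        assert score == 0.0
    else:
        assert min(parts) - 1e-9 <= score <= max(parts) + 1e-9


# --------------------------------------------------------------------------
# Full comparison


def test_self_comparison_scores_exactly_one():
    query = QueryCluster("q", [(n, PROT[n]) for n in ("p1", "p2", "p3")],
                         frozenset({"tagA", "tagB"}))
    self_ref = ReferenceEntry("BGC0000001",
                              tuple((n, PROT[n], ("tagA", "tagB"))
                                    for n in ("p1", "p2", "p3")))
    decoy = ref_entry("BGC0000002", ["p4"], components=("other",))
    ranked = compare([query], [decoy, self_ref])["q"]
    assert ranked[0].entry_id == "BGC0000001"
    assert ranked[0].final_score == 1.0
    assert (ranked[0].identity_part, ranked[0].synteny_part,
            ranked[0].components_part) == (1.0, 1.0, 1.0)


def test_shared_proteins_outrank_disjoint_entries():
    query = QueryCluster("q", [(n, PROT[n]) for n in ("p1", "p2", "p3", "p4")],
                         frozenset({"tag1"}))
    sharing = ref_entry("BGC0000010", ["p1", "p2"])
    disjoint = ReferenceEntry(
        "BGC0000011",
        (("d1", "MNNNNNNNNNNQQQQQQQQQQ", ("tag1",)),))
    ranked = compare([query], [disjoint, sharing])["q"]
    assert ranked[0].entry_id == "BGC0000010"
    assert ranked[0].final_score > ranked[1].final_score


def test_empty_database_gives_empty_results():
    query = QueryCluster("q", [("p1", PROT["p1"])], frozenset({"t"}))
    assert compare([query], []) == {"q": []}


def test_ranking_invariant_under_db_permutation():
    query = QueryCluster("q", [(n, PROT[n]) for n in ("p1", "p2")],
                         frozenset({"tag1"}))
    entries = [ref_entry(f"BGC{i:07d}", ["p1"]) for i in range(4)]
    forward = compare([query], entries)["q"]
    backward = compare([query], list(reversed(entries)))["q"]
    assert [r.entry_id for r in forward] == [r.entry_id for r in backward]


@pytest.mark.parametrize("seed", range(10))
def test_removing_reference_protein_never_raises_identity(seed):
    rng = random.Random(seed)
    aligner = EqualityAligner()
    alphabet = "ACDEFGHIKLMNPQRSTVWY"
    queries = [(f"q{i}", "".join(rng.choices(alphabet, k=20)))
               for i in range(rng.randint(1, 4))]
    refs = [(f"r{i}", "".join(rng.choices(alphabet, k=20)))
            for i in range(rng.randint(1, 4))]
    base = identity_part(best_hit_pairing(queries, refs, aligner), len(queries))
    for i in range(len(refs)):
        reduced = refs[:i] + refs[i + 1:]
        part = identity_part(best_hit_pairing(queries, reduced, aligner),
                             len(queries))
        assert part <= base + 1e-12


def test_reference_db_round_trip(tmp_path):
    entries = [ref_entry("BGC0001100", ["p1", "p2"]),
               ref_entry("BGC0000085", ["p3"])]
    path = tmp_path / "db.json"
    write_reference_db(entries, path)
    assert load_reference_db(path) == entries
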