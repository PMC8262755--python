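import random

import pytest

from bgcmine.core import Protocluster
from bgcmine.profiles import hits_by_cds
from bgcmine.core import ProfileHit
from bgcmine.rules import (And, CdsLocal, MinimumCount, Not, Or, ProfileRef,
                           RuleConfigurationError, RuleSyntaxError,
                           build_regions, evaluate_rule, form_protoclusters,
                           parse_rule, parse_rules)

from ._oracles import exhaustive_cores, random_rule_case
from .conftest import make_record

RULE_TEMPLATE = """RULE {name}
CATEGORY other
STRICTNESS strict
CUTOFF {cutoff}
NEIGHBOURHOOD {neigh}
CONDITIONS {cond}
"""


def make_rule(cond, name="testrule", cutoff=20, neigh=5):
    return parse_rule(RULE_TEMPLATE.format(name=name, cutoff=cutoff,
                                           neigh=neigh, cond=cond))


def hits_map(mapping):
    """cds_id -> profile names, as the hits_by_cds shape evaluate_rule takes."""
    return {cds: [ProfileHit(cds, p, 50.0, 0.0, 0, 10) for p in profiles]
            for cds, profiles in mapping.items()}


# --------------------------------------------------------------------------
# Parsing


def test_parse_cds_local_and():
    rule = make_rule("cds(PKS_KS and PKS_AT)", name="t1pks")
    assert rule.rule_name == "t1pks"
    assert rule.condition == CdsLocal(And((ProfileRef("PKS_KS"),
                                          ProfileRef("PKS_AT"))))


def test_parse_minimum():
    rule = make_rule("minimum(3, [A, B, C, D])")
    assert rule.condition == MinimumCount(3, ("A", "B", "C", "D"))


def test_parse_minimum_rejects_zero():
    with pytest.raises(RuleSyntaxError):
        make_rule("minimum(0, [A])")


def test_parse_precedence_not_and_or():
    rule = make_rule("not A and B or C")
    # not binds tightest, then and, then or
    assert rule.condition == Or((And((Not(ProfileRef("A")), ProfileRef("B"))),
                                 ProfileRef("C")))


def test_parse_parenthesised_grouping():
    rule = make_rule("A and (B or C)")
    assert rule.condition == And((ProfileRef("A"),
                                  Or((ProfileRef("B"), ProfileRef("C")))))


def test_parse_syntax_error_reports_position():
    with pytest.raises(RuleSyntaxError):
        make_rule("A and )")
    with pytest.raises(RuleSyntaxError):
        parse_rule("RULE x CONDITIONS A")  # missing mandatory keys


def test_duplicate_rule_names_rejected():
    text = RULE_TEMPLATE.format(name="dup", cutoff=20, neigh=5, cond="A") + \
        RULE_TEMPLATE.format(name="dup", cutoff=20, neigh=5, cond="B")
    with pytest.raises(RuleConfigurationError):
        parse_rules(text)


def test_unknown_profile_fails_at_load_time(catalogue):
    from bgcmine.rules import RuleCatalogue
    rule = make_rule("NO_SUCH_PROFILE")
    with pytest.raises(RuleConfigurationError, match="NO_SUCH_PROFILE"):
        RuleCatalogue([rule]).validate_against(catalogue)


# --------------------------------------------------------------------------
# Evaluation


def test_minimum_count_joins_cds_within_cutoff():
    rule = make_rule("minimum(2, [A, B, C])", cutoff=20)
    record = make_record([("cds1", 1000, 2000, 1, "M"),
                          ("cds2", 10000, 11000, 1, "M")])
    grouped = hits_map({"cds1": ["A"], "cds2": ["B"]})
    cores = evaluate_rule(rule, grouped, record)
    assert cores == [frozenset({"cds1", "cds2"})]
    profile_sets = {c: {h.profile_name for h in hs} for c, hs in grouped.items()}
    assert exhaustive_cores(rule, profile_sets, record) == set(cores)


def test_no_hits_gives_no_cores():
    rule = make_rule("minimum(2, [A, B, C])")
    record = make_record([("cds1", 1000, 2000, 1, "M")])
    assert evaluate_rule(rule, {}, record) == []


def test_cutoff_breaks_joint_satisfaction():
    rule = make_rule("minimum(2, [A, B, C])", cutoff=5)  # gap is 8 kb
    record = make_record([("cds1", 1000, 2000, 1, "M"),
                          ("cds2", 10000, 11000, 1, "M")])
    grouped = hits_map({"cds1": ["A"], "cds2": ["B"]})
    assert evaluate_rule(rule, grouped, record) == []
    profile_sets = {c: {h.profile_name for h in hs} for c, hs in grouped.items()}
    assert exhaustive_cores(rule, profile_sets, record) == set()


def test_cds_local_requires_single_gene():
    rule = make_rule("cds(A and B)")
    record = make_record([("cds1", 1000, 2000, 1, "M"),
                          ("cds2", 3000, 4000, 1, "M")])
    split = hits_map({"cds1": ["A"], "cds2": ["B"]})
    assert evaluate_rule(rule, split, record) == []
    joint = hits_map({"cds1": ["A", "B"]})
    assert evaluate_rule(rule, joint, record) == [frozenset({"cds1"})]


def test_negation_excludes_cds_sets():
    rule = make_rule("cds(A and not B)")
    record = make_record([("cds1", 1000, 2000, 1, "M")])
    assert evaluate_rule(rule, hits_map({"cds1": ["A"]}), record) == \
        [frozenset({"cds1"})]
    assert evaluate_rule(rule, hits_map({"cds1": ["A", "B"]}), record) == []


@pytest.mark.parametrize("seed", range(40))
def test_evaluate_rule_matches_exhaustive_enumeration(seed):
    """Chained evaluation equals brute-force maximal-subset search."""
    rng = random.Random(seed)
    rule, record, profile_sets = random_rule_case(rng)
    grouped = {c: [ProfileHit(c, p, 50.0, 0.0, 0, 10) for p in sorted(ps)]
               for c, ps in profile_sets.items()}
    assert set(evaluate_rule(rule, grouped, record)) == \
        exhaustive_cores(rule, profile_sets, record)


@pytest.mark.parametrize("seed", range(15))
def test_adding_hits_preserves_core_satisfiability(seed):
    """Monotonicity: an extra hit never invalidates an existing core."""
    rng = random.Random(1000 + seed)
    rule, record, profile_sets = random_rule_case(rng)
    grouped = {c: [ProfileHit(c, p, 50.0, 0.0, 0, 10) for p in sorted(ps)]
               for c, ps in profile_sets.items()}
    cores = evaluate_rule(rule, grouped, record)
    # add a random extra hit
    target = rng.choice(record.cds_features).cds_id
    augmented = dict(profile_sets)
    augmented[target] = augmented.get(target, set()) | {"pA"}
    for core in cores:
        assert rule.condition.evaluate(core, augmented)


@pytest.mark.parametrize("seed", range(15))
def test_increasing_cutoff_never_shrinks_core_coverage(seed):
    rng = random.Random(2000 + seed)
    rule, record, profile_sets = random_rule_case(rng)
    grouped = {c: [ProfileHit(c, p, 50.0, 0.0, 0, 10) for p in sorted(ps)]
               for c, ps in profile_sets.items()}
    from dataclasses import replace
    wide = replace(rule, cutoff_kb=rule.cutoff_kb * 2)
    covered_narrow = set().union(*evaluate_rule(rule, grouped, record), frozenset())
    covered_wide = set().union(*evaluate_rule(wide, grouped, record), frozenset())
    assert covered_narrow <= covered_wide


# --------------------------------------------------------------------------
# Protoclusters and regions


def test_form_protoclusters_extends_and_clips():
    rule = make_rule("A", neigh=5)
    record = make_record([("cds1", 10000, 12000, 1, "M")], length=50000)
    [proto] = form_protoclusters(rule, [frozenset({"cds1"})], record)
    assert proto.core == (10000, 12000)
    assert proto.neighbourhood == (5000, 17000)

    near_origin = make_record([("cds1", 1000, 3000, 1, "M")], length=50000)
    [proto] = form_protoclusters(rule, [frozenset({"cds1"})], near_origin)
    assert proto.neighbourhood == (0, 8000)


def proto(product, category, core, neigh, cds_ids, rule_name=None):
    return Protocluster(product, category, core[0], core[1], neigh[0], neigh[1],
                        frozenset(cds_ids), rule_name or product)


def test_single_protocluster_single_region():
    record = make_record([("a", 10000, 12000, 1, "M")], length=60000)
    p = proto("terpene", "terpene", (10000, 12000), (5000, 17000), {"a"})
    regions = build_regions([p], record)
    assert len(regions) == 1
    assert regions[0].region_number == 1
    assert [c.kind for c in regions[0].candidates] == ["single"]
    assert regions[0].interval == (5000, 17000)


def test_overlapping_assembly_cores_form_chemical_hybrid():
    record = make_record([("a", 10000, 14000, 1, "M"),
                          ("b", 13000, 18000, 1, "M")], length=80000)
    p1 = proto("t1pks", "PKS", (10000, 14000), (5000, 19000), {"a"})
    p2 = proto("NRPS", "NRPS", (13000, 18000), (8000, 23000), {"b"})
    regions = build_regions([p1, p2], record)
    assert len(regions) == 1
    kinds = {c.kind for c in regions[0].candidates}
    assert "chemical-hybrid" in kinds


def test_overlapping_incompatible_cores_are_interleaved():
    record = make_record([("a", 10000, 14000, 1, "M"),
                          ("b", 13000, 18000, 1, "M")], length=80000)
    p1 = proto("terpene", "terpene", (10000, 14000), (5000, 19000), {"a"})
    p2 = proto("lassopeptide", "RiPP", (13000, 18000), (8000, 23000), {"b"})
    regions = build_regions([p1, p2], record)
    assert {c.kind for c in regions[0].candidates} == {"interleaved"}


def test_distant_protoclusters_get_separate_numbered_regions():
    record = make_record([("a", 10000, 12000, 1, "M"),
                          ("b", 150000, 152000, 1, "M")], length=300000)
    p1 = proto("terpene", "terpene", (10000, 12000), (5000, 17000), {"a"})
    p2 = proto("NRPS", "NRPS", (150000, 152000), (145000, 157000), {"b"})
    regions = build_regions([p2, p1], record)  # input order irrelevant
    assert [r.region_number for r in regions] == [1, 2]
    assert regions[0].products == ["terpene"]
    assert regions[1].products == ["NRPS"]


def test_regions_partition_protoclusters():
    record = make_record([("a", 10000, 12000, 1, "M"),
                          ("b", 15000, 17000, 1, "M"),
                          ("c", 200000, 202000, 1, "M")], length=300000)
    protos = [
        proto("terpene", "terpene", (10000, 12000), (5000, 17000), {"a"}),
        proto("NRPS", "NRPS", (15000, 17000), (10000, 22000), {"b"}),
        proto("ectoine", "other", (200000, 202000), (195000, 207000), {"c"}),
    ]
    regions = build_regions(protos, record)
    assigned = [p for r in regions for p in r.protoclusters]
    assert len(assigned) == len(protos)
    assert {id(p) for p in assigned} == {id(p) for p in protos}


# --------------------------------------------------------------------------
# Bundled catalogue


def test_bundled_ruleset_has_71_distinct_types(ruleset):
    assert len(ruleset) == 71
    names = [r.rule_name for r in ruleset]
    assert len(set(names)) == 71


def test_bundled_ruleset_contains_new_type_names(ruleset):
    for name in ["lanthipeptide-class-i", "lanthipeptide-class-ii",
                 "lanthipeptide-class-iii", "lanthipeptide-class-iv",
                 "lanthipeptide-class-v", "lipolanthine", "thioamitides",
                 "ranthipeptide", "redox-cofactor", "epipeptide",
                 "cyclic-lactone-autoinducer", "spliceotide", "thioamide-NRP",
                 "tropodithietic-acid", "prodigiosin", "NAPAA", "pyrrolidine",
                 "RiPP-like", "sactipeptide", "RRE-containing"]:
        assert name in ruleset, name


def test_bacteriocin_replaced_by_ripp_like(ruleset):
    assert "bacteriocin" not in ruleset
    assert "RiPP-like" in ruleset


def test_rre_containing_rule_is_relaxed_tier(ruleset):
    assert ruleset["RRE-containing"].strictness == "relaxed"
    strict_names = {r.rule_name for r in ruleset.at_strictness("strict")}
    assert "RRE-containing" not in strict_names
    relaxed_names = {r.rule_name for r in ruleset.at_strictness("relaxed")}
    assert "RRE-containing" in relaxed_names


def test_strictness_tiers_nest(ruleset):
    strict = {r.rule_name for r in ruleset.at_strictness("strict")}
    relaxed = {r.rule_name for r in ruleset.at_strictness("relaxed")}
    loose = {r.rule_name for r in ruleset.at_strictness("loose")}
    assert strict < relaxed < loose
    assert len(loose) == 71


def test_bundled_rules_reference_known_profiles(ruleset, catalogue):
    ruleset.validate_against(catalogue)
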