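"""Independent oracles and random-case builders shared by the test suite.

These deliberately avoid the code paths they check: core-set enumeration is
exhaustive over subsets, the longest-increasing-subsequence oracle tries
every subsequence, and the test aligner scores identity by simple direct
comparison instead of local alignment.
"""

from __future__ import annotations

import random
from itertools import combinations
from typing import Dict, FrozenSet, List, Sequence, Set, Tuple

from bgcmine.core import CdsFeature, GenomeRecord
from bgcmine.rules import (And, CdsLocal, ConditionNode, DetectionRule,
                           MinimumCount, Or, ProfileRef)

ORACLE_PROFILES = ["pA", "pB", "pC", "pD", "pE", "pF"]


def exhaustive_cores(rule: DetectionRule, hits: Dict[str, Set[str]],
                     record: GenomeRecord) -> Set[FrozenSet[str]]:
    """All maximal CDS subsets satisfying rule condition + distance constraint.

    Candidates are CDSs with a positive-polarity profile hit; every subset of
    them is checked: consecutive members (genomic order) must be within
    cutoff, and the subset must satisfy the condition.  Maximal-by-inclusion
    survivors are the cores.
    """
    positives = rule.condition.profiles(True)
    candidates = [c for c in record.cds_features
                  if hits.get(c.cds_id, set()) & positives]
    cutoff_bp = rule.cutoff_kb * 1000
    satisfying: List[FrozenSet[str]] = []
    for size in range(1, len(candidates) + 1):
        for combo in combinations(candidates, size):
            ok = all(combo[i + 1].start - combo[i].end <= cutoff_bp
                     for i in range(len(combo) - 1))
            if not ok:
                continue
            ids = frozenset(c.cds_id for c in combo)
            if rule.condition.evaluate(ids, hits):
                satisfying.append(ids)
    return {s for s in satisfying
            if not any(s < t for t in satisfying)}


def random_monotone_condition(rng: random.Random, depth: int = 0) -> ConditionNode:
    """Random condition tree without negation (monotone in hits)."""
    choices = ["ref"]
    if depth < 2:
        choices += ["and", "or", "minimum", "cds"]
    kind = rng.choice(choices)
    if kind == "ref":
        return ProfileRef(rng.choice(ORACLE_PROFILES))
    if kind == "and":
        return And(tuple(random_monotone_condition(rng, depth + 1)
                         for _ in range(rng.randint(2, 3))))
    if kind == "or":
        return Or(tuple(random_monotone_condition(rng, depth + 1)
                        for _ in range(rng.randint(2, 3))))
    if kind == "minimum":
        names = rng.sample(ORACLE_PROFILES, rng.randint(2, 4))
        return MinimumCount(rng.randint(1, len(names)), tuple(names))
    return CdsLocal(random_monotone_condition(rng, depth + 1))


def random_rule_case(rng: random.Random
                     ) -> Tuple[DetectionRule, GenomeRecord, Dict[str, Set[str]]]:
    """A random rule plus a random small record with non-overlapping CDSs."""
    rule = DetectionRule(
        rule_name="random", category="other", strictness="strict",
        cutoff_kb=rng.uniform(2.0, 15.0), neighbourhood_kb=5.0,
        condition=random_monotone_condition(rng))
    n_cds = rng.randint(1, 12)
    features = []
    cursor = rng.randint(100, 2000)
    hits: Dict[str, Set[str]] = {}
    for i in range(n_cds):
        length = rng.randint(300, 2400)
        cds_id = f"c{i}"
        features.append(CdsFeature(cds_id, cursor, cursor + length,
                                   rng.choice((1, -1)), "M" * (length // 3)))
        cursor += length + rng.randint(200, 9000)
        if rng.random() < 0.85:
            hits[cds_id] = set(rng.sample(ORACLE_PROFILES,
                                          rng.randint(1, 3)))
    record = GenomeRecord("oracle-case", cursor + 1000, features)
    return rule, record, hits


def brute_force_lis(seq: Sequence[int]) -> int:
    """Longest strictly increasing subsequence by trying every subsequence."""
    best = 0
    for size in range(len(seq), 0, -1):
        for combo in combinations(seq, size):
            if all(a < b for a, b in zip(combo, combo[1:])):
                return size
    return best


class EqualityAligner:
    """Test aligner: position-wise identity of equal-length prefixes.

    identity = 100 * matching positions / longer length; coverage =
    shorter/longer.  Crude, deterministic, and independent of biopython.
    """

    name = "equality"

    def __call__(self, a: str, b: str) -> Tuple[float, float]:
        if not a or not b:
            return 0.0, 0.0
        matches = sum(1 for x, y in zip(a, b) if x == y)
        longer = max(len(a), len(b))
        return 100.0 * matches / longer, min(len(a), len(b)) / longer


def random_sideload_payload(rng: random.Random) -> dict:
    """A random valid sideload document as plain JSON data."""
    records = []
    for r in range(rng.randint(1, 3)):
        subregions = []
        for _ in range(rng.randint(0, 3)):
            start = rng.randrange(0, 50000)
            subregions.append({
                "start": start, "end": start + rng.randint(500, 8000),
                "label": rng.choice(["putative", "cryptic", "ml-hit"]),
                "details": {"score": str(rng.random())[:6]}})
        protoclusters = []
        for _ in range(rng.randint(0, 3)):
            core_start = rng.randrange(1000, 60000)
            core_end = core_start + rng.randint(1000, 9000)
            pad = rng.randint(0, 4000)
            protoclusters.append({
                "core_start": core_start, "core_end": core_end,
                "neighbourhood_start": max(0, core_start - pad),
                "neighbourhood_end": core_end + pad,
                "product": rng.choice(["deepclust", "mlbgc", "other"]),
                "details": {"labels": ["a", "b"]}})
        records.append({"record_id": f"REC{r}", "subregions": subregions,
                        "protoclusters": protoclusters})
    return {"tool": {"name": "exttool", "version": "1.2.3",
                     "description": "external predictor"},
            "records": records}
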