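"""Synthetic-genome fixture generation.

Fixture genomes carry planted clusters whose proteins contain the naive
scanner's signature peptides for exactly the profiles their detection rule
requires, embedded in background sequence drawn from an alphabet that
excludes tryptophan.  Every bundled signature contains a W, so background
genes can never produce a profile hit and the planted truth is exact by
construction: at strict strictness, detection must recover precisely the
planted cores.

All randomness flows from one seeded ``random.Random``; a fixed seed yields
byte-identical output files.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

from .core import CdsFeature, GenomeRecord, ProfileHit
from .genbank import back_translate, write_genbank
from .profiles import (NaiveSignatureScanner, ProfileCatalogue, filter_hits,
                       load_catalogue, write_hit_table)
from .rules import (And, CdsLocal, ConditionNode, DetectionRule, MinimumCount,
                    Not, Or, ProfileRef, RuleCatalogue, bundled_ruleset,
                    detect, evaluate_rule)
from .profiles import hits_by_cds

# Background alphabet: no W, so no bundled signature can occur by chance.
BACKGROUND_ALPHABET = "ACDEFGHIKLMNPQRSTVY"

# Genomic layout defaults (bp).
START_PAD = 2000
END_PAD = 2000
CLUSTER_SPACING = 65000
INTRA_CLUSTER_GAP = 300

# Domain-string token -> profile name for assembly-line fixtures.
DOMAIN_TOKEN_PROFILES = {
    "C": "Condensation", "A": "AMP-binding", "A:gly": "A_gly",
    "A:ser": "A_ser", "A:val": "A_val", "PCP": "PCP", "E": "Epimerization",
    "KS": "PKS_KS", "AT": "PKS_AT", "AT:mal": "AT_mal", "AT:mmal": "AT_mmal",
    "KR": "PKS_KR", "DH": "PKS_DH", "ER": "PKS_ER", "MT": "cMT",
    "ACP": "ACP", "TE": "Thioesterase", "ATd": "Trans_AT_docking",
}


class FixtureSpecError(ValueError):
    """The fixture specification is internally inconsistent."""


@dataclass
class PlantedCluster:
    """One cluster to plant: a rule plus optional explicit gene contents."""

    rule_name: str
    cds_count: Optional[int] = None
    gap_bp: int = INTRA_CLUSTER_GAP
    domain_strings: Optional[List[str]] = None  # e.g. ["KS-AT-ACP", ...]


@dataclass
class FixtureSpec:
    seed: int
    planted_clusters: List[PlantedCluster] = field(default_factory=list)
    decoy_cds_count: int = 20
    record_length: Optional[int] = None
    record_id: str = "FIXTURE1"


@dataclass
class TruthCluster:
    rule_name: str
    core_start: int
    core_end: int
    core_cds_ids: List[str]
    domain_strings: Optional[List[str]]


@dataclass
class Fixture:
    """An in-memory synthetic genome with its planted-cluster truth."""

    record: GenomeRecord
    sequence: str
    hits: List[ProfileHit]
    truth: List[TruthCluster]

    def truth_payload(self) -> dict:
        return {
            "record_id": self.record.record_id,
            "clusters": [
                {"rule_name": t.rule_name, "core_start": t.core_start,
                 "core_end": t.core_end, "core_cds_ids": t.core_cds_ids,
                 "domain_strings": t.domain_strings}
                for t in self.truth],
        }


# --------------------------------------------------------------------------
# Satisfying assignments


def satisfying_assignment(condition: ConditionNode) -> List[Set[str]]:
    """A canonical list of per-CDS profile sets satisfying a condition.

    Negated branches contribute nothing (their profiles are simply not
    planted); ``or`` takes its first satisfiable child; ``minimum(n, L)``
    spreads the first n profiles over n genes; ``cds(...)`` collapses its
    subtree onto a single gene.
    """
    if isinstance(condition, ProfileRef):
        return [{condition.name}]
    if isinstance(condition, Not):
        return []
    if isinstance(condition, And):
        out: List[Set[str]] = []
        for child in condition.children:
            out.extend(satisfying_assignment(child))
        return out
    if isinstance(condition, Or):
        for child in condition.children:
            sub = satisfying_assignment(child)
            if sub:
                return sub
        return []
    if isinstance(condition, MinimumCount):
        return [{name} for name in condition.names[:condition.n]]
    if isinstance(condition, CdsLocal):
        merged: Set[str] = set()
        for group in satisfying_assignment(condition.child):
            merged |= group
        return [merged] if merged else []
    raise TypeError(f"unknown condition node {type(condition).__name__}")


def _cluster_profile_sets(rule: DetectionRule,
                          planted: PlantedCluster) -> List[List[str]]:
    """Ordered per-CDS profile lists for one planted cluster."""
    if planted.domain_strings is not None:
        sets = []
        for dstring in planted.domain_strings:
            profiles = []
            for token in dstring.split("-"):
                if token not in DOMAIN_TOKEN_PROFILES:
                    raise FixtureSpecError(f"unknown domain token {token!r}")
                profiles.append(DOMAIN_TOKEN_PROFILES[token])
            sets.append(profiles)
    else:
        base = satisfying_assignment(rule.condition)
        if not base:
            raise FixtureSpecError(
                f"rule {rule.rule_name} has no plantable satisfying assignment")
        count = planted.cds_count or len(base)
        if count < len(base):
            raise FixtureSpecError(
                f"rule {rule.rule_name} needs >= {len(base)} CDSs, got {count}")
        sets = [sorted(group) for group in base]
        for i in range(count - len(base)):
            sets.append(sorted(base[i % len(base)]))
    # defensive: the union must satisfy the condition
    hits = {f"cds{i}": set(profs) for i, profs in enumerate(sets)}
    if not rule.condition.evaluate(frozenset(hits), hits):
        raise FixtureSpecError(
            f"planted contents do not satisfy rule {rule.rule_name}")
    return sets


def _planted_protein(profiles: Sequence[str], catalogue: ProfileCatalogue,
                     rng: random.Random) -> str:
    parts = ["".join(rng.choices(BACKGROUND_ALPHABET, k=rng.randint(15, 30)))]
    for profile in profiles:
        signature = catalogue[profile].signature
        if not signature:
            raise FixtureSpecError(f"profile {profile} has no signature")
        parts.append(signature)
        parts.append("".join(rng.choices(BACKGROUND_ALPHABET,
                                         k=rng.randint(10, 20))))
    return "".join(parts)


def make_fixture(spec: FixtureSpec,
                 ruleset: Optional[RuleCatalogue] = None,
                 catalogue: Optional[ProfileCatalogue] = None) -> Fixture:
    """Build the synthetic genome described by a FixtureSpec."""
    if ruleset is None:
        ruleset = bundled_ruleset()
    if catalogue is None:
        catalogue = load_catalogue()
    rng = random.Random(spec.seed)
    cds_features: List[CdsFeature] = []
    truth: List[TruthCluster] = []
    cursor = START_PAD
    cds_serial = 0
    n_groups = len(spec.planted_clusters) + 1
    decoys_per_group = [spec.decoy_cds_count // n_groups] * n_groups
    for i in range(spec.decoy_cds_count % n_groups):
        decoys_per_group[i] += 1

    def place(translation: str, tag: str) -> CdsFeature:
        nonlocal cursor, cds_serial
        cds_serial += 1
        span = 3 * (len(translation) + 1)
        cds = CdsFeature(f"{tag}{cds_serial}", cursor, cursor + span,
                         rng.choice((1, -1)) if tag == "decoy" else 1,
                         translation)
        cds_features.append(cds)
        cursor += span
        return cds

    def place_decoys(count: int) -> None:
        nonlocal cursor
        for _ in range(count):
            length = rng.randint(150, 400)
            translation = "".join(rng.choices(BACKGROUND_ALPHABET, k=length))
            place(translation, "decoy")
            cursor += rng.randint(300, 1500)

    for group_index, planted in enumerate(spec.planted_clusters):
        place_decoys(decoys_per_group[group_index])
        rule = ruleset[planted.rule_name]
        profile_sets = _cluster_profile_sets(rule, planted)
        members: List[CdsFeature] = []
        for profiles in profile_sets:
            cds = place(_planted_protein(profiles, catalogue, rng), "core")
            members.append(cds)
            cursor += planted.gap_bp
        truth.append(TruthCluster(
            planted.rule_name,
            min(m.start for m in members), max(m.end for m in members),
            [m.cds_id for m in members], planted.domain_strings))
        cursor += CLUSTER_SPACING
    place_decoys(decoys_per_group[-1])
    cursor += END_PAD

    length = spec.record_length or cursor
    if length < cursor:
        raise FixtureSpecError(
            f"record_length {length} too small for layout needing {cursor} bp")
    record = GenomeRecord(spec.record_id, length, cds_features)

    sequence = bytearray(b"A" * length)
    for cds in record.cds_features:
        nt = back_translate(cds.translation)
        sequence[cds.start:cds.start + len(nt)] = nt.encode()

    scanner = NaiveSignatureScanner()
    proteins = {c.cds_id: c.translation for c in record.cds_features}
    # keep duplicate per-profile hits: module assembly needs repeated domains
    hits = filter_hits(scanner(proteins, catalogue), catalogue,
                       best_per_profile=False)
    return Fixture(record, sequence.decode(), hits, truth)


def write_fixture(fixture: Fixture, outdir,
                  stem: Optional[str] = None) -> Dict[str, Path]:
    """Write the GenBank, hit-table and truth files for a fixture."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stem = stem or fixture.record.record_id.lower()
    paths = {
        "genbank": outdir / f"{stem}.gbk",
        "hit_table": outdir / f"{stem}.hits.tsv",
        "truth": outdir / f"{stem}.truth.json",
    }
    write_genbank(fixture.record, fixture.sequence, paths["genbank"])
    write_hit_table(fixture.hits, paths["hit_table"])
    with open(paths["truth"], "w") as fh:
        json.dump(fixture.truth_payload(), fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths


# --------------------------------------------------------------------------
# Plantable-rule discovery and random specs

_PLANTABLE_CACHE: Dict[int, List[str]] = {}


def plantable_rules(ruleset: Optional[RuleCatalogue] = None,
                    catalogue: Optional[ProfileCatalogue] = None,
                    strictness: str = "strict") -> List[str]:
    """Rules whose canonical planting is recovered cleanly at the given tier.

    A rule is plantable when detection on a genome containing only its
    canonical planted cluster yields exactly one protocluster, for that
    rule, whose core is exactly the planted CDS set.  Rules sharing
    trigger profiles with a broader rule are excluded automatically.
    """
    if ruleset is None:
        ruleset = bundled_ruleset()
    if catalogue is None:
        catalogue = load_catalogue()
    cache_key = id(ruleset)
    if cache_key in _PLANTABLE_CACHE:
        return _PLANTABLE_CACHE[cache_key]
    admitted = ruleset.at_strictness(strictness)
    names = []
    for rule in admitted:
        try:
            fixture = make_fixture(
                FixtureSpec(seed=0, planted_clusters=[PlantedCluster(rule.rule_name)],
                            decoy_cds_count=0),
                ruleset, catalogue)
        except FixtureSpecError:
            continue
        regions = detect(fixture.record, fixture.hits, admitted, strictness)
        protos = [p for r in regions for p in r.protoclusters]
        if (len(protos) == 1 and protos[0].rule_name == rule.rule_name
                and set(protos[0].core_cds_ids) == set(fixture.truth[0].core_cds_ids)):
            names.append(rule.rule_name)
    _PLANTABLE_CACHE[cache_key] = names
    return names


def random_fixture_spec(seed: int,
                        ruleset: Optional[RuleCatalogue] = None,
                        catalogue: Optional[ProfileCatalogue] = None,
                        max_clusters: int = 3) -> FixtureSpec:
    """A random FixtureSpec drawing from cleanly plantable strict rules."""
    rng = random.Random(seed)
    names = plantable_rules(ruleset, catalogue)
    n_clusters = rng.randint(1, max_clusters)
    planted = [PlantedCluster(rng.choice(names),
                              gap_bp=rng.randint(100, 900))
               for _ in range(n_clusters)]
    return FixtureSpec(seed=rng.randrange(2 ** 31), planted_clusters=planted,
                       decoy_cds_count=rng.randint(5, 30),
                       record_id=f"FIX{seed}")
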