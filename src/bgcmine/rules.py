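"""Detection-rule DSL, rule evaluation, and protocluster/region building.

Cluster detection is rule-based: each cluster type is defined by a condition
over profile hits that must be met by a group of nearby genes.  A rule also
carries two distances, both in kb: ``cutoff`` (the maximum gap between
consecutive core genes jointly satisfying the condition) and
``neighbourhood`` (the extension added around the core).

Rule text grammar (one or more blocks per file, '#' comments)::

    RULE <name>
    CATEGORY <category>
    STRICTNESS strict|relaxed|loose
    CUTOFF <kb>
    NEIGHBOURHOOD <kb>
    CONDITIONS <expr>

    expr    := or_expr
    or_expr := and_expr ('or' and_expr)*
    and_expr:= unary ('and' unary)*
    unary   := 'not' unary | 'cds' '(' expr ')'
             | 'minimum' '(' int ',' '[' name (',' name)* ']' ')'
             | name | '(' expr ')'

'not' binds tightest, then 'and', then 'or'.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

from .core import (CandidateCluster, GenomeRecord, Protocluster, Region,
                   clip_interval, overlaps)
from .profiles import ProfileCatalogue, hits_by_cds

STRICTNESS_ORDER = {"strict": 0, "relaxed": 1, "loose": 2}

# Assembly-line product families whose overlapping cores form one
# chemical-hybrid candidate (a single mixed assembly line).
HYBRID_COMPATIBLE = frozenset(
    {"t1pks", "transAT-PKS", "transAT-PKS-like", "PKS-like", "NRPS", "NRPS-like"})


class RuleSyntaxError(ValueError):
    """Rule text failed to parse; message includes the offending position."""


class RuleConfigurationError(ValueError):
    """A rule references a profile absent from the catalogue, or names clash."""


# --------------------------------------------------------------------------
# Condition tree


class ConditionNode:
    """Base class for condition-tree nodes.

    ``evaluate(cds_set, hits)`` asks whether the condition holds for the
    given CDS-id set, where ``hits`` maps cds_id -> set of profile names hit.
    """

    def evaluate(self, cds_set: FrozenSet[str], hits: Dict[str, Set[str]]) -> bool:
        raise NotImplementedError

    def profiles(self, polarity: bool = True) -> Set[str]:
        """Profile names referenced at the given polarity (True = positive)."""
        raise NotImplementedError


@dataclass(frozen=True)
class ProfileRef(ConditionNode):
    name: str

    def evaluate(self, cds_set, hits):
        return any(self.name in hits.get(c, ()) for c in cds_set)

    def profiles(self, polarity=True):
        return {self.name} if polarity else set()


@dataclass(frozen=True)
class And(ConditionNode):
    children: tuple

    def evaluate(self, cds_set, hits):
        return all(ch.evaluate(cds_set, hits) for ch in self.children)

    def profiles(self, polarity=True):
        out = set()
        for ch in self.children:
            out |= ch.profiles(polarity)
        return out


@dataclass(frozen=True)
class Or(ConditionNode):
    children: tuple

    def evaluate(self, cds_set, hits):
        return any(ch.evaluate(cds_set, hits) for ch in self.children)

    def profiles(self, polarity=True):
        out = set()
        for ch in self.children:
            out |= ch.profiles(polarity)
        return out


@dataclass(frozen=True)
class Not(ConditionNode):
    child: ConditionNode

    def evaluate(self, cds_set, hits):
        return not self.child.evaluate(cds_set, hits)

    def profiles(self, polarity=True):
        return self.child.profiles(not polarity)


@dataclass(frozen=True)
class MinimumCount(ConditionNode):
    """At least ``n`` distinct profiles from ``names`` hit within the set."""

    n: int
    names: tuple

    def __post_init__(self):
        if self.n < 1:
            raise RuleSyntaxError("minimum(): n must be >= 1")
        if self.n > len(self.names):
            raise RuleSyntaxError("minimum(): n exceeds list length")

    def evaluate(self, cds_set, hits):
        present = set()
        for c in cds_set:
            present |= hits.get(c, set()) & set(self.names)
        return len(present) >= self.n

    def profiles(self, polarity=True):
        return set(self.names) if polarity else set()


@dataclass(frozen=True)
class CdsLocal(ConditionNode):
    """The subtree must be satisfied by a single CDS on its own."""

    child: ConditionNode

    def evaluate(self, cds_set, hits):
        return any(self.child.evaluate(frozenset({c}), hits) for c in cds_set)

    def profiles(self, polarity=True):
        return self.child.profiles(polarity)


@dataclass(frozen=True)
class DetectionRule:
    rule_name: str
    category: str
    strictness: str
    cutoff_kb: float
    neighbourhood_kb: float
    condition: ConditionNode

    def __post_init__(self):
        if self.cutoff_kb <= 0:
            raise RuleConfigurationError(f"{self.rule_name}: cutoff must be > 0")
        if self.neighbourhood_kb < 0:
            raise RuleConfigurationError(f"{self.rule_name}: neighbourhood must be >= 0")
        if self.strictness not in STRICTNESS_ORDER:
            raise RuleConfigurationError(
                f"{self.rule_name}: unknown strictness {self.strictness!r}")


# --------------------------------------------------------------------------
# Parser

_TOKEN_RE = re.compile(r"\s*(\(|\)|\[|\]|,|[A-Za-z0-9_.+-]+)")
_KEYWORDS = ("RULE", "CATEGORY", "STRICTNESS", "CUTOFF", "NEIGHBOURHOOD", "CONDITIONS")


def _strip_comments(text: str) -> str:
    return "\n".join(line.split("#", 1)[0] for line in text.splitlines())


class _ExprParser:
    def __init__(self, tokens: List[str], offset_info: str = ""):
        self.tokens = tokens
        self.pos = 0
        self.info = offset_info

    def peek(self) -> Optional[str]:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def take(self) -> str:
        tok = self.peek()
        if tok is None:
            raise RuleSyntaxError(f"unexpected end of condition {self.info}")
        self.pos += 1
        return tok

    def expect(self, tok: str) -> None:
        got = self.take()
        if got != tok:
            raise RuleSyntaxError(
                f"expected {tok!r}, got {got!r} at token {self.pos} {self.info}")

    def parse(self) -> ConditionNode:
        node = self.or_expr()
        if self.peek() is not None:
            raise RuleSyntaxError(
                f"trailing tokens from {self.peek()!r} at token {self.pos} {self.info}")
        return node

    def or_expr(self) -> ConditionNode:
        parts = [self.and_expr()]
        while self.peek() == "or":
            self.take()
            parts.append(self.and_expr())
        return parts[0] if len(parts) == 1 else Or(tuple(parts))

    def and_expr(self) -> ConditionNode:
        parts = [self.unary()]
        while self.peek() == "and":
            self.take()
            parts.append(self.unary())
        return parts[0] if len(parts) == 1 else And(tuple(parts))

    def unary(self) -> ConditionNode:
        tok = self.take()
        if tok == "not":
            return Not(self.unary())
        if tok == "cds":
            self.expect("(")
            inner = self.or_expr()
            self.expect(")")
            return CdsLocal(inner)
        if tok == "minimum":
            self.expect("(")
            n_tok = self.take()
            try:
                n = int(n_tok)
            except ValueError:
                raise RuleSyntaxError(f"minimum(): expected integer, got {n_tok!r}") from None
            self.expect(",")
            self.expect("[")
            names = [self.take()]
            while self.peek() == ",":
                self.take()
                names.append(self.take())
            self.expect("]")
            self.expect(")")
            return MinimumCount(n, tuple(names))
        if tok == "(":
            inner = self.or_expr()
            self.expect(")")
            return inner
        if tok in (")", "]", ","):
            raise RuleSyntaxError(f"unexpected {tok!r} at token {self.pos} {self.info}")
        return ProfileRef(tok)


def parse_condition(text: str, info: str = "") -> ConditionNode:
    tokens = _TOKEN_RE.findall(text)
    if not tokens:
        raise RuleSyntaxError(f"empty condition {info}")
    return _ExprParser(tokens, info).parse()


def parse_rule(text: str) -> DetectionRule:
    """Parse a single RULE block."""
    rules = parse_rules(text)
    if len(rules) != 1:
        raise RuleSyntaxError(f"expected exactly one RULE block, found {len(rules)}")
    return rules[0]


def parse_rules(text: str) -> List[DetectionRule]:
    """Parse one or more RULE blocks from rule-catalogue text."""
    if not text.strip():
        raise RuleSyntaxError("empty rule text")
    body = _strip_comments(text)
    blocks = re.split(r"(?=\bRULE\b)", body)
    rules: List[DetectionRule] = []
    for block in blocks:
        if not block.strip():
            continue
        fields: Dict[str, str] = {}
        # key lines may wrap; CONDITIONS consumes to the end of the block
        m = re.match(
            r"\s*RULE\s+(?P<name>\S+)\s+"
            r"CATEGORY\s+(?P<cat>\S+)\s+"
            r"STRICTNESS\s+(?P<strict>\S+)\s+"
            r"CUTOFF\s+(?P<cutoff>\S+)\s+"
            r"NEIGHBOURHOOD\s+(?P<neigh>\S+)\s+"
            r"CONDITIONS\s+(?P<cond>.+)$",
            block.strip(), re.DOTALL)
        if m is None:
            raise RuleSyntaxError(
                f"malformed RULE block starting {block.strip()[:40]!r}")
        name = m.group("name")
        try:
            cutoff = float(m.group("cutoff"))
            neigh = float(m.group("neigh"))
        except ValueError:
            raise RuleSyntaxError(f"rule {name}: CUTOFF/NEIGHBOURHOOD must be numeric") from None
        condition = parse_condition(m.group("cond"), info=f"(rule {name})")
        rules.append(DetectionRule(name, m.group("cat"), m.group("strict"),
                                   cutoff, neigh, condition))
    names = [r.rule_name for r in rules]
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise RuleConfigurationError(f"duplicate rule names: {sorted(dupes)}")
    return rules


class RuleCatalogue:
    """An ordered, name-unique collection of detection rules."""

    def __init__(self, rules: Iterable[DetectionRule]):
        self.rules = list(rules)
        names = [r.rule_name for r in self.rules]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise RuleConfigurationError(f"duplicate rule names: {sorted(dupes)}")
        self._by_name = {r.rule_name: r for r in self.rules}

    def __len__(self):
        return len(self.rules)

    def __iter__(self):
        return iter(self.rules)

    def __contains__(self, name):
        return name in self._by_name

    def __getitem__(self, name) -> DetectionRule:
        return self._by_name[name]

    def at_strictness(self, strictness: str) -> "RuleCatalogue":
        """Rules admitted at the given strictness (strict < relaxed < loose)."""
        level = STRICTNESS_ORDER[strictness]
        return RuleCatalogue(
            [r for r in self.rules if STRICTNESS_ORDER[r.strictness] <= level])

    def validate_against(self, catalogue: ProfileCatalogue) -> None:
        """Fail at load time if any rule references an unknown profile."""
        for r in self.rules:
            unknown = ((r.condition.profiles(True) | r.condition.profiles(False))
                       - set(catalogue.names()))
            if unknown:
                raise RuleConfigurationError(
                    f"rule {r.rule_name} references unknown profiles: {sorted(unknown)}")


def bundled_ruleset() -> RuleCatalogue:
    """Load the bundled 71-type rule catalogue."""
    text = resources.files("bgcmine.data").joinpath("rules/bundled.rules").read_text()
    return RuleCatalogue(parse_rules(text))


# --------------------------------------------------------------------------
# Evaluation


def _positive_profiles(rule: DetectionRule) -> Set[str]:
    return rule.condition.profiles(True)


def evaluate_rule(rule: DetectionRule,
                  hits_by_cds_map: Dict[str, list],
                  record: GenomeRecord) -> List[FrozenSet[str]]:
    """Return the core CDS-id sets satisfying a rule on one record.

    Candidate CDSs are those hit by any profile the condition references at
    positive polarity.  Candidates are chained along the genome: consecutive
    candidates more than ``cutoff_kb`` apart (gap measured from the end of
    one CDS to the start of the next) break the chain.  Each maximal chain
    whose CDS set satisfies the condition is returned as one core set; the
    returned sets are disjoint by construction.  For monotone conditions
    (no ``not``) this is equivalent to taking the maximal satisfying CDS
    subsets under the same distance constraint.
    """
    profile_sets: Dict[str, Set[str]] = {
        cds_id: {h.profile_name for h in hs}
        for cds_id, hs in hits_by_cds_map.items()
    }
    positives = _positive_profiles(rule)
    candidates = [c for c in record.cds_features
                  if profile_sets.get(c.cds_id, set()) & positives]
    cutoff_bp = rule.cutoff_kb * 1000
    chains: List[List[str]] = []
    for cds in candidates:
        if chains:
            prev = record.get_cds(chains[-1][-1])
            if cds.start - prev.end <= cutoff_bp:
                chains[-1].append(cds.cds_id)
                continue
        chains.append([cds.cds_id])
    cores = []
    for chain in chains:
        cds_set = frozenset(chain)
        if rule.condition.evaluate(cds_set, profile_sets):
            cores.append(cds_set)
    return cores


def form_protoclusters(rule: DetectionRule, core_sets: Sequence[FrozenSet[str]],
                       record: GenomeRecord) -> List[Protocluster]:
    """Turn core CDS sets into protoclusters with neighbourhood extensions."""
    clusters = []
    for core in core_sets:
        members = [record.get_cds(c) for c in core]
        core_start = min(m.start for m in members)
        core_end = max(m.end for m in members)
        ext = int(round(rule.neighbourhood_kb * 1000))
        n_start, n_end = clip_interval(core_start - ext, core_end + ext,
                                       record.sequence_length)
        clusters.append(Protocluster(
            product=rule.rule_name, category=rule.category,
            core_start=core_start, core_end=core_end,
            neighbourhood_start=n_start, neighbourhood_end=n_end,
            core_cds_ids=frozenset(core), rule_name=rule.rule_name))
    clusters.sort(key=lambda p: (p.core_start, p.core_end, p.product))
    return clusters


def _cores_touch(a: Protocluster, b: Protocluster) -> bool:
    return overlaps(a.core, b.core) or bool(a.core_cds_ids & b.core_cds_ids)


def _components(n: int, edge) -> List[List[int]]:
    """Connected components of an implicit graph on range(n) (union-find)."""
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if edge(i, j):
                parent[find(i)] = find(j)
    groups: Dict[int, List[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return sorted(groups.values(), key=lambda g: min(g))


def _candidates_for(members: List[Protocluster]) -> List[CandidateCluster]:
    """Assign candidate-cluster groupings inside one region."""
    def envelope(ps):
        return (min(p.neighbourhood_start for p in ps),
                max(p.neighbourhood_end for p in ps))

    if len(members) == 1:
        s, e = envelope(members)
        return [CandidateCluster("single", list(members), s, e)]
    out: List[CandidateCluster] = []
    covered: Set[int] = set()
    # chemical hybrids: overlapping/shared cores of assembly-line products
    hybrid_groups = _components(
        len(members),
        lambda i, j: (_cores_touch(members[i], members[j])
                      and members[i].product in HYBRID_COMPATIBLE
                      and members[j].product in HYBRID_COMPATIBLE))
    for grp in hybrid_groups:
        if len(grp) > 1:
            ps = [members[i] for i in grp]
            s, e = envelope(ps)
            out.append(CandidateCluster("chemical-hybrid", ps, s, e))
            covered.update(grp)
    # interleaved: remaining core overlaps
    inter_groups = _components(
        len(members), lambda i, j: _cores_touch(members[i], members[j]))
    for grp in inter_groups:
        if len(grp) > 1 and not set(grp) <= covered:
            ps = [members[i] for i in grp]
            s, e = envelope(ps)
            out.append(CandidateCluster("interleaved", ps, s, e))
            covered.update(grp)
    # whatever remains shares only neighbourhood overlap with the region
    rest = [members[i] for i in range(len(members)) if i not in covered]
    if rest:
        if len(members) > 1:
            s, e = envelope(members)
            out.append(CandidateCluster("neighbouring", list(members), s, e))
        else:
            s, e = envelope(rest)
            out.append(CandidateCluster("single", rest, s, e))
    out.sort(key=lambda c: (c.start, c.end, c.kind))
    return out


def build_regions(protoclusters: Sequence[Protocluster],
                  record: GenomeRecord,
                  subregions: Sequence = ()) -> List[Region]:
    """Group protoclusters whose neighbourhoods overlap into regions.

    Sideloaded subregions become their own regions when they overlap no
    protocluster-derived region, and are attached to the overlapping region
    otherwise.  Regions are numbered left to right from 1.
    """
    protos = sorted(protoclusters,
                    key=lambda p: (p.neighbourhood_start, p.neighbourhood_end,
                                   p.product, p.rule_name))
    subs = sorted(subregions, key=lambda s: (s.start, s.end, s.label, s.tool))
    # transitive closure over all intervals (protocluster neighbourhoods and
    # subregions together), so grouping is order-independent and idempotent
    intervals = [p.neighbourhood for p in protos] + [(s.start, s.end)
                                                     for s in subs]
    groups = _components(
        len(intervals), lambda i, j: overlaps(intervals[i], intervals[j]))
    drafts = []
    for grp in groups:
        members = [protos[i] for i in grp if i < len(protos)]
        grp_subs = [subs[i - len(protos)] for i in grp if i >= len(protos)]
        start = min(intervals[i][0] for i in grp)
        end = max(intervals[i][1] for i in grp)
        drafts.append((start, end, members, grp_subs))
    drafts.sort(key=lambda d: (d[0], d[1]))
    regions = []
    for i, (start, end, members, grp_subs) in enumerate(drafts, 1):
        regions.append(Region(
            region_number=i, start=start, end=end,
            protoclusters=sorted(members, key=lambda p: (p.core_start, p.core_end,
                                                         p.product)),
            candidates=_candidates_for(members) if members else [],
            subregions=grp_subs))
    return regions


def detect(record: GenomeRecord, hits: Sequence, ruleset: RuleCatalogue,
           strictness: str = "relaxed") -> List[Region]:
    """Run all admitted rules over filtered hits and build regions."""
    grouped = hits_by_cds(hits)
    protoclusters: List[Protocluster] = []
    for rule in ruleset.at_strictness(strictness):
        cores = evaluate_rule(rule, grouped, record)
        protoclusters.extend(form_protoclusters(rule, cores, record))
    return build_regions(protoclusters, record)
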