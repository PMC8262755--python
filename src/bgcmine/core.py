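"""Core data model shared by every stage of the mining pipeline.

All genomic coordinates are 0-based half-open internally.  Conversion to the
1-based inclusive convention of GenBank happens only at the I/O boundary
(:mod:`bgcmine.genbank`), so interval arithmetic in the rest of the package is
free of off-by-one adjustments.

Circular records are treated as linear for detection purposes: windows never
wrap the origin.  This is a documented limitation, not an oversight.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Tuple

FUNCTIONAL_CLASSES = (
    "biosynthetic-core",
    "biosynthetic-additional",
    "transport",
    "regulatory",
    "other",
)

# Protocluster categories used for grouping and RiPP-specific analyses.
CATEGORIES = ("PKS", "NRPS", "RiPP", "terpene", "saccharide", "other")


class InvalidArgumentError(ValueError):
    """An operation was called with arguments violating its preconditions."""


def clip_interval(start: int, end: int, record_length: int) -> Tuple[int, int]:
    """Clamp a half-open interval to ``[0, record_length)``.

    Parameters
    ----------
    start, end:
        Interval bounds in bp; ``start <= end`` is required.  Bounds may lie
        outside the record (e.g. a neighbourhood extension past the origin).
    record_length:
        Length of the record in bp; must be non-negative.
    """
    if record_length < 0:
        raise InvalidArgumentError(f"negative record_length: {record_length}")
    if start > end:
        raise InvalidArgumentError(f"start {start} > end {end}")
    return max(0, start), min(end, record_length)


def overlaps(a: Tuple[int, int], b: Tuple[int, int]) -> bool:
    """True iff two half-open intervals intersect (adjacency is not overlap)."""
    return a[0] < b[1] and b[0] < a[1]


@dataclass(frozen=True)
class CdsFeature:
    """A protein-coding feature on a genome record.

    ``functional_class`` starts as ``"other"`` and is upgraded during
    detection when the gene product matches a detection profile or a rule
    core.
    """

    cds_id: str
    start: int
    end: int
    strand: int
    translation: str
    functional_class: str = "other"

    def __post_init__(self) -> None:
        if not self.cds_id:
            raise ValueError("cds_id must be non-empty")
        if self.start >= self.end:
            raise ValueError(f"{self.cds_id}: start {self.start} >= end {self.end}")
        if self.strand not in (1, -1):
            raise ValueError(f"{self.cds_id}: strand must be +1 or -1")
        if len(self.translation) < 1:
            raise ValueError(f"{self.cds_id}: empty translation")
        if self.functional_class not in FUNCTIONAL_CLASSES:
            raise ValueError(f"{self.cds_id}: unknown functional_class {self.functional_class!r}")

    @property
    def interval(self) -> Tuple[int, int]:
        return (self.start, self.end)

    def with_functional_class(self, functional_class: str) -> "CdsFeature":
        return CdsFeature(self.cds_id, self.start, self.end, self.strand,
                          self.translation, functional_class)


@dataclass
class GenomeRecord:
    """An annotated nucleotide record: an ordered list of CDS features.

    Only CDS-level information is modelled; full GenBank feature-table
    fidelity is a non-goal.
    """

    record_id: str
    sequence_length: int
    cds_features: list = field(default_factory=list)
    circular: bool = False

    def __post_init__(self) -> None:
        if not self.record_id:
            raise ValueError("record_id must be non-empty")
        if self.sequence_length < 0:
            raise ValueError("sequence_length must be >= 0")
        self.cds_features = sorted(self.cds_features, key=lambda c: (c.start, c.end, c.cds_id))
        seen = set()
        for cds in self.cds_features:
            if cds.cds_id in seen:
                raise ValueError(f"duplicate cds_id {cds.cds_id!r} in record {self.record_id}")
            seen.add(cds.cds_id)
            if cds.start < 0 or cds.end > self.sequence_length:
                raise ValueError(
                    f"{cds.cds_id}: interval {cds.interval} outside record "
                    f"[0, {self.sequence_length})"
                )

    def get_cds(self, cds_id: str) -> CdsFeature:
        for cds in self.cds_features:
            if cds.cds_id == cds_id:
                return cds
        raise KeyError(cds_id)

    def cds_in(self, start: int, end: int) -> list:
        """CDS features overlapping the half-open interval [start, end)."""
        return [c for c in self.cds_features if overlaps(c.interval, (start, end))]

    def cds_index(self, cds_id: str) -> int:
        for i, cds in enumerate(self.cds_features):
            if cds.cds_id == cds_id:
                return i
        raise KeyError(cds_id)


@dataclass(frozen=True)
class ProfileHit:
    """One profile-HMM match on one protein.

    Protein coordinates are 0-based half-open amino-acid positions.
    """

    cds_id: str
    profile_name: str
    bitscore: float
    evalue: float
    protein_start: int
    protein_end: int

    def __post_init__(self) -> None:
        if self.protein_start >= self.protein_end:
            raise ValueError(
                f"hit {self.profile_name} on {self.cds_id}: "
                f"protein_start {self.protein_start} >= protein_end {self.protein_end}"
            )
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")
        if not (self.bitscore == self.bitscore and abs(self.bitscore) != float("inf")):
            raise ValueError("bitscore must be finite")


@dataclass
class Protocluster:
    """A single detection rule's core CDS set plus its neighbourhood extension."""

    product: str
    category: str
    core_start: int
    core_end: int
    neighbourhood_start: int
    neighbourhood_end: int
    core_cds_ids: frozenset
    rule_name: str
    tool: str = "bgcmine"

    def __post_init__(self) -> None:
        if not (self.neighbourhood_start <= self.core_start < self.core_end
                <= self.neighbourhood_end):
            raise ValueError(
                f"protocluster {self.product}: bounds must nest "
                f"({self.neighbourhood_start}, {self.core_start}, "
                f"{self.core_end}, {self.neighbourhood_end})"
            )
        if not self.core_cds_ids:
            raise ValueError(f"protocluster {self.product}: core_cds_ids empty")
        self.core_cds_ids = frozenset(self.core_cds_ids)

    @property
    def core(self) -> Tuple[int, int]:
        return (self.core_start, self.core_end)

    @property
    def neighbourhood(self) -> Tuple[int, int]:
        return (self.neighbourhood_start, self.neighbourhood_end)


@dataclass
class SubRegion:
    """A sideloaded area of interest that is not a rule-detected protocluster."""

    start: int
    end: int
    label: str
    tool: str
    details: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"subregion {self.label}: start >= end")


@dataclass
class CandidateCluster:
    """A grouping of protoclusters inside a region.

    Kinds: ``chemical-hybrid`` (overlapping cores of assembly-line-compatible
    products), ``interleaved`` (overlapping cores otherwise), ``neighbouring``
    (only neighbourhoods overlap), ``single``.
    """

    kind: str
    protoclusters: list
    start: int
    end: int

    KINDS = ("single", "interleaved", "neighbouring", "chemical-hybrid")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown candidate kind {self.kind!r}")
        if not self.protoclusters:
            raise ValueError("candidate cluster needs >= 1 member")
        for p in self.protoclusters:
            if not (self.start <= p.neighbourhood_start and p.neighbourhood_end <= self.end):
                raise ValueError("candidate envelope must cover all members")


@dataclass
class Region:
    """The envelope of transitively-overlapping protocluster neighbourhoods.

    Regions are the unit of downstream analysis; every protocluster of a
    record belongs to exactly one region.
    """

    region_number: int
    start: int
    end: int
    protoclusters: list = field(default_factory=list)
    candidates: list = field(default_factory=list)
    subregions: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.region_number < 1:
            raise ValueError("region_number must be >= 1")
        if self.start >= self.end:
            raise ValueError("region start >= end")

    @property
    def interval(self) -> Tuple[int, int]:
        return (self.start, self.end)

    @property
    def products(self) -> list:
        return sorted({p.product for p in self.protoclusters})
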