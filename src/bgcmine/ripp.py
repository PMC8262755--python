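"""RiPP precursor-candidate flagging and RRE domain annotation.

RiPP biosynthesis starts from a short ribosomally made precursor peptide;
tailoring enzymes that modify it often carry a RiPP recognition element
(RRE) domain that binds the precursor's leader.  Annotating RRE hits makes
it possible to tell genuine tailoring enzymes from bystander genes matching
generic profiles, and an RRE hit outside any known RiPP cluster is itself
weak evidence of a novel RiPP cluster (the relaxed-tier "RRE-containing"
detection rule fires on exactly these profiles).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set

from .core import GenomeRecord, ProfileHit, Protocluster, overlaps
from .profiles import ProfileCatalogue

# A precursor candidate must be at most this many amino acids long.
MAX_PRECURSOR_AA = 120
# "near-core" means within this many CDS positions of a core gene.
NEAR_CORE_WINDOW = 10

# Cleavage-motif table for leader/core split prediction: motif -> offset of
# the core start relative to the motif start.  Deliberately tiny; a missing
# match leaves the split position unknown.
CLEAVAGE_MOTIFS = {"GG": 2, "GA": 2}


@dataclass(frozen=True)
class PrecursorCandidate:
    cds_id: str
    length: int
    split_position: Optional[int]  # aa index of the core start, or None
    flags: frozenset  # subset of {"short-orf", "near-core"}

    def __post_init__(self):
        if self.length > MAX_PRECURSOR_AA:
            raise ValueError("precursor candidate longer than the ceiling")
        if self.split_position is not None and not (0 < self.split_position < self.length):
            raise ValueError("split position outside the peptide")


@dataclass(frozen=True)
class RREHit:
    cds_id: str
    profile_name: str
    bitscore: float
    within_ripp_protocluster: bool


def _predict_split(translation: str) -> Optional[int]:
    """Last cleavage-motif match in the leader half; None when absent."""
    best = None
    for motif, offset in CLEAVAGE_MOTIFS.items():
        pos = translation.rfind(motif, 0, max(len(translation) // 2, 2))
        if pos != -1:
            split = pos + offset
            if 0 < split < len(translation) and (best is None or split > best):
                best = split
    return best


def find_precursor_candidates(record: GenomeRecord,
                              protocluster: Protocluster
                              ) -> List[PrecursorCandidate]:
    """Flag short ORFs in a RiPP protocluster neighbourhood as precursors.

    CDSs of at most MAX_PRECURSOR_AA amino acids get the ``short-orf`` flag;
    those within NEAR_CORE_WINDOW CDS positions of a core gene additionally
    get ``near-core``.
    """
    if protocluster.category != "RiPP":
        raise ValueError("precursor search requires a RiPP-category protocluster")
    core_indices = [record.cds_index(c) for c in protocluster.core_cds_ids]
    candidates = []
    for cds in record.cds_in(*protocluster.neighbourhood):
        if len(cds.translation) > MAX_PRECURSOR_AA:
            continue
        flags = {"short-orf"}
        index = record.cds_index(cds.cds_id)
        if any(abs(index - ci) <= NEAR_CORE_WINDOW for ci in core_indices):
            flags.add("near-core")
        candidates.append(PrecursorCandidate(
            cds.cds_id, len(cds.translation),
            _predict_split(cds.translation), frozenset(flags)))
    candidates.sort(key=lambda c: record.cds_index(c.cds_id))
    return candidates


def annotate_rre(hits: Iterable[ProfileHit],
                 protoclusters: Sequence[Protocluster],
                 catalogue: ProfileCatalogue,
                 record: GenomeRecord) -> List[RREHit]:
    """Mark every RRE-profile hit with its RiPP-protocluster containment.

    Exactly one RREHit per RRE ProfileHit.  A hit is "within" when its CDS
    overlaps the neighbourhood of any RiPP-category protocluster.
    """
    rre_profiles = {d.profile_name for d in catalogue.with_source_tag("RRE")}
    ripp_neighbourhoods = [p.neighbourhood for p in protoclusters
                           if p.category == "RiPP"]
    out = []
    for h in hits:
        if h.profile_name not in rre_profiles:
            continue
        cds = record.get_cds(h.cds_id)
        within = any(overlaps(cds.interval, n) for n in ripp_neighbourhoods)
        out.append(RREHit(h.cds_id, h.profile_name, h.bitscore, within))
    return out
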