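"""Profile catalogue handling and acquisition of per-protein profile hits.

Hits come from one of two sources: a precomputed whitespace-delimited hit
table (a column subset of HMMER's domtblout format) or a pluggable scanner
backend.  The backend contract keeps the HMM search engine out of the core:
production use can bind pyhmmer/hmmsearch, while tests and fixtures bind the
bundled :class:`NaiveSignatureScanner`, which finds exact signature-peptide
substrings and reports the signature length as the bitscore.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Callable, Dict, Iterable, List, Mapping, Optional

from .core import GenomeRecord, ProfileHit

logger = logging.getLogger(__name__)


class HitTableError(ValueError):
    """A hit table row could not be parsed."""


class ScannerError(RuntimeError):
    """A scanner backend failed; carries the backend identity."""


@dataclass(frozen=True)
class ProfileDefinition:
    """A curated detection profile with its per-profile gathering cutoff."""

    profile_name: str
    bitscore_cutoff: float
    description: str = ""
    source_tag: str = "custom"
    signature: str = ""


class ProfileCatalogue:
    """A set of profile definitions keyed by unique name."""

    def __init__(self, definitions: Iterable[ProfileDefinition]):
        self._by_name: Dict[str, ProfileDefinition] = {}
        for d in definitions:
            if d.profile_name in self._by_name:
                raise ValueError(f"duplicate profile {d.profile_name!r} in catalogue")
            self._by_name[d.profile_name] = d

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __getitem__(self, name: str) -> ProfileDefinition:
        return self._by_name[name]

    def __iter__(self):
        return iter(self._by_name.values())

    def __len__(self) -> int:
        return len(self._by_name)

    def names(self) -> List[str]:
        return sorted(self._by_name)

    def with_source_tag(self, tag: str) -> List[ProfileDefinition]:
        return [d for d in self if d.source_tag == tag]


def load_catalogue(path: Optional[Path] = None) -> ProfileCatalogue:
    """Load a profile catalogue from TSV (defaults to the bundled one).

    Columns: profile_name, bitscore_cutoff, source_tag, signature,
    description.  Lines starting with '#' are comments.
    """
    if path is None:
        text = resources.files("bgcmine.data").joinpath("profiles.tsv").read_text()
    else:
        text = Path(path).read_text()
    defs = []
    for lineno, line in enumerate(text.splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 4:
            raise HitTableError(f"profiles.tsv line {lineno}: expected >=4 columns")
        name, cutoff, tag, sig = parts[0], parts[1], parts[2], parts[3]
        desc = parts[4] if len(parts) > 4 else ""
        defs.append(ProfileDefinition(name, float(cutoff), desc, tag, sig))
    return ProfileCatalogue(defs)


def parse_hit_table(path, catalogue: ProfileCatalogue) -> List[ProfileHit]:
    """Parse a whitespace-delimited hit table into ProfileHits.

    Expected columns per row: target (CDS) name, profile name, full-sequence
    bitscore, full-sequence E-value, ali-from, ali-to.  Alignment coordinates
    are 1-based inclusive on disk and converted to 0-based half-open on read.
    Rows naming profiles absent from the catalogue are dropped with a warning.
    """
    hits: List[ProfileHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise HitTableError(f"{path}: line {lineno}: expected 6 columns, got {len(fields)}")
            cds_id, profile = fields[0], fields[1]
            try:
                bitscore = float(fields[2])
                evalue = float(fields[3])
                ali_from = int(fields[4])
                ali_to = int(fields[5])
            except ValueError as exc:
                raise HitTableError(f"{path}: line {lineno}: malformed numeric field: {exc}") from None
            if profile not in catalogue:
                logger.warning("hit table line %d: unknown profile %r dropped", lineno, profile)
                continue
            hits.append(ProfileHit(cds_id, profile, bitscore, evalue,
                                   ali_from - 1, ali_to))
    return hits


def write_hit_table(hits: Iterable[ProfileHit], path) -> None:
    """Write hits in the same dialect parse_hit_table reads (round-trip safe)."""
    with open(path, "w") as fh:
        fh.write("# target\tprofile\tbitscore\tevalue\tali_from\tali_to\n")
        for h in hits:
            fh.write(f"{h.cds_id} {h.profile_name} {h.bitscore:g} {h.evalue:g} "
                     f"{h.protein_start + 1} {h.protein_end}\n")


def filter_hits(hits: Iterable[ProfileHit], catalogue: ProfileCatalogue,
                best_per_profile: bool = True) -> List[ProfileHit]:
    """Apply per-profile bitscore cutoffs; optionally keep only the best hit
    per CDS+profile.

    Ties at exactly the cutoff are kept.  Idempotent.  Rule evaluation wants
    the deduplicated view (default); domain-architecture analysis needs every
    above-cutoff hit, since one megaenzyme gene legitimately carries the same
    domain profile several times (``best_per_profile=False``).
    """
    kept: List[ProfileHit] = []
    best: Dict[tuple, ProfileHit] = {}
    for h in hits:
        if h.profile_name not in catalogue:
            raise KeyError(f"hit names profile {h.profile_name!r} not in catalogue")
        if h.bitscore < catalogue[h.profile_name].bitscore_cutoff:
            continue
        if not best_per_profile:
            kept.append(h)
            continue
        key = (h.cds_id, h.profile_name)
        prev = best.get(key)
        if prev is None or h.bitscore > prev.bitscore:
            best[key] = h
    if best_per_profile:
        kept = list(best.values())
    return sorted(set(kept),
                  key=lambda h: (h.cds_id, h.protein_start, h.profile_name))


class NaiveSignatureScanner:
    """Scanner backend matching exact signature peptides.

    Each catalogue profile carries a short signature peptide; a hit is
    reported wherever the signature occurs as an exact substring of a
    translation, with bitscore equal to the signature length.  Deterministic
    and dependency-free; meant for fixtures and tests, not real genomes.
    """

    name = "naive-signature"

    def __call__(self, proteins: Mapping[str, str],
                 catalogue: ProfileCatalogue) -> List[ProfileHit]:
        hits = []
        for cds_id in sorted(proteins):
            seq = proteins[cds_id]
            for prof in catalogue:
                if not prof.signature:
                    continue
                start = seq.find(prof.signature)
                while start != -1:
                    hits.append(ProfileHit(cds_id, prof.profile_name,
                                           float(len(prof.signature)), 0.0,
                                           start, start + len(prof.signature)))
                    start = seq.find(prof.signature, start + 1)
        return hits


ScannerBackend = Callable[[Mapping[str, str], ProfileCatalogue], List[ProfileHit]]


def scan_proteins(record: GenomeRecord, catalogue: ProfileCatalogue,
                  backend: ScannerBackend,
                  best_per_profile: bool = True) -> List[ProfileHit]:
    """Run a scanner backend over all translations and filter the hits.

    Output order is stable: CDS genomic order, then protein_start.
    """
    proteins = {c.cds_id: c.translation for c in record.cds_features}
    try:
        raw = backend(proteins, catalogue)
    except Exception as exc:  # noqa: BLE001 - wrap with backend identity
        ident = getattr(backend, "name", repr(backend))
        raise ScannerError(f"scanner backend {ident!r} failed: {exc}") from exc
    for h in raw:
        if h.profile_name not in catalogue:
            ident = getattr(backend, "name", repr(backend))
            raise ScannerError(
                f"scanner backend {ident!r} returned unknown profile {h.profile_name!r}")
    filtered = filter_hits(raw, catalogue, best_per_profile=best_per_profile)
    order = {c.cds_id: i for i, c in enumerate(record.cds_features)}
    return sorted(filtered, key=lambda h: (order.get(h.cds_id, len(order)),
                                           h.protein_start, h.profile_name))


def hits_by_cds(hits: Iterable[ProfileHit]) -> Dict[str, List[ProfileHit]]:
    """Group hits per CDS, each list ordered by protein_start."""
    grouped: Dict[str, List[ProfileHit]] = {}
    for h in hits:
        grouped.setdefault(h.cds_id, []).append(h)
    for lst in grouped.values():
        lst.sort(key=lambda h: (h.protein_start, h.profile_name))
    return grouped
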