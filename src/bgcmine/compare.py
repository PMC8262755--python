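"""Cluster-to-reference comparison scoring.

A query cluster is scored against each reference entry with three parts,
each scaled to [0, 1], combined by their geometric mean:

* **identity** — mean best-hit percent identity over the query proteins
  (unpaired proteins count as 0), from greedy mutually-best one-to-one
  pairing of local protein alignments;
* **synteny** — conservation of gene order: the longest common subsequence
  of the paired reference indices walked in query genomic order, divided by
  the number of pairs, taking the better of the two reference orientations;
* **components** — Jaccard index of the biosynthetic component inventories
  (detection profiles hit, functional classes, smCOG classes, NRPS/PKS
  domain classes).

The exact part formulas are this package's own design; the constraints they
satisfy (0–1 scaling, synteny and presence/absence parts, geometric mean)
are the fidelity claim.  See docs/methods.md.
"""

from __future__ import annotations

import bisect
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

from .core import GenomeRecord, Protocluster, Region

# Pairing thresholds: below either, a candidate pair is discarded.
MIN_IDENTITY_PCT = 30.0
MIN_COVERAGE = 0.25


@dataclass(frozen=True)
class ReferenceEntry:
    """One reference cluster: ordered proteins plus component annotations."""

    entry_id: str
    proteins: tuple  # of (protein_id, sequence, component tag tuple)
    product: str = ""

    def __post_init__(self):
        if not self.proteins:
            raise ValueError(f"reference {self.entry_id}: needs >= 1 protein")

    @property
    def inventory(self) -> frozenset:
        tags: Set[str] = set()
        for _, _, components in self.proteins:
            tags.update(components)
        return frozenset(tags)


@dataclass
class ComparisonResult:
    query_id: str
    entry_id: str
    identity_part: float
    synteny_part: float
    components_part: float
    final_score: float
    pairing: list  # of (query cds_id, reference protein_id, percent identity)


def load_reference_db(path) -> List[ReferenceEntry]:
    """Load a JSON reference database (MIBiG-style accessions accepted).

    Format: list of {"entry_id", "product", "proteins": [{"protein_id",
    "sequence", "components"}]}.
    """
    with open(path) as fh:
        raw = json.load(fh)
    entries = []
    for item in raw:
        proteins = tuple(
            (p["protein_id"], p["sequence"], tuple(p.get("components", ())))
            for p in item["proteins"])
        entries.append(ReferenceEntry(item["entry_id"], proteins,
                                      item.get("product", "")))
    ids = [e.entry_id for e in entries]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate entry_id in reference database")
    return entries


def write_reference_db(entries: Iterable[ReferenceEntry], path) -> None:
    payload = [
        {"entry_id": e.entry_id, "product": e.product,
         "proteins": [{"protein_id": pid, "sequence": seq,
                       "components": list(comp)}
                      for pid, seq, comp in e.proteins]}
        for e in entries
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


# --------------------------------------------------------------------------
# Alignment


class Blosum62Aligner:
    """Local protein alignment (Smith-Waterman, BLOSUM62) via biopython.

    Returns (percent identity over aligned columns, coverage of the shorter
    sequence).  Pluggable: any callable with the same signature works.
    """

    name = "blosum62-local"

    def __init__(self):
        from Bio.Align import PairwiseAligner, substitution_matrices
        aligner = PairwiseAligner()
        aligner.mode = "local"
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -10.0
        aligner.extend_gap_score = -0.5
        self._aligner = aligner

    def __call__(self, a: str, b: str) -> Tuple[float, float]:
        if not a or not b:
            return 0.0, 0.0
        try:
            alignment = self._aligner.align(a, b)[0]
        except (IndexError, ValueError):
            return 0.0, 0.0
        counts = alignment.counts()
        aligned_cols = counts.identities + counts.mismatches + counts.gaps
        if aligned_cols == 0:
            return 0.0, 0.0
        identity = 100.0 * counts.identities / aligned_cols
        shorter = min(len(a), len(b))
        spans = [alignment.aligned[0], alignment.aligned[1]][0 if len(a) <= len(b) else 1]
        covered = sum(e - s for s, e in spans)
        return identity, covered / shorter


PairwiseAlignerContract = Callable[[str, str], Tuple[float, float]]


def best_hit_pairing(query_proteins: Sequence[Tuple[str, str]],
                     reference_proteins: Sequence[Tuple[str, str]],
                     aligner: PairwiseAlignerContract
                     ) -> List[Tuple[str, str, float]]:
    """Greedy mutually-best one-to-one pairing by percent identity.

    All query x reference alignments are computed; pairs under the identity
    or coverage thresholds are discarded; then the globally best remaining
    pair is taken repeatedly, removing both members.  Ties broken by
    (query id, reference id) for determinism.
    """
    scored = []
    for q_id, q_seq in query_proteins:
        for r_id, r_seq in reference_proteins:
            identity, coverage = aligner(q_seq, r_seq)
            if identity < MIN_IDENTITY_PCT or coverage < MIN_COVERAGE:
                continue
            scored.append((identity, q_id, r_id))
    scored.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_q: Set[str] = set()
    used_r: Set[str] = set()
    pairing = []
    for identity, q_id, r_id in scored:
        if q_id in used_q or r_id in used_r:
            continue
        pairing.append((q_id, r_id, identity))
        used_q.add(q_id)
        used_r.add(r_id)
    return pairing


# --------------------------------------------------------------------------
# Score parts


def identity_part(pairing: Sequence[Tuple[str, str, float]], n_query: int) -> float:
    """Mean paired identity over all query proteins; unpaired count as zero."""
    if n_query < 1:
        raise ValueError("n_query must be >= 1")
    return sum(identity / 100.0 for _, _, identity in pairing) / n_query


def _lis_length(seq: Sequence[int]) -> int:
    """Length of the longest strictly increasing subsequence (patience)."""
    tails: List[int] = []
    for x in seq:
        i = bisect.bisect_left(tails, x)
        if i == len(tails):
            tails.append(x)
        else:
            tails[i] = x
    return len(tails)


def synteny_part(pairing: Sequence[Tuple[str, str, float]],
                 query_order: Sequence[str],
                 reference_order: Sequence[str]) -> float:
    """Gene-order conservation of the paired genes, orientation-insensitive.

    Walk the pairs in query genomic order and take the paired reference
    indices; the part is the longest strictly increasing subsequence of that
    index sequence divided by the number of pairs, computed for both
    reference orientations with the maximum taken.  No pairs -> 0.
    """
    if not pairing:
        return 0.0
    ref_index = {pid: i for i, pid in enumerate(reference_order)}
    by_query = {q: r for q, r, _ in pairing}
    indices = [ref_index[by_query[q]] for q in query_order if q in by_query]
    forward = _lis_length(indices)
    reverse = _lis_length([-i for i in indices])
    return max(forward, reverse) / len(indices)


def components_part(query_inventory: Iterable[str],
                    reference_inventory: Iterable[str]) -> float:
    """Jaccard index of the two component-tag sets; both empty -> 0."""
    a, b = set(query_inventory), set(reference_inventory)
    if not a and not b:
        return 0.0
    return len(a & b) / len(a | b)


def final_score(parts: Sequence[float]) -> float:
    """Geometric mean of the parts; any zero part annihilates the score."""
    if not parts:
        raise ValueError("final_score needs >= 1 part")
    for p in parts:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"part {p} outside [0, 1]")
    product = 1.0
    for p in parts:
        product *= p
    return product ** (1.0 / len(parts))


# --------------------------------------------------------------------------
# Query assembly and top-level comparison


@dataclass
class QueryCluster:
    """The comparable view of a query protocluster or region."""

    query_id: str
    proteins: list  # ordered (cds_id, sequence)
    inventory: frozenset


def build_query(record: GenomeRecord, interval: Tuple[int, int], query_id: str,
                component_tags: Mapping[str, Iterable[str]]) -> QueryCluster:
    """Collect the proteins and component inventory inside one interval.

    ``component_tags`` maps cds_id -> tags contributed by annotation
    (detection profiles, functional classes, smCOG classes, domain classes).
    """
    proteins = [(c.cds_id, c.translation) for c in record.cds_in(*interval)]
    tags: Set[str] = set()
    for cds_id, _ in proteins:
        tags.update(component_tags.get(cds_id, ()))
    return QueryCluster(query_id, proteins, frozenset(tags))


def compare_one(query: QueryCluster, reference: ReferenceEntry,
                aligner: PairwiseAlignerContract) -> ComparisonResult:
    ref_proteins = [(pid, seq) for pid, seq, _ in reference.proteins]
    pairing = best_hit_pairing(query.proteins, ref_proteins, aligner)
    ident = identity_part(pairing, len(query.proteins)) if query.proteins else 0.0
    synteny = synteny_part(pairing, [q for q, _ in query.proteins],
                           [pid for pid, _ in ref_proteins])
    components = components_part(query.inventory, reference.inventory)
    score = final_score([ident, synteny, components])
    return ComparisonResult(query.query_id, reference.entry_id, ident, synteny,
                            components, score,
                            [(q, r, round(i, 4)) for q, r, i in pairing])


def compare(queries: Sequence[QueryCluster], db: Sequence[ReferenceEntry],
            aligner: Optional[PairwiseAlignerContract] = None,
            top_n: int = 10) -> Dict[str, List[ComparisonResult]]:
    """Score each query against every reference entry; rank per query.

    Results are sorted by final score descending, ties broken by entry_id
    lexicographically, truncated to ``top_n``.
    """
    if aligner is None:
        aligner = Blosum62Aligner()
    out: Dict[str, List[ComparisonResult]] = {}
    for query in queries:
        results = [compare_one(query, ref, aligner) for ref in db]
        results.sort(key=lambda r: (-r.final_score, r.entry_id))
        out[query.query_id] = results[:top_n]
    return out


def queries_from_regions(record: GenomeRecord, regions: Sequence[Region],
                         component_tags: Mapping[str, Iterable[str]],
                         mode: str = "protocluster-to-region"
                         ) -> List[QueryCluster]:
    """Build query clusters per the comparison mode.

    ``region-to-region`` takes whole regions; the protocluster modes score
    each protocluster independently.  (The reference side of the mode name
    describes how the database entries were built, not a different code
    path: entries always expose their full protein list.)
    """
    if mode not in ("region-to-region", "protocluster-to-region",
                    "protocluster-to-protocluster"):
        raise ValueError(f"unknown comparison mode {mode!r}")
    queries = []
    if mode == "region-to-region":
        for region in regions:
            queries.append(build_query(
                record, region.interval,
                f"{record.record_id}|region{region.region_number}",
                component_tags))
    else:
        for region in regions:
            for i, proto in enumerate(region.protoclusters, 1):
                queries.append(build_query(
                    record, proto.neighbourhood,
                    f"{record.record_id}|region{region.region_number}"
                    f"|protocluster{i}|{proto.product}",
                    component_tags))
    return queries


def results_to_tsv(ranked: Mapping[str, Sequence[ComparisonResult]], path) -> None:
    """Export ranked comparison results as a TSV table."""
    with open(path, "w") as fh:
        fh.write("query\trank\treference\tfinal_score\tidentity\tsynteny"
                 "\tcomponents\tpairs\n")
        for query_id in sorted(ranked):
            for rank, r in enumerate(ranked[query_id], 1):
                fh.write(f"{query_id}\t{rank}\t{r.entry_id}\t{r.final_score:.4f}"
                         f"\t{r.identity_part:.4f}\t{r.synteny_part:.4f}"
                         f"\t{r.components_part:.4f}\t{len(r.pairing)}\n")
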