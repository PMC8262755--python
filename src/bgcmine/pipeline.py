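"""The end-to-end mining pipeline and canonical results serialization.

Stages: acquire profile hits (hit table or scanner backend) -> per-profile
cutoff filtering -> rule evaluation -> protocluster/region building ->
module assembly -> RiPP precursor/RRE annotation -> optional reference
comparison -> optional sideload merging.  The results document is plain
JSON with canonical ordering and pinned float formatting, so identical
inputs and options produce byte-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

from . import __version__
from .compare import (Blosum62Aligner, ComparisonResult, QueryCluster,
                      load_reference_db, compare as compare_clusters,
                      queries_from_regions, results_to_tsv)
from .core import GenomeRecord, ProfileHit, Region
from .genbank import read_genbank, write_genbank
from .modules import (annotate_monomers, assemble_modules, classify_domains,
                      load_domain_mapping, load_monomer_table)
from .profiles import (NaiveSignatureScanner, ProfileCatalogue, filter_hits,
                       hits_by_cds, load_catalogue, parse_hit_table,
                       scan_proteins)
from .ripp import annotate_rre, find_precursor_candidates
from .rules import RuleCatalogue, bundled_ruleset, detect
from .sideload import SideloadDocument, merge_sideload

SCHEMA_VERSION = 1


def load_smcog_table() -> Dict[str, str]:
    text = resources.files("bgcmine.data").joinpath("smcog_classes.tsv").read_text()
    table = {}
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        name, cls = line.split("\t")[:2]
        table[name] = cls
    return table


@dataclass
class PipelineOptions:
    strictness: str = "relaxed"
    hit_table: Optional[Path] = None
    scanner: Optional[object] = None  # ScannerBackend; naive one by default
    sideload_docs: Sequence[SideloadDocument] = ()
    reference_db: Optional[Path] = None
    compare_mode: str = "protocluster-to-region"
    top_n: int = 10
    enabled_rules: Optional[Sequence[str]] = None
    taxon: str = "bacteria"

    def __post_init__(self):
        if self.strictness not in ("strict", "relaxed", "loose"):
            raise ValueError(f"unknown strictness {self.strictness!r}")
        if self.taxon not in ("bacteria", "fungi"):
            raise ValueError(f"unknown taxon {self.taxon!r}")


def _component_tags(record: GenomeRecord, hits: Sequence[ProfileHit],
                    regions: Sequence[Region],
                    domain_mapping: Mapping[str, str],
                    smcog: Mapping[str, str]) -> Dict[str, set]:
    """Biosynthetic component tags per CDS: profiles, functional classes,
    smCOG classes, and NRPS/PKS domain classes."""
    grouped = hits_by_cds(hits)
    core_ids = {c for r in regions for p in r.protoclusters for c in p.core_cds_ids}
    tags: Dict[str, set] = {}
    for cds in record.cds_features:
        cds_tags = set()
        for h in grouped.get(cds.cds_id, []):
            cds_tags.add(h.profile_name)
            if h.profile_name in domain_mapping:
                cds_tags.add(f"domain:{domain_mapping[h.profile_name]}")
            if h.profile_name in smcog:
                cds_tags.add(smcog[h.profile_name])
        if cds.cds_id in core_ids:
            cds_tags.add("class:biosynthetic-core")
        elif cds_tags:
            cds_tags.add("class:biosynthetic-additional")
        if cds_tags:
            tags[cds.cds_id] = cds_tags
    return tags


def _functional_class_for(cds_id: str, core_ids: set, grouped: Mapping,
                          smcog: Mapping[str, str]) -> str:
    if cds_id in core_ids:
        return "biosynthetic-core"
    hits = grouped.get(cds_id, [])
    for h in hits:
        label = smcog.get(h.profile_name, "")
        if "transporter" in label:
            return "transport"
        if "regulator" in label:
            return "regulatory"
    if hits:
        return "biosynthetic-additional"
    return "other"


def annotate_functional_classes(record: GenomeRecord,
                                hits: Sequence[ProfileHit],
                                regions: Sequence[Region],
                                smcog: Mapping[str, str]) -> GenomeRecord:
    """Return a copy of the record with functional_class set per CDS."""
    grouped = hits_by_cds(hits)
    core_ids = {c for r in regions for p in r.protoclusters for c in p.core_cds_ids}
    new_cds = [cds.with_functional_class(
        _functional_class_for(cds.cds_id, core_ids, grouped, smcog))
        for cds in record.cds_features]
    return GenomeRecord(record.record_id, record.sequence_length, new_cds,
                        record.circular)


# --------------------------------------------------------------------------
# Results document


def _jsonable(obj):
    if isinstance(obj, float):
        return round(obj, 6)
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    return obj


def canonical_json(payload: dict) -> str:
    """Canonical serialization: sorted keys, indent 1, floats to 6 dp."""
    return json.dumps(_jsonable(payload), sort_keys=True, indent=1) + "\n"


def _region_payload(region: Region) -> dict:
    return {
        "region_number": region.region_number,
        "start": region.start,
        "end": region.end,
        "products": region.products,
        "protoclusters": [
            {"product": p.product, "category": p.category,
             "core_start": p.core_start, "core_end": p.core_end,
             "neighbourhood_start": p.neighbourhood_start,
             "neighbourhood_end": p.neighbourhood_end,
             "core_cds_ids": sorted(p.core_cds_ids),
             "rule_name": p.rule_name, "tool": p.tool}
            for p in region.protoclusters],
        "candidates": [
            {"kind": c.kind, "start": c.start, "end": c.end,
             "products": sorted({p.product for p in c.protoclusters})}
            for c in region.candidates],
        "subregions": [
            {"start": s.start, "end": s.end, "label": s.label, "tool": s.tool}
            for s in region.subregions],
    }


@dataclass
class ResultsDocument:
    """The full pipeline output for one genome, JSON-serializable."""

    payload: dict

    def to_json(self) -> str:
        return canonical_json(self.payload)

    def write(self, path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path) -> "ResultsDocument":
        return cls(json.loads(Path(path).read_text()))


def run_pipeline(genome, options: Optional[PipelineOptions] = None,
                 ruleset: Optional[RuleCatalogue] = None,
                 catalogue: Optional[ProfileCatalogue] = None,
                 output_dir: Optional[Path] = None,
                 sequence: Optional[str] = None) -> ResultsDocument:
    """Run the full pipeline on one genome.

    ``genome`` is a GenBank path or an in-memory GenomeRecord.  When
    ``output_dir`` is set, results JSON, an annotated GenBank file and (if a
    comparison ran) a TSV table are written there.
    """
    options = options or PipelineOptions()
    ruleset = ruleset or bundled_ruleset()
    catalogue = catalogue or load_catalogue()
    ruleset.validate_against(catalogue)
    if options.enabled_rules is not None:
        unknown = set(options.enabled_rules) - {r.rule_name for r in ruleset}
        if unknown:
            raise ValueError(f"unknown rule names enabled: {sorted(unknown)}")
        ruleset = RuleCatalogue([r for r in ruleset
                                 if r.rule_name in set(options.enabled_rules)])

    if isinstance(genome, GenomeRecord):
        record = genome
    else:
        records = read_genbank(genome)
        if not records:
            raise ValueError(f"no records in {genome}")
        record = records[0]

    # domain-level view keeps every above-cutoff hit (megaenzymes repeat
    # domain profiles); rule evaluation uses the best-hit-per-profile view
    if options.hit_table is not None:
        domain_hits = filter_hits(parse_hit_table(options.hit_table, catalogue),
                                  catalogue, best_per_profile=False)
    else:
        backend = options.scanner or NaiveSignatureScanner()
        domain_hits = scan_proteins(record, catalogue, backend,
                                    best_per_profile=False)
    hits = filter_hits(domain_hits, catalogue)

    regions = detect(record, hits, ruleset, options.strictness)

    for doc in options.sideload_docs:
        merged = merge_sideload([record], {record.record_id: regions}, doc)
        regions = merged[record.record_id]

    smcog = load_smcog_table()
    record = annotate_functional_classes(record, hits, regions, smcog)

    domain_mapping = load_domain_mapping()
    translations = {c.cds_id: c.translation for c in record.cds_features}
    per_cds_domains = classify_domains(domain_hits, domain_mapping, translations)
    modules, unassigned = assemble_modules(per_cds_domains, record)
    annotate_monomers(modules, load_monomer_table())

    all_protos = [p for r in regions for p in r.protoclusters]
    precursors = []
    for proto in all_protos:
        if proto.category == "RiPP":
            precursors.extend(find_precursor_candidates(record, proto))
    rre_hits = annotate_rre(hits, all_protos, catalogue, record)

    comparisons: Dict[str, List[ComparisonResult]] = {}
    if options.reference_db is not None:
        db = load_reference_db(options.reference_db)
        tags = _component_tags(record, hits, regions, domain_mapping, smcog)
        mode = options.compare_mode
        queries = queries_from_regions(record, regions, tags, mode)
        comparisons = compare_clusters(queries, db, top_n=options.top_n)

    payload = {
        "schema_version": SCHEMA_VERSION,
        "provenance": {
            "tool": {"name": "bgcmine", "version": __version__},
            "strictness": options.strictness,
            "taxon": options.taxon,
            "sideload_tools": sorted({d.tool.name for d in options.sideload_docs}),
        },
        "records": [{
            "record_id": record.record_id,
            "sequence_length": record.sequence_length,
            "regions": [_region_payload(r) for r in regions],
            "modules": [
                {"module_type": m.module_type, "complete": m.complete,
                 "split": m.split, "monomer": m.monomer,
                 "domains": [{"cds_id": d.cds_id, "class": d.domain_class,
                              "start": d.protein_start, "end": d.protein_end}
                             for d in m.components]}
                for m in modules],
            "unassigned_domains": [
                {"cds_id": d.cds_id, "class": d.domain_class,
                 "start": d.protein_start, "end": d.protein_end}
                for d in unassigned],
            "precursor_candidates": [
                {"cds_id": p.cds_id, "length": p.length,
                 "split_position": p.split_position, "flags": sorted(p.flags)}
                for p in precursors],
            "rre_hits": [
                {"cds_id": h.cds_id, "profile": h.profile_name,
                 "bitscore": h.bitscore,
                 "within_ripp_protocluster": h.within_ripp_protocluster}
                for h in rre_hits],
            "comparisons": {
                qid: [{"reference": r.entry_id, "final_score": r.final_score,
                       "identity": r.identity_part, "synteny": r.synteny_part,
                       "components": r.components_part,
                       "pairing": [list(p) for p in r.pairing]}
                      for r in ranked]
                for qid, ranked in comparisons.items()},
        }],
    }
    doc = ResultsDocument(payload)
    if output_dir is not None:
        output_dir = Path(output_dir)
        output_dir.mkdir(parents=True, exist_ok=True)
        doc.write(output_dir / "results.json")
        seq = sequence or "A" * record.sequence_length
        write_genbank(record, seq, output_dir / f"{record.record_id}.gbk",
                      regions)
        if comparisons:
            results_to_tsv(comparisons, output_dir / "comparisons.tsv")
    return doc
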