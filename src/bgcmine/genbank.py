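"""Reading and writing annotated records (GenBank, FASTA+GFF3).

This is the only place where the internal 0-based half-open coordinate
convention meets GenBank's 1-based inclusive one; biopython's feature
locations are already 0-based half-open, so conversion is handled entirely
by SeqIO and intervals survive a parse -> serialize -> parse round-trip
exactly.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .core import CdsFeature, GenomeRecord, Protocluster, Region, SubRegion

# Minimal codon choice per amino acid (bacterial table 11) used when a
# protein must be embedded back into nucleotide sequence.
_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAA", "R": "CGT", "S": "TCT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}
_STOP = "TAA"


def back_translate(protein: str) -> str:
    """Deterministic nucleotide encoding of a protein, stop codon included."""
    return "".join(_CODON[aa] for aa in protein) + _STOP


def _cds_from_feature(feature: SeqFeature, index: int, parent_seq) -> CdsFeature:
    start = int(feature.location.start)
    end = int(feature.location.end)
    strand = feature.location.strand or 1
    quals = feature.qualifiers
    cds_id = (quals.get("locus_tag") or quals.get("gene")
              or quals.get("protein_id") or [f"cds{index}"])[0]
    if "translation" in quals:
        translation = quals["translation"][0]
    else:
        nt = feature.extract(parent_seq)
        translation = str(Seq(nt).translate(table=11, to_stop=True))
    return CdsFeature(cds_id, start, end, int(strand), translation)


def read_genbank(path) -> List[GenomeRecord]:
    """Read all records of a GenBank flat file into the internal model."""
    records = []
    for rec in SeqIO.parse(str(path), "genbank"):
        cds = [
            _cds_from_feature(f, i, rec.seq)
            for i, f in enumerate(rec.features) if f.type == "CDS"
        ]
        topology = rec.annotations.get("topology", "linear")
        records.append(GenomeRecord(rec.id, len(rec.seq), cds,
                                    circular=topology == "circular"))
    return records


def read_fasta_gff(fasta_path, gff_path) -> List[GenomeRecord]:
    """Read FASTA sequences plus GFF3 CDS features."""
    import gffutils

    seqs = {rec.id: rec.seq for rec in SeqIO.parse(str(fasta_path), "fasta")}
    db = gffutils.create_db(str(gff_path), ":memory:", force=True,
                            keep_order=True,
                            merge_strategy="create_unique")
    cds_by_record: Dict[str, List[CdsFeature]] = {rid: [] for rid in seqs}
    for i, feat in enumerate(db.features_of_type("CDS", order_by="start")):
        if feat.seqid not in seqs:
            continue
        start = feat.start - 1  # GFF is 1-based inclusive
        end = feat.end
        strand = -1 if feat.strand == "-" else 1
        cds_id = feat.attributes.get("ID", [f"cds{i}"])[0]
        nt = str(seqs[feat.seqid][start:end])
        if strand == -1:
            nt = str(Seq(nt).reverse_complement())
        translation = str(Seq(nt).translate(table=11, to_stop=True))
        cds_by_record[feat.seqid].append(
            CdsFeature(cds_id, start, end, strand, translation))
    return [GenomeRecord(rid, len(seq), cds_by_record.get(rid, []))
            for rid, seq in seqs.items()]


def _feature(start: int, end: int, ftype: str, qualifiers: Dict) -> SeqFeature:
    return SeqFeature(FeatureLocation(start, end), type=ftype,
                      qualifiers={k: v if isinstance(v, list) else [v]
                                  for k, v in qualifiers.items()})


def write_genbank(record: GenomeRecord, sequence: str, path,
                  regions: Sequence[Region] = ()) -> None:
    """Write a record with CDS plus detection features to GenBank.

    Protocluster core intervals are stored in ``core_location`` qualifiers
    (1-based inclusive, GenBank style) so that the full detection geometry
    survives a round-trip.
    """
    rec = SeqRecord(Seq(sequence), id=record.record_id, name=record.record_id[:16],
                    description="bgcmine annotated record")
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = "circular" if record.circular else "linear"
    rec.features.append(_feature(0, record.sequence_length, "source",
                                 {"organism": "synthetic construct"}))
    for region in regions:
        rec.features.append(_feature(region.start, region.end, "region", {
            "region_number": str(region.region_number),
            "product": region.products or ["unknown"],
            "candidate_kinds": sorted({c.kind for c in region.candidates}) or ["single"],
        }))
        for proto in region.protoclusters:
            rec.features.append(_feature(
                proto.neighbourhood_start, proto.neighbourhood_end,
                "protocluster", {
                    "product": proto.product,
                    "category": proto.category,
                    "core_location": f"{proto.core_start + 1}..{proto.core_end}",
                    "detection_rule": proto.rule_name,
                    "tool": proto.tool,
                    "core_cds": sorted(proto.core_cds_ids),
                }))
        for sub in region.subregions:
            rec.features.append(_feature(sub.start, sub.end, "subregion", {
                "label": sub.label, "tool": sub.tool}))
    for cds in record.cds_features:
        feature = SeqFeature(
            FeatureLocation(cds.start, cds.end, strand=cds.strand), type="CDS",
            qualifiers={"locus_tag": [cds.cds_id],
                        "translation": [cds.translation],
                        "transl_table": ["11"],
                        "gene_functions": [cds.functional_class]})
        rec.features.append(feature)
    SeqIO.write([rec], str(path), "genbank")


def read_annotated_intervals(path) -> Dict[str, Dict[str, List[Tuple[int, int]]]]:
    """Extract region/protocluster geometry from an annotated GenBank file.

    Returns per record_id: {"regions": [(start, end)], "protoclusters":
    [(neighbourhood interval)], "cores": [(core interval)]}.
    """
    out: Dict[str, Dict[str, List[Tuple[int, int]]]] = {}
    for rec in SeqIO.parse(str(path), "genbank"):
        entry = {"regions": [], "protoclusters": [], "cores": []}
        for f in rec.features:
            span = (int(f.location.start), int(f.location.end))
            if f.type == "region":
                entry["regions"].append(span)
            elif f.type == "protocluster":
                entry["protoclusters"].append(span)
                core = f.qualifiers.get("core_location", [None])[0]
                if core:
                    lo, hi = core.split("..")
                    entry["cores"].append((int(lo) - 1, int(hi)))
        out[rec.id] = entry
    return out
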