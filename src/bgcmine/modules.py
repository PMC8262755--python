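"""Explicit assembly-line module detection for NRPS and modular/trans-AT PKS.

Multimodular megaenzymes are annotated at two levels: individual enzymatic
domains (from profile hits, mapped to canonical domain classes via a bundled
table) and the modules those domains form.  The module grammar used here:

* a module opens at a C (NRPS) or KS (PKS) domain, or at an A/AT domain when
  it is the first module of an assembly line (a loading module);
* modification domains (KR, DH, ER, MT, E) accumulate into the open module;
* the module closes at the first carrier domain (PCP or ACP);
* a TE domain attaches to the final module of the line;
* a PKS module closed without an AT domain is a trans-AT module.

A module left open at the end of a CDS is merged with a compatible module
head at the start of the next CDS when the two CDSs are adjacent, on the
same strand, and separated by at most ``SPLIT_GAP_BP``; the merged module is
flagged ``split``.  Otherwise it is reported incomplete.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from .core import CdsFeature, GenomeRecord, ProfileHit

DOMAIN_CLASSES = ("C", "A", "PCP", "E", "KS", "AT", "KR", "DH", "ER", "MT",
                  "ACP", "TE", "other")
CARRIERS = {"PCP", "ACP"}
MODIFIERS = {"KR", "DH", "ER", "MT", "E"}
OPENERS = {"C", "KS"}
LOADING_OPENERS = {"A", "AT"}

# Maximum intergenic gap for merging a split module across two CDSs.
SPLIT_GAP_BP = 2000


@dataclass(frozen=True)
class DomainAnnotation:
    """One enzymatic domain on one protein, classified from its profile hit."""

    cds_id: str
    domain_class: str
    protein_start: int
    protein_end: int
    profile_name: str = ""
    peptide: str = ""

    def __post_init__(self):
        if self.domain_class not in DOMAIN_CLASSES:
            raise ValueError(f"unknown domain class {self.domain_class!r}")
        if self.protein_start >= self.protein_end:
            raise ValueError("domain protein_start >= protein_end")


@dataclass
class Module:
    """One assembly-line module: an ordered run of domains closing at a carrier."""

    components: List[DomainAnnotation]
    module_type: str  # nrps | pks | trans-at-pks
    complete: bool
    split: bool
    monomer: str = "?"

    def __post_init__(self):
        if self.module_type not in ("nrps", "pks", "trans-at-pks"):
            raise ValueError(f"unknown module type {self.module_type!r}")
        if not self.components:
            raise ValueError("module needs >= 1 domain")

    @property
    def domain_classes(self) -> List[str]:
        return [d.domain_class for d in self.components]

    @property
    def cds_ids(self) -> List[str]:
        out = []
        for d in self.components:
            if d.cds_id not in out:
                out.append(d.cds_id)
        return out


def load_domain_mapping(path: Optional[Path] = None) -> Dict[str, str]:
    """profile_name -> domain class table (defaults to the bundled TSV)."""
    if path is None:
        text = resources.files("bgcmine.data").joinpath("domain_classes.tsv").read_text()
    else:
        text = Path(path).read_text()
    mapping = {}
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        name, cls = line.split("\t")[:2]
        mapping[name] = cls
    return mapping


def load_monomer_table(path: Optional[Path] = None) -> Dict[str, str]:
    """signature peptide -> monomer label table (defaults to the bundled TSV)."""
    if path is None:
        text = resources.files("bgcmine.data").joinpath("monomer_signatures.tsv").read_text()
    else:
        text = Path(path).read_text()
    table = {}
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        sig, monomer = line.split("\t")[:2]
        table[sig] = monomer
    return table


def classify_domains(hits: Iterable[ProfileHit], mapping: Mapping[str, str],
                     translations: Optional[Mapping[str, str]] = None
                     ) -> Dict[str, List[DomainAnnotation]]:
    """Map profile hits to ordered per-CDS domain annotations.

    Profiles absent from the mapping become class ``other``.  When
    ``translations`` is given, each annotation carries the peptide its hit
    spans, which is what monomer assignment matches against.
    """
    per_cds: Dict[str, List[DomainAnnotation]] = {}
    for h in hits:
        cls = mapping.get(h.profile_name, "other")
        peptide = ""
        if translations and h.cds_id in translations:
            peptide = translations[h.cds_id][h.protein_start:h.protein_end]
        per_cds.setdefault(h.cds_id, []).append(DomainAnnotation(
            h.cds_id, cls, h.protein_start, h.protein_end,
            profile_name=h.profile_name, peptide=peptide))
    for lst in per_cds.values():
        lst.sort(key=lambda d: (d.protein_start, d.protein_end, d.domain_class))
    return per_cds


def _module_type_for(classes: List[str]) -> str:
    if "KS" in classes:
        return "pks" if "AT" in classes else "trans-at-pks"
    if "AT" in classes:
        return "pks"
    return "nrps"


def _is_complete(classes: List[str], first_in_line: bool) -> bool:
    if "KS" in classes:
        # pks: KS + AT + ACP; trans-AT: KS + ACP without AT
        return "ACP" in classes
    if "AT" in classes:  # loading pks module
        return "ACP" in classes
    # nrps: A + carrier; C optional for the first module of the line
    if "A" in classes and ("PCP" in classes or "ACP" in classes):
        return "C" in classes or first_in_line
    return False


def _finalise(components: List[DomainAnnotation], complete: bool,
              first_in_line: bool) -> Module:
    classes = [d.domain_class for d in components]
    split = len({d.cds_id for d in components}) > 1
    return Module(components=list(components),
                  module_type=_module_type_for(classes),
                  complete=complete and _is_complete(classes, first_in_line),
                  split=split)


def assemble_domain_sequence(domains: Sequence[DomainAnnotation]
                             ) -> Tuple[List[Module], List[DomainAnnotation]]:
    """Assemble modules from one ordered domain sequence.

    Returns (modules, unassigned domains).  The sequence may span several
    CDSs; the caller is responsible for only concatenating compatible CDSs.
    """
    modules: List[Module] = []
    unassigned: List[DomainAnnotation] = []
    current: List[DomainAnnotation] = []
    first_in_line = True

    def close(complete: bool):
        nonlocal current, first_in_line
        if current:
            modules.append(_finalise(current, complete, first_in_line))
            first_in_line = False
            current = []

    for dom in domains:
        cls = dom.domain_class
        if cls == "other":
            unassigned.append(dom)
            continue
        if cls in OPENERS:
            close(False)  # an opener before a carrier aborts the previous module
            current.append(dom)
        elif cls in LOADING_OPENERS:
            if not current:
                if first_in_line and not modules:
                    current.append(dom)  # loading module
                else:
                    unassigned.append(dom)
            else:
                current.append(dom)
        elif cls in MODIFIERS:
            if current:
                current.append(dom)
            else:
                unassigned.append(dom)
        elif cls in CARRIERS:
            if current:
                current.append(dom)
                close(True)
            else:
                unassigned.append(dom)
        elif cls == "TE":
            if current:
                current.append(dom)
                close(False)  # TE without carrier: incomplete
            elif modules:
                modules[-1].components.append(dom)
            else:
                unassigned.append(dom)
        else:  # pragma: no cover - enum is closed
            unassigned.append(dom)
    close(False)
    return modules, unassigned


def _chain_cds(record: GenomeRecord, cds_ids: Sequence[str]) -> List[List[str]]:
    """Split an ordered CDS-id list into chains mergeable for split modules.

    Consecutive CDSs stay in one chain when adjacent in the record (no CDS in
    between), on the same strand, and separated by at most SPLIT_GAP_BP.
    """
    chains: List[List[str]] = []
    prev: Optional[CdsFeature] = None
    prev_index = -2
    for cds_id in cds_ids:
        cds = record.get_cds(cds_id)
        index = record.cds_index(cds_id)
        if (prev is not None and index == prev_index + 1
                and cds.strand == prev.strand
                and cds.start - prev.end <= SPLIT_GAP_BP):
            chains[-1].append(cds_id)
        else:
            chains.append([cds_id])
        prev, prev_index = cds, index
    return chains


def assemble_modules(per_cds: Mapping[str, List[DomainAnnotation]],
                     record: GenomeRecord) -> Tuple[List[Module], List[DomainAnnotation]]:
    """Assemble modules across all CDSs of a record, merging split modules.

    CDSs carrying assembly-line domains are processed in genomic order;
    adjacent same-strand CDSs within SPLIT_GAP_BP form one concatenated
    domain sequence, so a module left open at a CDS boundary merges with the
    next CDS's head and is flagged split.  Modules are reported in
    assembly-line (genomic) order.
    """
    carrying = []
    modules: List[Module] = []
    unassigned: List[DomainAnnotation] = []
    for cds in record.cds_features:
        doms = per_cds.get(cds.cds_id)
        if not doms:
            continue
        if all(d.domain_class == "other" for d in doms):
            unassigned.extend(doms)  # no assembly domains: not part of a line
        else:
            carrying.append(cds.cds_id)
    for chain in _chain_cds(record, carrying):
        seq: List[DomainAnnotation] = []
        for cds_id in chain:
            seq.extend(per_cds[cds_id])
        mods, rest = assemble_domain_sequence(seq)
        modules.extend(mods)
        unassigned.extend(rest)
    return modules, unassigned


def assign_monomer(module: Module, signature_table: Mapping[str, str]) -> str:
    """Look up the module's A/AT-domain peptide in the signature table.

    Exact match only; a miss (or a selection domain with no extracted
    peptide) returns ``"?"``.  Calling this on an incomplete module is a
    contract violation.
    """
    if not module.complete:
        raise ValueError("assign_monomer requires a complete module")
    for dom in module.components:
        if dom.domain_class in ("A", "AT") and dom.peptide:
            return signature_table.get(dom.peptide, "?")
    return "?"


def annotate_monomers(modules: Iterable[Module],
                      signature_table: Mapping[str, str]) -> None:
    """Set ``monomer`` in place on every complete module."""
    for m in modules:
        if m.complete:
            m.monomer = assign_monomer(m, signature_table)
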