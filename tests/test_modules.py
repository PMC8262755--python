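import random

import pytest

from bgcmine.core import ProfileHit
from bgcmine.modules import (DOMAIN_CLASSES, DomainAnnotation, Module,
                             assemble_domain_sequence, assemble_modules,
                             assign_monomer, classify_domains,
                             load_domain_mapping, load_monomer_table)

from .conftest import make_record

MAPPING = load_domain_mapping()


def domains(classes, cds_id="g1", start=0):
    return [DomainAnnotation(cds_id, cls, start + i * 100, start + i * 100 + 80)
            for i, cls in enumerate(classes)]


def structures(modules):
    return [(tuple(m.domain_classes), m.module_type, m.complete)
            for m in modules]


# --------------------------------------------------------------------------
# Domain classification


def test_classify_domains_orders_and_maps():
    hits = [ProfileHit("g1", "PP-binding-ish-unknown", 30.0, 0.0, 900, 980),
            ProfileHit("g1", "PKS_KS", 300.0, 0.0, 10, 440),
            ProfileHit("g1", "PKS_AT", 200.0, 0.0, 500, 800)]
    per_cds = classify_domains(hits, MAPPING)
    assert [d.domain_class for d in per_cds["g1"]] == ["KS", "AT", "other"]


def test_classify_domains_empty():
    assert classify_domains([], MAPPING) == {}


def test_classify_domains_extracts_peptides():
    hits = [ProfileHit("g1", "A_gly", 30.0, 0.0, 2, 6)]
    per_cds = classify_domains(hits, MAPPING, {"g1": "MKWXYZAAA"})
    assert per_cds["g1"][0].peptide == "WXYZ"


# --------------------------------------------------------------------------
# Module grammar on one protein


def test_two_pks_modules_with_modification():
    mods, rest = assemble_domain_sequence(
        domains(["KS", "AT", "KR", "ACP", "KS", "AT", "ACP"]))
    assert structures(mods) == [
        (("KS", "AT", "KR", "ACP"), "pks", True),
        (("KS", "AT", "ACP"), "pks", True)]
    assert rest == []


def test_trans_at_module_closes_without_at():
    mods, _ = assemble_domain_sequence(domains(["KS", "KR", "ACP"]))
    assert structures(mods) == [(("KS", "KR", "ACP"), "trans-at-pks", True)]


def test_nrps_module_and_te_attachment():
    mods, _ = assemble_domain_sequence(
        domains(["C", "A", "PCP", "C", "A", "PCP", "TE"]))
    assert structures(mods) == [
        (("C", "A", "PCP"), "nrps", True),
        (("C", "A", "PCP", "TE"), "nrps", True)]


def test_loading_module_only_opens_at_line_start():
    mods, rest = assemble_domain_sequence(domains(["A", "PCP", "A", "PCP"]))
    # first A-PCP is a loading module; a later bare A cannot open a module
    assert structures(mods) == [(("A", "PCP"), "nrps", True)]
    assert [d.domain_class for d in rest] == ["A", "PCP"]


def test_open_module_at_end_is_incomplete():
    mods, _ = assemble_domain_sequence(domains(["C", "A"]))
    assert structures(mods) == [(("C", "A"), "nrps", False)]
    assert not mods[0].split


def test_unassigned_domains_are_conserved():
    seq = domains(["KR", "KS", "AT", "ACP", "other", "MT"])
    mods, rest = assemble_domain_sequence(seq)
    total = sum(len(m.components) for m in mods) + len(rest)
    assert total == len(seq)
    assert [d.domain_class for d in rest] == ["KR", "other", "MT"]


def test_no_module_has_two_carriers():
    rng = random.Random(7)
    for _ in range(200):
        classes = rng.choices([c for c in DOMAIN_CLASSES], k=rng.randint(1, 15))
        mods, _ = assemble_domain_sequence(domains(classes))
        for m in mods:
            carriers = [c for c in m.domain_classes if c in ("PCP", "ACP")]
            assert len(carriers) <= 1


# --------------------------------------------------------------------------
# Split modules across CDSs


def split_record(classes, split_at, gap=500, strand2=1, intervening=False):
    """Two CDSs holding classes[:split_at] and classes[split_at:]."""
    cds1_end = 10000
    specs = [("g1", 1000, cds1_end, 1, "M" * 3000)]
    nxt = cds1_end + gap
    if intervening:
        specs.append(("mid", nxt, nxt + 300, 1, "M" * 90))
        nxt += 600
    specs.append(("g2", nxt, nxt + 9000, strand2, "M" * 2900))
    record = make_record(specs)
    per_cds = {}
    if split_at > 0:
        per_cds["g1"] = domains(classes[:split_at], "g1")
    if split_at < len(classes):
        per_cds["g2"] = domains(classes[split_at:], "g2")
    if intervening:
        per_cds["mid"] = domains(["other"], "mid")
    return record, per_cds


def test_split_module_merges_across_adjacent_cds():
    classes = ["KS", "AT", "KR", "ACP", "KS", "AT", "ACP"]
    record, per_cds = split_record(classes, split_at=2)  # split inside module 1
    mods, _ = assemble_modules(per_cds, record)
    ref_mods, _ = assemble_domain_sequence(domains(classes))
    assert structures(mods) == structures(ref_mods)
    assert [m.split for m in mods] == [True, False]
    assert mods[0].cds_ids == ["g1", "g2"]


def test_split_requires_same_strand():
    classes = ["KS", "AT", "KR", "ACP"]
    record, per_cds = split_record(classes, split_at=2, strand2=-1)
    mods, _ = assemble_modules(per_cds, record)
    assert all(not m.complete for m in mods)
    assert all(not m.split for m in mods)


def test_split_requires_small_gap():
    classes = ["KS", "AT", "KR", "ACP"]
    record, per_cds = split_record(classes, split_at=2, gap=5000)
    mods, _ = assemble_modules(per_cds, record)
    assert all(not m.split for m in mods)


def test_split_blocked_by_intervening_cds():
    classes = ["KS", "AT", "KR", "ACP"]
    record, per_cds = split_record(classes, split_at=2, intervening=True)
    mods, _ = assemble_modules(per_cds, record)
    assert all(not m.split for m in mods)


@pytest.mark.parametrize("seed", range(30))
def test_concatenation_equivalence_random_strings(seed):
    """Cross-CDS assembly equals assembly on the concatenated domain string."""
    rng = random.Random(seed)
    classes = rng.choices(
        ["C", "A", "PCP", "KS", "AT", "KR", "DH", "ER", "MT", "ACP", "TE", "E"],
        k=rng.randint(2, 14))
    split_at = rng.randint(0, len(classes))
    record, per_cds = split_record(classes, split_at)
    mods, rest = assemble_modules(per_cds, record)
    ref_mods, ref_rest = assemble_domain_sequence(domains(classes))
    assert structures(mods) == structures(ref_mods)
    assert [d.domain_class for d in rest] == [d.domain_class for d in ref_rest]
    # conservation across the whole assembly
    assert sum(len(m.components) for m in mods) + len(rest) == len(classes)


# --------------------------------------------------------------------------
# Monomer assignment


MONOMERS = load_monomer_table()


def complete_module(selection_class, peptide):
    comps = [DomainAnnotation("g1", "KS", 0, 80),
             DomainAnnotation("g1", selection_class, 100, 180, peptide=peptide),
             DomainAnnotation("g1", "ACP", 200, 280)]
    return Module(comps, "pks", True, False)


def test_assign_monomer_lookups(catalogue):
    mal_sig = catalogue["AT_mal"].signature
    assert assign_monomer(complete_module("AT", mal_sig), MONOMERS) == "mal"
    gly_sig = catalogue["A_gly"].signature
    nrps = Module([DomainAnnotation("g1", "C", 0, 80),
                   DomainAnnotation("g1", "A", 100, 180, peptide=gly_sig),
                   DomainAnnotation("g1", "PCP", 200, 280)], "nrps", True, False)
    assert assign_monomer(nrps, MONOMERS) == "gly"


def test_assign_monomer_unknown_signature():
    assert assign_monomer(complete_module("AT", "WNOTINTABLE"), MONOMERS) == "?"


def test_assign_monomer_rejects_incomplete():
    incomplete = Module([DomainAnnotation("g1", "KS", 0, 80)], "pks", False, False)
    with pytest.raises(ValueError):
        assign_monomer(incomplete, MONOMERS)
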