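"""Sideloading: merging external cluster predictions into detection output.

External predictors (e.g. machine-learning cluster finders) can hand their
results to this package as a JSON document; validated documents contribute
protoclusters and subregions that are then treated exactly like native
detections, including region building and downstream analyses.

Document shape (all coordinates 0-based half-open; see
``data/sideload.schema.json`` for the machine-readable schema)::

    {
      "tool": {"name": ..., "version": ..., "description": ...},
      "records": [
        {"record_id": ...,
         "subregions": [{"start", "end", "label", "details"}],
         "protoclusters": [{"core_start", "core_end",
                            "neighbourhood_start", "neighbourhood_end",
                            "product", "details"}]}
      ]
    }
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence

from .core import GenomeRecord, Protocluster, Region, SubRegion, overlaps
from .rules import build_regions

logger = logging.getLogger(__name__)

_TOP_LEVEL_KEYS = {"tool", "records"}
_TOOL_KEYS = {"name", "version", "description"}
_RECORD_KEYS = {"record_id", "subregions", "protoclusters"}
_SUBREGION_KEYS = {"start", "end", "label", "details"}
_PROTO_KEYS = {"core_start", "core_end", "neighbourhood_start",
               "neighbourhood_end", "product", "details"}


class SideloadSchemaError(ValueError):
    """The document violates the sideload schema."""


class SideloadCoordinateError(ValueError):
    """An interval in the document is malformed; names record and index."""


@dataclass(frozen=True)
class SideloadTool:
    name: str
    version: str
    description: str = ""


@dataclass(frozen=True)
class SideloadSubregion:
    start: int
    end: int
    label: str
    details: Mapping[str, object] = field(default_factory=dict)


@dataclass(frozen=True)
class SideloadProtocluster:
    core_start: int
    core_end: int
    neighbourhood_start: int
    neighbourhood_end: int
    product: str
    details: Mapping[str, object] = field(default_factory=dict)


@dataclass(frozen=True)
class SideloadRecord:
    record_id: str
    subregions: tuple = ()
    protoclusters: tuple = ()


@dataclass(frozen=True)
class SideloadDocument:
    tool: SideloadTool
    records: tuple = ()


def _require(condition: bool, exc_type, message: str) -> None:
    if not condition:
        raise exc_type(message)


def _check_details(details: object, where: str) -> Dict[str, object]:
    if details is None:
        return {}
    _require(isinstance(details, dict), SideloadSchemaError,
             f"{where}: details must be an object")
    for key, value in details.items():
        ok = isinstance(value, str) or (
            isinstance(value, list) and all(isinstance(v, str) for v in value))
        _require(ok, SideloadSchemaError,
                 f"{where}: details[{key!r}] must be a string or list of strings")
    return dict(details)


def validate_sideload(document: object) -> SideloadDocument:
    """Validate a parsed JSON document into a SideloadDocument.

    Unknown top-level keys are rejected; coordinate errors name the
    offending record and feature index.
    """
    _require(isinstance(document, dict), SideloadSchemaError,
             "document must be a JSON object")
    unknown = set(document) - _TOP_LEVEL_KEYS
    _require(not unknown, SideloadSchemaError,
             f"unknown top-level keys: {sorted(unknown)}")
    _require("tool" in document, SideloadSchemaError, 'missing required key "tool"')
    tool_raw = document["tool"]
    _require(isinstance(tool_raw, dict), SideloadSchemaError, "tool must be an object")
    _require(not set(tool_raw) - _TOOL_KEYS, SideloadSchemaError,
             f"unknown tool keys: {sorted(set(tool_raw) - _TOOL_KEYS)}")
    for key in ("name", "version"):
        _require(isinstance(tool_raw.get(key), str) and tool_raw[key],
                 SideloadSchemaError, f"tool.{key} must be a non-empty string")
    tool = SideloadTool(tool_raw["name"], tool_raw["version"],
                        tool_raw.get("description", ""))

    records = []
    for r_idx, rec in enumerate(document.get("records", [])):
        _require(isinstance(rec, dict), SideloadSchemaError,
                 f"records[{r_idx}] must be an object")
        _require(not set(rec) - _RECORD_KEYS, SideloadSchemaError,
                 f"records[{r_idx}]: unknown keys {sorted(set(rec) - _RECORD_KEYS)}")
        record_id = rec.get("record_id")
        _require(isinstance(record_id, str) and record_id, SideloadSchemaError,
                 f"records[{r_idx}].record_id must be a non-empty string")
        subregions = []
        for s_idx, sub in enumerate(rec.get("subregions", [])):
            where = f"record {record_id!r} subregion {s_idx}"
            _require(isinstance(sub, dict), SideloadSchemaError,
                     f"{where}: must be an object")
            _require(not set(sub) - _SUBREGION_KEYS, SideloadSchemaError,
                     f"{where}: unknown keys {sorted(set(sub) - _SUBREGION_KEYS)}")
            for key in ("start", "end"):
                _require(isinstance(sub.get(key), int) and not isinstance(sub[key], bool),
                         SideloadSchemaError, f"{where}: {key} must be an integer")
            _require(sub["start"] >= 0, SideloadCoordinateError,
                     f"{where}: start {sub['start']} is negative")
            _require(sub["start"] < sub["end"], SideloadCoordinateError,
                     f"{where}: end {sub['end']} <= start {sub['start']}")
            _require(isinstance(sub.get("label"), str) and sub["label"],
                     SideloadSchemaError, f"{where}: label must be a non-empty string")
            subregions.append(SideloadSubregion(
                sub["start"], sub["end"], sub["label"],
                _check_details(sub.get("details"), where)))
        protoclusters = []
        for p_idx, proto in enumerate(rec.get("protoclusters", [])):
            where = f"record {record_id!r} protocluster {p_idx}"
            _require(isinstance(proto, dict), SideloadSchemaError,
                     f"{where}: must be an object")
            _require(not set(proto) - _PROTO_KEYS, SideloadSchemaError,
                     f"{where}: unknown keys {sorted(set(proto) - _PROTO_KEYS)}")
            for key in ("core_start", "core_end",
                        "neighbourhood_start", "neighbourhood_end"):
                _require(isinstance(proto.get(key), int)
                         and not isinstance(proto[key], bool),
                         SideloadSchemaError, f"{where}: {key} must be an integer")
            _require(proto["neighbourhood_start"] >= 0, SideloadCoordinateError,
                     f"{where}: neighbourhood_start is negative")
            _require(proto["core_start"] < proto["core_end"],
                     SideloadCoordinateError,
                     f"{where}: core_end <= core_start")
            _require(proto["neighbourhood_start"] <= proto["core_start"]
                     and proto["core_end"] <= proto["neighbourhood_end"],
                     SideloadCoordinateError,
                     f"{where}: neighbourhood must contain the core")
            _require(isinstance(proto.get("product"), str) and proto["product"],
                     SideloadSchemaError, f"{where}: product must be a non-empty string")
            protoclusters.append(SideloadProtocluster(
                proto["core_start"], proto["core_end"],
                proto["neighbourhood_start"], proto["neighbourhood_end"],
                proto["product"], _check_details(proto.get("details"), where)))
        records.append(SideloadRecord(record_id, tuple(subregions),
                                      tuple(protoclusters)))
    return SideloadDocument(tool, tuple(records))


def load_sideload(path) -> SideloadDocument:
    with open(path) as fh:
        try:
            raw = json.load(fh)
        except json.JSONDecodeError as exc:
            raise SideloadSchemaError(f"{path}: not valid JSON: {exc}") from None
    return validate_sideload(raw)


def serialize_sideload(doc: SideloadDocument) -> dict:
    """Serialize back to the JSON document shape (round-trip safe)."""
    return {
        "tool": {"name": doc.tool.name, "version": doc.tool.version,
                 "description": doc.tool.description},
        "records": [
            {"record_id": rec.record_id,
             "subregions": [
                 {"start": s.start, "end": s.end, "label": s.label,
                  "details": dict(s.details)} for s in rec.subregions],
             "protoclusters": [
                 {"core_start": p.core_start, "core_end": p.core_end,
                  "neighbourhood_start": p.neighbourhood_start,
                  "neighbourhood_end": p.neighbourhood_end,
                  "product": p.product, "details": dict(p.details)}
                 for p in rec.protoclusters]}
            for rec in doc.records],
    }


def _dedup_key(proto: Protocluster):
    return (proto.tool, proto.core_start, proto.core_end,
            proto.neighbourhood_start, proto.neighbourhood_end, proto.product)


def _sub_dedup_key(sub: SubRegion):
    return (sub.tool, sub.start, sub.end, sub.label)


def merge_sideload(records: Sequence[GenomeRecord],
                   detected: Mapping[str, Sequence[Region]],
                   doc: SideloadDocument) -> Dict[str, List[Region]]:
    """Merge a validated sideload document into per-record region lists.

    Sideloaded protoclusters re-enter region building exactly like native
    ones; subregions overlapping no region become their own regions.
    Records named in the document but absent from the input are skipped with
    a warning.  Merging is idempotent: features already present (same tool,
    coordinates, and product/label) are not duplicated.
    """
    by_id = {r.record_id: r for r in records}
    merged: Dict[str, List[Region]] = {rid: list(regs) for rid, regs in detected.items()}
    for sl_record in doc.records:
        if sl_record.record_id not in by_id:
            logger.warning("sideload document names unknown record %r; skipped",
                           sl_record.record_id)
            continue
        record = by_id[sl_record.record_id]
        existing_regions = merged.get(sl_record.record_id, [])
        protos: List[Protocluster] = []
        subs: List[SubRegion] = []
        for region in existing_regions:
            protos.extend(region.protoclusters)
            subs.extend(region.subregions)
        seen_protos = {_dedup_key(p) for p in protos}
        seen_subs = {_sub_dedup_key(s) for s in subs}
        for p in sl_record.protoclusters:
            core_cds = [c.cds_id for c in record.cds_in(p.core_start, p.core_end)]
            if not core_cds:
                logger.warning("sideloaded protocluster %s[%d:%d] covers no CDS; "
                               "kept as subregion", sl_record.record_id,
                               p.core_start, p.core_end)
                sub = SubRegion(p.neighbourhood_start, p.neighbourhood_end,
                                p.product, doc.tool.name, dict(p.details))
                if _sub_dedup_key(sub) not in seen_subs:
                    subs.append(sub)
                    seen_subs.add(_sub_dedup_key(sub))
                continue
            n_start, core_start = min(p.neighbourhood_start, p.core_start), p.core_start
            proto = Protocluster(
                product=p.product, category="other",
                core_start=core_start, core_end=p.core_end,
                neighbourhood_start=n_start,
                neighbourhood_end=max(p.neighbourhood_end, p.core_end),
                core_cds_ids=frozenset(core_cds),
                rule_name=f"sideload:{doc.tool.name}",
                tool=doc.tool.name)
            if _dedup_key(proto) not in seen_protos:
                protos.append(proto)
                seen_protos.add(_dedup_key(proto))
        for s in sl_record.subregions:
            sub = SubRegion(s.start, s.end, s.label, doc.tool.name,
                            dict(s.details))
            if _sub_dedup_key(sub) not in seen_subs:
                subs.append(sub)
                seen_subs.add(_sub_dedup_key(sub))
        merged[sl_record.record_id] = build_regions(protos, record, subs)
    return merged
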