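"""Rewrite bibliographic graphs into SIO/Bio2RDF-compatible graphs.

The rewrite is driven by an editable mapping table rather than code:
type-assertions whose class is mapped are re-typed, statements whose
predicate is mapped are re-predicated, and everything else passes through
unchanged with a logged note.  Rewrites are strictly 1:1, so the output
has exactly as many statements as the input.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

from rdflib import Graph, URIRef
from rdflib.namespace import RDF

from . import rdfizer
from .vocab import bind_prefixes

logger = logging.getLogger(__name__)

_RDF_NS = str(RDF)

KINDS = ("class", "objprop", "dataprop", "passthrough")


class MappingError(ValueError):
    pass


@dataclass
class MappingTable:
    class_map: dict = field(default_factory=dict)
    objprop_map: dict = field(default_factory=dict)
    dataprop_map: dict = field(default_factory=dict)
    passthrough: set = field(default_factory=set)

    def __post_init__(self) -> None:
        seen: dict = {}
        conflicts = []
        for kind, mapping in (("class", self.class_map),
                              ("objprop", self.objprop_map),
                              ("dataprop", self.dataprop_map)):
            for src in mapping:
                if src in seen or src in self.passthrough:
                    conflicts.append(src)
                seen[src] = kind
        overlap = self.passthrough & set(seen)
        conflicts.extend(overlap)
        if conflicts:
            raise MappingError(f"source IRIs mapped more than once: {sorted(set(conflicts))}")

    def property_target(self, predicate: str) -> Optional[str]:
        return self.objprop_map.get(predicate) or self.dataprop_map.get(predicate)

    def coverage_gap(self) -> dict:
        """Emitted classes/properties absent from every map and the
        passthrough list (rdf container-membership is structural and
        always passes through)."""
        known = (set(self.class_map) | set(self.objprop_map)
                 | set(self.dataprop_map) | self.passthrough)
        missing_classes = {str(c) for c in rdfizer.EMITTED_CLASSES} - known
        missing_props = {str(p) for p in rdfizer.EMITTED_PROPERTIES
                         if str(p) not in known and not _is_membership(str(p))}
        return {"classes": sorted(missing_classes), "properties": sorted(missing_props)}


def _is_membership(iri: str) -> bool:
    return iri.startswith(_RDF_NS + "_")


def load_mapping(lines) -> MappingTable:
    """Load a mapping TSV (source IRI, target IRI or '-', kind); duplicate
    source IRIs are rejected with the conflicting entries listed."""
    class_map: dict = {}
    objprop_map: dict = {}
    dataprop_map: dict = {}
    passthrough: set = set()
    rows = 0
    for ln in lines:
        ln = ln.rstrip("\n")
        if not ln.strip() or ln.lstrip().startswith("#"):
            continue
        cols = ln.split("\t")
        if len(cols) != 3:
            raise MappingError(f"mapping row needs 3 columns: {ln!r}")
        src, target, kind = (c.strip() for c in cols)
        if kind not in KINDS:
            raise MappingError(f"unknown mapping kind {kind!r} for {src}")
        rows += 1
        if kind == "passthrough":
            passthrough.add(src)
        else:
            {"class": class_map, "objprop": objprop_map,
             "dataprop": dataprop_map}[kind][src] = target
    table = MappingTable(class_map=class_map, objprop_map=objprop_map,
                         dataprop_map=dataprop_map, passthrough=passthrough)
    if rows != (len(class_map) + len(objprop_map) + len(dataprop_map) + len(passthrough)):
        raise MappingError("duplicate source IRIs within one mapping kind")
    gap = table.coverage_gap()
    if gap["classes"] or gap["properties"]:
        logger.warning("mapping coverage gap: %s", gap)
    return table


def default_mapping() -> MappingTable:
    text = resources.files("biotea.data").joinpath("sio_mapping.tsv").read_text("utf-8")
    return load_mapping(text.splitlines())


def map_to_sio(graph: Graph, table: Optional[MappingTable] = None) -> Graph:
    """Rewrite one graph through the table; |output| == |input|."""
    table = table or default_mapping()
    out = Graph()
    bind_prefixes(out)
    for s, p, o in graph:
        p_str = str(p)
        if p == RDF.type and str(o) in table.class_map:
            out.add((s, p, URIRef(table.class_map[str(o)])))
            continue
        target = table.property_target(p_str)
        if target is not None:
            out.add((s, URIRef(target), o))
            continue
        if p_str in table.passthrough or _is_membership(p_str):
            out.add((s, p, o))
            continue
        logger.info("passing through unmapped predicate %s", p_str)
        out.add((s, p, o))
    return out
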