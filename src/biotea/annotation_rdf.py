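"""Serialize annotations to RDF in the Annotation Ontology layout, with
literal-targeting selectors.

Two selector variants exist: an exact-text selector (ELEMENT) and an
offset selector (START_END) that adds 1-based inclusive start/end
positions.  Both point at the single content literal of the annotated
node — the property whose object is that literal (``cnt:chars``) must be
used only once on the node, which is what makes the exact/offset pair an
unambiguous address.  Offset-route annotations get START_END selectors;
exact-text-route annotations get ELEMENT selectors.
"""
from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timezone
from enum import Enum
from typing import Optional
from urllib.parse import unquote

from rdflib import Graph, Literal, URIRef
from rdflib.namespace import OWL, RDF, RDFS, XSD

from .annotator import Annotation, TermMatch
from .registry import VocabularyRegistry
from .uris import UriPolicy
from .vocab import AO_ROLES, CNT, FOAF, bind_prefixes


class SelectorVariant(Enum):
    ELEMENT = "element"
    START_END = "start_end"


class SelectorError(ValueError):
    pass


@dataclass(frozen=True)
class Selector:
    variant: SelectorVariant
    exact: str
    start: Optional[int]
    end: Optional[int]
    target_node: str  # IRI of the node holding the content literal
    target_property: str = str(CNT.chars)  # occurs exactly once on the node

    def __post_init__(self) -> None:
        if self.variant is SelectorVariant.START_END:
            if self.start is None or self.end is None:
                raise SelectorError("START_END selector needs start and end")
            if self.end - self.start + 1 != len(self.exact):
                raise SelectorError(
                    f"end - start + 1 = {self.end - self.start + 1} but exact "
                    f"text has {len(self.exact)} code points")


@dataclass(frozen=True)
class AnnotationProvenance:
    agent: str  # annotator agent IRI
    created: datetime


def make_selector(match: TermMatch, mode: SelectorVariant) -> Selector:
    """Build a selector for one occurrence; the START_END variant keeps the
    1-based inclusive positions and enforces the length identity."""
    if mode is SelectorVariant.START_END:
        if match.start is None:
            raise SelectorError("occurrence has no positions for a START_END selector")
        return Selector(variant=mode, exact=match.surface, start=match.start,
                        end=match.end, target_node=match.paragraph_ref)
    return Selector(variant=mode, exact=match.surface, start=None, end=None,
                    target_node=match.paragraph_ref)


def selector_variant_for_route(route: str) -> SelectorVariant:
    return SelectorVariant.START_END if route == "ncbo_like" else SelectorVariant.ELEMENT


def annotation_to_triples(ann: Annotation, selectors: list[Selector],
                          prov: AnnotationProvenance,
                          policy: Optional[UriPolicy] = None) -> list[tuple]:
    """Statements for one annotation node: document link, term body, one
    selector per occurrence, one topic per entity, related entities, and
    provenance (agent + creation date)."""
    policy = policy or UriPolicy()
    if len(selectors) != len(ann.occurrences):
        raise SelectorError(
            f"{len(ann.occurrences)} occurrences but {len(selectors)} selectors")
    lid = unquote(ann.document.rsplit("/", 1)[-1])
    node = policy.mint("annotation", [lid, ann.annotator_id, ann.term])
    stmts: list[tuple] = [
        (node, RDF.type, AO_ROLES["annotation_class"]),
        (node, AO_ROLES["annotates"], URIRef(ann.document)),
        (node, AO_ROLES["body"], Literal(ann.term)),
        (node, AO_ROLES["creator"], URIRef(prov.agent)),
        (URIRef(prov.agent), RDF.type, FOAF.Agent),
        (node, AO_ROLES["created"],
         Literal(prov.created.isoformat(), datatype=XSD.dateTime)),
    ]
    for i, sel in enumerate(selectors):
        sel_iri = policy.mint(
            "selector", [lid, ann.annotator_id, ann.term, str(i)])
        cls = (AO_ROLES["start_end_selector"]
               if sel.variant is SelectorVariant.START_END
               else AO_ROLES["element_selector"])
        stmts.append((node, AO_ROLES["context"], sel_iri))
        stmts.append((sel_iri, RDF.type, cls))
        stmts.append((sel_iri, AO_ROLES["exact"], Literal(sel.exact)))
        stmts.append((sel_iri, AO_ROLES["on_element"], URIRef(sel.target_node)))
        stmts.append((sel_iri, AO_ROLES["on_property"], URIRef(sel.target_property)))
        if sel.variant is SelectorVariant.START_END:
            stmts.append((sel_iri, AO_ROLES["start"],
                          Literal(sel.start, datatype=XSD.integer)))
            stmts.append((sel_iri, AO_ROLES["end"],
                          Literal(sel.end, datatype=XSD.integer)))
    for entity, _vocab in sorted(ann.entities):
        stmts.append((node, AO_ROLES["topic"], URIRef(entity)))
    for entity in sorted(ann.related):
        stmts.append((node, AO_ROLES["related_topic"], URIRef(entity)))
    return stmts


def external_entity_iris(entity: tuple, registry: VocabularyRegistry) -> dict:
    """sameAs / seeAlso link sets for one (entity IRI, vocabulary) pair.

    sameAs links come from the Bio2RDF and identifiers.org templates of the
    seven linked vocabularies; every vocabulary with a topic-page template
    yields a seeAlso link.  Unlinked vocabularies get an empty sameAs set.
    """
    entity_iri, vocab = entity
    rec = registry[vocab]
    local = rec.local_id(entity_iri)
    sameas = set()
    if rec.bio2rdf_linked:
        if rec.identifiersorg_template:
            sameas.add(rec.identifiersorg_template.format(id=local))
        if rec.bio2rdf_template:
            sameas.add(rec.bio2rdf_template.format(id=local))
    seealso = set()
    if rec.seealso_template:
        seealso.add(rec.seealso_template.format(id=local))
    return {"sameas": sameas, "seealso": seealso}


def annotations_to_graph(annotations: list[Annotation],
                         registry: VocabularyRegistry,
                         policy: Optional[UriPolicy] = None,
                         agent: Optional[str] = None,
                         created: Optional[datetime] = None) -> Graph:
    """One annotation graph for a document: annotation nodes, selectors,
    provenance, plus owl:sameAs / rdfs:seeAlso links for every entity."""
    policy = policy or UriPolicy()
    g = Graph()
    bind_prefixes(g)
    for ann in annotations:
        mode = selector_variant_for_route(ann.annotator_id)
        selectors = [make_selector(m, mode) for m in ann.occurrences]
        prov = AnnotationProvenance(
            agent=agent or str(policy.mint("agent", [ann.annotator_id])),
            created=created or ann.created or datetime.now(timezone.utc),
        )
        for stmt in annotation_to_triples(ann, selectors, prov, policy):
            g.add(stmt)
        for pair in ann.entities:
            links = external_entity_iris(pair, registry)
            for iri in links["sameas"]:
                g.add((URIRef(pair[0]), OWL.sameAs, URIRef(iri)))
            for iri in links["seealso"]:
                g.add((URIRef(pair[0]), RDFS.seeAlso, URIRef(iri)))
    return g


def parse_annotation_graph(g: Graph,
                           registry: Optional[VocabularyRegistry] = None) -> list[Annotation]:
    """Recover Annotation records from an emitted annotation graph.

    START_END selectors yield occurrences with positions; ELEMENT selectors
    yield position-less occurrences (the exact text only).
    """
    annotations = []
    for node in sorted(g.subjects(RDF.type, AO_ROLES["annotation_class"])):
        document = str(next(g.objects(node, AO_ROLES["annotates"])))
        term = str(next(g.objects(node, AO_ROLES["body"])))
        created_lit = next(g.objects(node, AO_ROLES["created"]), None)
        created = (datetime.fromisoformat(str(created_lit))
                   if created_lit is not None else None)
        route = _route_from_iri(str(node))
        occurrences = []
        for sel in sorted(g.objects(node, AO_ROLES["context"])):
            exact = str(next(g.objects(sel, AO_ROLES["exact"])))
            target = str(next(g.objects(sel, AO_ROLES["on_element"])))
            start_lit = next(g.objects(sel, AO_ROLES["start"]), None)
            end_lit = next(g.objects(sel, AO_ROLES["end"]), None)
            occurrences.append(TermMatch(
                surface=exact,
                start=int(start_lit) if start_lit is not None else None,
                end=int(end_lit) if end_lit is not None else None,
                paragraph_ref=target,
            ))
        occurrences.sort(key=lambda m: (m.paragraph_ref, m.start or 0))
        topics = {str(o) for o in g.objects(node, AO_ROLES["topic"])}
        related = {str(o) for o in g.objects(node, AO_ROLES["related_topic"])}

        def vocab_of(iri: str) -> str:
            return (registry.vocabulary_of(iri) or "") if registry else ""

        annotations.append(Annotation(
            document=document,
            term=term,
            annotator_id=route,
            entities=frozenset((t, vocab_of(t)) for t in topics),
            occurrences=occurrences,
            related=frozenset(related),
            created=created,
        ))
    return annotations


def _route_from_iri(node_iri: str) -> str:
    frag = node_iri.split("#", 1)[-1]  # annotation-<route>-<term>...
    for route in ("ncbo_like", "whatizit_like"):
        if frag.startswith(f"annotation-{route}-"):
            return route
    return "unknown"
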