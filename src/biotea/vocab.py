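"""Namespace bindings for every vocabulary the RDFizer and annotator emit.

The annotation vocabulary uses the Annotation Ontology layout (annotation
node, body, context/selector, topic, provenance).  The original AO
namespaces are no longer served, so the concrete predicate IRIs are pinned
here in one table; swapping the table re-targets the whole annotation
output (e.g. onto the W3C Web Annotation vocabulary) without touching the
serializer.
"""
from __future__ import annotations

from rdflib import Namespace
from rdflib.namespace import OWL, RDF, RDFS, XSD  # re-exported for convenience

BIBO = Namespace("http://purl.org/ontology/bibo/")
DCTERMS = Namespace("http://purl.org/dc/terms/")
FOAF = Namespace("http://xmlns.com/foaf/0.1/")
DOCO = Namespace("http://purl.org/spar/doco/")
CNT = Namespace("http://www.w3.org/2011/content#")
PROV = Namespace("http://www.w3.org/ns/prov#")
SIO = Namespace("http://semanticscience.org/resource/")

# Annotation Ontology core + selectors, and the offset-selector extension
# namespace used for literal-targeted selectors.
AO = Namespace("http://purl.org/ao/core/")
AOS = Namespace("http://purl.org/ao/selectors/")
AOLD = Namespace("http://biotea.ws/ontologies/aold/")

#: prefix -> namespace; total over everything the package serializes.
PREFIXES = {
    "rdf": RDF,
    "rdfs": RDFS,
    "owl": OWL,
    "xsd": XSD,
    "bibo": BIBO,
    "dcterms": DCTERMS,
    "foaf": FOAF,
    "doco": DOCO,
    "cnt": CNT,
    "prov": PROV,
    "ao": AO,
    "aos": AOS,
    "aold": AOLD,
    "sio": SIO,
}

#: Pinned annotation predicate/class roles (see module docstring).
AO_ROLES = {
    "annotation_class": AO["Annotation"],
    "annotates": AO["annotatesResource"],
    "body": AO["body"],
    "context": AO["context"],
    "topic": AO["hasTopic"],
    "related_topic": AOLD["hasRelatedTopic"],
    "element_selector": AOLD["ElementSelector"],
    "start_end_selector": AOLD["StartEndElementSelector"],
    "exact": AOS["exact"],
    "start": AOLD["start"],
    "end": AOLD["end"],
    "on_element": AOLD["onElement"],
    "on_property": AOLD["onProperty"],
    "created": DCTERMS["created"],
    "creator": DCTERMS["creator"],
}


def bind_prefixes(graph) -> None:
    """Bind the full prefix table onto an rdflib Graph."""
    for prefix, ns in PREFIXES.items():
        graph.bind(prefix, ns, replace=True)
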