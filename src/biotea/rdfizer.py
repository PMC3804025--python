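"""Map an ArticleDocument onto the multi-vocabulary bibliographic RDF graph.

Bibliographic metadata uses BIBO and DCMI Terms, document structure DoCO
(sections, paragraphs) with CNT content literals, people and organizations
FOAF, and provenance both PROV-O and DCMI Terms.  Every content-bearing
resource gets a deterministic HTTP IRI (see :mod:`biotea.uris`) so that
annotations can target paragraphs by reference; each paragraph node carries
exactly one ``cnt:chars`` literal.
"""
from __future__ import annotations

import logging
from datetime import datetime, timezone
from typing import Callable, Optional
from urllib.parse import unquote

from rdflib import Graph, Literal, URIRef
from rdflib.namespace import OWL, RDF, RDFS, XSD

from .model import ArticleDocument, Reference, Section
from .uris import UriPolicy
from .vocab import BIBO, CNT, DCTERMS, DOCO, FOAF, PROV, bind_prefixes

logger = logging.getLogger(__name__)

#: Classes the RDFizer can emit; the SIO mapping table must cover all of them.
EMITTED_CLASSES = frozenset({
    BIBO.Document, BIBO.AcademicArticle, BIBO.Journal,
    DOCO.Section, DOCO.Abstract, DOCO.Paragraph,
    CNT.ContentAsText, FOAF.Person, FOAF.Organization, RDF.Seq,
})

#: Properties the RDFizer can emit (rdf:type and the rdf:_n container
#: membership properties are structural and handled as passthrough).
EMITTED_PROPERTIES = frozenset({
    DCTERMS.title, DCTERMS.identifier, DCTERMS.subject, DCTERMS.isPartOf,
    DCTERMS.hasPart, DCTERMS.publisher, DCTERMS.created, DCTERMS.creator,
    DCTERMS.source, DCTERMS.date, DCTERMS.bibliographicCitation,
    DCTERMS.license,
    BIBO.pmid, BIBO.doi, BIBO.issn, BIBO.volume, BIBO.issue,
    BIBO.pageStart, BIBO.pageEnd, BIBO.pages, BIBO.authorList,
    BIBO.cites, BIBO.citedBy,
    FOAF.surname, FOAF.givenName, FOAF.name, FOAF.mbox, FOAF.member,
    CNT.chars,
    PROV.generatedAtTime, PROV.wasAttributedTo,
    OWL.sameAs, RDFS.seeAlso, RDFS.comment,
})


def serialize_graph(graph: Graph, dialect: str = "turtle") -> bytes:
    """Serialize to Turtle or RDF/XML; the output parses back isomorphic."""
    formats = {"turtle": "turtle", "rdfxml": "xml"}
    if dialect not in formats:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {sorted(formats)}")
    return graph.serialize(format=formats[dialect], encoding="utf-8")


def rdfize_article(doc: ArticleDocument, policy: Optional[UriPolicy] = None,
                   created: Optional[datetime] = None) -> Graph:
    """Build the full bibliographic/section/content graph for one article."""
    policy = policy or UriPolicy()
    created = created or datetime.now(timezone.utc)
    g = Graph()
    bind_prefixes(g)

    lid = doc.local_id
    article = policy.mint("article", [lid])
    g.add((article, RDF.type, BIBO.Document))
    if doc.article_type == "research-article":
        # more accurate class added whenever the input allows it
        g.add((article, RDF.type, BIBO.AcademicArticle))

    _add_identifiers(g, article, doc)
    if doc.title:
        g.add((article, DCTERMS.title, Literal(doc.title)))
    for kw in doc.keywords:
        g.add((article, DCTERMS.subject, Literal(kw)))
    if doc.license_note:
        g.add((article, DCTERMS.license, Literal(doc.license_note)))

    _add_journal(g, article, doc, policy, lid)
    _add_contributors(g, article, doc, policy, lid)

    if doc.abstract is not None:
        sec_iri = _add_section(g, article, doc.abstract, policy, lid, ("abstract",))
        g.add((sec_iri, RDF.type, DOCO.Abstract))
    for sec in doc.sections:
        _add_section(g, article, sec, policy, lid, (sec.index,))

    for n, ref in enumerate(doc.references):
        for stmt in rdfize_reference(ref, article, policy, ordinal=n):
            g.add(stmt)

    # dual provenance: PROV-O and DCMI Terms
    stamp = Literal(created.isoformat(), datatype=XSD.dateTime)
    g.add((article, DCTERMS.created, stamp))
    g.add((article, PROV.generatedAtTime, stamp))
    g.add((article, DCTERMS.creator, policy.agent_iri))
    g.add((article, PROV.wasAttributedTo, policy.agent_iri))
    return g


def _add_identifiers(g: Graph, article: URIRef, doc: ArticleDocument) -> None:
    ids = doc.identifiers
    if ids.pmid:
        g.add((article, BIBO.pmid, Literal(ids.pmid)))
        g.add((article, RDFS.seeAlso, URIRef(f"https://pubmed.ncbi.nlm.nih.gov/{ids.pmid}/")))
    if ids.doi:
        g.add((article, BIBO.doi, Literal(ids.doi)))
        g.add((article, OWL.sameAs, URIRef(f"https://doi.org/{ids.doi}")))
    # CURIE-style values keep the generic identifiers distinct from the
    # typed bibo:pmid/bibo:doi literals
    curies = [f"pmc:{ids.pmcid}" if ids.pmcid else None,
              f"pmid:{ids.pmid}" if ids.pmid else None,
              f"doi:{ids.doi}" if ids.doi else None, *ids.generic]
    for value in filter(None, curies):
        g.add((article, DCTERMS.identifier, Literal(value)))
    if ids.pmcid:
        g.add((article, OWL.sameAs, URIRef(f"http://identifiers.org/pmc/{ids.pmcid}")))
        g.add((article, RDFS.seeAlso,
               URIRef(f"https://www.ncbi.nlm.nih.gov/pmc/articles/{ids.pmcid}/")))


def _add_journal(g: Graph, article: URIRef, doc: ArticleDocument,
                 policy: UriPolicy, lid: str) -> None:
    j = doc.journal
    if j.title or j.issn:
        journal = policy.mint("journal", [lid])
        g.add((journal, RDF.type, BIBO.Journal))
        if j.title:
            g.add((journal, DCTERMS.title, Literal(j.title)))
        if j.issn:
            g.add((journal, BIBO.issn, Literal(j.issn)))
        g.add((article, DCTERMS.isPartOf, journal))
    if j.publisher:
        g.add((article, DCTERMS.publisher, Literal(j.publisher)))
    if j.volume:
        g.add((article, BIBO.volume, Literal(j.volume)))
    if j.issue:
        g.add((article, BIBO.issue, Literal(j.issue)))
    if j.fpage:
        g.add((article, BIBO.pageStart, Literal(j.fpage)))
    if j.lpage:
        g.add((article, BIBO.pageEnd, Literal(j.lpage)))


def _add_contributors(g: Graph, article: URIRef, doc: ArticleDocument,
                      policy: UriPolicy, lid: str) -> None:
    org_iris = {}
    for org in doc.affiliations:
        iri = policy.mint("organization", [lid, org.key])
        org_iris[org.key] = iri
        g.add((iri, RDF.type, FOAF.Organization))
        g.add((iri, FOAF.name, Literal(org.name)))
    if not doc.contributors:
        return
    seq = policy.mint("authorlist", [lid])
    g.add((article, BIBO.authorList, seq))
    g.add((seq, RDF.type, RDF.Seq))
    for i, person in enumerate(doc.contributors):
        p = policy.mint("person", [lid, str(i)])
        # ordered membership preserves document author order
        g.add((seq, URIRef(f"{RDF}_{i + 1}"), p))
        g.add((p, RDF.type, FOAF.Person))
        g.add((p, FOAF.surname, Literal(person.surname)))
        if person.given:
            g.add((p, FOAF.givenName, Literal(person.given)))
            g.add((p, FOAF.name, Literal(f"{person.given} {person.surname}")))
        if person.email:
            g.add((p, FOAF.mbox, URIRef(f"mailto:{person.email}")))
        for key in person.affiliation_refs:
            if key in org_iris:
                g.add((org_iris[key], FOAF.member, p))
            else:
                logger.warning("contributor cites unknown affiliation %r", key)


def _add_section(g: Graph, parent: URIRef, sec: Section, policy: UriPolicy,
                 lid: str, path: tuple) -> URIRef:
    keys = [lid] + [str(k) for k in path]
    sec_iri = policy.mint("section", keys)
    g.add((sec_iri, RDF.type, DOCO.Section))
    g.add((sec_iri, DCTERMS.title, Literal(sec.title)))
    g.add((parent, DCTERMS.hasPart, sec_iri))
    for para in sec.paragraphs:
        p_iri = policy.mint("paragraph", keys + [str(para.index)])
        g.add((p_iri, RDF.type, DOCO.Paragraph))
        g.add((p_iri, RDF.type, CNT.ContentAsText))
        g.add((p_iri, CNT.chars, Literal(para.text)))  # exactly one per paragraph
        g.add((sec_iri, DCTERMS.hasPart, p_iri))
    for sub in sec.subsections:
        _add_section(g, sec_iri, sub, policy, lid, path + (sub.index,))
    return sec_iri


def paragraph_iri(policy: UriPolicy, lid: str, path: tuple, para_index: int) -> URIRef:
    """The IRI rdfize_article assigns to a paragraph; shared with the annotator."""
    return policy.mint("paragraph", [lid] + [str(k) for k in path] + [str(para_index)])


def rdfize_reference(ref: Reference, article: URIRef, policy: UriPolicy,
                     ordinal: int = 0) -> list[tuple]:
    """Statements for one reference: a document node with its recoverable
    metadata plus mutual cites/citedBy links to the citing article."""
    lid = unquote(str(article).rsplit("/", 1)[-1])
    node = policy.mint("reference", [lid, str(ordinal)])
    stmts: list[tuple] = [
        (node, RDF.type, BIBO.Document),
        (article, BIBO.cites, node),
        (node, BIBO.citedBy, article),
        (node, DCTERMS.bibliographicCitation, Literal(ref.raw)),
    ]
    if ref.title is not None:
        stmts.append((node, DCTERMS.title, Literal(ref.title)))
    if ref.source is not None:
        stmts.append((node, DCTERMS.source, Literal(ref.source)))
    if ref.year is not None:
        stmts.append((node, DCTERMS.date, Literal(ref.year)))
    if ref.volume is not None:
        stmts.append((node, BIBO.volume, Literal(ref.volume)))
    if ref.pages is not None:
        stmts.append((node, BIBO.pages, Literal(ref.pages)))
    if ref.identifiers.pmid is not None:
        stmts.append((node, BIBO.pmid, Literal(ref.identifiers.pmid)))
    if ref.identifiers.doi is not None:
        stmts.append((node, BIBO.doi, Literal(ref.identifiers.doi)))
    for author in ref.authors:
        name = f"{author.given} {author.surname}" if author.given else author.surname
        stmts.append((node, DCTERMS.creator, Literal(name)))
    if ref.incomplete:
        stmts.append((node, RDFS.comment,
                      Literal("incomplete reference: no title and no pmid/doi recovered")))
    return stmts


Resolver = Callable[[Reference], Optional[dict]]


def complete_reference(ref: Reference, resolver: Optional[Resolver]) -> Reference:
    """Enrich an incomplete reference through an external-resolver contract.

    The resolver maps a Reference to a dict of field updates (``title``,
    ``pmid``, ``doi``) or None to decline.  A null resolver, a declining
    resolver, and a failing resolver all leave the reference unchanged;
    failures are logged, since such services are not always reliable.
    """
    if resolver is None:
        return ref
    try:
        updates = resolver(ref)
    except Exception as exc:  # noqa: BLE001 - contract: never propagate
        logger.warning("reference resolver failed: %s", exc)
        return ref
    if not updates:
        return ref
    ids = ref.identifiers
    new_ids = type(ids)(
        pmcid=ids.pmcid,
        pmid=updates.get("pmid", ids.pmid),
        doi=updates.get("doi", ids.doi),
        generic=list(ids.generic),
    )
    title = updates.get("title", ref.title)
    return Reference(
        style=ref.style,
        authors=list(ref.authors),
        title=title,
        source=updates.get("source", ref.source),
        year=ref.year,
        volume=ref.volume,
        pages=ref.pages,
        identifiers=new_ids,
        raw=ref.raw,
        incomplete=Reference.incomplete_rule(title, new_ids),
    )
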