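"""Retrieval over RDFized articles and their annotation graphs.

Three families of access are provided: section-scoped full-text queries
over the bibliographic graphs, annotation-based queries (articles by
entity), and an embedded corpus index answering the eight API request
kinds (terms, prefix autocompletion, topics/vocabularies by term, topics
by vocabulary, articles by term/vocabulary, article counts).  On top of
the index sits the NACAP construction: a graph with articles as nodes and
shared annotated terms as edges, an edge kept only when its term has more
than the threshold number of associated biological entities.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import networkx as nx
from rdflib import Graph
from rdflib.namespace import RDF

from .annotation_rdf import parse_annotation_graph
from .registry import VocabularyRegistry
from .vocab import AO_ROLES, BIBO, CNT, DCTERMS, DOCO

REQUEST_KINDS = (
    "terms", "terms_by_prefix", "topics_by_term", "vocabularies_by_term",
    "topics_by_vocabulary", "articles_by_term", "articles_by_vocabulary",
    "article_count_by_term",
)


class QueryError(ValueError):
    pass


# -- bibliographic-graph access ---------------------------------------------


def article_node(g: Graph):
    """The article subject of a bibliographic graph: the bibo:Document that
    is never the object of a cites link (references are also documents)."""
    cited = set(g.objects(None, BIBO.cites))
    for s in g.subjects(RDF.type, BIBO.Document):
        if s not in cited:
            return s
    return None


def _article_meta(g: Graph):
    node = article_node(g)
    if node is None:
        return None, None, None
    pmid = next(g.objects(node, BIBO.pmid), None)
    title = next(g.objects(node, DCTERMS.title), None)
    return node, (str(pmid) if pmid else None), (str(title) if title else None)


@dataclass
class SectionTermRow:
    pmid: Optional[str]
    article_title: Optional[str]
    section_title: str
    paragraphs: list[str]


def find_articles_by_section_term(graphs: Iterable[Graph], title_substring: str,
                                  term: str) -> list[SectionTermRow]:
    """Paragraphs containing ``term`` inside sections whose title contains
    ``title_substring``; both matches are case-insensitive containment."""
    rows = []
    sub = title_substring.lower()
    needle = term.lower()
    for g in graphs:
        _node, pmid, art_title = _article_meta(g)
        for sec in sorted(g.subjects(RDF.type, DOCO.Section)):
            sec_title = str(next(g.objects(sec, DCTERMS.title), ""))
            if sub not in sec_title.lower():
                continue
            paragraphs = []
            for para in sorted(g.objects(sec, DCTERMS.hasPart)):
                for chars in g.objects(para, CNT.chars):
                    if needle in str(chars).lower():
                        paragraphs.append(str(chars))
            if paragraphs:
                rows.append(SectionTermRow(pmid=pmid, article_title=art_title,
                                           section_title=sec_title,
                                           paragraphs=paragraphs))
    return rows


def find_articles_by_entity(article_graphs: Iterable[Graph],
                            annotation_graphs: Iterable[Graph],
                            entity: str) -> list[str]:
    """pmids of articles with at least one annotation whose topic set
    contains ``entity``."""
    pmid_by_article: dict = {}
    for g in article_graphs:
        node, pmid, _ = _article_meta(g)
        if node is not None:
            pmid_by_article[str(node)] = pmid
    hits = set()
    for g in annotation_graphs:
        for ann in g.subjects(RDF.type, AO_ROLES["annotation_class"]):
            topics = {str(o) for o in g.objects(ann, AO_ROLES["topic"])}
            if entity in topics:
                doc = str(next(g.objects(ann, AO_ROLES["annotates"])))
                hits.add(pmid_by_article.get(doc) or doc)
    return sorted(hits)


# -- corpus index -----------------------------------------------------------


@dataclass
class CorpusIndex:
    """term -> articles/topics/vocabularies; vocabulary -> topics/articles;
    article -> pmid/title.  Rebuildable from a rescan of the graphs."""

    term_articles: dict = field(default_factory=dict)
    term_topics: dict = field(default_factory=dict)
    term_vocabularies: dict = field(default_factory=dict)
    vocab_topics: dict = field(default_factory=dict)
    vocab_articles: dict = field(default_factory=dict)
    article_meta: dict = field(default_factory=dict)  # iri -> {pmid, title}

    def to_json_dict(self) -> dict:
        def s(d):
            return {k: sorted(v) for k, v in d.items()}
        return {
            "term_articles": s(self.term_articles),
            "term_topics": s(self.term_topics),
            "term_vocabularies": s(self.term_vocabularies),
            "vocab_topics": s(self.vocab_topics),
            "vocab_articles": s(self.vocab_articles),
            "article_meta": self.article_meta,
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "CorpusIndex":
        def s(dd):
            return {k: set(v) for k, v in dd.items()}
        return cls(
            term_articles=s(d["term_articles"]),
            term_topics=s(d["term_topics"]),
            term_vocabularies=s(d["term_vocabularies"]),
            vocab_topics=s(d["vocab_topics"]),
            vocab_articles=s(d["vocab_articles"]),
            article_meta=dict(d["article_meta"]),
        )


def build_index(article_graphs: Iterable[Graph],
                annotation_graphs: Iterable[Graph],
                registry: VocabularyRegistry) -> CorpusIndex:
    """Scan bibliographic and annotation graphs into a CorpusIndex; the
    vocabulary of a topic is recovered from its IRI via the registry."""
    idx = CorpusIndex()
    for g in article_graphs:
        node, pmid, title = _article_meta(g)
        if node is not None:
            idx.article_meta[str(node)] = {"pmid": pmid, "title": title}
    for g in annotation_graphs:
        for ann in parse_annotation_graph(g, registry):
            article = ann.document
            term = ann.term
            idx.term_articles.setdefault(term, set()).add(article)
            for entity, vocab in ann.entities:
                idx.term_topics.setdefault(term, set()).add(entity)
                if vocab:
                    idx.term_vocabularies.setdefault(term, set()).add(vocab)
                    idx.vocab_topics.setdefault(vocab, set()).add(entity)
                    idx.vocab_articles.setdefault(vocab, set()).add(article)
    return idx


def query_index(index: CorpusIndex, kind: str, **params):
    """Answer one of the eight request kinds from the index."""
    if kind not in REQUEST_KINDS:
        raise QueryError(f"unknown request kind {kind!r}; expected one of {REQUEST_KINDS}")
    if kind == "terms":
        return sorted(index.term_articles)
    if kind == "terms_by_prefix":
        prefix = params["prefix"]
        return sorted(t for t in index.term_articles if t.startswith(prefix))
    if kind == "topics_by_term":
        return sorted(index.term_topics.get(params["term"], ()))
    if kind == "vocabularies_by_term":
        return sorted(index.term_vocabularies.get(params["term"], ()))
    if kind == "topics_by_vocabulary":
        return sorted(index.vocab_topics.get(params["vocabulary"], ()))
    if kind == "articles_by_term":
        return sorted(index.term_articles.get(params["term"], ()))
    if kind == "articles_by_vocabulary":
        return sorted(index.vocab_articles.get(params["vocabulary"], ()))
    return len(index.term_articles.get(params["term"], ()))  # article_count_by_term


# -- coverage statistics ----------------------------------------------------


@dataclass
class CoverageStats:
    """Per-vocabulary counts: articles covered, distinct terms, distinct
    entities."""

    per_vocabulary: dict = field(default_factory=dict)

    def row(self, vocab: str) -> dict:
        return self.per_vocabulary.get(vocab, {"articles": 0, "terms": 0, "entities": 0})


def coverage_stats(annotation_graphs: Iterable[Graph],
                   registry: VocabularyRegistry) -> CoverageStats:
    acc: dict = {}
    for g in annotation_graphs:
        for ann in parse_annotation_graph(g, registry):
            for entity, vocab in ann.entities:
                if not vocab:
                    continue
                bucket = acc.setdefault(vocab, {"articles": set(), "terms": set(),
                                                "entities": set()})
                bucket["articles"].add(ann.document)
                bucket["terms"].add(ann.term)
                bucket["entities"].add(entity)
    return CoverageStats(per_vocabulary={
        vocab: {k: len(v) for k, v in bucket.items()} for vocab, bucket in acc.items()
    })


# -- NACAP ------------------------------------------------------------------


@dataclass
class NacapGraph:
    """Article nodes, shared-term edges weighted by the number of entities
    associated with the term corpus-wide."""

    graph: nx.MultiGraph

    @property
    def nodes(self) -> list:
        return sorted(self.graph.nodes)

    @property
    def edges(self) -> list[tuple]:
        """(article_a, article_b, term, weight), endpoints ordered."""
        out = []
        for a, b, data in self.graph.edges(data=True):
            a, b = sorted((a, b))
            out.append((a, b, data["term"], data["weight"]))
        return sorted(out)

    def to_json_dict(self) -> dict:
        return {
            "nodes": [{"id": n, "title": self.graph.nodes[n].get("title")}
                      for n in self.nodes],
            "edges": [{"source": a, "target": b, "term": t, "weight": w}
                      for a, b, t, w in self.edges],
        }


def build_nacap(index: CorpusIndex, seed: str, min_entities: int = 30) -> NacapGraph:
    """Retrieve the articles matching ``seed`` (an annotated term, or an
    entity IRI) and connect every pair by each shared annotated term whose
    corpus-wide entity count strictly exceeds ``min_entities``."""
    if seed in index.term_articles:
        articles = sorted(index.term_articles[seed])
    else:
        articles = sorted(a for term, topics in index.term_topics.items()
                          if seed in topics
                          for a in index.term_articles.get(term, ()))
    g = nx.MultiGraph()
    for a in articles:
        meta = index.article_meta.get(a, {})
        g.add_node(a, title=meta.get("title"))
    article_set = set(articles)
    for term, term_articles in index.term_articles.items():
        weight = len(index.term_topics.get(term, ()))
        if weight <= min_entities:  # strictly "more than" the threshold
            continue
        members = sorted(term_articles & article_set)
        for i, a in enumerate(members):
            for b in members[i + 1:]:
                g.add_edge(a, b, term=term, weight=weight)
    return NacapGraph(graph=g)


def tag_cloud_weights(annotations) -> dict:
    """term -> number of biological entities associated with it across one
    article's annotations (union over annotator routes)."""
    entities: dict = {}
    for ann in annotations:
        entities.setdefault(ann.term, set()).update(e for e, _v in ann.entities)
    return {term: len(ents) for term, ents in entities.items()}
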