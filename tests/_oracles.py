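"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's own scanning/indexing code paths:
the scanner enumerates every substring, the tag stripper walks the XML
tree generically, and the index oracles iterate raw graph triples.
"""
from __future__ import annotations

from rdflib.namespace import RDF

from biotea.vocab import AO_ROLES


def brute_force_scan(text: str, surfaces: set, case_mode: str = "exact",
                     boundary_mode: str = "word_boundary") -> list[tuple]:
    """All-substring scan + the same policy rules, resolved by an
    independent left-to-right longest-first sweep.

    Returns (surface_as_in_text, start, end) with 1-based inclusive ends.
    """
    if not text:
        return []
    keys = {s.lower() for s in surfaces} if case_mode == "fold" else set(surfaces)
    lengths = sorted({len(s) for s in surfaces}, reverse=True)
    hay = text.lower() if case_mode == "fold" else text
    out = []
    i = 0
    n = len(text)
    while i < n:
        hit = None
        for L in lengths:  # longest first at each position
            if i + L > n:
                continue
            if hay[i:i + L] not in keys:
                continue
            if boundary_mode == "word_boundary":
                if i > 0 and text[i - 1].isalnum():
                    continue
                if i + L < n and text[i + L].isalnum():
                    continue
            hit = L
            break
        if hit is None:
            i += 1
        else:
            out.append((text[i:i + hit], i + 1, i + hit))
            i += hit
    return out


def strip_tags_oracle(element) -> str:
    """Generic tree-walk tag stripper (keeps all text and tails)."""
    parts = []

    def walk(el):
        if el.text:
            parts.append(el.text)
        for child in el:
            if isinstance(child.tag, str):
                walk(child)
            if child.tail:
                parts.append(child.tail)

    walk(element)
    return "".join(parts)


def index_oracle(annotation_graphs, registry) -> dict:
    """Recompute all index content by iterating raw annotation triples."""
    term_articles: dict = {}
    term_topics: dict = {}
    term_vocabs: dict = {}
    vocab_topics: dict = {}
    vocab_articles: dict = {}
    for g in annotation_graphs:
        for ann in g.subjects(RDF.type, AO_ROLES["annotation_class"]):
            term = str(next(g.objects(ann, AO_ROLES["body"])))
            article = str(next(g.objects(ann, AO_ROLES["annotates"])))
            term_articles.setdefault(term, set()).add(article)
            for topic in g.objects(ann, AO_ROLES["topic"]):
                topic = str(topic)
                term_topics.setdefault(term, set()).add(topic)
                vocab = registry.vocabulary_of(topic)
                if vocab:
                    term_vocabs.setdefault(term, set()).add(vocab)
                    vocab_topics.setdefault(vocab, set()).add(topic)
                    vocab_articles.setdefault(vocab, set()).add(article)
    return {
        "term_articles": term_articles,
        "term_topics": term_topics,
        "term_vocabularies": term_vocabs,
        "vocab_topics": vocab_topics,
        "vocab_articles": vocab_articles,
    }


def nacap_oracle(term_articles: dict, term_topics: dict, articles: set,
                 min_entities: int) -> set:
    """Pairwise shared-term edges by direct enumeration."""
    edges = set()
    for term, members in term_articles.items():
        weight = len(term_topics.get(term, ()))
        if weight <= min_entities:
            continue
        inside = sorted(members & articles)
        for i, a in enumerate(inside):
            for b in inside[i + 1:]:
                edges.add((a, b, term, weight))
    return edges
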