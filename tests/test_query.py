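"""Retrieval: section-scoped search, entity search, the corpus index,
coverage statistics and NACAP construction."""
import random

import pytest

from biotea.annotation_rdf import annotations_to_graph
from biotea.annotator import Annotation, TermMatch, annotate_document, compile_dictionary
from biotea.jats import parse_jats
from biotea.query import (
    CorpusIndex,
    QueryError,
    REQUEST_KINDS,
    build_index,
    build_nacap,
    coverage_stats,
    find_articles_by_entity,
    find_articles_by_section_term,
    query_index,
    tag_cloud_weights,
)
from biotea.rdfizer import rdfize_article

from ._oracles import index_oracle, nacap_oracle
from .conftest import FIXED_TS


@pytest.fixture(scope="session")
def corpus_graphs(small_corpus, registry):
    """(article graphs, annotation graphs) for the generated corpus."""
    by_vocab = {}
    for e in small_corpus.dictionary:
        by_vocab.setdefault(e.vocabulary, []).append(e)
    dicts = {v: compile_dictionary(es) for v, es in by_vocab.items()}
    articles, annotations = [], []
    for pmcid in small_corpus.manifest.articles:
        doc = parse_jats(small_corpus.jats[f"{pmcid}.nxml"])
        articles.append(rdfize_article(doc, created=FIXED_TS))
        anns = annotate_document(doc, registry, dicts, small_corpus.hierarchy,
                                 created=FIXED_TS)
        annotations.append(annotations_to_graph(anns, registry, created=FIXED_TS))
    return articles, annotations


# -- section-scoped search --------------------------------------------------


def test_section_term_search_finds_planted_paragraph(worked, registry):
    g = rdfize_article(worked.chemical_article, created=FIXED_TS)
    rows = find_articles_by_section_term([g], "preparation", "CHOLESTEROL")
    assert len(rows) == 1
    assert rows[0].section_title == "Preparation of LT-NLC and LT-NLC-apo"
    assert any("cholesterol" in p for p in rows[0].paragraphs)


def test_absent_term_yields_no_rows(corpus_graphs):
    articles, _ = corpus_graphs
    assert find_articles_by_section_term(articles, "", "unobtainium") == []


def test_section_term_search_equals_brute_force_scan(small_corpus, corpus_graphs):
    articles, _ = corpus_graphs
    rng = random.Random(41)
    surfaces = list(small_corpus.manifest.entity_counts) + ["zq", "nothing"]
    for _ in range(50):
        term = rng.choice(surfaces)
        title_sub = rng.choice(["", "section", "Section 0", "2", "zz"])
        rows = find_articles_by_section_term(articles, title_sub, term)
        # oracle: rescan the parsed documents directly
        expected = 0
        for pmcid in small_corpus.manifest.articles:
            doc = parse_jats(small_corpus.jats[f"{pmcid}.nxml"])
            sections = list(doc.sections) + ([doc.abstract] if doc.abstract else [])
            for sec in sections:
                if title_sub.lower() not in sec.title.lower():
                    continue
                if any(term.lower() in p.text.lower() for p in sec.paragraphs):
                    expected += 1
        assert len(rows) == expected


# -- entity search ----------------------------------------------------------


def test_entity_search_returns_only_annotated_article(small_corpus, corpus_graphs,
                                                      registry):
    articles, annotations = corpus_graphs
    entity = next(e.entity for e in small_corpus.dictionary
                  if e.surface == "cholesterol")
    # cholesterol planted in every article of the small corpus
    hits = find_articles_by_entity(articles, annotations, entity)
    planted = {p for p, t in small_corpus.manifest.articles.items()
               if any(o.surface == "cholesterol" for o in t.occurrences)}
    assert len(hits) == len(planted)


def test_unknown_entity_matches_nothing(corpus_graphs):
    articles, annotations = corpus_graphs
    assert find_articles_by_entity(articles, annotations, "http://x/none") == []


# -- the corpus index -------------------------------------------------------


def test_empty_corpus_gives_empty_index(registry):
    idx = build_index([], [], registry)
    assert query_index(idx, "terms") == []


def test_index_contents_match_manifest(small_corpus, corpus_graphs, registry):
    articles, annotations = corpus_graphs
    idx = build_index(articles, annotations, registry)
    assert set(query_index(idx, "terms")) == set(small_corpus.manifest.entity_counts)
    for surface, n in small_corpus.manifest.entity_counts.items():
        assert len(query_index(idx, "topics_by_term", term=surface)) == n


def test_incremental_indexing_equals_rebuild(corpus_graphs, registry):
    articles, annotations = corpus_graphs
    full = build_index(articles, annotations, registry)
    partial = build_index(articles[:-1], annotations[:-1], registry)
    delta = build_index(articles[-1:], annotations[-1:], registry)
    merged_terms = set(partial.term_articles) | set(delta.term_articles)
    assert merged_terms == set(full.term_articles)
    for t in merged_terms:
        assert (partial.term_articles.get(t, set()) | delta.term_articles.get(t, set())
                ) == full.term_articles[t]


def test_prefix_autocompletion(corpus_graphs, registry):
    articles, annotations = corpus_graphs
    idx = build_index(articles, annotations, registry)
    assert "cancer" in query_index(idx, "terms_by_prefix", prefix="canc")
    assert query_index(idx, "terms_by_prefix", prefix="zzz") == []


def test_count_request_consistent_with_article_list(corpus_graphs, registry):
    articles, annotations = corpus_graphs
    idx = build_index(articles, annotations, registry)
    for term in query_index(idx, "terms"):
        assert query_index(idx, "article_count_by_term", term=term) == \
            len(query_index(idx, "articles_by_term", term=term))


def test_unknown_request_kind_rejected(registry):
    with pytest.raises(QueryError):
        query_index(build_index([], [], registry), "documents_by_mood")


def test_all_eight_request_kinds_equal_brute_force(corpus_graphs, registry):
    articles, annotations = corpus_graphs
    idx = build_index(articles, annotations, registry)
    oracle = index_oracle(annotations, registry)
    assert query_index(idx, "terms") == sorted(oracle["term_articles"])
    for term in list(oracle["term_articles"]) + ["missing"]:
        assert query_index(idx, "topics_by_term", term=term) == \
            sorted(oracle["term_topics"].get(term, ()))
        assert query_index(idx, "vocabularies_by_term", term=term) == \
            sorted(oracle["term_vocabularies"].get(term, ()))
        assert query_index(idx, "articles_by_term", term=term) == \
            sorted(oracle["term_articles"].get(term, ()))
        assert query_index(idx, "article_count_by_term", term=term) == \
            len(oracle["term_articles"].get(term, ()))
        for k in range(1, len(term) + 1):
            pre = term[:k]
            assert query_index(idx, "terms_by_prefix", prefix=pre) == \
                sorted(t for t in oracle["term_articles"] if t.startswith(pre))
    for vocab in list(oracle["vocab_topics"]) + ["mddb"]:
        assert query_index(idx, "topics_by_vocabulary", vocabulary=vocab) == \
            sorted(oracle["vocab_topics"].get(vocab, ()))
        assert query_index(idx, "articles_by_vocabulary", vocabulary=vocab) == \
            sorted(oracle["vocab_articles"].get(vocab, ()))


def test_index_json_round_trip(corpus_graphs, registry):
    articles, annotations = corpus_graphs
    idx = build_index(articles, annotations, registry)
    back = CorpusIndex.from_json_dict(idx.to_json_dict())
    for kind in ("terms",):
        assert query_index(back, kind) == query_index(idx, kind)
    assert back.term_topics == idx.term_topics


# -- coverage ---------------------------------------------------------------


def test_empty_corpus_coverage_is_zero(registry):
    stats = coverage_stats([], registry)
    assert stats.per_vocabulary == {}
    assert stats.row("chebi") == {"articles": 0, "terms": 0, "entities": 0}


def test_coverage_matches_manifest(small_corpus, corpus_graphs, registry):
    _, annotations = corpus_graphs
    stats = coverage_stats(annotations, registry)
    # every planted vocabulary appears with the manifest's entity counts
    planted_vocabs = {e.vocabulary for e in small_corpus.dictionary}
    assert set(stats.per_vocabulary) == planted_vocabs
    for e in small_corpus.dictionary:
        row = stats.row(e.vocabulary)
        assert row["articles"] >= 1
        assert row["entities"] >= row["terms"]


def test_multi_mapping_vocabulary_has_more_entities_than_terms(worked, registry):
    anns = annotate_document(worked.protein_article, registry,
                             {"uniprot": compile_dictionary(worked.protein_dictionary)},
                             created=FIXED_TS)
    g = annotations_to_graph(anns, registry, created=FIXED_TS)
    stats = coverage_stats([g], registry)
    row = stats.row("uniprot")
    assert row["terms"] == 2 and row["entities"] == 19
    assert row["entities"] > row["terms"]


# -- NACAP ------------------------------------------------------------------


def _toy_index(shared_weights: dict, n_articles=2) -> CorpusIndex:
    """All articles share every term; each term carries `weight` topics."""
    arts = {f"http://x/a{i}" for i in range(n_articles)}
    idx = CorpusIndex()
    for term, weight in shared_weights.items():
        idx.term_articles[term] = set(arts)
        idx.term_topics[term] = {f"http://x/{term}/e{i}" for i in range(weight)}
    for a in arts:
        idx.article_meta[a] = {"pmid": None, "title": a}
    return idx


def test_single_article_retrieval_has_no_edges():
    idx = _toy_index({"catalase": 40}, n_articles=1)
    g = build_nacap(idx, "catalase")
    assert len(g.nodes) == 1 and g.edges == []


def test_threshold_boundary_30_vs_31():
    idx = _toy_index({"seed": 40, "rich": 31, "poor": 30})
    g = build_nacap(idx, "seed", min_entities=30)
    terms = {t for _a, _b, t, _w in g.edges}
    assert "rich" in terms and "seed" in terms
    assert "poor" not in terms  # weight 30 is not "more than 30"


def test_edges_symmetric_and_above_threshold():
    idx = _toy_index({"seed": 45, "x": 33, "y": 31, "z": 12}, n_articles=3)
    g = build_nacap(idx, "seed", min_entities=30)
    for a, b, _t, w in g.edges:
        assert w > 30
        assert g.graph.has_edge(a, b) and g.graph.has_edge(b, a)


def test_raising_threshold_never_adds_edges():
    idx = _toy_index({"seed": 45, "x": 33, "y": 31}, n_articles=3)
    lo = {(a, b, t) for a, b, t, _w in build_nacap(idx, "seed", 30).edges}
    hi = {(a, b, t) for a, b, t, _w in build_nacap(idx, "seed", 32).edges}
    assert hi <= lo


def test_entity_seed_retrieves_annotating_articles():
    idx = _toy_index({"catalase": 35})
    g = build_nacap(idx, "http://x/catalase/e0")
    assert len(g.nodes) == 2


def test_random_corpora_match_pairwise_oracle():
    rng = random.Random(43)
    for _ in range(100):
        idx = CorpusIndex()
        arts = [f"http://x/a{i}" for i in range(rng.randint(1, 6))]
        terms = [f"t{i}" for i in range(rng.randint(1, 8))]
        for t in terms:
            members = set(rng.sample(arts, rng.randint(1, len(arts))))
            idx.term_articles[t] = members
            idx.term_topics[t] = {f"http://x/{t}/{j}"
                                  for j in range(rng.randint(0, 40))}
        for a in arts:
            idx.article_meta[a] = {"pmid": None, "title": a}
        seed = rng.choice(terms)
        threshold = rng.choice([0, 10, 30])
        g = build_nacap(idx, seed, min_entities=threshold)
        got = {(a, b, t, w) for a, b, t, w in g.edges}
        expected = nacap_oracle(idx.term_articles, idx.term_topics,
                                set(idx.term_articles[seed]), threshold)
        assert got == expected


def test_nacap_json_shape():
    idx = _toy_index({"seed": 40})
    d = build_nacap(idx, "seed").to_json_dict()
    assert {"nodes", "edges"} == set(d)
    assert all({"source", "target", "term", "weight"} == set(e) for e in d["edges"])
    assert all({"id", "title"} == set(n) for n in d["nodes"])


# -- tag cloud --------------------------------------------------------------


def test_tag_cloud_weights_on_worked_example(worked, registry):
    anns = annotate_document(worked.protein_article, registry,
                             {"uniprot": compile_dictionary(worked.protein_dictionary)})
    weights = tag_cloud_weights(anns)
    assert weights == {"lacZ": 17, "Scr": 2}


def test_unannotated_article_has_empty_cloud():
    assert tag_cloud_weights([]) == {}


def test_tag_cloud_matches_counting_oracle():
    rng = random.Random(47)
    for _ in range(50):
        anns = []
        expected: dict = {}
        for t in range(rng.randint(0, 6)):
            term = f"term{t}"
            ents = frozenset((f"http://x/{term}/{i}", "mesh")
                             for i in range(rng.randint(1, 20)))
            anns.append(Annotation(
                document="http://x/d", term=term, annotator_id="ncbo_like",
                entities=ents,
                occurrences=[TermMatch(surface=term, start=1,
                                       end=len(term), paragraph_ref="p")],
            ))
            expected[term] = len(ents)
        assert tag_cloud_weights(anns) == expected
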