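"""Dictionary compilation, exact-match scanning, hierarchy expansion and
document annotation."""
import random

import pytest

from biotea.annotator import (
    AnnotatorConfigError,
    DictionaryError,
    DictionaryEntry,
    MatchPolicy,
    OntologyHierarchy,
    TermMatch,
    annotate_document,
    compile_dictionary,
    expand_related,
    resolve_overlaps,
    scan_text,
)
from biotea.jats import parse_jats

from ._oracles import brute_force_scan
from .conftest import FIXED_TS


# -- dictionaries -----------------------------------------------------------


def test_worked_example_lookup_sizes(protein_dict):
    assert len(protein_dict.lookup("Scr")) == 2
    assert len(protein_dict.lookup("lacZ")) == 17


def test_single_entry_dictionary_has_size_one():
    d = compile_dictionary([DictionaryEntry("aspirin", "http://x/1", "chebi")])
    assert len(d) == 1


def test_duplicate_surface_entity_pairs_rejected():
    entries = [DictionaryEntry("a", "http://x/1", "chebi")] * 2
    with pytest.raises(DictionaryError, match="duplicate"):
        compile_dictionary(entries)


def test_recognized_set_equals_inserted_set():
    rng = random.Random(3)
    surfaces = {"s" + "".join(rng.choice("abcdef") for _ in range(rng.randint(2, 8)))
                for _ in range(500)}
    entries = [DictionaryEntry(s, f"http://x/{i}", "mesh")
               for i, s in enumerate(sorted(surfaces))]
    d = compile_dictionary(entries)
    assert {e.surface for e in d.entries} == surfaces
    for s in surfaces:
        assert d.lookup(s), s
    assert not d.lookup("notinserted")


# -- scanning ---------------------------------------------------------------


def test_empty_text_yields_no_matches(chemical_dict):
    assert scan_text("", chemical_dict) == []


def test_cholesterol_selector_positions(worked, chemical_dict):
    text = worked.chemical_article.sections[0].paragraphs[0].text
    matches = scan_text(text, chemical_dict)
    assert [(m.start, m.end) for m in matches] == [(291, 301)]
    assert text[290:301] == "cholesterol"


def test_word_boundary_blocks_embedded_match(protein_dict):
    assert scan_text("The Screen protein", protein_dict) == []
    hits = scan_text("The Scr protein", protein_dict)
    assert [(m.start, m.end) for m in hits] == [(5, 7)]


def test_free_boundary_mode_matches_inside_words(protein_dict):
    policy = MatchPolicy(boundary_mode="free")
    d = compile_dictionary(protein_dict.entries, policy)
    assert len(scan_text("Screen", d, policy)) == 1


def test_case_fold_mode_matches_other_casing(protein_dict):
    policy = MatchPolicy(case_mode="fold")
    d = compile_dictionary(protein_dict.entries, policy)
    hits = scan_text("the LACZ reporter", d, policy)
    assert [(m.surface, m.start, m.end) for m in hits] == [("LACZ", 5, 8)]
    assert d.lookup("LACZ") == d.lookup("lacZ")


def test_scan_matches_brute_force_on_random_planted_texts(match_policy):
    rng = random.Random(17)
    surfaces = ["cancer", "lipoprotein", "high-density lipoprotein", "Scr",
                "catalase", "Na"]
    entries = [DictionaryEntry(s, f"http://x/{i}", "mesh")
               for i, s in enumerate(surfaces)]
    d = compile_dictionary(entries)
    from .conftest import random_planted_text
    for _ in range(300):
        text = random_planted_text(rng, surfaces)
        got = [(m.surface, m.start, m.end) for m in scan_text(text, d, match_policy)]
        assert got == brute_force_scan(text, set(surfaces))


def test_match_invariant_slice_equals_surface(chemical_dict, worked):
    text = worked.chemical_article.sections[0].paragraphs[0].text
    for m in scan_text(text, chemical_dict):
        assert m.end - m.start + 1 == len(m.surface)
        assert text[m.start - 1:m.end] == m.surface


def test_termmatch_position_invariants_enforced():
    with pytest.raises(ValueError):
        TermMatch(surface="ab", start=1, end=3, paragraph_ref="p")
    with pytest.raises(ValueError):
        TermMatch(surface="ab", start=0, end=1, paragraph_ref="p")
    with pytest.raises(ValueError):
        TermMatch(surface="ab", start=None, end=2, paragraph_ref="p")


# -- overlap resolution -----------------------------------------------------


def _m(surface, start):
    return TermMatch(surface=surface, start=start,
                     end=start + len(surface) - 1, paragraph_ref="p")


def test_single_candidate_survives():
    assert resolve_overlaps([_m("abc", 1)]) == [_m("abc", 1)]


def test_longer_of_two_cospanning_candidates_retained():
    text = "high-density lipoprotein"
    long, short = _m(text, 1), _m("lipoprotein", 14)
    kept = resolve_overlaps(sorted([short, long], key=lambda m: (m.start, -len(m.surface))))
    assert kept == [long]


def test_random_candidates_match_greedy_rule_oracle():
    rng = random.Random(23)
    for _ in range(300):
        cands = []
        for _ in range(rng.randint(0, 12)):
            start = rng.randint(1, 40)
            length = rng.randint(1, 8)
            cands.append(_m("x" * length, start))
        cands.sort(key=lambda m: (m.start, -(m.end - m.start)))
        kept = resolve_overlaps(cands)
        # oracle: independent greedy sweep over the same ordering
        expected, last = [], 0
        for c in cands:
            if c.start > last:
                expected.append(c)
                last = c.end
        assert kept == expected
        for a, b in zip(kept, kept[1:]):
            assert b.start > a.end  # no overlap among survivors


# -- hierarchy expansion ----------------------------------------------------


def test_siblings_of_toy_tree():
    h = OntologyHierarchy.from_pairs([("B", "A"), ("C", "A"), ("D", "A")])
    assert expand_related("B", h) == {"C", "D"}


def test_root_term_expands_to_equivalents_only():
    h = OntologyHierarchy.from_pairs([("B", "A")], [("A", "A'")])
    assert expand_related("A", h) == {"A'"}
    assert expand_related("A'", h) == {"A"}  # symmetry


def test_unknown_entity_expands_to_empty_set():
    assert expand_related("nowhere", OntologyHierarchy()) == set()


def test_random_forests_match_brute_force_sibling_oracle():
    rng = random.Random(29)
    for _ in range(100):
        nodes = [f"n{i}" for i in range(rng.randint(2, 30))]
        pairs = []
        for i, n in enumerate(nodes[1:], start=1):
            if rng.random() < 0.8:
                pairs.append((n, nodes[rng.randrange(i)]))
        h = OntologyHierarchy.from_pairs(pairs)
        parent = dict(pairs)
        for n in nodes:
            expected = ({c for c, p in pairs if p == parent.get(n) and c != n}
                        if n in parent else set())
            assert expand_related(n, h) == expected


def test_cyclic_hierarchy_rejected():
    with pytest.raises(ValueError, match="cycle"):
        OntologyHierarchy.from_pairs([("A", "B"), ("B", "A")])


# -- document annotation ----------------------------------------------------


def test_worked_example_annotation_entity_counts(worked, registry, protein_dict):
    anns = annotate_document(worked.protein_article, registry,
                             {"uniprot": protein_dict}, created=FIXED_TS)
    by_term = {a.term: a for a in anns}
    assert set(by_term) == {"Scr", "lacZ"}
    assert len(by_term["Scr"].entities) == 2
    assert len(by_term["lacZ"].entities) == 17
    assert all(a.annotator_id == "whatizit_like" for a in anns)


def test_article_without_hits_yields_no_annotations(worked, registry, chemical_dict):
    anns = annotate_document(worked.protein_article, registry,
                             {"chebi": chemical_dict})
    assert anns == []


def test_unknown_vocabulary_key_is_configuration_error(worked, registry, chemical_dict):
    with pytest.raises(AnnotatorConfigError):
        annotate_document(worked.chemical_article, registry,
                          {"not_a_vocab": chemical_dict})


def test_annotation_counts_match_fixture_manifest(small_corpus, registry):
    by_vocab = {}
    for e in small_corpus.dictionary:
        by_vocab.setdefault(e.vocabulary, []).append(e)
    dicts = {v: compile_dictionary(es) for v, es in by_vocab.items()}
    for pmcid, truth in small_corpus.manifest.articles.items():
        doc = parse_jats(small_corpus.jats[f"{pmcid}.nxml"])
        anns = annotate_document(doc, registry, dicts,
                                 small_corpus.hierarchy, created=FIXED_TS)
        planted_by_surface = {}
        for occ in truth.occurrences:
            planted_by_surface.setdefault(occ.surface, []).append(occ)
        assert {a.term for a in anns} == set(planted_by_surface)
        for a in anns:
            assert len(a.occurrences) == len(planted_by_surface[a.term])
            assert len(a.entities) == small_corpus.manifest.entity_counts[a.term]
            assert sorted((m.start, m.end) for m in a.occurrences) == \
                sorted((o.start, o.end) for o in planted_by_surface[a.term])


def test_offset_route_gets_hierarchy_expansion(small_corpus, registry):
    by_vocab = {}
    for e in small_corpus.dictionary:
        by_vocab.setdefault(e.vocabulary, []).append(e)
    dicts = {v: compile_dictionary(es) for v, es in by_vocab.items()}
    pmcid = next(iter(small_corpus.manifest.articles))
    doc = parse_jats(small_corpus.jats[f"{pmcid}.nxml"])
    anns = annotate_document(doc, registry, dicts, small_corpus.hierarchy,
                             created=FIXED_TS)
    for a in anns:
        if a.annotator_id == "ncbo_like" and len(a.entities) > 1:
            # entities under one synthetic parent are mutual siblings
            assert a.related
        if a.annotator_id == "whatizit_like":
            assert a.related == frozenset()


def test_annotating_twice_is_idempotent(worked, registry, protein_dict):
    a = annotate_document(worked.protein_article, registry,
                          {"uniprot": protein_dict}, created=FIXED_TS)
    b = annotate_document(worked.protein_article, registry,
                          {"uniprot": protein_dict}, created=FIXED_TS)
    assert a == b


def test_entity_links_at_least_distinct_terms(small_corpus, registry):
    by_vocab = {}
    for e in small_corpus.dictionary:
        by_vocab.setdefault(e.vocabulary, []).append(e)
    dicts = {v: compile_dictionary(es) for v, es in by_vocab.items()}
    for pmcid in small_corpus.manifest.articles:
        doc = parse_jats(small_corpus.jats[f"{pmcid}.nxml"])
        anns = annotate_document(doc, registry, dicts)
        total_links = sum(len(a.entities) for a in anns)
        assert total_links >= len({a.term for a in anns})
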