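# biotea

Semantic publishing tools for biomedical literature: convert JATS/NXML
full-text articles (the XML dialect used by PubMed Central) into richly
linked RDF, enrich them with offset-accurate, ontology-linked dictionary
annotations, rewrite the result into SIO/Bio2RDF-compatible graphs, and
query the corpus — by section, by biological entity, through an embedded
term/topic/vocabulary index, or as a co-annotation article network.

It is aimed at people building semantic digital libraries or text-mining
infrastructure over scholarly XML: the package turns each document into an
entry point to the Web of Data, where every section, paragraph, author and
annotated biological term has a dereferenceable HTTP IRI.

## The model

**Document graph.** An article is modeled with BIBO and DCMI Terms
(bibliographic metadata, `bibo:pmid` / `bibo:doi` identifiers, mutual
`bibo:cites` / `bibo:citedBy` links to references), DoCO (`doco:Section`,
`doco:Paragraph`), CNT (each paragraph node carries exactly one `cnt:chars`
literal holding the formatting-stripped text), FOAF (authors as
`foaf:Person` in an ordered collection, affiliations as
`foaf:Organization`), and dual PROV-O + DCMI provenance. `owl:sameAs`
points to equivalent linked-data resources, `rdfs:seeAlso` to web pages.

**Annotations.** Dictionary-based exact string matching over paragraph
text emulates two annotator styles: an offset-reporting route that records
1-based, inclusive code-point positions and expands each entity with its
ontology siblings and declared cross-ontology equivalents, and an
exact-text route that may link one surface form to many entities (one
gene-product name to many protein accessions). Annotations follow the
Annotation Ontology layout — annotation node, term body, topic per entity,
provenance agent and timestamp — with two literal-targeting selector
variants: an exact-text selector and a start/end selector satisfying
`end − start + 1 = length(exact)`. A match of the 11-character term
*cholesterol* starting at position 291 therefore ends at 301, and slicing
the paragraph at `[291, 301]` returns exactly `cholesterol`.

**Vocabulary registry.** 18 controlled vocabularies are routed 13/5 across
the two annotator styles; exactly 7 (ChEBI, GO, MeSH, NCIt, UniProt
proteins, UniProt Taxonomy, NCBI Taxon) carry Bio2RDF and identifiers.org
`owl:sameAs` templates.

**SIO rewrite.** A declarative table maps the document vocabulary onto the
Semantic Science Integrated Ontology: object properties to `sio:000008`
("has attribute"), citing/referencing relations to `sio:000628` ("refers
to") and `sio:000212` ("is referenced by"), all data-type properties to
`sio:000300` ("has value"). Rewrites are 1:1; unmapped statements pass
through unchanged.

**Retrieval.** An embedded index answers eight request kinds (terms,
prefix autocompletion, topics/vocabularies by term, topics by vocabulary,
articles by term/vocabulary, article counts). NACAP — network of
associated concepts across papers — renders a retrieved set as a graph
with articles as nodes and shared annotated terms as edges, keeping only
terms with more than 30 (configurable) associated biological entities;
per-article tag-cloud weights equal the number of entities linked to each
term.

## Worked example

```python
from biotea import (annotate_document, compile_dictionary, default_registry,
                    tag_cloud_weights)
from biotea.fixtures import paper_worked_examples

reg = default_registry()
wx = paper_worked_examples(reg)

anns = annotate_document(wx.protein_article, reg,
                         {"uniprot": compile_dictionary(wx.protein_dictionary)})
for a in anns:
    occ = a.occurrences[0]
    print(f"{a.term}: {len(a.entities)} entities, route={a.annotator_id}, "
          f"at [{occ.start}, {occ.end}]")
print(tag_cloud_weights(anns))
```

prints

```
Scr: 2 entities, route=whatizit_like, at [5, 7]
lacZ: 17 entities, route=whatizit_like, at [52, 55]
{'Scr': 2, 'lacZ': 17}
```

— the surface form `Scr` resolves to two UniProt accessions and `lacZ` to
seventeen, so a tag cloud weighs `lacZ` most heavily; the chemical fixture
behaves the same way for offsets:

```python
anns = annotate_document(wx.chemical_article, reg,
                         {"chebi": compile_dictionary(wx.chemical_dictionary)})
occ = anns[0].occurrences[0]
text = wx.chemical_article.sections[0].paragraphs[0].text
print(f"cholesterol selector: [{occ.start}, {occ.end}] ->",
      repr(text[occ.start - 1:occ.end]))
```

```
cholesterol selector: [291, 301] -> 'cholesterol'
```

The same pipeline is scriptable from the shell — `biotea gen-fixtures`,
`biotea parse`, `biotea rdfize`, `biotea annotate`, `biotea map-sio`,
`biotea index`, `biotea api`, `biotea query`, `biotea nacap` — see
`biotea --help`.

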