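# Methods

This note documents the models, conventions and numerical choices behind
the package, what the synthetic fixtures do and do not emulate, and the
design decisions taken where the design was genuinely open.

## Document model and text extraction

JATS/NXML (PMC open-access dialect) is parsed into a flat document model:
identifiers, journal metadata, ordered contributors, affiliations,
abstract, a section tree with ordered paragraphs, and references. Two
rules govern text handling:

- **Formatting omitted, characters conserved.** Paragraph text is the
  concatenated character data with inline tags removed; whitespace and
  Unicode code points are kept exactly as they appear in the XML (no NFC
  normalization, no collapsing). Everything downstream — annotation
  offsets in particular — must be reproducible from the stored text
  alone, so the stored text is the single source of truth.
- **Block intrusions dropped.** Tables, figures, and formulas embedded in
  a paragraph contribute nothing to its text; their tail text, which
  belongs to the surrounding prose, is kept. Captions are not modeled.

References in PMC XML arrive in (at least) four mark-up shapes; the
classifier distinguishes `element-citation`, `mixed-citation`, legacy
`citation` with structured children, and free-text citations
(`UNSTRUCTURED`). The split of legacy `citation` into structured vs.
free-text is this package's judgment call — the shapes are not named
canonically anywhere — and is applied exhaustively: every parseable
reference receives exactly one style. A reference is *incomplete* iff it
has no title and neither pmid nor doi; completion through external
resolver services (CrossRef-style) is a pluggable callable contract, and
a failing resolver never propagates (the reference is returned unchanged
with a logged warning).

## RDFization

Every content-bearing resource — article, journal, section, paragraph,
person, organization, reference, annotation, selector — receives a
deterministic HTTP IRI under a configurable base
(`<base>/<PMCID>#section-…`, `#paragraph-…`, …). Blank nodes are avoided
so annotations can target paragraphs by IRI. The fragment patterns are
implementation-defined; only the article-level pattern
(`<base>/<PMCID>`) is externally constrained.

Notable choices:

- **Author order is emitted** as an `rdf:Seq` under `bibo:authorList`,
  preserving document order. Historical datasets in this style dropped
  the order; we keep it, as ordered authorship is the stated intent of
  the BIBO list model.
- **Dual provenance**: `dcterms:created`/`prov:generatedAtTime` and
  `dcterms:creator`/`prov:wasAttributedTo` are both emitted. The
  generation timestamp is an explicit parameter (defaulting to now) so
  that equal inputs can be tested for graph isomorphism.
- **`dcterms:identifier` carries CURIE-style values** (`pmc:…`, `pmid:…`,
  `doi:…`). This keeps the generic identifier triples distinct from the
  typed `bibo:pmid`/`bibo:doi` literals — necessary for the 1:1 statement
  accounting of the SIO rewrite (below) and harmless to consumers, who
  get the typed properties as well.
- **`foaf:name` is emitted only when a given name exists**; otherwise it
  would duplicate `foaf:surname` and collapse under the SIO has-value
  lineage.
- Exactly one `cnt:chars` literal per paragraph node. This single-literal
  rule is what makes exact-text selectors unambiguous.
- Serialization: Turtle by default, RDF/XML for era compatibility; both
  round-trip to isomorphic graphs, including non-ASCII literals.

## Annotation

Matching is exact string matching against pre-defined dictionaries
(surface → entity IRI, vocabulary key; one surface may map to many
entities). The scanner is a pure-Python multi-pattern sweep; an
independent all-substring brute-force scanner serves as the test oracle.
Conventions, fixed once and used everywhere:

- **Offsets are 1-based, inclusive at both ends, in Unicode code points**
  over the formatting-stripped paragraph text, so
  `end − start + 1 = length(surface)`. The convention is anchored by the
  11-character term *cholesterol* spanning [291, 301].
- **Case**: exact (case-sensitive) by default, with an optional fold mode
  (`str.lower`, which preserves code-point length; a pathological
  locale-sensitive fold falls back to exact comparison).
- **Boundaries**: alphanumeric neighbours block a match by default
  (`Scr` does not match inside `Screen`); a free mode exists.
- **Overlaps**: leftmost-longest. Candidates are ordered by start
  position (longer first at ties) and kept greedily if they do not
  overlap a previously kept match.

One annotation aggregates all occurrences of one term in one document
under one annotator route; its entity set is the union over vocabularies
sharing that route. The offset route (13 vocabularies) additionally
carries hierarchy-expanded related entities — siblings (children of the
entity's parent, excluding itself) plus declared cross-ontology
equivalents, over a user-supplied parent forest and symmetric equivalence
pairs. The exact-text route (5 vocabularies) records matched text only.
Remote annotation services are represented only by this pluggable local
contract; no network calls are made.

### Annotation RDF

Annotations serialize in the Annotation Ontology layout: annotation node
→ document, term body, one selector per occurrence, one topic per entity,
related entities under a distinct predicate, and provenance
(`foaf:Agent` + creation date). Since the original AO namespaces are no
longer served, the concrete predicate IRIs are pinned in one table
(`biotea.vocab.AO_ROLES`); re-pointing that table re-targets the entire
annotation output (e.g. onto the W3C Web Annotation vocabulary). Selector
variants: `ElementSelector` (exact text) for the exact-text route,
`StartEndElementSelector` (exact + start + end) for the offset route,
both addressing the single `cnt:chars` literal of their paragraph via
`onElement`/`onProperty`. Entities of the seven linked vocabularies get
`owl:sameAs` links expanded from per-vocabulary Bio2RDF and
identifiers.org templates; every vocabulary with a topic-page template
yields `rdfs:seeAlso`.

The registry reconciles a counting tension in its sources: the published
totals are 18 vocabularies (13 offset-routed, 5 exact-text-routed), yet
more than 13 candidate ontologies are named for the offset route. The
shipped table honors the totals; the four omitted candidates and the
reasoning are recorded in the header of `src/biotea/data/registry.tsv`.

## SIO rewrite

The Bio2RDF-compatibility rewrite is data, not code: a TSV of (source
IRI, target IRI, kind ∈ class/objprop/dataprop/passthrough). Property
lineage: object properties → `sio:000008` (has attribute), citing and
referencing relations → `sio:000628` (refers to) / `sio:000212` (is
referenced by), data properties → `sio:000300` (has value). Domains and
ranges are not enforced. The class-target column is a reconstruction (the
canonical class correspondence is not available in machine-readable form)
and is flagged as such in the file. Unmapped predicates pass through with
a log note rather than failing. Rewrites are 1:1 and tests assert
`|output| = |input|`; because RDF graphs are statement *sets*, the
RDFizer deliberately never emits two distinct statements that would
rewrite to the same triple (see the identifier and `foaf:name` choices
above). The W3C PROV pair passes through unrewritten for the same reason
— and because PROV is an upper vocabulary Bio2RDF consumers accept as-is.

## Retrieval, index and NACAP

Section-scoped search and entity search use case-insensitive substring
containment (for both the section-title filter and the paragraph term) —
regex dialects are deliberately avoided. "Term" means a surface string;
"topic" means an ontology entity IRI attached to an annotation; a topic's
vocabulary is recovered from its IRI by longest-prefix match against the
registry. The embedded index answers the eight request kinds and is
rebuild-equivalent by construction: the test suite checks every kind
against direct brute-force recomputation from the raw annotation graphs.

NACAP: for a seed term (or entity IRI), the retrieved articles become
nodes; every article pair sharing an annotated term gains one edge per
shared term, weighted by the number of entities associated with that term
**corpus-wide** (the per-pair alternative is defensible but the
corpus-wide reading matches "entities associated with a term"). Edges
with weight ≤ 30 (default) are excluded — the threshold is strict, so a
term with exactly 30 entities draws no edge and one with 31 does. Raising
the threshold can only remove edges.

## Synthetic fixtures

The generator emits JATS articles whose prose is filler drawn from a
seven-consonant sentinel alphabet, with dictionary terms planted as whole
tokens; offsets, counts and reference styles are recorded in a manifest
and re-verified against the reparsed XML before the corpus is returned
(any collision aborts generation). Same spec + seed → identical bytes.
Entity counts per term, a per-term parent in the hierarchy (making a
term's entities mutual siblings), and the four reference styles are all
exercised. Default corpus size used in tests: 3 articles × 3 sections ×
2 paragraphs with three planted terms — small enough that every property
suite (hundreds of randomized cases) runs in seconds.

What the fixtures do **not** emulate: real PMC front-matter richness
(funding, history, license corpora), natural-language ambiguity
(tokenization, hyphenation variants, abbreviation expansion), dictionary
noise, or corpus-scale statistics. Passing tests therefore demonstrate
the correctness of the mechanics — parsing, offset arithmetic, graph
shape, query semantics — not recognition quality on real articles.

The two worked-example fixtures are transcriptions: a protein fixture
whose surfaces map to 2 and 17 UniProt accessions respectively, and a
chemical fixture placing an 11-character term at code points 291–301 of
its paragraph under the section title "Preparation of LT-NLC and
LT-NLC-apo". They pin the offset convention and the one-surface-to-many-
entities behaviour to externally stated values.

## Known limitations

- Only the PMC open-access JATS dialect is parsed; other publisher XML is
  out of scope.
- Structured-abstract subsections are flattened into one paragraph list.
- Case-fold matching assumes a length-preserving fold; texts where
  `str.lower` changes the code-point count are scanned case-sensitively.
- The index is in-memory with JSON persistence; no HTTP service is
  provided.
- The SIO class targets are reconstructions, editable in the shipped
  table.
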