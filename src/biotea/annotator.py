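"""Dictionary-based entity recognition over paragraph text.

Two annotator styles are emulated locally: an offset-reporting route
(``ncbo_like``) that records 1-based inclusive start/end positions and
expands entities through the vocabulary hierarchy (siblings + declared
equivalents), and an exact-text route (``whatizit_like``) that records the
matched text only and may link one surface form to many entities (e.g. one
gene-product name to many protein accessions).

Matching is exact string matching against pre-defined dictionaries; a word
boundary policy (alphanumeric neighbours block a match) prevents surfaces
matching inside longer words, and overlapping candidates are resolved
leftmost-longest.  Offsets are counted in Unicode code points over the
formatting-stripped paragraph text, 1-based and inclusive at both ends, so
a match of length L satisfies end - start + 1 = L.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timezone
from typing import Iterable, Optional

from .model import ArticleDocument
from .registry import VocabularyRegistry
from .rdfizer import paragraph_iri
from .uris import UriPolicy


class DictionaryError(ValueError):
    pass


class AnnotatorConfigError(ValueError):
    pass


@dataclass(frozen=True)
class DictionaryEntry:
    surface: str
    entity: str  # entity IRI
    vocabulary: str  # registry key
    label: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.surface:
            raise DictionaryError("dictionary surface must be non-empty")


@dataclass(frozen=True)
class MatchPolicy:
    case_mode: str = "exact"  # exact | fold
    boundary_mode: str = "word_boundary"  # word_boundary | free
    overlap_rule: str = "leftmost_longest"

    def __post_init__(self) -> None:
        if self.case_mode not in ("exact", "fold"):
            raise ValueError(f"unknown case_mode {self.case_mode!r}")
        if self.boundary_mode not in ("word_boundary", "free"):
            raise ValueError(f"unknown boundary_mode {self.boundary_mode!r}")
        if self.overlap_rule != "leftmost_longest":
            raise ValueError("only leftmost_longest overlap resolution is supported")


@dataclass(frozen=True)
class TermMatch:
    """One occurrence of a surface form inside one paragraph.

    Positions are 1-based inclusive Unicode code-point offsets; they are
    None only for matches recovered from exact-text selectors, which carry
    no positions.
    """

    surface: str
    start: Optional[int]
    end: Optional[int]
    paragraph_ref: str

    def __post_init__(self) -> None:
        if (self.start is None) != (self.end is None):
            raise ValueError("start and end must be both present or both absent")
        if self.start is not None:
            if self.start < 1 or self.end < self.start:
                raise ValueError("positions must satisfy 1 <= start <= end")
            if self.end - self.start + 1 != len(self.surface):
                raise ValueError("end - start + 1 must equal the surface length")


@dataclass
class Annotation:
    """All occurrences of one term in one document under one annotator route."""

    document: str
    term: str
    annotator_id: str  # ncbo_like | whatizit_like
    entities: frozenset  # of (entity IRI, vocabulary key)
    occurrences: list[TermMatch]
    related: frozenset = frozenset()  # hierarchy-expanded entity IRIs
    created: Optional[datetime] = None

    def __post_init__(self) -> None:
        if not self.entities:
            raise ValueError("annotation must link at least one entity")
        if not self.occurrences:
            raise ValueError("annotation must have at least one occurrence")


@dataclass
class OntologyHierarchy:
    """A parent forest plus a symmetric cross-ontology equivalence relation."""

    parent: dict = field(default_factory=dict)  # child IRI -> parent IRI
    equivalents: dict = field(default_factory=dict)  # IRI -> set of IRIs

    def __post_init__(self) -> None:
        for child in self.parent:
            seen = {child}
            node = child
            while node in self.parent:
                node = self.parent[node]
                if node in seen:
                    raise ValueError(f"cycle in hierarchy at {node}")
                seen.add(node)
        for a, partners in list(self.equivalents.items()):
            for b in partners:
                self.equivalents.setdefault(b, set()).add(a)

    @classmethod
    def from_pairs(cls, parent_pairs: Iterable[tuple], equiv_pairs: Iterable[tuple] = ()):
        parent = {child: par for child, par in parent_pairs}
        equivalents: dict = {}
        for a, b in equiv_pairs:
            equivalents.setdefault(a, set()).add(b)
            equivalents.setdefault(b, set()).add(a)
        return cls(parent=parent, equivalents=equivalents)


def expand_related(entity: str, hierarchy: OntologyHierarchy) -> set:
    """Siblings (children of the entity's parent, excluding itself) plus
    declared equivalents.  An entity unknown to the hierarchy expands to
    its equivalents only, possibly the empty set."""
    related = set(hierarchy.equivalents.get(entity, ()))
    parent = hierarchy.parent.get(entity)
    if parent is not None:
        related.update(c for c, p in hierarchy.parent.items()
                       if p == parent and c != entity)
    return related


class CompiledDictionary:
    """Matcher state over a set of surfaces with surface -> entities lookup."""

    def __init__(self, entries: list[DictionaryEntry], policy: MatchPolicy):
        if not entries:
            raise DictionaryError("dictionary must contain at least one entry")
        seen = set()
        dupes = []
        for e in entries:
            key = (e.surface, e.entity)
            if key in seen:
                dupes.append(key)
            seen.add(key)
        if dupes:
            raise DictionaryError(f"duplicate (surface, entity) pairs: {sorted(dupes)}")
        self.policy = policy
        self.entries = list(entries)
        self._lookup: dict = {}
        for e in entries:
            self._lookup.setdefault(self._key(e.surface), []).append(e)
        # surfaces grouped by key, longest first so candidate generation is
        # deterministic; the canonical surface is the first inserted
        self._surfaces = {k: es[0].surface for k, es in self._lookup.items()}

    def _key(self, surface: str) -> str:
        # lower() rather than casefold(): offsets must survive, so the fold
        # has to preserve code-point length for the text being scanned
        return surface.lower() if self.policy.case_mode == "fold" else surface

    def __len__(self) -> int:
        return len(self._surfaces)

    @property
    def surfaces(self) -> list[str]:
        return sorted(self._surfaces.values())

    def lookup(self, surface: str) -> set:
        """(entity, vocabulary) pairs for a surface under the case policy."""
        return {(e.entity, e.vocabulary) for e in self._lookup.get(self._key(surface), ())}

    def canonical_surface(self, matched_text: str) -> str:
        return self._surfaces.get(self._key(matched_text), matched_text)


def compile_dictionary(entries: list[DictionaryEntry],
                       policy: Optional[MatchPolicy] = None) -> CompiledDictionary:
    return CompiledDictionary(entries, policy or MatchPolicy())


def _boundary_ok(text: str, i: int, j: int) -> bool:
    """No alphanumeric character directly adjacent to text[i:j]."""
    if i > 0 and text[i - 1].isalnum():
        return False
    if j < len(text) and text[j].isalnum():
        return False
    return True


def scan_text(text: str, dictionary: CompiledDictionary,
              policy: Optional[MatchPolicy] = None,
              paragraph_ref: str = "") -> list[TermMatch]:
    """Every non-overlapping dictionary match in ``text`` after
    leftmost-longest overlap resolution, sorted by start position."""
    policy = policy or dictionary.policy
    if not text:
        return []
    haystack = text.lower() if policy.case_mode == "fold" else text
    if len(haystack) != len(text):  # pathological locale-sensitive fold
        haystack = text
    candidates: list[TermMatch] = []
    for needle in dictionary._lookup:
        start = haystack.find(needle)
        while start != -1:
            stop = start + len(needle)
            if policy.boundary_mode == "free" or _boundary_ok(text, start, stop):
                candidates.append(TermMatch(
                    surface=text[start:stop],
                    start=start + 1,
                    end=stop,
                    paragraph_ref=paragraph_ref,
                ))
            start = haystack.find(needle, start + 1)
    candidates.sort(key=lambda m: (m.start, -(m.end - m.start)))
    return resolve_overlaps(candidates)


def resolve_overlaps(candidates: list[TermMatch]) -> list[TermMatch]:
    """Leftmost-longest: scan candidates (sorted by start, longer first at
    ties) and keep each one that does not overlap a previously kept match."""
    kept: list[TermMatch] = []
    last_end = 0
    for m in candidates:
        if m.start > last_end:
            kept.append(m)
            last_end = m.end
    return kept


def annotate_document(doc: ArticleDocument,
                      registry: VocabularyRegistry,
                      dictionaries: dict,
                      hierarchy: Optional[OntologyHierarchy] = None,
                      policy: Optional[MatchPolicy] = None,
                      uri_policy: Optional[UriPolicy] = None,
                      created: Optional[datetime] = None) -> list[Annotation]:
    """Scan the abstract and every section of a document against
    per-vocabulary dictionaries and group matches into annotations.

    One annotation is produced per (document, term, annotator route); its
    entity set is the union over vocabularies sharing that route.  The
    offset route additionally carries hierarchy-expanded related entities.
    """
    hierarchy = hierarchy or OntologyHierarchy()
    uri_policy = uri_policy or UriPolicy()
    created = created or datetime.now(timezone.utc)
    unknown = set(dictionaries) - set(registry.keys())
    if unknown:
        raise AnnotatorConfigError(f"dictionaries for unknown vocabularies: {sorted(unknown)}")

    lid = doc.local_id
    article_iri = str(uri_policy.mint("article", [lid]))
    units = [(path, para) for path, _sec, para in doc.iter_paragraph_units()]

    grouped: dict = {}
    for vocab_key, dictionary in sorted(dictionaries.items()):
        route = registry[vocab_key].route
        for path, para in units:
            p_iri = str(paragraph_iri(uri_policy, lid, path, para.index))
            for match in scan_text(para.text, dictionary, policy, paragraph_ref=p_iri):
                term = dictionary.canonical_surface(match.surface)
                entities = dictionary.lookup(match.surface)
                key = (term, route)
                bucket = grouped.setdefault(key, {"entities": set(), "occ": []})
                bucket["entities"].update(entities)
                bucket["occ"].append(match)

    annotations = []
    for (term, route), bucket in sorted(grouped.items()):
        occurrences = sorted(bucket["occ"], key=lambda m: (m.paragraph_ref, m.start))
        related: set = set()
        if route == "ncbo_like":
            for entity, _vocab in bucket["entities"]:
                related |= expand_related(entity, hierarchy)
        annotations.append(Annotation(
            document=article_iri,
            term=term,
            annotator_id=route,
            entities=frozenset(bucket["entities"]),
            occurrences=occurrences,
            related=frozenset(related),
            created=created,
        ))
    return annotations


# -- dictionary / hierarchy file formats ------------------------------------


def load_dictionary_entries(lines) -> list[DictionaryEntry]:
    """TSV: surface, entity IRI, vocabulary key, optional label; '#' comments."""
    entries = []
    for ln in lines:
        ln = ln.rstrip("\n")
        if not ln.strip() or ln.lstrip().startswith("#"):
            continue
        cols = ln.split("\t")
        if len(cols) < 3:
            raise DictionaryError(f"dictionary row needs >= 3 columns: {ln!r}")
        label = cols[3] if len(cols) > 3 and cols[3] else None
        entries.append(DictionaryEntry(surface=cols[0], entity=cols[1],
                                       vocabulary=cols[2], label=label))
    return entries


def load_hierarchy(parent_lines, equiv_lines=()) -> OntologyHierarchy:
    """Edge-list TSVs: (child IRI, parent IRI) and optional (IRI, IRI)
    equivalence pairs."""
    def pairs(lines):
        for ln in lines:
            ln = ln.rstrip("\n")
            if not ln.strip() or ln.lstrip().startswith("#"):
                continue
            cols = ln.split("\t")
            if len(cols) != 2:
                raise DictionaryError(f"edge row needs 2 columns: {ln!r}")
            yield cols[0], cols[1]

    return OntologyHierarchy.from_pairs(pairs(parent_lines), pairs(equiv_lines))
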