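"""In-memory model of a scholarly article parsed from JATS/NXML.

The model is deliberately flat and serializable: everything downstream
(RDFization, annotation offsets, retrieval) is derived from the text stored
here, so paragraph text is kept byte-for-byte as extracted — no whitespace
collapsing, no Unicode normalization.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from enum import Enum
from typing import Any, Optional


class ReferenceStyle(Enum):
    """The four reference mark-up shapes found in PMC article XML."""

    ELEMENT_CITATION = "element-citation"
    MIXED_CITATION = "mixed-citation"
    CITATION_LEGACY = "citation"
    UNSTRUCTURED = "unstructured"


@dataclass
class IdentifierSet:
    pmcid: Optional[str] = None
    pmid: Optional[str] = None
    doi: Optional[str] = None
    generic: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in ("pmcid", "pmid", "doi"):
            value = getattr(self, name)
            if value is not None and not value:
                raise ValueError(f"{name} must be non-empty when present")
        if self.pmcid is not None:
            body = self.pmcid.removeprefix("PMC")
            if not (self.pmcid.startswith("PMC") and body.isdigit()):
                raise ValueError(f"pmcid must match 'PMC' + digits, got {self.pmcid!r}")


@dataclass
class Contributor:
    surname: str
    given: Optional[str] = None  # may be bare initials; stored verbatim
    affiliation_refs: list[str] = field(default_factory=list)
    email: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.surname:
            raise ValueError("contributor surname must be non-empty")


@dataclass
class Organization:
    key: str
    name: str


@dataclass
class JournalInfo:
    title: Optional[str] = None
    issn: Optional[str] = None
    publisher: Optional[str] = None
    volume: Optional[str] = None
    issue: Optional[str] = None
    fpage: Optional[str] = None
    lpage: Optional[str] = None


@dataclass
class Paragraph:
    index: int
    text: str  # formatting-stripped Unicode; offsets are counted over this


@dataclass
class Section:
    index: int
    title: str  # possibly empty, never None
    paragraphs: list[Paragraph] = field(default_factory=list)
    subsections: list["Section"] = field(default_factory=list)


@dataclass
class Reference:
    style: ReferenceStyle
    authors: list[Contributor] = field(default_factory=list)
    title: Optional[str] = None
    source: Optional[str] = None
    year: Optional[str] = None
    volume: Optional[str] = None
    pages: Optional[str] = None
    identifiers: IdentifierSet = field(default_factory=IdentifierSet)
    raw: str = ""
    incomplete: bool = False

    @staticmethod
    def incomplete_rule(title: Optional[str], identifiers: IdentifierSet) -> bool:
        """A reference is incomplete iff it has no title and no pmid/doi."""
        return title is None and identifiers.pmid is None and identifiers.doi is None

    def __post_init__(self) -> None:
        expected = self.incomplete_rule(self.title, self.identifiers)
        if self.incomplete != expected:
            raise ValueError(
                "incomplete flag inconsistent: must be true iff title is null "
                "and identifiers carry neither pmid nor doi"
            )


@dataclass
class ArticleDocument:
    identifiers: IdentifierSet
    journal: JournalInfo = field(default_factory=JournalInfo)
    title: str = ""
    keywords: list[str] = field(default_factory=list)
    contributors: list[Contributor] = field(default_factory=list)
    affiliations: list[Organization] = field(default_factory=list)
    abstract: Optional[Section] = None
    sections: list[Section] = field(default_factory=list)
    references: list[Reference] = field(default_factory=list)
    license_note: Optional[str] = None
    article_type: Optional[str] = None  # JATS article-type attribute, e.g. research-article

    def __post_init__(self) -> None:
        if self.identifiers.pmcid is None and not self.identifiers.generic:
            raise ValueError("document needs a pmcid or a synthetic local id")
        keys = [org.key for org in self.affiliations]
        if len(keys) != len(set(keys)):
            raise ValueError("affiliation keys must be unique within a document")

    @property
    def local_id(self) -> str:
        """Stable per-document key: the pmcid, else the first generic id."""
        return self.identifiers.pmcid or self.identifiers.generic[0]

    def iter_paragraph_units(self):
        """Yield (section_path, section, paragraph) over abstract + body, in order.

        section_path is a tuple of indices from the top (the abstract uses
        the reserved path ("abstract",)).  This single traversal order is
        shared by the RDFizer and the annotator so paragraph IRIs agree.
        """
        if self.abstract is not None:
            for para in self.abstract.paragraphs:
                yield ("abstract",), self.abstract, para
        yield from _walk_sections(self.sections, ())


def _walk_sections(sections: list[Section], prefix: tuple):
    for sec in sections:
        path = prefix + (sec.index,)
        for para in sec.paragraphs:
            yield path, sec, para
        yield from _walk_sections(sec.subsections, path)


# ---------------------------------------------------------------------------
# Canonical debug form: a plain-dict serialization used for round-trip tests
# and `biotea parse --dump-model`.


def to_debug_dict(doc: ArticleDocument) -> dict[str, Any]:
    d = dataclasses.asdict(doc)
    _style_to_str(d)
    return d


def _style_to_str(d: dict) -> None:
    for ref in d.get("references", []):
        ref["style"] = ref["style"].value if isinstance(ref["style"], ReferenceStyle) else ref["style"]


def from_debug_dict(d: dict[str, Any]) -> ArticleDocument:
    def mk_section(s: Optional[dict]) -> Optional[Section]:
        if s is None:
            return None
        return Section(
            index=s["index"],
            title=s["title"],
            paragraphs=[Paragraph(**p) for p in s["paragraphs"]],
            subsections=[mk_section(sub) for sub in s["subsections"]],
        )

    return ArticleDocument(
        identifiers=IdentifierSet(**d["identifiers"]),
        journal=JournalInfo(**d["journal"]),
        title=d["title"],
        keywords=list(d["keywords"]),
        contributors=[Contributor(**c) for c in d["contributors"]],
        affiliations=[Organization(**o) for o in d["affiliations"]],
        abstract=mk_section(d["abstract"]),
        sections=[mk_section(s) for s in d["sections"]],
        references=[
            Reference(
                style=ReferenceStyle(r["style"]),
                authors=[Contributor(**c) for c in r["authors"]],
                title=r["title"],
                source=r["source"],
                year=r["year"],
                volume=r["volume"],
                pages=r["pages"],
                identifiers=IdentifierSet(**r["identifiers"]),
                raw=r["raw"],
                incomplete=r["incomplete"],
            )
            for r in d["references"]
        ],
        license_note=d["license_note"],
        article_type=d.get("article_type"),
    )
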