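"""JATS/NXML parsing: article metadata, sections/paragraphs, references.

Only the PMC open-access dialect of JATS is handled.  Text extraction keeps
the original character data exactly (no whitespace collapsing) so that
annotation offsets computed later remain reproducible from the stored text
alone.  Tables, figures and formulas embedded in paragraphs are dropped:
paragraph text is the running prose with formatting omitted.
"""
from __future__ import annotations

import logging
from typing import Optional

from lxml import etree

from .model import (
    ArticleDocument,
    Contributor,
    IdentifierSet,
    JournalInfo,
    Organization,
    Paragraph,
    Reference,
    ReferenceStyle,
    Section,
)

logger = logging.getLogger(__name__)


class JatsParseError(ValueError):
    """Malformed XML; message carries the parser's line/column report."""


class UnsupportedInputError(ValueError):
    """Well-formed XML whose root is not a JATS `article`."""


class ReferenceClassificationError(ValueError):
    """A `ref` node with no classifiable content."""


# Block-level structures removed from paragraph prose entirely.
_DROP_TAGS = frozenset(
    {"table-wrap", "table", "fig", "disp-formula", "inline-formula",
     "graphic", "media", "supplementary-material"}
)

_STRUCTURED_CITATION_CHILDREN = frozenset(
    {"person-group", "article-title", "source", "year", "volume", "fpage",
     "lpage", "pub-id", "publisher-name", "name", "collab"}
)


def _localname(el) -> str:
    return etree.QName(el).localname if isinstance(el.tag, str) else ""


def extract_text(node) -> str:
    """Concatenate character data of ``node`` with all inline tags removed.

    Character data is not otherwise modified.  Elements in the drop set
    (tables, figures, formulas) contribute nothing, but their tail text —
    which belongs to the surrounding prose — is kept.
    """
    if node is None:
        return ""
    parts: list[str] = []
    _collect_text(node, parts, top=True)
    return "".join(parts)


def _collect_text(el, parts: list[str], top: bool = False) -> None:
    if isinstance(el.tag, str) and _localname(el) in _DROP_TAGS and not top:
        return
    if el.text:
        parts.append(el.text)
    for child in el:
        if isinstance(child.tag, str):
            _collect_text(child, parts)
        if child.tail:
            parts.append(child.tail)


def parse_jats(xml: bytes) -> ArticleDocument:
    """Parse JATS/NXML bytes into an :class:`ArticleDocument`.

    Raises :class:`JatsParseError` on malformed XML and
    :class:`UnsupportedInputError` when the root element is not ``article``.
    Unknown elements are skipped with a logged warning.
    """
    try:
        root = etree.fromstring(xml)
    except etree.XMLSyntaxError as exc:
        raise JatsParseError(f"malformed XML: {exc}") from exc
    if _localname(root) != "article":
        raise UnsupportedInputError(
            f"root element is <{_localname(root)}>, expected <article>"
        )

    front = _find(root, "front")
    meta = _find(front, "article-meta") if front is not None else None
    journal_meta = _find(front, "journal-meta") if front is not None else None

    identifiers = _parse_identifiers(meta)
    journal = _parse_journal(journal_meta, meta)
    title = extract_text(_find_deep(meta, "title-group", "article-title")) if meta is not None else ""
    keywords = [extract_text(k) for k in _iter_deep(meta, "kwd-group", "kwd")] if meta is not None else []
    contributors, affiliations = _parse_contributors(meta)
    abstract = _parse_abstract(meta)
    license_note = None
    if meta is not None:
        lic = _find_deep(meta, "permissions", "license")
        if lic is not None:
            license_note = extract_text(lic).strip() or None

    body = _find(root, "body")
    sections = _parse_body(body) if body is not None else []

    references = []
    back = _find(root, "back")
    if back is not None:
        for ref in _iter_deep(back, "ref-list", "ref"):
            try:
                style = classify_reference(ref)
            except ReferenceClassificationError:
                logger.warning("skipping empty <ref> element")
                continue
            references.append(normalize_reference(ref, style))

    if identifiers.pmcid is None and not identifiers.generic:
        identifiers.generic.append("local:untitled-article")

    return ArticleDocument(
        identifiers=identifiers,
        journal=journal,
        title=title,
        keywords=keywords,
        contributors=contributors,
        affiliations=affiliations,
        abstract=abstract,
        sections=sections,
        references=references,
        license_note=license_note,
        article_type=root.get("article-type"),
    )


# -- front matter -----------------------------------------------------------


def _find(el, name: str):
    if el is None:
        return None
    for child in el:
        if isinstance(child.tag, str) and _localname(child) == name:
            return child
    return None


def _find_deep(el, *names: str):
    cur = el
    for name in names:
        cur = _find(cur, name)
        if cur is None:
            return None
    return cur


def _iter_deep(el, container: str, item: str):
    if el is None:
        return
    for cont in el.iter():
        if isinstance(cont.tag, str) and _localname(cont) == container:
            for child in cont:
                if isinstance(child.tag, str) and _localname(child) == item:
                    yield child


def _parse_identifiers(meta) -> IdentifierSet:
    ids = IdentifierSet(generic=[])
    if meta is None:
        return ids
    for aid in meta.iter():
        if not isinstance(aid.tag, str) or _localname(aid) != "article-id":
            continue
        kind = (aid.get("pub-id-type") or "").lower()
        value = (aid.text or "").strip()
        if not value:
            continue
        if kind in ("pmcid", "pmc"):
            ids.pmcid = value if value.startswith("PMC") else f"PMC{value}"
        elif kind == "pmid":
            ids.pmid = value
        elif kind == "doi":
            ids.doi = value
        else:
            ids.generic.append(value)
    return ids


def _parse_journal(journal_meta, article_meta) -> JournalInfo:
    info = JournalInfo()
    if journal_meta is not None:
        jt = _find_deep(journal_meta, "journal-title-group", "journal-title")
        if jt is None:
            jt = _find(journal_meta, "journal-title")
        info.title = extract_text(jt).strip() or None if jt is not None else None
        issn = _find(journal_meta, "issn")
        info.issn = (issn.text or "").strip() or None if issn is not None else None
        pub = _find_deep(journal_meta, "publisher", "publisher-name")
        info.publisher = extract_text(pub).strip() or None if pub is not None else None
    if article_meta is not None:
        for name in ("volume", "issue", "fpage", "lpage"):
            el = _find(article_meta, name)
            if el is not None and (el.text or "").strip():
                setattr(info, name, el.text.strip())
    return info


def _parse_contributors(meta) -> tuple[list[Contributor], list[Organization]]:
    contributors: list[Contributor] = []
    affiliations: list[Organization] = []
    if meta is None:
        return contributors, affiliations
    for contrib in _iter_deep(meta, "contrib-group", "contrib"):
        name = _find(contrib, "name")
        surname_el = _find(name, "surname") if name is not None else None
        if surname_el is None or not (surname_el.text or "").strip():
            logger.warning("skipping contributor without a surname")
            continue
        given_el = _find(name, "given-names")
        email_el = _find(contrib, "email")
        refs = [
            x.get("rid")
            for x in contrib
            if isinstance(x.tag, str) and _localname(x) == "xref"
            and x.get("ref-type") == "aff" and x.get("rid")
        ]
        contributors.append(
            Contributor(
                surname=surname_el.text.strip(),
                given=(given_el.text or "").strip() or None if given_el is not None else None,
                affiliation_refs=refs,
                email=(email_el.text or "").strip() or None if email_el is not None else None,
            )
        )
    seen: set[str] = set()
    for aff in meta.iter():
        if not isinstance(aff.tag, str) or _localname(aff) != "aff":
            continue
        key = aff.get("id") or f"aff{len(affiliations) + 1}"
        if key in seen:
            continue
        seen.add(key)
        label = _find(aff, "label")
        text = extract_text(aff)
        if label is not None and label.text:
            text = text.replace(label.text, "", 1)
        affiliations.append(Organization(key=key, name=text.strip()))
    return contributors, affiliations


def _parse_abstract(meta) -> Optional[Section]:
    if meta is None:
        return None
    abstract = _find(meta, "abstract")
    if abstract is None:
        return None
    title_el = _find(abstract, "title")
    paragraphs = [
        Paragraph(index=i, text=extract_text(p))
        for i, p in enumerate(c for c in abstract if isinstance(c.tag, str) and _localname(c) == "p")
    ]
    # structured abstracts nest their paragraphs inside <sec>
    if not paragraphs:
        texts = [extract_text(p) for p in abstract.iter() if isinstance(p.tag, str) and _localname(p) == "p"]
        paragraphs = [Paragraph(index=i, text=t) for i, t in enumerate(texts)]
    return Section(index=0, title=extract_text(title_el) if title_el is not None else "Abstract",
                   paragraphs=paragraphs)


# -- body -------------------------------------------------------------------

_KNOWN_BODY_TAGS = frozenset({"sec", "p", "title"} | _DROP_TAGS)


def _parse_body(body) -> list[Section]:
    sections: list[Section] = []
    loose: list[Paragraph] = []
    for child in body:
        if not isinstance(child.tag, str):
            continue
        tag = _localname(child)
        if tag == "sec":
            sections.append(_parse_section(child, len(sections)))
        elif tag == "p":
            loose.append(Paragraph(index=len(loose), text=extract_text(child)))
        elif tag not in _KNOWN_BODY_TAGS:
            logger.warning("ignoring unknown body element <%s>", tag)
    if loose:
        sections.insert(0, Section(index=0, title="", paragraphs=loose))
        for i, sec in enumerate(sections):
            sec.index = i
    return sections


def _parse_section(sec, index: int) -> Section:
    title_el = _find(sec, "title")
    paragraphs: list[Paragraph] = []
    subsections: list[Section] = []
    for child in sec:
        if not isinstance(child.tag, str):
            continue
        tag = _localname(child)
        if tag == "p":
            paragraphs.append(Paragraph(index=len(paragraphs), text=extract_text(child)))
        elif tag == "sec":
            subsections.append(_parse_section(child, len(subsections)))
        elif tag not in _KNOWN_BODY_TAGS:
            logger.warning("ignoring unknown section element <%s>", tag)
    return Section(
        index=index,
        title=extract_text(title_el) if title_el is not None else "",
        paragraphs=paragraphs,
        subsections=subsections,
    )


# -- references -------------------------------------------------------------


def classify_reference(ref) -> ReferenceStyle:
    """Assign one of the four PMC reference mark-up styles to a ``ref`` node."""
    children = [c for c in ref if isinstance(c.tag, str)]
    text = (ref.text or "").strip()
    if not children and not text:
        raise ReferenceClassificationError("empty <ref> element")
    for child in children:
        tag = _localname(child)
        if tag == "element-citation":
            return ReferenceStyle.ELEMENT_CITATION
        if tag == "mixed-citation":
            return ReferenceStyle.MIXED_CITATION
        if tag == "citation":
            # legacy citation splits two ways: structured children vs free text
            if any(_localname(g) in _STRUCTURED_CITATION_CHILDREN
                   for g in child if isinstance(g.tag, str)):
                return ReferenceStyle.CITATION_LEGACY
            return ReferenceStyle.UNSTRUCTURED
    return ReferenceStyle.UNSTRUCTURED


def normalize_reference(ref, style: ReferenceStyle) -> Reference:
    """Extract whatever structured fields the node offers into a Reference.

    Unrecoverable fields stay null; the raw text is always retained and the
    incomplete flag follows the no-title-and-no-pmid/doi rule.
    """
    cite = None
    for child in ref:
        if isinstance(child.tag, str) and _localname(child) in (
                "element-citation", "mixed-citation", "citation"):
            cite = child
            break
    node = cite if cite is not None else ref

    raw = extract_text(node)
    label = _find(ref, "label")
    if cite is None and label is not None and label.text:
        raw = raw.replace(label.text, "", 1).strip()

    title_el = None
    for el in node.iter():
        if isinstance(el.tag, str) and _localname(el) == "article-title":
            title_el = el
            break
    title = extract_text(title_el) or None if title_el is not None else None

    def field_text(name: str) -> Optional[str]:
        for el in node.iter():
            if isinstance(el.tag, str) and _localname(el) == name and (el.text or "").strip():
                return el.text.strip()
        return None

    source = field_text("source")
    year = field_text("year")
    volume = field_text("volume")
    fpage, lpage = field_text("fpage"), field_text("lpage")
    pages = f"{fpage}-{lpage}" if fpage and lpage else fpage

    ids = IdentifierSet(generic=[])
    for el in node.iter():
        if isinstance(el.tag, str) and _localname(el) == "pub-id":
            kind = (el.get("pub-id-type") or "").lower()
            value = (el.text or "").strip()
            if not value:
                continue
            if kind == "pmid":
                ids.pmid = value
            elif kind == "doi":
                ids.doi = value
            else:
                ids.generic.append(value)

    authors = []
    for name in node.iter():
        if isinstance(name.tag, str) and _localname(name) == "name":
            surname = _find(name, "surname")
            if surname is None or not (surname.text or "").strip():
                continue
            given = _find(name, "given-names")
            authors.append(Contributor(
                surname=surname.text.strip(),
                given=(given.text or "").strip() or None if given is not None else None,
            ))

    return Reference(
        style=style,
        authors=authors,
        title=title,
        source=source,
        year=year,
        volume=volume,
        pages=pages,
        identifiers=ids,
        raw=raw,
        incomplete=Reference.incomplete_rule(title, ids),
    )
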