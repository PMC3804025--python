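"""Deterministic URI minting for every resource the pipeline creates.

One article gets one HTTP IRI under the configured base; everything inside
it (sections, paragraphs, people, references, annotations, selectors) hangs
off that IRI as a fragment so content-bearing resources are addressable —
never blank nodes — and annotations can target them.
"""
from __future__ import annotations

from dataclasses import dataclass
from urllib.parse import quote

from rdflib import URIRef

DEFAULT_ARTICLE_BASE = "http://biotea.idiginfo.org/pubmedOpenAccess/rdf"


class UriPolicyError(ValueError):
    """Unknown resource kind or empty key list."""


#: kind -> fragment pattern; {keys} is the '-'-joined, percent-encoded key list.
_FRAGMENT_PATTERNS = {
    "section": "section-{keys}",
    "paragraph": "paragraph-{keys}",
    "person": "person-{keys}",
    "organization": "org-{keys}",
    "reference": "ref-{keys}",
    "annotation": "annotation-{keys}",
    "selector": "selector-{keys}",
    "authorlist": "authors",
    "journal": "journal",
}


@dataclass(frozen=True)
class UriPolicy:
    """Minting rules: same inputs always give the same IRI."""

    article_base: str = DEFAULT_ARTICLE_BASE
    agent_name: str = "rdfizer"

    def mint(self, kind: str, keys: list[str] | tuple) -> URIRef:
        keys = [str(k) for k in keys]
        if not keys:
            raise UriPolicyError("keys must be non-empty")
        if kind == "article":
            return URIRef(f"{self.article_base}/{quote(keys[0], safe='')}")
        if kind == "agent":
            return URIRef(f"{self.article_base}/agent/{quote(keys[0], safe='')}")
        pattern = _FRAGMENT_PATTERNS.get(kind)
        if pattern is None:
            raise UriPolicyError(f"unknown resource kind {kind!r}")
        article_iri = self.mint("article", [keys[0]])
        joined = "-".join(quote(k, safe="") for k in keys[1:])
        if "{keys}" in pattern and not joined:
            raise UriPolicyError(f"kind {kind!r} needs local keys after the article id")
        return URIRef(f"{article_iri}#{pattern.format(keys=joined)}")

    @property
    def agent_iri(self) -> URIRef:
        return self.mint("agent", [self.agent_name])


def mint_uri(policy: UriPolicy, kind: str, keys: list[str] | tuple) -> URIRef:
    """Functional wrapper over :meth:`UriPolicy.mint`."""
    return policy.mint(kind, keys)
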