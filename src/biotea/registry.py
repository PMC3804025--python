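"""The vocabulary registry: which controlled vocabularies are annotated,
by which annotator route, and which yield linked-data IRIs.

The default table (data/registry.tsv) ships 18 vocabularies — 13 routed to
the offset-reporting annotator (``ncbo_like``) and 5 to the exact-text
annotator (``whatizit_like``) — of which exactly 7 carry Bio2RDF and
identifiers.org owl:sameAs templates.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from typing import Optional

ROUTES = ("ncbo_like", "whatizit_like")


class RegistryError(ValueError):
    pass


@dataclass(frozen=True)
class VocabularyRecord:
    key: str
    display_name: str
    route: str  # ncbo_like | whatizit_like
    bio2rdf_linked: bool
    entity_prefix: str  # IRI prefix under which this vocabulary's entities live
    identifiersorg_template: Optional[str] = None  # '{id}' placeholder
    bio2rdf_template: Optional[str] = None
    seealso_template: Optional[str] = None

    def entity_iri(self, local_id: str) -> str:
        return self.entity_prefix + local_id

    def local_id(self, entity_iri: str) -> str:
        if not entity_iri.startswith(self.entity_prefix):
            raise RegistryError(f"{entity_iri} is not under {self.key} prefix")
        return entity_iri[len(self.entity_prefix):]


class VocabularyRegistry:
    """Routing table over vocabulary records, keyed by registry key."""

    def __init__(self, records: list[VocabularyRecord]):
        self.records = {r.key: r for r in records}
        if len(self.records) != len(records):
            raise RegistryError("duplicate vocabulary keys")

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, key: str) -> bool:
        return key in self.records

    def __getitem__(self, key: str) -> VocabularyRecord:
        try:
            return self.records[key]
        except KeyError:
            raise RegistryError(f"unknown vocabulary key {key!r}") from None

    def keys(self):
        return self.records.keys()

    def by_route(self, route: str) -> list[VocabularyRecord]:
        if route not in ROUTES:
            raise RegistryError(f"unknown annotator route {route!r}")
        return [r for r in self.records.values() if r.route == route]

    def linked(self) -> list[VocabularyRecord]:
        return [r for r in self.records.values() if r.bio2rdf_linked]

    def vocabulary_of(self, entity_iri: str) -> Optional[str]:
        """Recover the vocabulary key of an entity IRI by longest-prefix match."""
        best = None
        for rec in self.records.values():
            if entity_iri.startswith(rec.entity_prefix):
                if best is None or len(rec.entity_prefix) > len(best.entity_prefix):
                    best = rec
        return best.key if best else None


def load_registry(lines) -> VocabularyRegistry:
    """Load a registry from an iterable of TSV lines ('#' comments allowed)."""
    rows = [ln for ln in lines if ln.strip() and not ln.lstrip().startswith("#")]
    records = []
    for row in csv.reader(rows, delimiter="\t"):
        if len(row) != 8:
            raise RegistryError(f"registry row needs 8 columns, got {len(row)}: {row!r}")
        key, name, route, linked, prefix, ids_t, b2r_t, see_t = (c.strip() for c in row)
        if route not in ROUTES:
            raise RegistryError(f"unknown route {route!r} for vocabulary {key!r}")
        records.append(VocabularyRecord(
            key=key,
            display_name=name,
            route=route,
            bio2rdf_linked=linked.lower() == "true",
            entity_prefix=prefix,
            identifiersorg_template=None if ids_t == "-" else ids_t,
            bio2rdf_template=None if b2r_t == "-" else b2r_t,
            seealso_template=None if see_t == "-" else see_t,
        ))
    return VocabularyRegistry(records)


def default_registry() -> VocabularyRegistry:
    """The shipped 18-vocabulary registry (13 ncbo_like / 5 whatizit_like,
    7 Bio2RDF-linked)."""
    text = resources.files("biotea.data").joinpath("registry.tsv").read_text("utf-8")
    return load_registry(text.splitlines())
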