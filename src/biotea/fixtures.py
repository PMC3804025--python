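"""Deterministic synthetic corpora with ground-truth manifests.

The generator emits small JATS articles whose prose is built from a
sentinel filler alphabet that cannot collide with planted dictionary
terms, so every manifest claim (section/paragraph counts, 1-based
inclusive term offsets, per-term entity counts, reference styles) is
exact by construction and re-derivable from the emitted files.

Two worked-example fixtures are packaged alongside: a protein fixture in
which the surface form "Scr" maps to two UniProt accessions and "lacZ" to
seventeen, and a chemical fixture in which "cholesterol" maps to the ChEBI
entity 16113 and sits at code points 291-301 of its paragraph.
"""
from __future__ import annotations

import random
from dataclasses import dataclass, field
from lxml import etree

from .annotator import DictionaryEntry, OntologyHierarchy
from .jats import parse_jats
from .model import ReferenceStyle
from .registry import VocabularyRegistry, default_registry


class GenerationError(RuntimeError):
    pass


@dataclass(frozen=True)
class PlantedTerm:
    surface: str
    vocabulary: str
    n_entities: int
    occurrences: int  # per article


@dataclass
class FixtureSpec:
    seed: int = 0
    n_articles: int = 3
    sections_per_article: int = 3
    paragraphs_per_section: int = 2
    planted_terms: list[PlantedTerm] = field(default_factory=list)
    reference_styles_mix: list[ReferenceStyle] = field(
        default_factory=lambda: list(ReferenceStyle))


@dataclass
class PlantedOccurrence:
    surface: str
    section_index: int
    paragraph_index: int
    start: int  # 1-based inclusive code points
    end: int


@dataclass
class ArticleTruth:
    pmcid: str
    n_sections: int
    n_paragraphs: int
    occurrences: list[PlantedOccurrence] = field(default_factory=list)
    reference_styles: list[ReferenceStyle] = field(default_factory=list)


@dataclass
class GroundTruthManifest:
    articles: dict = field(default_factory=dict)  # pmcid -> ArticleTruth
    entity_counts: dict = field(default_factory=dict)  # surface -> n_entities


@dataclass
class GeneratedCorpus:
    jats: dict  # filename -> bytes
    dictionary: list  # DictionaryEntry
    hierarchy: OntologyHierarchy
    manifest: GroundTruthManifest


_FILLER_ALPHABET = "zqxkvwj"


def _filler_word(rng: random.Random) -> str:
    return "".join(rng.choice(_FILLER_ALPHABET) for _ in range(rng.randint(3, 7)))


def generate_corpus(spec: FixtureSpec,
                    registry: VocabularyRegistry | None = None) -> GeneratedCorpus:
    """Emit a deterministic corpus: same spec + seed give identical bytes.

    Planted offsets are verified against the emitted XML (reparsed through
    the JATS parser) before returning; any collision between a planted term
    and surrounding text raises :class:`GenerationError`.
    """
    registry = registry or default_registry()
    for term in spec.planted_terms:
        if term.vocabulary not in registry:
            raise GenerationError(f"unknown vocabulary {term.vocabulary!r}")
    for a in spec.planted_terms:
        for b in spec.planted_terms:
            if a is not b and a.surface in b.surface:
                raise GenerationError(
                    f"planted term {a.surface!r} is a substring of {b.surface!r}")

    rng = random.Random(spec.seed)
    dictionary: list[DictionaryEntry] = []
    parent_pairs = []
    entity_counts: dict = {}
    for t_idx, term in enumerate(spec.planted_terms):
        prefix = registry[term.vocabulary].entity_prefix
        parent = f"{prefix}G{t_idx:03d}"
        for e_idx in range(term.n_entities):
            entity = f"{prefix}E{t_idx:03d}{e_idx:03d}"
            dictionary.append(DictionaryEntry(
                surface=term.surface, entity=entity, vocabulary=term.vocabulary,
                label=f"{term.surface} [{e_idx}]"))
            parent_pairs.append((entity, parent))
        entity_counts[term.surface] = term.n_entities
    hierarchy = OntologyHierarchy.from_pairs(parent_pairs)

    jats: dict = {}
    manifest = GroundTruthManifest(entity_counts=entity_counts)
    for a_idx in range(spec.n_articles):
        pmcid = f"PMC9{spec.seed % 1000:03d}{a_idx:03d}"
        truth, xml = _generate_article(spec, rng, pmcid, a_idx)
        jats[f"{pmcid}.nxml"] = xml
        manifest.articles[pmcid] = truth
        _self_check(xml, truth)
    return GeneratedCorpus(jats=jats, dictionary=dictionary,
                           hierarchy=hierarchy, manifest=manifest)


def _generate_article(spec: FixtureSpec, rng: random.Random, pmcid: str,
                      a_idx: int):
    # assign each planted occurrence to a (section, paragraph) slot
    slots: dict = {}
    n_paras = spec.sections_per_article * spec.paragraphs_per_section
    for term in spec.planted_terms:
        for _ in range(term.occurrences):
            slot = rng.randrange(n_paras)
            slots.setdefault(slot, []).append(term.surface)

    truth = ArticleTruth(pmcid=pmcid,
                         n_sections=spec.sections_per_article,
                         n_paragraphs=n_paras)

    root = etree.Element("article", attrib={"article-type": "research-article"})
    front = etree.SubElement(root, "front")
    jm = etree.SubElement(front, "journal-meta")
    jt = etree.SubElement(etree.SubElement(jm, "journal-title-group"), "journal-title")
    jt.text = "Journal of Synthetic Fixtures"
    issn = etree.SubElement(jm, "issn")
    issn.text = "0000-000X"
    am = etree.SubElement(front, "article-meta")
    aid = etree.SubElement(am, "article-id", attrib={"pub-id-type": "pmcid"})
    aid.text = pmcid
    pmid = etree.SubElement(am, "article-id", attrib={"pub-id-type": "pmid"})
    pmid.text = str(90000000 + spec.seed * 100 + a_idx)
    at = etree.SubElement(etree.SubElement(am, "title-group"), "article-title")
    at.text = f"Synthetic article {a_idx} ({' '.join(_filler_word(rng) for _ in range(3))})"
    cg = etree.SubElement(am, "contrib-group")
    for surname in ("Alpha", "Beta"):
        name = etree.SubElement(
            etree.SubElement(cg, "contrib", attrib={"contrib-type": "author"}), "name")
        etree.SubElement(name, "surname").text = surname
        etree.SubElement(name, "given-names").text = surname[0] + "."
    abstract = etree.SubElement(am, "abstract")
    etree.SubElement(abstract, "p").text = " ".join(
        _filler_word(rng) for _ in range(12))

    body = etree.SubElement(root, "body")
    for s_idx in range(spec.sections_per_article):
        sec = etree.SubElement(body, "sec")
        etree.SubElement(sec, "title").text = f"Section {s_idx}"
        for p_idx in range(spec.paragraphs_per_section):
            slot = s_idx * spec.paragraphs_per_section + p_idx
            text, offsets = _paragraph_text(rng, slots.get(slot, []))
            etree.SubElement(sec, "p").text = text
            for surface, start, end in offsets:
                truth.occurrences.append(PlantedOccurrence(
                    surface=surface, section_index=s_idx,
                    paragraph_index=p_idx, start=start, end=end))

    back = etree.SubElement(root, "back")
    ref_list = etree.SubElement(back, "ref-list")
    for r_idx, style in enumerate(spec.reference_styles_mix):
        ref_list.append(_reference_node(style, r_idx))
        truth.reference_styles.append(style)

    xml = etree.tostring(root, xml_declaration=True, encoding="UTF-8",
                         pretty_print=False)
    return truth, xml


def _paragraph_text(rng: random.Random, planted: list[str]):
    """Filler words with the planted surfaces inserted as whole tokens;
    returns the text and each planting's 1-based inclusive offsets."""
    tokens = [_filler_word(rng) for _ in range(rng.randint(8, 14))]
    positions = sorted(rng.sample(range(len(tokens) + 1), len(planted)))
    for shift, (pos, surface) in enumerate(zip(positions, planted)):
        tokens.insert(pos + shift, surface)
    text = ""
    offsets = []
    for tok in tokens:
        if text:
            text += " "
        start = len(text) + 1
        text += tok
        if tok in planted:
            offsets.append((tok, start, start + len(tok) - 1))
    return text, offsets


def _reference_node(style: ReferenceStyle, r_idx: int):
    ref = etree.Element("ref", attrib={"id": f"B{r_idx + 1}"})
    if style is ReferenceStyle.ELEMENT_CITATION:
        cite = etree.SubElement(ref, "element-citation")
        etree.SubElement(cite, "article-title").text = f"Structured finding {r_idx}"
        etree.SubElement(cite, "source").text = "J Synth Res"
        etree.SubElement(cite, "year").text = "2011"
        etree.SubElement(cite, "volume").text = str(10 + r_idx)
        etree.SubElement(cite, "fpage").text = "1"
        etree.SubElement(cite, "lpage").text = "9"
        pid = etree.SubElement(cite, "pub-id", attrib={"pub-id-type": "pmid"})
        pid.text = str(12340000 + r_idx)
    elif style is ReferenceStyle.MIXED_CITATION:
        cite = etree.SubElement(ref, "mixed-citation")
        cite.text = "Gamma G. "
        etree.SubElement(cite, "article-title").text = f"Mixed finding {r_idx}"
        cite[-1].tail = ". "
        etree.SubElement(cite, "source").text = "Synth Lett"
        cite[-1].tail = " 2012."
    elif style is ReferenceStyle.CITATION_LEGACY:
        cite = etree.SubElement(ref, "citation")
        etree.SubElement(cite, "article-title").text = f"Legacy finding {r_idx}"
        etree.SubElement(cite, "source").text = "Old J"
        etree.SubElement(cite, "year").text = "1999"
    else:  # UNSTRUCTURED: legacy citation holding free text only
        cite = etree.SubElement(ref, "citation")
        cite.text = f"Delta, D. ({1990 + r_idx}). Unparsed Citations J. {40 + r_idx}, 1-2."
    return ref


def _self_check(xml: bytes, truth: ArticleTruth) -> None:
    doc = parse_jats(xml)
    paragraphs = {}
    for s_idx, sec in enumerate(doc.sections):
        for para in sec.paragraphs:
            paragraphs[(s_idx, para.index)] = para.text
    if len(paragraphs) != truth.n_paragraphs or len(doc.sections) != truth.n_sections:
        raise GenerationError("structure mismatch between manifest and emitted XML")
    for occ in truth.occurrences:
        text = paragraphs[(occ.section_index, occ.paragraph_index)]
        if text[occ.start - 1:occ.end] != occ.surface:
            raise GenerationError(
                f"planted offset check failed for {occ.surface!r} at "
                f"({occ.start}, {occ.end})")
    # collision check: each surface occurs exactly as often as planted
    for surface in {o.surface for o in truth.occurrences}:
        planted = sum(1 for o in truth.occurrences if o.surface == surface)
        found = sum(text.count(surface) for text in paragraphs.values())
        if found != planted:
            raise GenerationError(
                f"planting collision: {surface!r} found {found} times, "
                f"planted {planted}")


# ---------------------------------------------------------------------------
# Worked-example fixtures


#: Two UniProt accessions for the gene-product surface form "Scr".
SCR_ACCESSIONS = ("Q93CH6", "P09077")

#: Seventeen UniProt accessions for the surface form "lacZ".
LACZ_ACCESSIONS = (
    "Q59750", "P30812", "P23989", "P06219", "Q48727", "Q56307", "P70753",
    "P26257", "P81650", "P0C1Y0", "P77989", "Q9K9C6", "Q59140", "O33815",
    "P00722", "Q47077", "Q1G9Z4",
)

CHOLESTEROL_CHEBI_ID = "16113"
CHOLESTEROL_START = 291  # 1-based inclusive; "cholesterol" has 11 code points
CHOLESTEROL_SECTION_TITLE = "Preparation of LT-NLC and LT-NLC-apo"


@dataclass
class WorkedExamples:
    protein_article: object  # ArticleDocument with "Scr" and "lacZ" once each
    protein_dictionary: list  # DictionaryEntry: Scr -> 2, lacZ -> 17 accessions
    chemical_article: object  # ArticleDocument placing "cholesterol" at 291
    chemical_dictionary: list  # DictionaryEntry: cholesterol -> one ChEBI entity


def paper_worked_examples(registry: VocabularyRegistry | None = None) -> WorkedExamples:
    registry = registry or default_registry()
    uniprot = registry["uniprot"].entity_prefix
    chebi = registry["chebi"].entity_prefix

    protein_dictionary = (
        [DictionaryEntry("Scr", uniprot + acc, "uniprot") for acc in SCR_ACCESSIONS]
        + [DictionaryEntry("lacZ", uniprot + acc, "uniprot") for acc in LACZ_ACCESSIONS]
    )
    protein_xml = _worked_article(
        pmcid="PMC1043860",
        title="Regulatory interactions in the developing leg imaginal disc",
        section_title="Results",
        paragraph="The Scr homeotic product directs activation of the lacZ "
                  "reporter in the developing imaginal disc.",
    )
    chemical_dictionary = [DictionaryEntry(
        "cholesterol", chebi + CHOLESTEROL_CHEBI_ID, "chebi")]
    chemical_xml = _worked_article(
        pmcid="PMC3225525",
        title="Preparation and Characterization of a Lovastatin-Loaded "
              "Protein-Free Nanostructured Lipid Carrier Resembling "
              "High-Density Lipoprotein and Evaluation of its Targeting "
              "to Foam Cells",
        section_title=CHOLESTEROL_SECTION_TITLE,
        paragraph=_cholesterol_paragraph(),
    )
    return WorkedExamples(
        protein_article=parse_jats(protein_xml),
        protein_dictionary=protein_dictionary,
        chemical_article=parse_jats(chemical_xml),
        chemical_dictionary=chemical_dictionary,
    )


def _cholesterol_paragraph() -> str:
    """A paragraph whose substring at 1-based inclusive [291, 301] is
    exactly "cholesterol"."""
    lead = ("The lipid carrier was prepared by emulsification and "
            "solvent evaporation. Lovastatin and the lipid phase were "
            "dissolved in dichloromethane, injected into the aqueous "
            "phase under stirring, and the dispersion was homogenized "
            "until a uniform nanostructured suspension formed over the "
            "course of the procedure. ")
    lead = (lead + "The core composition including free ")[:CHOLESTEROL_START - 1]
    lead = lead[:-1] + " " if not lead.endswith(" ") else lead
    text = lead + "cholesterol was quantified against the apolipoprotein standard."
    assert text[CHOLESTEROL_START - 1:CHOLESTEROL_START + 10] == "cholesterol"
    return text


def _worked_article(pmcid: str, title: str, section_title: str,
                    paragraph: str) -> bytes:
    root = etree.Element("article", attrib={"article-type": "research-article"})
    front = etree.SubElement(root, "front")
    am = etree.SubElement(front, "article-meta")
    aid = etree.SubElement(am, "article-id", attrib={"pub-id-type": "pmcid"})
    aid.text = pmcid
    at = etree.SubElement(etree.SubElement(am, "title-group"), "article-title")
    at.text = title
    body = etree.SubElement(root, "body")
    sec = etree.SubElement(body, "sec")
    etree.SubElement(sec, "title").text = section_title
    etree.SubElement(sec, "p").text = paragraph
    return etree.tostring(root, xml_declaration=True, encoding="UTF-8")
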