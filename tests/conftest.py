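import random
from datetime import datetime, timezone

import pytest

from biotea.annotator import MatchPolicy, compile_dictionary
from biotea.fixtures import FixtureSpec, PlantedTerm, generate_corpus, paper_worked_examples
from biotea.registry import default_registry

FIXED_TS = datetime(2013, 4, 15, 12, 0, 0, tzinfo=timezone.utc)


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def worked(registry):
    return paper_worked_examples(registry)


@pytest.fixture(scope="session")
def protein_dict(worked):
    return compile_dictionary(worked.protein_dictionary)


@pytest.fixture(scope="session")
def chemical_dict(worked):
    return compile_dictionary(worked.chemical_dictionary)


@pytest.fixture
def fixed_ts():
    return FIXED_TS


@pytest.fixture(scope="session")
def small_corpus(registry):
    """3 articles x 3 sections x 2 paragraphs with three planted terms."""
    spec = FixtureSpec(
        seed=42,
        n_articles=3,
        sections_per_article=3,
        paragraphs_per_section=2,
        planted_terms=[
            PlantedTerm("cancer", "mesh", 4, 2),
            PlantedTerm("cholesterol", "chebi", 1, 1),
            PlantedTerm("catalase", "uniprot", 3, 1),
        ],
    )
    return generate_corpus(spec, registry)


def random_planted_text(rng: random.Random, surfaces: list, n_words=(5, 20)):
    """Filler text with some surfaces planted as whole tokens."""
    fillers = ["zqv", "xkwj", "qvvk", "wjzz", "kxq", "vzkw"]
    tokens = [rng.choice(fillers) for _ in range(rng.randint(*n_words))]
    for s in rng.sample(surfaces, rng.randint(0, min(3, len(surfaces)))):
        tokens.insert(rng.randrange(len(tokens) + 1), s)
    return " ".join(tokens)


@pytest.fixture
def match_policy():
    return MatchPolicy()
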