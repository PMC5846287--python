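import pytest

from datasetir.filtering import TermLexicon, build_lexicon
from datasetir.fixtures import FixtureSpec, make_domain_tokens, make_fixture_dir


@pytest.fixture(scope="session")
def tiny_lexicon() -> TermLexicon:
    """Hand-picked lexicon with disjoint English and MeSH-only words."""
    return TermLexicon(
        english_words=frozenset({
            "the", "of", "and", "acute", "melanoma", "diabetes", "mice",
            "cell", "protein", "gene", "expression", "study", "data",
        }),
        mesh_words=frozenset({"mip-2", "cd69", "ldlr", "abdomen", "acute"}),
    )


@pytest.fixture(scope="session")
def fixture_spec() -> FixtureSpec:
    return FixtureSpec(seed=0, n_docs=200)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory, fixture_spec):
    """A complete generated fixture set shared across the session."""
    out = tmp_path_factory.mktemp("fixtures")
    paths = make_fixture_dir(fixture_spec, out)
    return paths


@pytest.fixture(scope="session")
def full_lexicon(fixture_dir) -> TermLexicon:
    """Packaged English wordlist + MeSH words from the generated files."""
    mesh_files = sorted(fixture_dir["mesh_dir"].glob("*.xml"))
    return build_lexicon(mesh_files)


@pytest.fixture(scope="session")
def domain_tokens(fixture_spec):
    return make_domain_tokens(fixture_spec)
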