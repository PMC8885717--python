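import warnings

import pytest

from pubcorpus.cli import process_article
from pubcorpus.fixtures import fixture_config, gen_corpus
from pubcorpus.sections import SectionDigraph, accumulate_digraph, build_dpg, default_lexicon


@pytest.fixture(scope="session")
def lexicon():
    return default_lexicon()


@pytest.fixture(scope="session")
def fix_config():
    return fixture_config()


@pytest.fixture(scope="session")
def corpus20(lexicon):
    """A 20-article synthetic corpus plus the digraph built from it."""
    corpus = gen_corpus(20, seed=7)
    digraph = SectionDigraph()
    for article in corpus.articles:
        dpg = build_dpg([p.header for p in article.spec.sections], lexicon)
        accumulate_digraph(digraph, dpg, lexicon)
    return corpus, digraph


def run_pipeline(article, config, digraph=None):
    """process_article with classification warnings silenced."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return process_article(
            article.html,
            config,
            article.spec.document_id,
            linked_table_htmls=[html for _, html in article.linked_tables],
            digraph=digraph,
        )
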