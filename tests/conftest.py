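import pytest

from ephysminer.vocab import default_vocabulary


@pytest.fixture(scope="session")
def vocab():
    return default_vocabulary()


@pytest.fixture(scope="session")
def tiny_corpus(tmp_path_factory):
    """A small noise-free corpus shared by pipeline-level tests."""
    from ephysminer.synth import GenerationParams, generate_corpus

    out = tmp_path_factory.mktemp("tiny_corpus")
    params = GenerationParams(
        seed=11, n_articles=6, typo_rate=0.0, synonym_use_prob=0.0
    )
    manifest = generate_corpus(params, out, force=True)
    return out, manifest
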