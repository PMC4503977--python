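import pytest

from cnvmir import synthetic


@pytest.fixture(scope="session")
def small_config():
    """8-species fixture at reduced size for fast structural tests."""
    return synthetic.default_config(seed=7, n_genes=150)


@pytest.fixture(scope="session")
def small_tables(small_config):
    return synthetic.generate_tables(small_config)


@pytest.fixture(scope="session")
def small_bundle(small_tables, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("bundle")
    return synthetic.write_bundle(small_tables, outdir)
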