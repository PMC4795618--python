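import pytest

from varthesaurus.pipeline import run_pair_benchmark


@pytest.fixture(scope="session")
def pair200k(tmp_path_factory):
    """A complete matched-pair run on a 200 kb genome (10% two-copy repeats,
    germline 1e-3, somatic 5e-4, 20x reads): shared by end-to-end tests."""
    wd = tmp_path_factory.mktemp("pair200k")
    return run_pair_benchmark(seed=11, genome_size=200_000, workdir=wd)
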