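import numpy as np
import pytest

from atacdiff.simulate import GeneratorConfig, write_fixture


@pytest.fixture(scope="session")
def default_fixture(tmp_path_factory):
    """The default synthetic study (seed 1), generated once per session."""
    outdir = tmp_path_factory.mktemp("fixture_seed1")
    return write_fixture(outdir, GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def default_manifest(default_fixture):
    p = default_fixture["paths"]
    return {
        "reads_mutant": p["reads_mut"],
        "reads_control": p["reads_ctrl"],
        "genes": p["genes"],
        "chrom_sizes": p["chrom_sizes"],
        "blacklist": p["blacklist"],
        "k27_reads": p["k27_reads"],
        "k27_input": p["k27_input"],
        "tf_reads": p["tf_reads"],
        "de_table": p["de_table"],
        "signatures": p["signatures"],
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(20_240_901)
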