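import numpy as np
import pytest

from lampsmith import datasets, synth


@pytest.fixture(scope="session")
def qff():
    """The bundled Queensland fruit fly COI primer set."""
    return datasets.qff_primer_set()


@pytest.fixture(scope="session")
def design_fixture():
    """Constrained target/non-target pair with a single feasible layout."""
    return synth.make_design_fixture(seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def write_fasta(tmp_path):
    def _write(name, ids, seqs):
        path = tmp_path / name
        synth.write_fasta(path, ids, seqs)
        return path

    return _write
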