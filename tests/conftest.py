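import pytest

from softcontact import (
    ComplexSpec,
    make_toy_complex,
    read_structure,
    select_complex,
    write_pdb,
)


@pytest.fixture(scope="session")
def spec_ab():
    return ComplexSpec(chains_A=("A",), chains_B=("B",))


@pytest.fixture(scope="session")
def toy_truth():
    """One default toy complex with ground truth (fixed seed)."""
    return make_toy_complex(seed=11)


@pytest.fixture(scope="session")
def toy_roundtrip(toy_truth, spec_ab, tmp_path_factory):
    """The same toy complex after a write->read round trip, pre-selected."""
    path = tmp_path_factory.mktemp("toy") / "toy.pdb"
    write_pdb(toy_truth.model, path)
    model = read_structure(path)
    sel = select_complex(model, spec_ab)
    return model, sel, toy_truth
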