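import pytest

from thermoshift.core import Mutation, MutationRecord, Condition, ProteinRecord
from thermoshift.simulate import SEQ_WEIGHTS, SyntheticSpec, generate


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """The deterministic on-disk fixture tree shared across tests."""
    from thermoshift.simulate import make_fixture_suite

    out = tmp_path_factory.mktemp("fixtures")
    make_fixture_suite(out)
    return out


@pytest.fixture(scope="session")
def small_dataset():
    """A small labelled synthetic dataset (sequence-dependent labels)."""
    spec = SyntheticSpec(
        n_proteins=12,
        mutations_per_protein=4,
        length_min=40,
        length_max=120,
        weights=dict(SEQ_WEIGHTS),
        seed=42,
    )
    return generate(spec)


@pytest.fixture
def toy_protein():
    return ProteinRecord("toy1", "MKVLATGEIRSDFWYHQCNP")


@pytest.fixture
def toy_record(toy_protein):
    return MutationRecord(
        protein_id=toy_protein.id,
        mutation=Mutation("K", 2, "I"),
        condition=Condition(ph=7.0, tm_wild=65.0),
        delta_tm=-1.5,
    )
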