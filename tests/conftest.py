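import pytest

from edna_profiler import binning, synth
from edna_profiler.refdb import ReferenceDB, ReferenceSequence


@pytest.fixture(scope="session")
def watershed_db():
    return synth.watershed_reference_db(seed=1)


@pytest.fixture(scope="session")
def watershed_assignment(watershed_db):
    """Simulated per-accession reads mapped back to the watershed DB.

    600 reads per accession keeps the binomial error on the overall
    assignment-error estimate well under a tenth of a percentage point
    while staying desk-scale.
    """
    assignments, truth = binning.simulate_assignment_error(
        watershed_db, n_per_accession=600, seed=1)
    return assignments, truth


@pytest.fixture(scope="session")
def watershed_community(watershed_db):
    """A realized synthetic community with reads, truth and manifest."""
    spec = synth.watershed_community_spec(
        watershed_db, seed=5, reads_per_sample=2500)
    model = synth.ErrorModel.study_default()
    comm = synth.generate_community(watershed_db, spec, model)
    return spec, comm


@pytest.fixture()
def toy_db():
    """Three well-separated species, one with two accessions."""
    return ReferenceDB([
        ReferenceSequence("ACC001", "Alpha_one", "ACGTACGTACGTACGTACGTACGTACGT"),
        ReferenceSequence("ACC002", "Alpha_one", "ACGTACGTACGTACGTACGTACGTACGA"),
        ReferenceSequence("ACC003", "Beta_two", "TTTTCCCCGGGGAAAATTTTCCCCGGGG"),
        ReferenceSequence("ACC004", "Gamma_three", "GACTGACTGACTGACTGACTGACTGACT"),
    ])
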