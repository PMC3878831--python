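import pytest

from detoxcat import FamilyOntology, SimulationParams, simulate_dataset


@pytest.fixture(scope="session")
def ontology():
    return FamilyOntology.default()


@pytest.fixture(scope="session")
def small_params():
    # small but fully featured: contamination, decoys, mixed fragment lengths
    return SimulationParams(
        n_genes_per_category={
            "oxidation_reduction": 8,
            "conjugation": 5,
            "hydrolysis": 6,
            "other": 4,
            "none": 6,
        },
        contaminant_fraction=0.2,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_dataset(small_params):
    return simulate_dataset(small_params)
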