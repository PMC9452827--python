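import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow], deadline=None
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table1():
    from exonskip.fixtures import load_table1

    return load_table1()


@pytest.fixture(scope="session")
def table3():
    from exonskip.fixtures import load_table3

    return load_table3()


@pytest.fixture(scope="session")
def models():
    """Partial SLC12A1/CLCNKB transcript models solved from the annotation anchors."""
    from exonskip.fixtures import reference_models

    return reference_models()


@pytest.fixture(scope="session")
def motif_sets():
    from exonskip.synthetic import make_motif_sets

    return make_motif_sets(seed=11)


@pytest.fixture(scope="session")
def synthetic_transcript(motif_sets):
    from exonskip.synthetic import PlantedMotif, SyntheticGeneSpec, make_transcript

    ese, ess = motif_sets
    some_ese = sorted(ese.entries)[:3]
    spec = SyntheticGeneSpec(
        gene_id="SYN1",
        exon_lengths=(140, 111, 112, 87),
        planted_motifs=(
            PlantedMotif(1, 20, some_ese[0], "enhancer"),
            PlantedMotif(2, 10, some_ese[1], "enhancer"),
            PlantedMotif(3, 50, some_ese[2], "enhancer"),
        ),
        planted_donors={1: "strong", 2: "strong"},
        seed=7,
    )
    return make_transcript(spec)
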