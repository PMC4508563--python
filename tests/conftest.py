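import pytest

from panbin.pipeline import RunConfig, compute_pairwise_hits
from panbin.synthetic import GeneratorParams, generate_genome_set


SMALL = dict(
    n_genomes=5,
    n_core_families=30,
    n_flex_families=15,
    flex_presence_prob=0.5,
    n_unique_per_genome=8,
    mean_protein_len=150,
    within_family_identity=0.9,
    dropout_rate=0.0,
    n_marker_families=20,
    seed=11,
)


@pytest.fixture(scope="session")
def small_set():
    """A 5-genome planted set shared across module tests."""
    params = GeneratorParams(**SMALL)
    proteomes, truth = generate_genome_set(params)
    return proteomes, truth


@pytest.fixture(scope="session")
def small_hits(small_set):
    proteomes, _ = small_set
    cfg = RunConfig(
        n_genomes=SMALL["n_genomes"],
        n_core_families=SMALL["n_core_families"],
        n_flex_families=SMALL["n_flex_families"],
        n_unique_per_genome=SMALL["n_unique_per_genome"],
        mean_protein_len=SMALL["mean_protein_len"],
        marker_count=SMALL["n_marker_families"],
        seed=SMALL["seed"],
    )
    return compute_pairwise_hits(proteomes, cfg)
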