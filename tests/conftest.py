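import pytest

from mirgonad.hairpin import DiscoveryParams
from mirgonad.pipeline import PipelineConfig, run_pipeline
from mirgonad.synthio import GenomeSpec, build_toy_genome, default_profiles, simulate_libraries

#: reduced genome for unit tests that exercise generation/discovery
SMALL_SPEC = dict(
    genome_length=40_000,
    n_novel_hairpins=4,
    decoy_reasons=("mature_length", "free_energy", "max_bulge", "cut_depth"),
    n_conserved_hairpins=2,
    n_pirna_clusters=1,
    n_decoy_ncrnas={"rRNA": 1},
    n_gene_models=1,
    n_repeats=1,
    isolation=800,
)


@pytest.fixture(scope="session")
def small_toy():
    return build_toy_genome(GenomeSpec(rng_seed=5, **SMALL_SPEC), DiscoveryParams())


@pytest.fixture(scope="session")
def toy_bundle():
    """Full-size synthetic dataset: genome, profiles, reads, truth."""
    toy = build_toy_genome(GenomeSpec(rng_seed=7))
    profiles = default_profiles(toy)
    reads, truth = simulate_libraries(toy, profiles)
    return toy, profiles, reads, truth


@pytest.fixture(scope="session")
def pipeline_result():
    """One in-memory end-to-end run under the default study conditions."""
    return run_pipeline(PipelineConfig(seed=11, write_outputs=False))
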