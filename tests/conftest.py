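import pytest

from paness.synthetic_fixtures import (
    generate_gene_models,
    generate_genome,
    plant_variants,
    synthetic_worked_example,
)


@pytest.fixture(scope="session")
def fixture_universe():
    """Synthetic genome + transcripts + planted trio VCF with ground truth.

    Seeds are fixed so every test sees the same universe: 100 kb genome,
    20 mixed-strand transcripts, 200 splice-creating variants (5 with the
    recessive trio pattern), 200 nulls, 10 common creations above the
    frequency gate.
    """
    genome = generate_genome(11, 100_000, gc=0.45)
    models = generate_gene_models(genome, 20, 12)
    vcf_text, truth = plant_variants(genome, models, 200, 200, 13)
    return genome, models, vcf_text, truth


@pytest.fixture(scope="session")
def worked_example():
    return synthetic_worked_example()


@pytest.fixture(scope="session")
def cli_fixture_dir(tmp_path_factory):
    """Small on-disk fixture set for command-line tests."""
    from paness.cli import cmd_make_fixtures

    out = tmp_path_factory.mktemp("fixtures")
    cmd_make_fixtures(seed=5, length=60_000, n_transcripts=10, n_creations=40,
                      n_nulls=40, n_common=5, n_recessive=5, gc=0.45, out=out)
    return out
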