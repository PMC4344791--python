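import pytest

from wheattf.reporting import PipelineConfig, run_pipeline
from wheattf.synthetic import SyntheticConfig, generate_corpus


@pytest.fixture(scope="session")
def planted_corpus():
    """Default study-condition corpus: 3 families, 30 TF transcripts,
    duplicates, one blast-update and one filtered-recovery scenario."""
    return generate_corpus(SyntheticConfig(rng_seed=1))


@pytest.fixture(scope="session")
def pipeline_result(planted_corpus):
    """Full pipeline run on the planted corpus (computed once per session)."""
    c = planted_corpus
    return run_pipeline(
        PipelineConfig(rng_seed=1),
        c.est_records,
        c.library_annotations,
        c.seeds,
        c.rules,
        c.subject_records,
    )


@pytest.fixture(scope="session")
def tiny_seeds():
    """A cheap 2-family seed/rule set for unit-level profile tests."""
    from wheattf.synthetic import generate_family_seeds

    cfg = SyntheticConfig(n_families=2, core_length=20,
                          seed_sequences_per_family=10, rng_seed=3)
    seeds, rules, consensus = generate_family_seeds(cfg)
    return seeds, rules, consensus
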