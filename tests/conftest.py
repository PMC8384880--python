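import pytest

from pdxkit import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One structurally complete cohort shared (read-only) across tests."""
    return generate_cohort(CohortConfig(seed=11))


@pytest.fixture(scope="session")
def small_config_kwargs():
    """Trimmed generator knobs for tests that only need one data modality."""
    return dict(n_genes=50, n_clonal_mutations=5, n_subclone_mutations=2,
                n_model_private_mutations=2, n_passage_private_mutations=1,
                background_fusions_per_cohort=0, arm_spikes=[],
                snp_panel_size=20)
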