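import pytest

from neofunnel import FilterConfig, SomaticVariant, generate_variant_cohort


def make_variant(**overrides) -> SomaticVariant:
    """A variant passing every criterion at comfortable margins."""
    fields = dict(
        variant_id="var1",
        gene="Daglb",
        transcript="Tx1",
        protein_pos=238,
        aa_ref="G",
        aa_alt="C",
        tumor_dna_depth=100,
        tumor_dna_alt=30,
        tumor_rna_depth=80,
        tumor_rna_alt=24,
        normal_depth=120,
        normal_alt=0,
    )
    fields.update(overrides)
    return SomaticVariant(**fields)


@pytest.fixture(scope="session")
def small_cohort():
    """A 60-variant cohort with planted funnel (60, 25, 8)."""
    return generate_variant_cohort(60, 25, 8, seed=11)


@pytest.fixture(scope="session")
def default_config():
    return FilterConfig()
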