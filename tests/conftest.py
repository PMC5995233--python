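import pytest

from panelval import synthetic


@pytest.fixture(scope="session")
def small_reference():
    """20 genes x 300 bp, half tier 1 — the default desk-scale panel."""
    return synthetic.generate_reference(seed=7, n_genes=20, gene_length=300, tier1_fraction=0.5)


@pytest.fixture(scope="session")
def tier1_reference():
    """All-tier-1 panel used by the titration-style tests."""
    return synthetic.generate_reference(seed=7, n_genes=20, gene_length=300, tier1_fraction=1.0)


@pytest.fixture
def tumor_profile():
    return synthetic.SampleProfile(
        sample_id="T1", role="tumor", purity=1.0, mean_depth=500, error_rate=0.001, seed=11
    )


@pytest.fixture
def normal_profile():
    return synthetic.SampleProfile(
        sample_id="N1", role="normal", purity=0.0, mean_depth=500, error_rate=0.001, seed=11
    )


def make_site(contig, pos, ref, alt_counts, ref_count):
    """Shorthand SiteCounts constructor used across test modules."""
    counts = dict(alt_counts)
    counts[ref] = ref_count
    return synthetic.SiteCounts(
        contig=contig, pos=pos, depth=sum(counts.values()), allele_counts=counts, ref=ref
    )
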