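import pandas as pd
import pytest

from pgsapply import (
    apply_polygenic_score,
    combine_vcf_with_pgs,
    import_pgs_weight_file,
    import_vcf,
)
from pgsapply.simulate import SimConfig, simulate_cohort


@pytest.fixture
def make_cohort(tmp_path):
    """Factory writing a simulated cohort under tmp_path and returning it."""

    counter = {"n": 0}

    def _make(**kwargs):
        counter["n"] += 1
        config = SimConfig(**kwargs)
        return simulate_cohort(config, prefix=tmp_path / f"cohort{counter['n']}")

    return _make


@pytest.fixture
def score_cohort():
    """Run the import -> merge -> score pipeline on a simulated cohort."""

    def _score(cohort, **kwargs):
        model = import_pgs_weight_file(cohort.paths["weights"])
        genotypes = import_vcf(cohort.paths["vcf"])
        merged, _ = combine_vcf_with_pgs(genotypes, model)
        kwargs.setdefault("max_strand_flips", cohort.config.m_variants)
        kwargs.setdefault("correct_strand_flips", True)
        return apply_polygenic_score(merged, genotypes, **kwargs), merged, genotypes

    return _score


@pytest.fixture
def scored_table(make_cohort, score_cohort) -> pd.DataFrame:
    """A realistic score table with phenotype columns, for viz/association tests."""
    cohort = make_cohort(n_samples=120, m_variants=40, seed=42, h2=0.4)
    result, _, _ = score_cohort(cohort, phenotypes=cohort.phenotypes)
    return result.table
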