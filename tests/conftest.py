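import numpy as np
import pandas as pd
import pytest

from packstats.genotype_model import GenotypeMatrix, SampleRecord


def make_gm(dosages, positions=None, contig="chr1", quals=None, sample_meta=None):
    """Build a small GenotypeMatrix from a (samples x variants) dosage array."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n_samples, n_variants = dosages.shape
    if positions is None:
        positions = np.arange(1, n_variants + 1) * 1000
    if quals is None:
        quals = np.full(n_variants, 60.0)
    refs = np.resize(list("ACGT"), n_variants)
    alts = np.array([{"A": "G", "C": "T", "G": "A", "T": "C"}[r] for r in refs])
    variants = pd.DataFrame(
        {
            "contig": [contig] * n_variants if isinstance(contig, str) else contig,
            "pos": positions,
            "ref": refs,
            "alt": alts,
            "qual": quals,
        }
    )
    if sample_meta is None:
        samples = [SampleRecord(f"s{i}", "pack1", "central") for i in range(n_samples)]
    else:
        samples = sample_meta
    return GenotypeMatrix(samples, variants, dosages)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def study_cohort_run(tmp_path_factory):
    """One shared study-shaped simulated cohort, analysis-ready."""
    from packstats.simulate import study_cohort_config, simulate_cohort

    cohort, gm, truth = simulate_cohort(study_cohort_config(seed=11, n_snps=8000))
    return cohort, gm, truth
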