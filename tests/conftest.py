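import numpy as np
import pytest

from causal_gwas import GenotypeDataset, SNPInfo, SimulationSpec, generate_dataset


def make_dataset(calls, phenotype=None, snp_ids=None, chrom="1"):
    """Small helper: dataset from a dosage matrix with default metadata."""
    calls = np.asarray(calls, dtype=np.int8)
    n_subj, n_snp = calls.shape
    ids = snp_ids or [f"rs{j + 1:06d}" for j in range(n_snp)]
    snps = [SNPInfo(s, chrom, (j + 1) * 1000, "A", "G") for j, s in enumerate(ids)]
    subjects = [f"S{i + 1:04d}" for i in range(n_subj)]
    return GenotypeDataset(calls, snps, subjects, phenotype)


def counts_to_column(n0, n1, n2):
    """Dosage column realizing exact genotype counts (hom-major, het, hom-minor)."""
    return np.concatenate(
        [np.zeros(n0, dtype=np.int8), np.ones(n1, dtype=np.int8), np.full(n2, 2, np.int8)]
    )


@pytest.fixture
def planted_dataset():
    """2,000 subjects, 100 SNPs, five causal with one exact duplicate."""
    spec = SimulationSpec(
        n_cases=1000,
        n_controls=1000,
        n_snps=100,
        ld_block_size=10,
        ld_rho=0.4,
        causal_snps=((5, 1.2), (25, 0.9), (45, 0.8), (65, 0.7), (85, 0.6)),
        duplicate_pairs=((45, 48),),
        seed=7,
    )
    return generate_dataset(spec)


@pytest.fixture
def small_labeled_dataset():
    spec = SimulationSpec(
        n_cases=150,
        n_controls=150,
        n_snps=30,
        causal_snps=((3, 1.2), (17, 1.0)),
        seed=11,
    )
    ds, _ = generate_dataset(spec)
    return ds
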