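import numpy as np
import pytest

from wincurse.data import CaseControlGenotypes


def genotypes_from_counts(case_counts, control_counts, n_cases, n_controls):
    """Deterministic genotype matrix realizing given per-variant allele
    counts (alleles packed into the first subjects of each stratum)."""
    case_counts = np.asarray(case_counts)
    control_counts = np.asarray(control_counts)
    m = len(case_counts)
    dos = np.zeros((n_cases + n_controls, m), dtype=np.int8)
    for j in range(m):
        for offset, count, n in (
            (0, int(case_counts[j]), n_cases),
            (n_cases, int(control_counts[j]), n_controls),
        ):
            full, rem = divmod(count, 2)
            assert full + (rem > 0) <= n, "counts exceed stratum capacity"
            dos[offset : offset + full, j] = 2
            if rem:
                dos[offset + full, j] = 1
    status = np.r_[np.ones(n_cases, dtype=np.int8), np.zeros(n_controls, dtype=np.int8)]
    return CaseControlGenotypes(dosages=dos, status=status)


@pytest.fixture
def counts_genotypes():
    return genotypes_from_counts


@pytest.fixture
def small_polymorphic_gene():
    """A 200+200-subject, 5-variant gene with moderate MAFs, fixed draw."""
    rng = np.random.default_rng(42)
    maf = np.array([0.05, 0.1, 0.02, 0.15, 0.08])
    dos = rng.binomial(2, maf, size=(400, 5)).astype(np.int8)
    status = np.r_[np.ones(200, dtype=np.int8), np.zeros(200, dtype=np.int8)]
    return CaseControlGenotypes(dosages=dos, status=status)
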