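import numpy as np
import pytest

from crosstrait import LdBlock, OverlapSpec, SnpInfo, build_null, theoretical_overlap_cov

# sample sizes of the motivating SCZ (study 1) / BD (study 2) pair
SCZ_BD_OVERLAP = OverlapSpec(
    n1_case=35_476, n1_control=46_839,
    n2_case=9_747, n2_control=14_278,
    ns_case=500, ns_control=9_200,
)
SCZ_INFLATION = 1.82
BD_INFLATION = 1.24

# Table-1-style nominal p-values of the 22 cross-trait hits (ascending)
TABLE1_NOMINAL_P = [
    2.03e-5, 4.68e-5, 0.0030, 0.0032, 0.0043, 0.0063, 0.0075, 0.0088,
    0.0098, 0.0098, 0.0109, 0.0120, 0.0181, 0.0301, 0.0307, 0.0323,
    0.0351, 0.0367, 0.0380, 0.0387, 0.0429, 0.0465,
]


@pytest.fixture(scope="session")
def scz_bd_overlap() -> OverlapSpec:
    return SCZ_BD_OVERLAP


@pytest.fixture(scope="session")
def scz_bd_model():
    return build_null(SCZ_INFLATION, BD_INFLATION, theoretical_overlap_cov(SCZ_BD_OVERLAP))


def make_block(corr, chrom="1", start=1000, spacing=1000) -> LdBlock:
    """Toy LD block with rs1..rsN at evenly spaced positions."""
    corr = np.asarray(corr, dtype=float)
    n = corr.shape[0]
    snps = [
        SnpInfo(f"rs{i + 1}", chrom, start + i * spacing, "A", "G") for i in range(n)
    ]
    return LdBlock(snps, corr)


def random_corr(rng: np.random.Generator, n: int) -> np.ndarray:
    """A random well-conditioned correlation matrix."""
    a = rng.standard_normal((n, n + 3))
    cov = a @ a.T + 0.5 * np.eye(n)
    d = np.sqrt(np.diag(cov))
    return cov / np.outer(d, d)
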