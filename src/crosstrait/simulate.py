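"""Synthetic paired GWAS summary statistics with known ground truth.

The generator works at the z-score level: for each SNP j it draws a
pair (z1j, z2j) from a bivariate normal whose marginal variances are
the two studies' inflation factors, whose covariance is the
overlap-induced covariance implied by the shared-sample counts, and
whose means are shifted by a common non-centrality at the designated
truly shared loci.  LD is imposed within blocks by mixing the z
vectors through the Cholesky factor of an AR-1 correlation matrix, so
cov(z1, z2) retains the target cross-study covariance at every SNP
while neighbouring SNPs become correlated within a study.

Individual-level genotypes are never simulated: the downstream
methods operate entirely on z-scores, and the z-level model is exactly
the null those methods assume, which makes calibration checks sharp.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genesets import GeneAnnotation, GeneSet
from .ld import Interval, LdBlock, SnpInfo
from .overlap import OverlapSpec, theoretical_overlap_cov
from .sumstats import p_from_z

#: sample sizes and overlap of the motivating SCZ/BD study pair
DEFAULT_OVERLAP = OverlapSpec(
    n1_case=35_476, n1_control=46_839,
    n2_case=9_747, n2_control=14_278,
    ns_case=500, ns_control=9_200,
)
DEFAULT_INFLATION_1 = 1.82
DEFAULT_INFLATION_2 = 1.24


@dataclass
class SimulationConfig:
    """Knobs of the paired-study z-score simulator.

    Defaults reproduce the statistical conditions of the motivating
    cross-disorder analysis: study sizes 35,476/46,839 and
    9,747/14,278 with 500 shared cases and 9,200 shared controls, and
    marginal z-variance inflation 1.82 (study 1) and 1.24 (study 2).
    """

    n_snps: int = 100_000
    n_blocks: int = 1_000
    ld_decay: float = 0.0  # AR-1 rho; 0 = independent SNPs
    overlap: OverlapSpec = field(default_factory=lambda: DEFAULT_OVERLAP)
    inflation1: float = DEFAULT_INFLATION_1
    inflation2: float = DEFAULT_INFLATION_2
    shared_fraction: float = 0.0
    shared_effect_z: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snps % self.n_blocks:
            raise ValueError("n_snps must be divisible by n_blocks")
        if not 0.0 <= self.ld_decay < 1.0:
            raise ValueError("ld_decay must be in [0, 1)")
        if not 0.0 <= self.shared_fraction <= 1.0:
            raise ValueError("shared_fraction must be in [0, 1]")
        if self.inflation1 < 1.0 or self.inflation2 < 1.0:
            raise ValueError("inflation factors must be >= 1")

    @property
    def block_size(self) -> int:
        return self.n_snps // self.n_blocks


def ar1_corr(size: int, rho: float) -> np.ndarray:
    """AR-1 correlation matrix: r_ij = rho^|i-j|."""
    idx = np.arange(size)
    return rho ** np.abs(idx[:, None] - idx[None, :])


_BASES = np.array(list("ACGT"))


def simulate_pair(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, list[LdBlock], pd.DataFrame]:
    """Draw a pair of overlapping GWAS z-score sets with LD and shared loci.

    Returns ``(study1, study2, blocks, truth)``: two sumstats frames
    (snp_id, chrom, pos, allele1, allele2, z, p, n_case, n_control),
    the LD panel used, and a truth table flagging the genuinely shared
    SNPs.  All randomness flows from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n, b, bs = config.n_snps, config.n_blocks, config.block_size
    cov = theoretical_overlap_cov(config.overlap)
    v1, v2 = config.inflation1, config.inflation2

    # per-SNP bivariate normal innovations
    cov_mat = np.array([[v1, cov], [cov, v2]])
    chol2 = np.linalg.cholesky(cov_mat)
    x = rng.standard_normal((2, n))
    z = chol2 @ x  # rows: study1, study2; cross-cov = cov at each SNP

    # mix within blocks through the AR-1 Cholesky factor (unit diagonal
    # variance is preserved because the factor rows have unit norm)
    if config.ld_decay > 0:
        L = np.linalg.cholesky(ar1_corr(bs, config.ld_decay))
        z = np.einsum("ij,sbj->sbi", L, z.reshape(2, b, bs)).reshape(2, n)

    n_shared = int(round(config.shared_fraction * n))
    shared_idx = rng.choice(n, size=n_shared, replace=False) if n_shared else np.array([], int)
    mu = np.zeros(n)
    mu[shared_idx] = config.shared_effect_z * rng.choice([-1.0, 1.0], size=n_shared)
    z[0] += mu
    z[1] += mu

    # SNP metadata: one pseudo-chromosome per 100 blocks, 10 kb spacing
    snp_ids = np.array([f"rs{j + 1}" for j in range(n)], dtype=object)
    blocks_per_chrom = max(1, min(100, b))
    chrom = np.array([str(1 + (j // bs) // blocks_per_chrom) for j in range(n)], dtype=object)
    pos = np.array([10_000 * (1 + (j // bs) % blocks_per_chrom * bs + j % bs) for j in range(n)])
    a_idx = rng.integers(0, 4, size=n)
    a1 = _BASES[a_idx]
    a2 = _BASES[(a_idx + rng.integers(1, 4, size=n)) % 4]

    def frame(which: int, n_case: int, n_control: int) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp_id": snp_ids,
                "chrom": chrom,
                "pos": pos,
                "allele1": a1,
                "allele2": a2,
                "z": z[which],
                "p": p_from_z(z[which]),
                "n_case": n_case,
                "n_control": n_control,
            }
        )

    study1 = frame(0, config.overlap.n1_case, config.overlap.n1_control)
    study2 = frame(1, config.overlap.n2_case, config.overlap.n2_control)

    blocks = []
    corr = ar1_corr(bs, config.ld_decay)
    for k in range(b):
        sl = slice(k * bs, (k + 1) * bs)
        snps = [
            SnpInfo(snp_ids[j], chrom[j], int(pos[j]), a1[j], a2[j])
            for j in range(sl.start, sl.stop)
        ]
        blocks.append(LdBlock(snps, corr.copy()))

    truth = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "shared": np.isin(np.arange(n), shared_idx),
            "true_effect": mu,
        }
    )
    return study1, study2, blocks, truth


def simulate_annotation(
    genome_size: int | dict[str, int],
    n_genes: int,
    n_sets: int,
    set_size_range: tuple[int, int] = (10, 200),
    gene_length: int = 20_000,
    enriched_near: list[Interval] | None = None,
    seed: int | None = None,
) -> tuple[list[GeneAnnotation], list[GeneSet]]:
    """Place non-overlapping genes uniformly and sample random gene sets.

    ``genome_size`` is either a single chromosome length or a mapping
    chrom -> length.  When ``enriched_near`` intervals are given, an
    extra set 'ENRICHED' is appended, seeded with the genes closest to
    those intervals so that it is genuinely enriched by construction.
    """
    rng = np.random.default_rng(seed)
    genome = {"1": int(genome_size)} if isinstance(genome_size, int) else dict(genome_size)
    total = sum(genome.values())
    if n_genes * gene_length > 0.8 * total:
        raise ValueError("cannot pack genes: genome too small for n_genes * gene_length")
    lo, hi = set_size_range
    if n_sets > 0 and lo > n_genes:
        raise ValueError("set_size_range minimum exceeds gene count")

    genes: list[GeneAnnotation] = []
    # allocate gene counts per chromosome proportional to length
    chroms = sorted(genome)
    weights = np.array([genome[c] for c in chroms], float)
    counts = rng.multinomial(n_genes, weights / weights.sum())
    gi = 0
    for c, cnt in zip(chroms, counts):
        if cnt == 0:
            continue
        # slot the chromosome into cnt lanes, one gene per lane: disjoint by construction
        lane = genome[c] // cnt
        if lane <= gene_length:
            raise ValueError(f"cannot pack {cnt} genes of {gene_length} bp on chrom {c}")
        for k in range(cnt):
            start = int(k * lane + rng.integers(1, lane - gene_length + 1))
            genes.append(GeneAnnotation(f"G{gi + 1}", c, start, start + gene_length - 1))
            gi += 1

    gene_ids = np.array([g.gene_id for g in genes], dtype=object)
    sets: list[GeneSet] = []
    for si in range(n_sets):
        size = int(rng.integers(lo, min(hi, n_genes) + 1))
        members = rng.choice(gene_ids, size=size, replace=False)
        sets.append(GeneSet(f"SET{si + 1}", f"random set {si + 1}", frozenset(members)))

    if enriched_near:
        near: list[str] = []
        for iv in enriched_near:
            dists = [
                max(g.start - iv.end, 0) + max(iv.start - g.end, 0)
                if str(g.chrom) == str(iv.chrom) else np.inf
                for g in genes
            ]
            near.append(genes[int(np.argmin(dists))].gene_id)
        size = max(lo, len(set(near)))
        fill = rng.choice(
            np.array([g for g in gene_ids if g not in near], dtype=object),
            size=max(0, size - len(set(near))),
            replace=False,
        )
        sets.append(GeneSet("ENRICHED", "seeded near intervals", frozenset(near) | set(fill)))
    return genes, sets
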