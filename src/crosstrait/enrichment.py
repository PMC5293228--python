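"""Shared-locus analysis: filtering, counting, and enrichment testing.

Given one trait's index SNPs and the (overlap-corrected) association
results of a second trait, this module counts how many index SNPs show
nominal association in the second trait and asks, with an exact
binomial test, whether that count exceeds the alpha * n expected by
chance.  Per-SNP Bonferroni-corrected p-values and a Table-style
report round out the analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .sumstats import SnpAssoc, VALID_BASES

SYMBOLIC_ALLELES = frozenset({"I", "D", "R", "-", "*"})


@dataclass
class MappingTally:
    n_input: int = 0
    n_excluded_x: int = 0
    n_excluded_indel: int = 0
    n_mapped: int = 0
    n_absent_from_target: int = 0
    n_tested: int = 0
    excluded_x: list[str] = field(default_factory=list)
    excluded_indel: list[str] = field(default_factory=list)
    absent: list[str] = field(default_factory=list)


@dataclass
class SharedLocusReport:
    """Counts and per-SNP rows of a shared-locus analysis run."""

    table: pd.DataFrame  # sorted by corrected p; full (S1-style) listing
    nominal_table: pd.DataFrame  # rows with p_corrected < alpha (Table-1-style)
    tally: MappingTally
    m_bonferroni: int
    alpha: float
    n_nominal: int
    n_bonferroni: int
    enrichment_p: float

    def summary(self) -> dict:
        return {
            "n_input": self.tally.n_input,
            "n_excluded_x": self.tally.n_excluded_x,
            "n_excluded_indel": self.tally.n_excluded_indel,
            "n_mapped": self.tally.n_mapped,
            "n_tested": self.tally.n_tested,
            "n_nominal": self.n_nominal,
            "n_bonferroni": self.n_bonferroni,
            "m_bonferroni": self.m_bonferroni,
            "alpha": self.alpha,
            "enrichment_p": self.enrichment_p,
        }


def _is_indel(rec: SnpAssoc) -> bool:
    a1, a2 = rec.allele1, rec.allele2
    if a1 in SYMBOLIC_ALLELES or a2 in SYMBOLIC_ALLELES:
        return True
    if a1.startswith("<") or a2.startswith("<"):
        return True
    return not (len(a1) == 1 and len(a2) == 1 and a1 in VALID_BASES and a2 in VALID_BASES)


def _is_x(chrom: str) -> bool:
    c = chrom.removeprefix("chr").upper()
    return c in {"X", "23"}


def map_snps(
    index_list: Sequence[SnpAssoc], target_ids: set[str] | Sequence[str]
) -> tuple[list[SnpAssoc], MappingTally]:
    """Filter index SNPs to those testable in the target study.

    X-chromosomal variants and insertions/deletions are excluded (they
    cannot be imputed from an autosomal SNV reference), then the
    survivors are intersected with the target study's SNP ids.
    """
    target_ids = set(target_ids)
    tally = MappingTally(n_input=len(index_list))
    mapped: list[SnpAssoc] = []
    for rec in index_list:
        if _is_x(rec.chrom):
            tally.n_excluded_x += 1
            tally.excluded_x.append(rec.snp_id)
            continue
        if _is_indel(rec):
            tally.n_excluded_indel += 1
            tally.excluded_indel.append(rec.snp_id)
            continue
        mapped.append(rec)
    tally.n_mapped = len(mapped)
    tested = [r for r in mapped if r.snp_id in target_ids]
    tally.absent = [r.snp_id for r in mapped if r.snp_id not in target_ids]
    tally.n_absent_from_target = len(tally.absent)
    tally.n_tested = len(tested)
    return tested, tally


def count_nominal(p_values, alpha: float = 0.05) -> int:
    """Number of p-values strictly below alpha."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return int(np.sum(p < alpha))


def binomial_enrichment(k: int, n: int, p0: float) -> float:
    """Exact upper-tail binomial probability P(X >= k), X ~ Bin(n, p0).

    Summed in log space so that tail probabilities far below machine
    epsilon relative to 1 are still accurate.
    """
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not 0 < p0 < 1:
        raise ValueError("p0 must be in (0, 1)")
    if k == 0:
        return 1.0
    j = np.arange(k, n + 1)
    log_terms = (
        gammaln(n + 1) - gammaln(j + 1) - gammaln(n - j + 1)
        + j * np.log(p0) + (n - j) * np.log1p(-p0)
    )
    return float(np.exp(logsumexp(log_terms)))


def bonferroni(p, m: int):
    """Bonferroni-corrected p-value(s): min(1, m * p)."""
    if m < 1:
        raise ValueError("m must be >= 1")
    p = np.asarray(p, dtype=float)
    out = np.minimum(1.0, m * p)
    return float(out) if out.ndim == 0 else out


def format_p_display(p: float, cap: float = 0.9999) -> str:
    """Render a corrected p, capping near-1 values as '>0.9999'."""
    return f">{cap}" if p > cap else f"{p:.4g}"


def direction_concordance(z_pairs) -> tuple[float, np.ndarray]:
    """Fraction of harmonized z-score pairs with matching effect direction.

    A zero z-score in either study counts as discordant and is flagged
    (False) in the returned per-pair array.
    """
    pairs = np.asarray(z_pairs, dtype=float)
    if pairs.size == 0:
        raise ValueError("no pairs supplied")
    concordant = (np.sign(pairs[:, 0]) == np.sign(pairs[:, 1])) & (pairs != 0).all(axis=1)
    return float(concordant.mean()), concordant


def build_report(
    tested: Sequence[SnpAssoc],
    p_corrected,
    z_corrected,
    tally: MappingTally,
    m: int,
    alpha: float = 0.05,
    p0: float | None = None,
    source_p=None,
    gene_annotations: pd.DataFrame | None = None,
) -> SharedLocusReport:
    """Assemble the shared-locus report.

    ``m`` is the Bonferroni multiplicity — the total number of lookups
    performed across both directions of the cross-trait query, recorded
    explicitly in the report.  ``p0`` defaults to ``alpha`` (the chance
    rate of nominal hits under the null).  ``gene_annotations`` is an
    optional BED-like frame (gene_id, chrom, start, end) used to label
    each SNP with the nearest overlapping-or-closest gene.
    """
    p_corrected = np.asarray(p_corrected, dtype=float)
    z_corrected = np.asarray(z_corrected, dtype=float)
    if len(tested) != p_corrected.size:
        raise ValueError("tested records and p_corrected lengths differ")
    rows = pd.DataFrame(
        {
            "snp_id": [r.snp_id for r in tested],
            "chrom": [r.chrom for r in tested],
            "pos": [r.pos for r in tested],
            "allele1": [r.allele1 for r in tested],
            "allele2": [r.allele2 for r in tested],
            "z_corrected": z_corrected,
            "p_corrected": p_corrected,
        }
    )
    rows["p_bonferroni"] = bonferroni(rows["p_corrected"].to_numpy(), m)
    rows["p_bonferroni_display"] = [format_p_display(x) for x in rows["p_bonferroni"]]
    if source_p is not None:
        rows["p_source_study"] = np.asarray(source_p, dtype=float)
    if gene_annotations is not None:
        rows["nearby_gene"] = [
            nearest_gene(c, p, gene_annotations) for c, p in zip(rows["chrom"], rows["pos"])
        ]
    rows = rows.sort_values(
        ["p_corrected", "chrom", "pos"], kind="mergesort"
    ).reset_index(drop=True)

    n_nominal = count_nominal(rows["p_corrected"], alpha)
    n_bonf = count_nominal(rows["p_bonferroni"], alpha)
    enr = binomial_enrichment(n_nominal, len(rows), p0 if p0 is not None else alpha)
    return SharedLocusReport(
        table=rows,
        nominal_table=rows[rows["p_corrected"] < alpha].reset_index(drop=True),
        tally=tally,
        m_bonferroni=m,
        alpha=alpha,
        n_nominal=n_nominal,
        n_bonferroni=n_bonf,
        enrichment_p=enr,
    )


def nearest_gene(chrom: str, pos: int, genes: pd.DataFrame) -> str:
    """Name of the gene overlapping pos, else the closest gene on the chromosome."""
    sub = genes[genes["chrom"].astype(str) == str(chrom)]
    if sub.empty:
        return "-"
    dist = np.maximum(sub["start"] - pos, 0) + np.maximum(pos - sub["end"], 0)
    return str(sub.loc[dist.idxmin(), "gene_id"])
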