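"""LD reference panel: per-block correlation matrices and LD intervals.

The panel is a list of :class:`LdBlock` objects, each holding an
ordered SNP list and the pairwise allelic correlation matrix (r, not
r^2) between them.  Blocks are the unit of summary-statistic
imputation; intervals built from them feed gene-set enrichment.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PSD_TOL = 1e-8


@dataclass(frozen=True)
class SnpInfo:
    snp_id: str
    chrom: str
    pos: int
    allele1: str
    allele2: str


@dataclass
class LdBlock:
    """A contiguous set of SNPs with their pairwise correlation matrix."""

    snps: list[SnpInfo]
    corr: np.ndarray
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.corr = np.asarray(self.corr, dtype=float)
        n = len(self.snps)
        if self.corr.shape != (n, n):
            raise ValueError(
                f"correlation matrix shape {self.corr.shape} does not match {n} SNPs"
            )
        if not np.allclose(self.corr, self.corr.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(self.corr), 1.0, atol=1e-8):
            raise ValueError("correlation matrix must have unit diagonal")
        evals = np.linalg.eigvalsh(self.corr)
        if evals.min() < -PSD_TOL:
            # repair mild indefiniteness from rounding: clip and rescale
            w, v = np.linalg.eigh(self.corr)
            w = np.clip(w, 0.0, None)
            repaired = (v * w) @ v.T
            d = np.sqrt(np.diag(repaired))
            self.corr = repaired / np.outer(d, d)
            np.fill_diagonal(self.corr, 1.0)
            logger.warning(
                "LD block repaired to positive semi-definite (min eigenvalue %.3g)",
                evals.min(),
            )
        object.__setattr__(self, "_index", {s.snp_id: i for i, s in enumerate(self.snps)})

    def __len__(self) -> int:
        return len(self.snps)

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index

    def index_of(self, snp_id: str) -> int:
        try:
            return self._index[snp_id]
        except KeyError:
            raise KeyError(f"SNP {snp_id} not in block") from None

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]


@dataclass(frozen=True)
class Interval:
    """A closed genomic interval around one or more index SNPs (1-based)."""

    chrom: str
    start: int
    end: int
    index_snps: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"interval start {self.start} > end {self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "Interval") -> bool:
        return self.chrom == other.chrom and self.start <= other.end and other.start <= self.end


def pairwise_r2(block: LdBlock, id_a: str, id_b: str) -> float:
    """Squared allelic correlation between two SNPs of a block."""
    i, j = block.index_of(id_a), block.index_of(id_b)
    return float(block.corr[i, j] ** 2)


def build_intervals(
    index_snps: Iterable,
    blocks: Sequence[LdBlock],
    r2_threshold: float = 0.5,
    pad_bp: int = 0,
) -> list[Interval]:
    """Construct LD-based intervals around index SNPs and merge overlaps.

    Each interval spans from the leftmost to the rightmost panel SNP
    whose r^2 with the index SNP is at or above ``r2_threshold``,
    extended by ``pad_bp`` on each side.  Index SNPs absent from the
    panel degenerate to ``pos +/- pad_bp`` with a warning.  Overlapping
    intervals on a chromosome are merged (keeping all index ids), so
    the output is a set of LD-independent intervals.
    """
    if not 0.0 < r2_threshold <= 1.0:
        raise ValueError("r2_threshold must be in (0, 1]")
    raw: list[Interval] = []
    for snp in index_snps:
        block = next((b for b in blocks if snp.snp_id in b), None)
        if block is None:
            warnings.warn(
                f"index SNP {snp.snp_id} absent from LD panel; "
                "interval degenerates to its position",
                stacklevel=2,
            )
            raw.append(
                Interval(str(snp.chrom), max(1, snp.pos - pad_bp), snp.pos + pad_bp, (snp.snp_id,))
            )
            continue
        i = block.index_of(snp.snp_id)
        r2 = block.corr[i] ** 2
        linked = [s.pos for s, keep in zip(block.snps, r2 >= r2_threshold) if keep]
        start = min(linked + [snp.pos]) - pad_bp
        end = max(linked + [snp.pos]) + pad_bp
        raw.append(Interval(str(snp.chrom), max(1, start), end, (snp.snp_id,)))
    return merge_intervals(raw)


def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Merge overlapping intervals per chromosome, pooling index ids."""
    out: list[Interval] = []
    by_chrom: dict[str, list[Interval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for chrom in sorted(by_chrom, key=_chrom_key):
        ivs = sorted(by_chrom[chrom], key=lambda v: (v.start, v.end))
        current = ivs[0]
        for nxt in ivs[1:]:
            if nxt.start <= current.end:
                current = Interval(
                    chrom,
                    current.start,
                    max(current.end, nxt.end),
                    current.index_snps + nxt.index_snps,
                )
            else:
                out.append(current)
                current = nxt
        out.append(current)
    return out


def exclude_ld_proxies(
    candidates: Sequence,
    reference_ids: Sequence[str],
    r2_lookup,
    proxy_r2: float = 0.8,
) -> tuple[list, list[tuple[str, str, float]]]:
    """Drop candidate index SNPs in high LD with any reference index SNP.

    ``r2_lookup(id_a, id_b)`` returns pairwise r^2 or None when the pair
    is not in the panel.  Returns (kept, excluded) where each exclusion
    is (candidate_id, reference_id, r2).  Used to avoid double-counting
    one association signal tagged by both traits' hit lists.
    """
    kept, excluded = [], []
    for cand in candidates:
        hit = None
        for ref_id in reference_ids:
            r2 = r2_lookup(cand.snp_id, ref_id)
            if r2 is not None and r2 > proxy_r2:
                hit = (cand.snp_id, ref_id, float(r2))
                break
        if hit:
            excluded.append(hit)
        else:
            kept.append(cand)
    return kept, excluded


def panel_r2_lookup(blocks: Sequence[LdBlock]):
    """Return an ``r2_lookup`` closure over a block panel."""

    def lookup(id_a: str, id_b: str):
        for b in blocks:
            if id_a in b and id_b in b:
                return pairwise_r2(b, id_a, id_b)
        return None

    return lookup


def _chrom_key(chrom: str):
    c = chrom.removeprefix("chr")
    return (0, int(c)) if c.isdigit() else (1, c)


# ---------------------------------------------------------------------------
# Panel I/O: one whitespace-delimited matrix file per block plus a SNP
# metadata table (block, snp_id, chrom, pos, allele1, allele2).

def save_panel(blocks: Sequence[LdBlock], directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta_rows = []
    for k, block in enumerate(blocks):
        np.savetxt(directory / f"block{k:04d}.ld", block.corr, fmt="%.10g")
        for s in block.snps:
            meta_rows.append((k, s.snp_id, s.chrom, s.pos, s.allele1, s.allele2))
    pd.DataFrame(
        meta_rows, columns=["block", "snp_id", "chrom", "pos", "allele1", "allele2"]
    ).to_csv(directory / "snps.tsv", sep="\t", index=False)


def load_panel(directory) -> list[LdBlock]:
    directory = Path(directory)
    meta = pd.read_csv(directory / "snps.tsv", sep="\t", dtype={"chrom": str})
    blocks = []
    for k, grp in meta.groupby("block", sort=True):
        corr = np.loadtxt(directory / f"block{int(k):04d}.ld")
        corr = np.atleast_2d(corr)
        snps = [
            SnpInfo(str(r.snp_id), str(r.chrom), int(r.pos), str(r.allele1), str(r.allele2))
            for r in grp.itertuples(index=False)
        ]
        blocks.append(LdBlock(snps, corr))
    return blocks


def load_r2_table(path) -> dict[frozenset, float]:
    """Load a pre-computed pairwise r^2 list (id_a, id_b, r2)."""
    df = pd.read_csv(path, sep=r"\s+", names=["id_a", "id_b", "r2"], header=None, comment="#")
    return {frozenset((a, b)): float(r2) for a, b, r2 in df.itertuples(index=False)}
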