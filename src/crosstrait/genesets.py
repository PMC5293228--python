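"""Interval-based gene-set enrichment with a relocation permutation null.

The observed statistic for a gene set is the number of LD-independent
association intervals that overlap at least one of the set's genes
(genes extended by a flanking window, 50 kb by default).  The null is
generated by relocating each interval uniformly at random in the
genome, preserving its length and, optionally, its gene-count class;
the empirical p-value is the permutation tail fraction with the +1
correction.  A second, familywise stage corrects each set's empirical
p for the number of sets tested by re-sampling whole pseudo-experiments
from the permutation null and recording how often the best set in a
pseudo-experiment beats the observed set.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ld import Interval

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneAnnotation:
    """One gene's span (1-based, inclusive)."""

    gene_id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")


@dataclass(frozen=True)
class GeneSet:
    set_id: str
    description: str
    gene_ids: frozenset


@dataclass(frozen=True)
class GeneSetResult:
    set_id: str
    description: str
    n_genes: int
    observed_overlap: int
    empirical_p: float
    corrected_p: float


def read_gene_bed(path) -> list[GeneAnnotation]:
    """Read a BED-like gene table: gene_id, chrom, start, end (TSV, header optional)."""
    df = pd.read_csv(path, sep=r"\s+", comment="#", header=None, dtype={1: str})
    if str(df.iloc[0, 2]).isalpha():  # header row present
        df = df.iloc[1:].reset_index(drop=True)
    return [
        GeneAnnotation(str(r[0]), str(r[1]), int(r[2]), int(r[3]))
        for r in df.itertuples(index=False)
    ]


def write_gene_bed(genes: Sequence[GeneAnnotation], path) -> None:
    pd.DataFrame(
        [(g.gene_id, g.chrom, g.start, g.end) for g in genes],
        columns=["gene_id", "chrom", "start", "end"],
    ).to_csv(path, sep="\t", index=False, header=False)


def read_gmt(path) -> list[GeneSet]:
    """Read gene sets in GMT format: set_id <tab> description <tab> gene..."""
    sets = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"GMT line has fewer than 3 fields: {line[:80]!r}")
        sets.append(GeneSet(fields[0], fields[1], frozenset(fields[2:])))
    return sets


def write_gmt(sets: Sequence[GeneSet], path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.set_id, s.description, *sorted(s.gene_ids)]) + "\n")


def filter_sets_by_size(
    sets: Sequence[GeneSet],
    universe: set[str],
    min_size: int = 10,
    max_size: int = 200,
) -> list[GeneSet]:
    """Keep sets whose intersection with the annotation universe has size in range."""
    out = []
    for s in sets:
        genes = frozenset(s.gene_ids & universe)
        if min_size <= len(genes) <= max_size:
            out.append(GeneSet(s.set_id, s.description, genes))
    return out


def _norm_chrom(chrom: str) -> str:
    return str(chrom).removeprefix("chr")


class _GeneIndex:
    """Per-chromosome arrays of gene spans for fast interval queries."""

    def __init__(self, genes: Sequence[GeneAnnotation]):
        self.by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        grouped: dict[str, list[GeneAnnotation]] = {}
        for g in genes:
            grouped.setdefault(_norm_chrom(g.chrom), []).append(g)
        for chrom, gl in grouped.items():
            gl.sort(key=lambda g: (g.start, g.end))
            self.by_chrom[chrom] = (
                np.array([g.start for g in gl]),
                np.array([g.end for g in gl]),
                np.array([g.gene_id for g in gl], dtype=object),
            )

    def query(self, chrom: str, start: int, end: int, flank: int) -> np.ndarray:
        """Ids of genes whose flank-extended span intersects [start, end]."""
        entry = self.by_chrom.get(_norm_chrom(chrom))
        if entry is None:
            return np.array([], dtype=object)
        gstart, gend, ids = entry
        mask = (gstart - flank <= end) & (gend + flank >= start)
        return ids[mask]


def intervals_to_genes(
    intervals: Sequence[Interval],
    annotations: Sequence[GeneAnnotation],
    flank_bp: int = 50_000,
) -> dict[Interval, frozenset]:
    """Assign genes to intervals: closed-interval intersection with flanks.

    Gene g belongs to interval i iff [g.start - flank, g.end + flank]
    intersects [i.start, i.end].  Chromosome names are normalized
    ('chr1' and '1' match), with a warning when conventions differ.
    """
    if flank_bp < 0:
        raise ValueError("flank_bp must be >= 0")
    iv_chroms = {str(iv.chrom) for iv in intervals}
    gene_chroms = {str(g.chrom) for g in annotations}
    if iv_chroms and gene_chroms:
        iv_pref = any(c.startswith("chr") for c in iv_chroms)
        g_pref = any(c.startswith("chr") for c in gene_chroms)
        if iv_pref != g_pref:
            warnings.warn(
                "interval and gene chromosome naming differ ('chr' prefix); normalizing",
                stacklevel=2,
            )
    index = _GeneIndex(annotations)
    return {
        iv: frozenset(index.query(iv.chrom, iv.start, iv.end, flank_bp))
        for iv in intervals
    }


def _relocate(
    rng: np.random.Generator,
    length: int,
    chrom_names: list[str],
    chrom_lengths: np.ndarray,
    probs: np.ndarray,
) -> tuple[str, int, int]:
    ci = rng.choice(len(chrom_names), p=probs)
    max_start = int(chrom_lengths[ci]) - length + 1
    start = int(rng.integers(1, max_start + 1))
    return chrom_names[ci], start, start + length - 1


def test_gene_sets(
    intervals: Sequence[Interval],
    annotations: Sequence[GeneAnnotation],
    sets: Sequence[GeneSet],
    n_perm: int = 10_000,
    n_boot: int = 1_000,
    seed: int | None = None,
    flank_bp: int = 50_000,
    genome: Mapping[str, int] | None = None,
    match_gene_count: bool = True,
    gene_count_tol: int = 1,
    max_relocation_tries: int = 100,
) -> list[GeneSetResult]:
    """Permutation enrichment of gene sets in association intervals.

    ``genome`` maps chromosome name to length in bp; when omitted it is
    inferred from the annotation span per chromosome (plus the flank).
    With ``match_gene_count`` each relocated interval is re-drawn until
    its gene count is within ``gene_count_tol`` of the original
    interval's, approximating a density-matched background; after
    ``max_relocation_tries`` failures the last draw is accepted.

    Returns one :class:`GeneSetResult` per set with the observed
    interval-overlap count, the permutation ``empirical_p`` and the
    familywise resampling-corrected ``corrected_p``.
    """
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    if not intervals:
        raise ValueError("no intervals supplied")
    rng = np.random.default_rng(seed)
    index = _GeneIndex(annotations)

    if genome is None:
        genome = {}
        for g in annotations:
            c = _norm_chrom(g.chrom)
            genome[c] = max(genome.get(c, 0), g.end + flank_bp)
    else:
        genome = {_norm_chrom(c): int(ln) for c, ln in genome.items()}

    lengths = [iv.length for iv in intervals]
    max_len = max(lengths)
    chrom_names = [c for c, ln in genome.items() if ln >= max_len]
    if not chrom_names:
        raise ValueError("no chromosome long enough to host the longest interval")
    chrom_lengths = np.array([genome[c] for c in chrom_names], dtype=float)
    probs = chrom_lengths / chrom_lengths.sum()

    obs_genes = [
        frozenset(index.query(iv.chrom, iv.start, iv.end, flank_bp)) for iv in intervals
    ]
    if not any(obs_genes):
        warnings.warn("no interval overlaps any annotated gene", stacklevel=2)
    obs_counts_per_iv = [len(g) for g in obs_genes]

    set_list = list(sets)
    observed = np.array(
        [sum(1 for g in obs_genes if g & s.gene_ids) for s in set_list], dtype=int
    )

    # permutation null: relocate every interval, recount per set
    null_counts = np.empty((n_perm, len(set_list)), dtype=np.int32)
    for r in range(n_perm):
        perm_genes = []
        for iv, length, target in zip(intervals, lengths, obs_counts_per_iv):
            for _ in range(max_relocation_tries):
                chrom, start, end = _relocate(rng, length, chrom_names, chrom_lengths, probs)
                genes = index.query(chrom, start, end, flank_bp)
                if not match_gene_count or abs(len(genes) - target) <= gene_count_tol:
                    break
            perm_genes.append(frozenset(genes))
        for si, s in enumerate(set_list):
            null_counts[r, si] = sum(1 for g in perm_genes if g & s.gene_ids)

    tail = (null_counts >= observed[None, :]).sum(axis=0)
    empirical_p = (1.0 + tail) / (n_perm + 1.0)

    # familywise stage: resample pseudo-experiments from the null and ask
    # how often the best set anywhere beats each observed set
    sorted_null = np.sort(null_counts, axis=0)
    corrected_p = np.ones(len(set_list))
    if n_boot > 0 and len(set_list) > 0:
        boot_rows = rng.integers(0, n_perm, size=n_boot)
        pseudo = null_counts[boot_rows]  # (B, S)
        # pseudo empirical p of each set in each pseudo-experiment
        ge = np.empty_like(pseudo, dtype=float)
        for si in range(len(set_list)):
            ge[:, si] = n_perm - np.searchsorted(sorted_null[:, si], pseudo[:, si], side="left")
        pseudo_p = (1.0 + ge) / (n_perm + 1.0)
        min_p = pseudo_p.min(axis=1)
        exceed = (min_p[:, None] <= empirical_p[None, :]).sum(axis=0)
        corrected_p = (1.0 + exceed) / (n_boot + 1.0)
    corrected_p = np.maximum(corrected_p, empirical_p)

    return [
        GeneSetResult(
            set_id=s.set_id,
            description=s.description,
            n_genes=len(s.gene_ids),
            observed_overlap=int(observed[si]),
            empirical_p=float(empirical_p[si]),
            corrected_p=float(corrected_p[si]),
        )
        for si, s in enumerate(set_list)
    ]


def results_to_frame(results: Sequence[GeneSetResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.set_id, r.description, r.n_genes, r.observed_overlap, r.empirical_p, r.corrected_p)
            for r in results
        ],
        columns=["set_id", "description", "n_genes", "observed_overlap", "empirical_p", "corrected_p"],
    ).sort_values("empirical_p", kind="mergesort").reset_index(drop=True)
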