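"""Sample-size-weighted z-score meta-analysis (the METAL scheme).

Each study i contributes its signed z-score with weight w_i; the
combined statistic

    z_meta = sum_i w_i z_i / sqrt(sum_i w_i^2)

is standard normal under the null whenever the per-study z's are.  The
default weight is sqrt(N_i) with N_i the total sample size; an
effective-sample-size variant 4 / (1/n_case + 1/n_control) is
available for unbalanced case-control designs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .sumstats import SnpAssoc, p_from_z

WeightScheme = Literal["total", "effective"]


@dataclass(frozen=True)
class MetaResult:
    snp_id: str
    allele1: str
    allele2: str
    z_meta: float
    p_meta: float
    n_studies: int
    weights: tuple[float, ...]


def _weight(rec: SnpAssoc, scheme: WeightScheme) -> float:
    if scheme == "total":
        n = rec.n_total
    elif scheme == "effective":
        if rec.n_case == 0 or rec.n_control == 0:
            raise ValueError(f"{rec.snp_id}: effective-N weight needs case and control counts")
        n = 4.0 / (1.0 / rec.n_case + 1.0 / rec.n_control)
    else:
        raise ValueError(f"unknown weight scheme {scheme!r}")
    if n <= 0:
        raise ValueError(f"{rec.snp_id}: non-positive sample size")
    return float(np.sqrt(n))


def combine(records: Sequence[SnpAssoc], weight: WeightScheme = "total") -> MetaResult:
    """Combine one SNP's harmonized per-study records into a meta z-score.

    All records must share the snp_id and the same (effect, other)
    allele orientation — harmonize first; a mismatch is an error, never
    silently dropped.
    """
    if not records:
        raise ValueError("need at least one study record")
    first = records[0]
    for rec in records[1:]:
        if rec.snp_id != first.snp_id:
            raise ValueError(f"mixed SNPs: {first.snp_id} vs {rec.snp_id}")
        if (rec.allele1, rec.allele2) != (first.allele1, first.allele2):
            raise ValueError(
                f"{rec.snp_id}: unharmonized alleles "
                f"{first.allele1}/{first.allele2} vs {rec.allele1}/{rec.allele2}"
            )
    w = np.array([_weight(r, weight) for r in records])
    z = np.array([r.z for r in records])
    z_meta = float(w @ z / np.sqrt(w @ w))
    return MetaResult(
        snp_id=first.snp_id,
        allele1=first.allele1,
        allele2=first.allele2,
        z_meta=z_meta,
        p_meta=float(p_from_z(z_meta)),
        n_studies=len(records),
        weights=tuple(float(x) for x in w),
    )


def combine_studies(
    studies: Sequence[Sequence[SnpAssoc]],
    weight: WeightScheme = "total",
    require_all: bool = False,
) -> list[MetaResult]:
    """Meta-analyse every SNP across studies, harmonizing to study 1.

    SNPs present in a single study are meta-analysed as that study
    unless ``require_all`` restricts output to the intersection.
    """
    from .sumstats import harmonize

    by_id: dict[str, list[SnpAssoc]] = {}
    for study in studies:
        for rec in study:
            by_id.setdefault(rec.snp_id, []).append(rec)
    out = []
    for snp_id in by_id:
        recs = by_id[snp_id]
        if require_all and len(recs) < len(studies):
            continue
        anchor = recs[0]
        aligned = [anchor]
        for rec in recs[1:]:
            _, rec_aligned, _ = harmonize(anchor, rec)
            aligned.append(rec_aligned)
        out.append(combine(aligned, weight=weight))
    return out
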