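"""GWAS summary-statistics data model, I/O and allele harmonization.

A study's association results are held as a list of :class:`SnpAssoc`
records (or, in the vectorised paths, as a pandas DataFrame with the
same column semantics).  The effect allele (``allele1``) is the allele
the z-score is predicted for: a positive z means the effect allele
increases risk.  Coordinates are 1-based GRCh37 throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")

#: allele pairs that cannot be strand-resolved from summary data alone
AMBIGUOUS_PAIRS = frozenset({("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")})

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: default column names for tab-delimited summary statistics
DEFAULT_DIALECT: Mapping[str, str] = {
    "snp_id": "SNP",
    "chrom": "CHR",
    "pos": "BP",
    "allele1": "A1",
    "allele2": "A2",
    "z": "Z",
    "p": "P",
    "beta": "BETA",
    "se": "SE",
    "direction": "DIR",
    "n_case": "NCASE",
    "n_control": "NCONTROL",
    "accuracy": "INFO",
}


class SumstatsFormatError(ValueError):
    """Raised when a summary-statistics table cannot be parsed."""


class AlleleMismatchError(ValueError):
    """Raised when two records' alleles are neither equal, swapped nor complements."""


@dataclass
class SnpAssoc:
    """One SNP's association record in one study.

    ``allele1`` is the effect allele; ``accuracy`` is the imputation
    accuracy metric (1.0 for genotyped SNPs).
    """

    snp_id: str
    chrom: str
    pos: int
    allele1: str
    allele2: str
    z: float
    p: float | None = None
    n_case: int = 0
    n_control: int = 0
    accuracy: float = 1.0
    ambiguous: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        self.chrom = str(self.chrom)
        self.allele1 = self.allele1.upper()
        self.allele2 = self.allele2.upper()
        if self.allele1 == self.allele2:
            raise ValueError(
                f"{self.snp_id}: effect and other allele are identical ({self.allele1})"
            )
        if self.p is None and np.isfinite(self.z):
            self.p = p_from_z(self.z)
        if (self.allele1, self.allele2) in AMBIGUOUS_PAIRS:
            self.ambiguous = True

    @property
    def n_total(self) -> int:
        return self.n_case + self.n_control

    @property
    def is_snv(self) -> bool:
        """True for single-base substitutions with canonical bases."""
        return (
            len(self.allele1) == 1
            and len(self.allele2) == 1
            and self.allele1 in VALID_BASES
            and self.allele2 in VALID_BASES
        )


@dataclass(frozen=True)
class StudyMeta:
    """Per-study sample sizes and z-score variance inflation.

    ``inflation`` is sigma^2, the marginal variance of the study's
    z-scores over a well-behaved SNP set; it exceeds 1 under
    polygenicity or confounding.
    """

    label: str
    n_case: int
    n_control: int
    inflation: float = 1.0

    def __post_init__(self) -> None:
        if self.n_case + self.n_control <= 0:
            raise ValueError(f"{self.label}: total sample size must be positive")
        if self.inflation <= 0:
            raise ValueError(f"{self.label}: inflation must be positive")

    @property
    def n_total(self) -> int:
        return self.n_case + self.n_control


def p_from_z(z: float | np.ndarray) -> float | np.ndarray:
    """Two-sided p-value for a z statistic: 2*Phi(-|z|)."""
    return 2.0 * norm.sf(np.abs(z))


def z_from_p(p: float | np.ndarray, direction: float | np.ndarray) -> float | np.ndarray:
    """Signed z from a two-sided p and an effect direction (sign)."""
    return np.sign(direction) * norm.isf(np.asarray(p) / 2.0)


def read_sumstats(
    path,
    dialect: Mapping[str, str] | None = None,
    drop_ambiguous: bool = False,
) -> list[SnpAssoc]:
    """Read a tab/whitespace-delimited summary-statistics table.

    The z-score is taken from the Z column when present, else derived
    as beta/se, else as sign(direction) * Phi^-1(1 - p/2).  Records
    with p but no direction column are rejected: an unsigned statistic
    cannot be harmonized.  Rows missing mandatory fields are skipped
    and counted in the log.
    """
    cols = dict(DEFAULT_DIALECT)
    if dialect:
        cols.update(dialect)
    try:
        df = pd.read_csv(path, sep=r"\s+", dtype={cols["chrom"]: str})
    except Exception as exc:  # noqa: BLE001 - wrap any parse failure
        raise SumstatsFormatError(f"cannot parse {path}: {exc}") from exc

    required = [cols[k] for k in ("snp_id", "chrom", "pos", "allele1", "allele2")]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SumstatsFormatError(f"{path}: missing required columns {missing}")

    has_z = cols["z"] in df.columns
    has_beta = cols["beta"] in df.columns and cols["se"] in df.columns
    has_p = cols["p"] in df.columns
    has_dir = cols["direction"] in df.columns
    if not (has_z or has_beta or (has_p and has_dir)):
        raise SumstatsFormatError(
            f"{path}: need one of Z, (BETA,SE) or (P,direction) to obtain z-scores"
        )
    if not (has_z or has_beta) and has_p and not has_dir:
        raise SumstatsFormatError(
            f"{path}: p-values without a direction column cannot be signed"
        )

    dup = df[cols["snp_id"]][df[cols["snp_id"]].duplicated()].tolist()
    if dup:
        raise SumstatsFormatError(f"{path}: duplicated SNP ids: {sorted(set(dup))}")

    records: list[SnpAssoc] = []
    skipped = 0
    for row in df.itertuples(index=False):
        row = row._asdict()
        try:
            if any(pd.isna(row[c]) for c in required):
                skipped += 1
                continue
            if has_z and not pd.isna(row[cols["z"]]):
                z = float(row[cols["z"]])
            elif has_beta and not pd.isna(row[cols["beta"]]):
                z = float(row[cols["beta"]]) / float(row[cols["se"]])
            elif has_p and has_dir and not pd.isna(row[cols["p"]]):
                z = float(z_from_p(float(row[cols["p"]]), float(row[cols["direction"]])))
            else:
                skipped += 1
                continue
            rec = SnpAssoc(
                snp_id=str(row[cols["snp_id"]]),
                chrom=str(row[cols["chrom"]]),
                pos=int(row[cols["pos"]]),
                allele1=str(row[cols["allele1"]]),
                allele2=str(row[cols["allele2"]]),
                z=z,
                p=float(row[cols["p"]]) if has_p and not pd.isna(row.get(cols["p"])) else None,
                n_case=int(row[cols["n_case"]]) if cols["n_case"] in row and not pd.isna(row.get(cols["n_case"])) else 0,
                n_control=int(row[cols["n_control"]]) if cols["n_control"] in row and not pd.isna(row.get(cols["n_control"])) else 0,
                accuracy=float(row[cols["accuracy"]]) if cols["accuracy"] in row and not pd.isna(row.get(cols["accuracy"])) else 1.0,
            )
        except (ValueError, TypeError):
            skipped += 1
            continue
        records.append(rec)
    if skipped:
        logger.info("read_sumstats(%s): skipped %d incomplete rows", path, skipped)
    if drop_ambiguous:
        n0 = len(records)
        records = [r for r in records if not r.ambiguous]
        logger.info("dropped %d strand-ambiguous records", n0 - len(records))
    return records


def write_sumstats(records: Iterable[SnpAssoc], path, dialect: Mapping[str, str] | None = None) -> None:
    """Write records as a tab-delimited table (inverse of :func:`read_sumstats`)."""
    cols = dict(DEFAULT_DIALECT)
    if dialect:
        cols.update(dialect)
    df = pd.DataFrame(
        {
            cols["snp_id"]: [r.snp_id for r in records],
        }
    )
    recs = list(records)
    df = pd.DataFrame(
        {
            cols["snp_id"]: [r.snp_id for r in recs],
            cols["chrom"]: [r.chrom for r in recs],
            cols["pos"]: [r.pos for r in recs],
            cols["allele1"]: [r.allele1 for r in recs],
            cols["allele2"]: [r.allele2 for r in recs],
            cols["z"]: [repr(r.z) for r in recs],
            cols["p"]: [repr(r.p) if r.p is not None else "" for r in recs],
            cols["n_case"]: [r.n_case for r in recs],
            cols["n_control"]: [r.n_control for r in recs],
            cols["accuracy"]: [repr(r.accuracy) for r in recs],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def to_dataframe(records: Sequence[SnpAssoc]) -> pd.DataFrame:
    """Vectorised view of a record list."""
    return pd.DataFrame(
        {
            "snp_id": [r.snp_id for r in records],
            "chrom": [r.chrom for r in records],
            "pos": [r.pos for r in records],
            "allele1": [r.allele1 for r in records],
            "allele2": [r.allele2 for r in records],
            "z": [r.z for r in records],
            "p": [r.p for r in records],
            "n_case": [r.n_case for r in records],
            "n_control": [r.n_control for r in records],
            "accuracy": [r.accuracy for r in records],
            "ambiguous": [r.ambiguous for r in records],
        }
    )


def harmonize(a: SnpAssoc, b: SnpAssoc) -> tuple[SnpAssoc, SnpAssoc, bool]:
    """Align ``b``'s effect allele to ``a``'s, flipping the sign of z if needed.

    Returns ``(a, b_aligned, flipped)``.  Strand complements (b reported
    on the opposite strand) are resolved the same way.  Strand-ambiguous
    pairs (A/T, C/G) pass through with their ``ambiguous`` flag set —
    for those, complement and swap are indistinguishable.
    """
    if a.snp_id != b.snp_id:
        raise ValueError(f"cannot harmonize different SNPs: {a.snp_id} vs {b.snp_id}")
    if (b.allele1, b.allele2) == (a.allele1, a.allele2):
        return a, b, False
    if (b.allele1, b.allele2) == (a.allele2, a.allele1):
        flipped = replace(
            b, allele1=a.allele1, allele2=a.allele2, z=-b.z
        )
        return a, flipped, True
    comp1 = _COMPLEMENT.get(b.allele1)
    comp2 = _COMPLEMENT.get(b.allele2)
    if comp1 and comp2:
        if (comp1, comp2) == (a.allele1, a.allele2):
            return a, replace(b, allele1=comp1, allele2=comp2), False
        if (comp1, comp2) == (a.allele2, a.allele1):
            flipped = replace(b, allele1=a.allele1, allele2=a.allele2, z=-b.z)
            return a, flipped, True
    raise AlleleMismatchError(
        f"{a.snp_id}: alleles {a.allele1}/{a.allele2} vs {b.allele1}/{b.allele2} "
        "are neither equal, swapped nor strand complements"
    )
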