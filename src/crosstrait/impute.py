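"""Gaussian (ImpG-style) imputation of untyped SNPs' z-scores.

Under the null, the vector of z-scores in an LD block is multivariate
normal with covariance equal to the SNP correlation matrix.  The
z-score of an untyped SNP t is therefore predicted by the conditional
mean given the typed SNPs,

    z_t = w' (Sigma + lambda I)^-1 z_typed,

where Sigma is the typed-by-typed correlation submatrix, w the vector
of correlations between t and the typed SNPs, and lambda a small ridge
regularizer guarding near-singular reference LD.  The predicted
squared accuracy (expected squared correlation between imputed and
true z) is r2pred = w' (Sigma + lambda I)^-1 w, clipped to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .ld import LdBlock

DEFAULT_RIDGE = 0.1


@dataclass(frozen=True)
class ImputationResult:
    snp_id: str
    z_imputed: float
    r2pred: float
    typed: bool


class SingularLdError(np.linalg.LinAlgError):
    """Typed-SNP correlation matrix is numerically singular at lambda=0."""


def impute_block(
    block: LdBlock,
    typed: Mapping[str, float],
    ridge: float = DEFAULT_RIDGE,
) -> list[ImputationResult]:
    """Impute every untyped SNP in a block from the typed z-scores.

    Typed SNPs are passed through with ``r2pred = 1``.  A block with no
    typed SNPs yields z = 0, r2pred = 0 for every target (the
    unconditional null mean).
    """
    if ridge < 0:
        raise ValueError("ridge must be >= 0")
    unknown = set(typed) - set(block.snp_ids)
    if unknown:
        raise KeyError(f"typed SNPs not in block: {sorted(unknown)}")

    typed_idx = [i for i, s in enumerate(block.snps) if s.snp_id in typed]
    untyped_idx = [i for i, s in enumerate(block.snps) if s.snp_id not in typed]
    results: list[ImputationResult] = []

    if typed_idx:
        z_typed = np.array([typed[block.snps[i].snp_id] for i in typed_idx])
        sigma = block.corr[np.ix_(typed_idx, typed_idx)] + ridge * np.eye(len(typed_idx))
        if ridge == 0:
            # reject ill-conditioned systems rather than return noise
            if np.linalg.cond(sigma) > 1e12:
                raise SingularLdError(
                    "typed-SNP correlation matrix is singular; use a positive ridge"
                )
        w_all = block.corr[np.ix_(untyped_idx, typed_idx)]
        solved = np.linalg.solve(sigma, np.column_stack([z_typed[:, None], w_all.T]))
        z_imp = w_all @ solved[:, 0]
        r2pred = np.clip(np.einsum("ij,ji->i", w_all, solved[:, 1:]), 0.0, 1.0)
    else:
        z_imp = np.zeros(len(untyped_idx))
        r2pred = np.zeros(len(untyped_idx))

    for i in typed_idx:
        sid = block.snps[i].snp_id
        results.append(ImputationResult(sid, float(typed[sid]), 1.0, True))
    for j, i in enumerate(untyped_idx):
        results.append(
            ImputationResult(block.snps[i].snp_id, float(z_imp[j]), float(r2pred[j]), False)
        )
    order = {s.snp_id: k for k, s in enumerate(block.snps)}
    results.sort(key=lambda r: order[r.snp_id])
    return results


def filter_by_accuracy(
    results: Sequence[ImputationResult], min_r2pred: float
) -> tuple[list[ImputationResult], int]:
    """Keep results with ``r2pred >= min_r2pred``; typed SNPs always survive."""
    if not 0.0 <= min_r2pred <= 1.0:
        raise ValueError("min_r2pred must be in [0, 1]")
    kept = [r for r in results if r.typed or r.r2pred >= min_r2pred]
    return kept, len(results) - len(kept)
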