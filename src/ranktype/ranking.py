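"""Intrasample rank transform and differentially ranked gene screening.

The core idea: within one sample, order all genes ascending by expression and
replace each value by its rank (lowest-expressed gene = rank 1).  Ranks are
invariant under any strictly increasing per-sample transformation, which is
what makes everything downstream robust to sample-level batch distortions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import DataError, ExpressionMatrix

logger = logging.getLogger("ranktype")


@dataclass
class RankMatrix:
    """Per-column ascending ranks of an expression matrix.

    Ties get the mean of the positions they span (fractional ranks), so every
    column sums to n(n+1)/2 exactly.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    ranks: np.ndarray

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.ranks, index=self.gene_ids, columns=self.sample_ids)


def rank_transform(X: ExpressionMatrix) -> RankMatrix:
    """Convert expression to intrasample (per-sample-column) ascending ranks."""
    if X.n_genes < 2:
        raise DataError("rank_transform needs at least 2 genes")
    ranks = stats.rankdata(X.values, method="average", axis=0)
    return RankMatrix(list(X.gene_ids), list(X.sample_ids), ranks)


@dataclass
class DiffRankResult:
    """Differential ranking between two subtypes, oriented (A, B).

    ``difference`` = per-gene (mean rank in A) - (mean rank in B); ``pvalues``
    from a two-sided t-test on per-sample ranks.  ``up_genes`` /``down_genes``
    are the genes whose difference exceeds +/- the rank threshold with
    p < alpha.
    """

    comparison: tuple[str, str]
    gene_ids: list[str]
    difference: np.ndarray
    pvalues: np.ndarray
    up_genes: set[str]
    down_genes: set[str]
    threshold: int
    alpha: float

    def to_frame(self) -> pd.DataFrame:
        direction = np.where(
            [g in self.up_genes for g in self.gene_ids], "up",
            np.where([g in self.down_genes for g in self.gene_ids], "down", "-"),
        )
        return pd.DataFrame(
            {"difference": self.difference, "p": self.pvalues, "direction": direction},
            index=pd.Index(self.gene_ids, name="gene_id"),
        )


def _subtype_columns(sample_ids: list[str], labels, subtype: str) -> np.ndarray:
    cols = np.array(
        [i for i, s in enumerate(sample_ids) if labels.get(s) == subtype], dtype=int
    )
    return cols


def diff_rank_genes(
    R: RankMatrix,
    labels,
    a: str,
    b: str,
    rank_frac: float = 0.11,
    alpha: float = 0.05,
    equal_var: bool = False,
) -> DiffRankResult:
    """Screen genes whose mean intrasample rank differs between subtypes A and B.

    A gene is "up" (for A) when mean_rank_A - mean_rank_B > round(rank_frac * n)
    with p < alpha from a two-sided t-test (Welch by default), and "down"
    symmetrically.  ``rank_frac`` generalises the absolute rank-difference
    cutoff as a fraction of the gene count (default 0.11).
    """
    if not 0 < rank_frac < 1:
        raise DataError(f"rank_frac must be in (0, 1), got {rank_frac}")
    n = R.n_genes
    threshold = int(round(rank_frac * n))
    if threshold < 1:
        raise DataError(f"rank_frac {rank_frac} gives a threshold < 1 for n={n}")
    cols_a = _subtype_columns(R.sample_ids, labels, a)
    cols_b = _subtype_columns(R.sample_ids, labels, b)
    for name, cols in ((a, cols_a), (b, cols_b)):
        if len(cols) < 2:
            raise DataError(f"subtype {name!r} has {len(cols)} sample(s); need >= 2")
    ra, rb = R.ranks[:, cols_a], R.ranks[:, cols_b]
    difference = ra.mean(axis=1) - rb.mean(axis=1)
    import warnings as _warnings

    with np.errstate(invalid="ignore", divide="ignore"), _warnings.catch_warnings():
        # constant-rank genes trigger a precision warning; their p becomes 1
        _warnings.simplefilter("ignore", RuntimeWarning)
        _, pvalues = stats.ttest_ind(ra, rb, axis=1, equal_var=equal_var)
    pvalues = np.nan_to_num(pvalues, nan=1.0)  # zero-variance-both-groups genes
    sig = pvalues < alpha
    up = sig & (difference > threshold)
    down = sig & (difference < -threshold)
    gene_arr = np.array(R.gene_ids)
    return DiffRankResult(
        comparison=(a, b),
        gene_ids=list(R.gene_ids),
        difference=difference,
        pvalues=pvalues,
        up_genes=set(gene_arr[up]),
        down_genes=set(gene_arr[down]),
        threshold=threshold,
        alpha=alpha,
    )


def subtype_signature_genes(results: list[DiffRankResult], subtype: str) -> set[str]:
    """Intersect the three pairwise screens for one subtype.

    Each result must be oriented with ``subtype`` first.  The signature is the
    union of (genes up in all three comparisons) and (genes down in all three
    comparisons): genes consistently over- or under-ranked in this subtype
    relative to every other subtype.
    """
    if len(results) != 3:
        raise DataError(f"expected exactly 3 comparisons, got {len(results)}")
    others = []
    for r in results:
        if r.comparison[0] != subtype:
            raise DataError(
                f"comparison {r.comparison} is not oriented with {subtype!r} first"
            )
        others.append(r.comparison[1])
    if len(set(others)) != 3 or subtype in others:
        raise DataError(f"comparisons {others} must be against 3 distinct other subtypes")
    up = set.intersection(*[r.up_genes for r in results])
    down = set.intersection(*[r.down_genes for r in results])
    return up | down
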