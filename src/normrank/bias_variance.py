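"""Bias and variance of a normalization on housekeeping control genes.

A true housekeeping gene has the same expected count in every sample, so the
true log ratio of a sample's (normalized) count to the gene's mean is 0.  For
control gene i with normalized counts K_ij and mean Kbar_i:

    bias_i     = sqrt( (1/m)   sum_j log2(K_ij / Kbar_i)^2 )          (RMSE; accuracy proxy)
    variance_i = (1/(m-1)) sum_j ( log2(K_ij/Kbar_i) - mean log ratio )^2   (precision proxy)

A method's bias/variance is the unweighted mean over the surviving control
genes; lower is better.  Both quantities are invariant to rescaling a gene by
a constant, so they probe how well the per-sample divisors remove the
library-size signal from genes that should be flat.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .counts_io import CountMatrix, CountsValidationError, GeneList


@dataclass
class BiasVarianceResult:
    """Bias/variance of one normalization method on the control genes."""

    method: str
    gene_ids: list[str]
    per_gene_bias: np.ndarray
    per_gene_variance: np.ndarray
    n_excluded: int

    @property
    def method_bias(self) -> float:
        return float(self.per_gene_bias.mean())

    @property
    def method_variance(self) -> float:
        return float(self.per_gene_variance.mean())


def _control_log_ratios(
    normalized_counts: np.ndarray, gene_ids: list[str], hg: GeneList
) -> tuple[list[str], np.ndarray, int]:
    """log2 ratios of each usable control gene to its own mean.

    Control genes with a zero (or negative) normalized count in any sample
    have an undefined log ratio and are excluded with a warning.
    """
    index = {g: i for i, g in enumerate(gene_ids)}
    missing = [g for g in hg.ids if g not in index]
    if missing:
        raise CountsValidationError(
            f"control genes absent from the matrix: {missing[:5]}"
        )
    rows = np.array([index[g] for g in hg.ids], dtype=int)
    sub = np.asarray(normalized_counts, dtype=float)[rows, :]
    usable = (sub > 0).all(axis=1)
    n_excluded = int((~usable).sum())
    if n_excluded:
        warnings.warn(
            f"excluded {n_excluded} control gene(s) with a nonpositive "
            "normalized count (log ratio undefined)"
        )
    if not usable.any():
        raise CountsValidationError("no control gene has all-positive normalized counts")
    sub = sub[usable, :]
    kept = [g for g, u in zip(hg.ids, usable) if u]
    ratios = np.log2(sub / sub.mean(axis=1, keepdims=True))
    return kept, ratios, n_excluded


def control_gene_bias(
    normalized_counts: np.ndarray, gene_ids: list[str], hg: GeneList
) -> pd.Series:
    """Per-control-gene RMSE of log2 ratios to the gene's mean (true log ratio 0)."""
    kept, ratios, _ = _control_log_ratios(normalized_counts, gene_ids, hg)
    return pd.Series(np.sqrt(np.mean(ratios**2, axis=1)), index=kept, name="bias")


def control_gene_variance(
    normalized_counts: np.ndarray, gene_ids: list[str], hg: GeneList
) -> pd.Series:
    """Per-control-gene unbiased sample variance (divisor m-1) of the log2 ratios."""
    if np.asarray(normalized_counts).shape[1] < 2:
        raise CountsValidationError("variance needs at least two samples")
    kept, ratios, _ = _control_log_ratios(normalized_counts, gene_ids, hg)
    return pd.Series(np.var(ratios, axis=1, ddof=1), index=kept, name="variance")


def bias_variance_for_method(
    method: str, normalized_counts: np.ndarray, gene_ids: list[str], hg: GeneList
) -> BiasVarianceResult:
    """Bias and variance of one method in a single pass over the control genes."""
    kept, ratios, n_excluded = _control_log_ratios(normalized_counts, gene_ids, hg)
    return BiasVarianceResult(
        method=method,
        gene_ids=kept,
        per_gene_bias=np.sqrt(np.mean(ratios**2, axis=1)),
        per_gene_variance=np.var(ratios, axis=1, ddof=1),
        n_excluded=n_excluded,
    )


def rank_methods_by(values: dict[str, float] | pd.Series, direction: str = "lower_better") -> pd.Series:
    """Tie-averaged competition ranks: the best method gets rank 1; tied
    methods share the mean of the tied positions (a two-way tie for first is
    1.5/1.5)."""
    s = pd.Series(values, dtype=float)
    if s.isna().any() or not np.isfinite(s.to_numpy()).all():
        raise CountsValidationError("every method needs one finite value to rank")
    if direction == "lower_better":
        ranks = rankdata(s.to_numpy(), method="average")
    elif direction == "higher_better":
        ranks = rankdata(-s.to_numpy(), method="average")
    else:
        raise CountsValidationError(f"unknown direction {direction!r}")
    return pd.Series(ranks, index=s.index, name="rank")
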