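"""Analytical housekeeping-gene selection.

Real housekeeping lists are rarely available for a new experiment, so the
control set is defined analytically: the fraction (default 1%) of genes whose
raw counts are most stable across samples, measured by the per-gene mean
squared deviation around the gene's own mean

    MSE_g = sum_j (K_gj - Kbar_g)^2 / m

min-max normalized to [0, 1].  Selection is on raw, unnormalized counts — the
control set must not depend on the normalization under evaluation.  The
selected set is invariant under any strictly increasing transform of the
score, so whether one reports the MSE or its square root cannot change it.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .counts_io import CountMatrix, CountsValidationError, GeneList


@dataclass
class HousekeepingScores:
    """Per-gene stability scores; lower means more stable."""

    gene_ids: list[str]
    mse: np.ndarray
    mse_normalized: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"mse": self.mse, "mse_normalized": self.mse_normalized},
            index=self.gene_ids,
        )


def gene_stability_scores(cm: CountMatrix) -> HousekeepingScores:
    """MSE of each gene's raw counts around its mean (divisor m), min-max
    normalized across genes.  If every gene has the same score the min-max
    transform is undefined; all normalized scores are set to 0 with a warning.
    """
    if cm.n_samples < 2:
        raise CountsValidationError("stability scores need at least two samples")
    counts = cm.counts.astype(float)
    mse = np.mean((counts - counts.mean(axis=1, keepdims=True)) ** 2, axis=1)
    lo, hi = mse.min(), mse.max()
    if hi == lo:
        warnings.warn("all stability scores identical; min-max normalization undefined")
        norm = np.zeros_like(mse)
    else:
        norm = (mse - lo) / (hi - lo)
    return HousekeepingScores(list(cm.gene_ids), mse, norm)


def select_housekeeping(
    scores: HousekeepingScores, fraction: float = 0.01
) -> GeneList:
    """The floor(fraction * G) genes with the lowest normalized score, ties at
    the boundary broken by input gene order."""
    if not 0 < fraction < 1:
        raise CountsValidationError("fraction must lie in (0, 1)")
    n = math.floor(fraction * len(scores.gene_ids))
    if n == 0:
        raise CountsValidationError(
            f"fraction {fraction} of {len(scores.gene_ids)} genes selects no gene"
        )
    order = np.argsort(scores.mse_normalized, kind="stable")
    chosen = [scores.gene_ids[i] for i in sorted(order[:n])]
    return GeneList(tuple(chosen), role="housekeeping")
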