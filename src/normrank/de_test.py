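"""Negative-binomial exact test for two-group differential expression.

The count model is K_gj ~ NB(d_j * lambda_gj, phi): the expected count is the
gene's expression level scaled by the sample's normalization divisor, with a
single common dispersion phi shared across genes.  Testing proceeds the way
exact count tests classically do:

1. counts are divided by their divisors so all samples sit on one effective
   library scale (pseudo-counts), and each gene's per-group sums S1, S2 are
   formed (rounded to integers);
2. under the null of equal expression, each group sum is NB with mean n_k*mu
   and dispersion phi/n_k (the sum of n_k i.i.d. NB variates); the test
   conditions on the total S = S1 + S2 and computes the distribution of S1
   over all splits of S;
3. the two-sided p-value is the total probability of outcomes no more likely
   than the observed one.  At phi = 0 the conditional distribution is exactly
   binomial(S, n1/(n1+n2)).

Very large per-gene totals are rescaled down to a configurable cap before the
split enumeration, which bounds the work per gene while leaving the group
proportions intact.  Multiplicity is controlled by Benjamini-Hochberg and a
gene is called differentially expressed when its adjusted p-value falls below
the threshold (default 0.05).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .counts_io import CountMatrix, CountsValidationError, GeneList
from .normalization import ScalingFactorSet, normalize_counts


class DETestError(ValueError):
    pass


@dataclass
class DEResult:
    """Per-gene differential expression results for one normalization."""

    gene_ids: list[str]
    log2_fold_change: np.ndarray
    p_value: np.ndarray
    base_mean: np.ndarray
    method: str
    adj_p_value: np.ndarray | None = None
    is_deg: np.ndarray | None = None
    alpha: float | None = None
    zero_total: np.ndarray = field(default_factory=lambda: np.array([], dtype=bool))

    @property
    def n_deg(self) -> int:
        if self.is_deg is None:
            raise DETestError("DEGs not called yet; apply adjust/call first")
        return int(self.is_deg.sum())

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "base_mean": self.base_mean,
                "log2FC": self.log2_fold_change,
                "p": self.p_value,
            },
            index=self.gene_ids,
        )
        if self.adj_p_value is not None:
            df["adj_p"] = self.adj_p_value
            df["is_deg"] = self.is_deg
        df["method"] = self.method
        return df


def estimate_common_dispersion(cm: CountMatrix, sf: ScalingFactorSet) -> float:
    """Single common dispersion by pooled moment matching.

    Within each group the NB model implies Var = mu + phi*mu^2 on normalized
    counts.  For every gene and group with at least two samples the moment
    residual (s^2 - mhat) and the scale mhat^2 are accumulated with their
    degrees of freedom, and phi is the ratio of the pooled sums — a
    variance-weighted average of the per-gene moment estimates, floored at 0.
    Returns 0 with a warning when no group has replication (Poisson fallback).
    """
    norm = normalize_counts(cm, sf)
    num = 0.0
    den = 0.0
    any_replication = False
    for _, idx in cm.group_indices().items():
        if idx.size < 2:
            continue
        any_replication = True
        sub = norm[:, idx]
        mu = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        df = idx.size - 1
        num += df * float(np.sum(v - mu))
        den += df * float(np.sum(mu**2))
    if not any_replication:
        warnings.warn("no within-group replication; dispersion set to 0 (Poisson)")
        return 0.0
    if den == 0:
        return 0.0
    return max(0.0, num / den)


def _nb_logpmf(k: np.ndarray, mean: float, size: float) -> np.ndarray:
    """NB log pmf with mean/size parametrisation (size = 1/dispersion)."""
    k = np.asarray(k, dtype=float)
    return (
        gammaln(k + size)
        - gammaln(size)
        - gammaln(k + 1)
        + size * np.log(size / (size + mean))
        + k * np.log(mean / (size + mean))
    )


def _poisson_logpmf(k: np.ndarray, mean: float) -> np.ndarray:
    k = np.asarray(k, dtype=float)
    return k * np.log(mean) - mean - gammaln(k + 1)


def _exact_p(s1: int, total: int, n1: int, n2: int, phi: float) -> float:
    """Two-sided conditional exact p-value for the split (s1, total - s1)."""
    s = np.arange(total + 1)
    mu = total / (n1 + n2)
    if phi <= 0:
        logf = _poisson_logpmf(s, n1 * mu) + _poisson_logpmf(total - s, n2 * mu)
    else:
        logf = _nb_logpmf(s, n1 * mu, n1 / phi) + _nb_logpmf(total - s, n2 * mu, n2 / phi)
    logf -= logsumexp(logf)
    obs = logf[s1]
    # tolerance keeps ties with the observed probability inside the rejection set
    p = float(np.exp(logsumexp(logf[logf <= obs + 1e-10])))
    return min(1.0, p)


def nb_exact_test(
    cm: CountMatrix,
    sf: ScalingFactorSet,
    phi: float,
    pseudocount: float = 0.5,
    cap: int = 2000,
) -> DEResult:
    """Exact two-sided NB test of the second group against the first.

    Groups are taken in sorted label order; the reported fold change is
    group2 over group1 on divisor-normalized means, with ``pseudocount``
    added to each mean so it stays finite at zero counts.  Genes with zero
    total count get p = 1, fold change 0, and are flagged.  Per-gene totals
    above ``cap`` are proportionally rescaled before the split enumeration.
    """
    if phi < 0:
        raise DETestError("dispersion must be nonnegative")
    norm = normalize_counts(cm, sf)
    gi = cm.group_indices()
    (g1, idx1), (g2, idx2) = gi.items()
    n1, n2 = idx1.size, idx2.size
    mean1 = norm[:, idx1].mean(axis=1)
    mean2 = norm[:, idx2].mean(axis=1)
    base_mean = norm.mean(axis=1)
    lfc = np.log2((mean2 + pseudocount) / (mean1 + pseudocount))
    s1_all = np.rint(norm[:, idx1].sum(axis=1)).astype(np.int64)
    s2_all = np.rint(norm[:, idx2].sum(axis=1)).astype(np.int64)
    totals = s1_all + s2_all
    zero_total = totals == 0
    lfc[zero_total] = 0.0
    p = np.ones(cm.n_genes)
    for g in range(cm.n_genes):
        total = int(totals[g])
        if total == 0:
            continue
        s1 = int(s1_all[g])
        if total > cap:
            scale = cap / total
            s1 = int(round(s1 * scale))
            total = int(round(s1_all[g] * scale)) + int(round(s2_all[g] * scale))
            s1 = min(s1, total)
        p[g] = _exact_p(s1, total, n1, n2, phi)
    if zero_total.any():
        warnings.warn(f"{int(zero_total.sum())} gene(s) with zero total count: p set to 1")
    return DEResult(
        gene_ids=list(cm.gene_ids),
        log2_fold_change=lfc,
        p_value=p,
        base_mean=base_mean,
        method=sf.method,
        zero_total=zero_total,
    )


def adjust_p_values(p: np.ndarray, method: str = "fdr_bh") -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (other statsmodels multiple-test
    procedures accepted by name)."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise DETestError("p-values must lie in [0, 1]")
    return multipletests(p, method=method)[1]


def call_degs(de: DEResult, alpha: float = 0.05) -> GeneList:
    """Genes with adjusted p < alpha, ordered by adjusted p ascending (ties by
    input gene order).  Adjusts p-values first if not done yet; sets
    ``is_deg``/``alpha`` on the result in place."""
    if not 0 < alpha < 1:
        raise DETestError("alpha must lie in (0, 1)")
    if de.adj_p_value is None:
        de.adj_p_value = adjust_p_values(de.p_value)
    de.is_deg = de.adj_p_value < alpha
    de.alpha = alpha
    order = np.argsort(de.adj_p_value, kind="stable")
    ids = [de.gene_ids[i] for i in order if de.is_deg[i]]
    return GeneList(tuple(ids), role="generic")


def run_de(
    cm: CountMatrix,
    sf: ScalingFactorSet,
    alpha: float = 0.05,
    phi: float | None = None,
    **test_kwargs,
) -> DEResult:
    """Dispersion estimate + exact test + BH adjustment + DEG call."""
    if phi is None:
        phi = estimate_common_dispersion(cm, sf)
    de = nb_exact_test(cm, sf, phi, **test_kwargs)
    call_degs(de, alpha=alpha)
    return de


def ma_values(de: DEResult) -> pd.DataFrame:
    """MA-plot coordinates: A = log10(base mean), M = log2 fold change, with a
    DEG flag.  Genes with zero base mean are omitted (count reported via attrs)."""
    keep = de.base_mean > 0
    df = pd.DataFrame(
        {
            "A": np.log10(de.base_mean[keep]),
            "M": de.log2_fold_change[keep],
            "is_deg": (de.is_deg[keep] if de.is_deg is not None else False),
        },
        index=[g for g, k in zip(de.gene_ids, keep) if k],
    )
    df.attrs["n_omitted"] = int((~keep).sum())
    return df
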