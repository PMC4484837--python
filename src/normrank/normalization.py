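"""Per-sample scaling factors by five between-sample normalization methods.

Methods
-------
TMM
    Trimmed mean of M-values: a weighted mean of per-gene log2 ratios between
    each sample and a reference sample, after two-sided trimming of extreme
    log-ratios (M) and extreme average abundances (A).  Corrects the library
    size, so its count-scale divisor is the *effective library size* N_j * d_j.
UQ
    Upper quartile: the 75th percentile of each library's counts (after
    removing genes that are zero in every library) divided by the library size.
DES
    Median-of-ratios: the median over genes of the ratio of a sample's count
    to the gene's geometric mean across samples (a pseudoreference sample).
EBS
    Quantile scaling: sequencing depth estimated from the upper quartile of
    each sample's counts, centred on the log10 scale.
PS
    PoissonSeq depth estimate: the share of reads a sample holds within a set
    of putatively non-differential genes selected by a Poisson goodness-of-fit
    statistic.
RD
    Raw data passthrough (all divisors 1), the unnormalized benchmark.

Every method returns a :class:`ScalingFactorSet` holding both the method's
native factor d_j and a *divisor* s_j — the count-scale quantity by which
counts are divided to normalize.  Divisors are rescaled to geometric mean 1 so
that all methods live on one comparable scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .counts_io import CountMatrix

METHODS = ("TMM", "UQ", "DES", "EBS", "PS", "RD")


class NormalizationError(ValueError):
    """Raised when a scaling factor cannot be computed for a matrix."""


def _geometric_mean(x: np.ndarray) -> float:
    return float(np.exp(np.mean(np.log(x))))


def upper_quartile(x: np.ndarray) -> float:
    """75th percentile with linear interpolation on the sorted values.

    Quartile dialects differ between implementations; this package fixes the
    NumPy ``linear`` rule everywhere a 75th percentile appears.
    """
    return float(np.percentile(x, 75, method="linear"))


@dataclass
class ScalingFactorSet:
    """Per-sample factors of one method plus the count-scale divisor convention."""

    method: str
    sample_ids: list[str]
    factors: np.ndarray
    divisors: np.ndarray
    reference_sample: str | None = None

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise NormalizationError(f"unknown method {self.method!r}")
        self.factors = np.asarray(self.factors, dtype=float)
        self.divisors = np.asarray(self.divisors, dtype=float)
        for name, arr in (("factors", self.factors), ("divisors", self.divisors)):
            if arr.shape != (len(self.sample_ids),):
                raise NormalizationError(f"{name} misaligned with sample_ids")
            if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
                raise NormalizationError(f"{name} must be finite and > 0")
        gm = _geometric_mean(self.divisors)
        if abs(gm - 1.0) > 1e-9:
            raise NormalizationError(
                f"divisors must have geometric mean 1 (got {gm!r})"
            )

    def aligned_divisors(self, cm: CountMatrix) -> np.ndarray:
        if list(self.sample_ids) != list(cm.sample_ids):
            raise NormalizationError("scaling factors not aligned with count matrix samples")
        return self.divisors


def _rescaled(divisors: np.ndarray) -> np.ndarray:
    d = np.asarray(divisors, dtype=float)
    if np.any(~np.isfinite(d)) or np.any(d <= 0):
        raise NormalizationError("cannot rescale non-positive divisors")
    return d / _geometric_mean(d)


@dataclass
class TmmInternals:
    """Per-sample working quantities of the TMM computation."""

    M: dict[str, np.ndarray] = field(default_factory=dict)
    w: dict[str, np.ndarray] = field(default_factory=dict)
    A: dict[str, np.ndarray] = field(default_factory=dict)
    kept_genes: dict[str, list[str]] = field(default_factory=dict)


@dataclass
class PoissonSeqInternals:
    """Goodness-of-fit statistics and the gene set behind the PS factor."""

    gof: np.ndarray
    selected_genes: list[str]
    tc_factors: np.ndarray


def _pick_tmm_reference(cm: CountMatrix) -> int:
    """Sample whose upper quartile of library-size-scaled counts is closest to
    the mean of those upper quartiles (ties broken by sample order)."""
    N = cm.library_sizes.astype(float)
    if np.any(N == 0):
        j = int(np.flatnonzero(N == 0)[0])
        raise NormalizationError(f"sample {cm.sample_ids[j]!r} has zero library size")
    uq = np.array([upper_quartile(cm.counts[:, j] / N[j]) for j in range(cm.n_samples)])
    return int(np.argmin(np.abs(uq - uq.mean())))


def _trim_mask(values: np.ndarray, trim: float) -> np.ndarray:
    """Two-sided trim: drop the ``trim`` fraction from EACH tail by average
    rank (ties share a rank, so tied boundary values drop together)."""
    n = values.size
    lo = np.floor(n * trim) + 1
    hi = n + 1 - lo
    ranks = rankdata(values, method="average")
    return (ranks >= lo) & (ranks <= hi)


def tmm_factors(
    cm: CountMatrix,
    trim_M: float = 0.30,
    trim_A: float = 0.05,
    reference: str | None = None,
    return_internals: bool = False,
):
    """Trimmed mean of M-values factor for every sample against a reference.

    For sample j and reference r, with library sizes N_j, N_r and counts
    K_gj, K_gr restricted to genes positive in both samples::

        M_gj = log2((K_gj/N_j) / (K_gr/N_r))
        v_gj = (N_j - K_gj)/(N_j K_gj) + (N_r - K_gr)/(N_r K_gr)
        log2 d_j = sum_{g in G'} M_gj / v_gj  /  sum_{g in G'} 1 / v_gj

    v_gj is the delta-method variance of M_gj, so each log-ratio is weighted
    by its inverse variance (precise genes count more), and G' keeps genes
    surviving a two-sided trim of ``trim_M`` per tail on
    M and ``trim_A`` per tail on the average abundance
    A_g = (log2(K_gj/N_j) + log2(K_gr/N_r)) / 2.  Under the assumption that
    most genes are not differentially expressed, d_j stays close to 1.

    The divisor is the effective library size N_j * d_j, rescaled to
    geometric mean 1.
    """
    if not (0 <= trim_M < 0.5 and 0 <= trim_A < 0.5):
        raise NormalizationError("trim fractions must lie in [0, 0.5)")
    N = cm.library_sizes.astype(float)
    if reference is None:
        r = _pick_tmm_reference(cm)
    else:
        if reference not in cm.sample_ids:
            raise NormalizationError(f"unknown reference sample {reference!r}")
        r = cm.sample_ids.index(reference)
        if N[r] == 0:
            raise NormalizationError(f"reference sample {reference!r} has zero library size")
    internals = TmmInternals()
    log2d = np.zeros(cm.n_samples)
    Kr = cm.counts[:, r].astype(float)
    for j in range(cm.n_samples):
        Kj = cm.counts[:, j].astype(float)
        pos = (Kj > 0) & (Kr > 0)
        if not pos.any():
            raise NormalizationError(
                f"no gene is positive in both sample {cm.sample_ids[j]!r} "
                f"and reference {cm.sample_ids[r]!r}"
            )
        kj, kr = Kj[pos], Kr[pos]
        M = np.log2((kj / N[j]) / (kr / N[r]))
        A = 0.5 * (np.log2(kj / N[j]) + np.log2(kr / N[r]))
        v = (N[j] - kj) / (N[j] * kj) + (N[r] - kr) / (N[r] * kr)
        w = 1.0 / v
        keep = _trim_mask(M, trim_M) & _trim_mask(A, trim_A)
        if not keep.any():
            raise NormalizationError(
                f"trimming removed every gene for sample {cm.sample_ids[j]!r}"
            )
        wsum = w[keep].sum()
        log2d[j] = 0.0 if wsum == 0 else float((w[keep] * M[keep]).sum() / wsum)
        if return_internals:
            gene_pos = [g for g, p in zip(cm.gene_ids, pos) if p]
            internals.M[cm.sample_ids[j]] = M
            internals.w[cm.sample_ids[j]] = w
            internals.A[cm.sample_ids[j]] = A
            internals.kept_genes[cm.sample_ids[j]] = [
                g for g, k in zip(gene_pos, keep) if k
            ]
    factors = 2.0 ** log2d
    sfs = ScalingFactorSet(
        method="TMM",
        sample_ids=list(cm.sample_ids),
        factors=factors,
        divisors=_rescaled(N * factors),
        reference_sample=cm.sample_ids[r],
    )
    return (sfs, internals) if return_internals else sfs


def uq_factors(cm: CountMatrix) -> ScalingFactorSet:
    """Upper-quartile factor: d_j = UQ(K_.j) / sum_g K_gj after removing genes
    that are zero in all libraries.  The divisor is the per-sample upper
    quartile itself (equivalently N_j * d_j), rescaled to geometric mean 1."""
    keep = cm.counts.sum(axis=1) > 0
    if not keep.any():
        raise NormalizationError("all genes are zero in every library")
    counts = cm.counts[keep, :].astype(float)
    N = counts.sum(axis=0)
    uq = np.array([upper_quartile(counts[:, j]) for j in range(cm.n_samples)])
    if np.any(uq == 0):
        j = int(np.flatnonzero(uq == 0)[0])
        raise NormalizationError(
            f"upper quartile of sample {cm.sample_ids[j]!r} is 0 after filtering"
        )
    factors = uq / N
    return ScalingFactorSet(
        method="UQ",
        sample_ids=list(cm.sample_ids),
        factors=factors,
        divisors=_rescaled(uq),
    )


def median_ratio_factors(cm: CountMatrix) -> ScalingFactorSet:
    """Median-of-ratios factor: d_j = median_g K_gj / (prod_v K_gv)^(1/m).

    Genes with a zero count in any sample have geometric mean 0 and are
    excluded from the median.  The native factor is already count-scale, so
    the divisor is d_j rescaled to geometric mean 1.
    """
    usable = (cm.counts > 0).all(axis=1)
    if not usable.any():
        raise NormalizationError(
            "no gene has strictly positive counts in every sample"
        )
    counts = cm.counts[usable, :].astype(float)
    geo = np.exp(np.mean(np.log(counts), axis=1))
    factors = np.median(counts / geo[:, None], axis=0)
    return ScalingFactorSet(
        method="DES",
        sample_ids=list(cm.sample_ids),
        factors=factors,
        divisors=_rescaled(factors),
    )


def quantile_factors(cm: CountMatrix) -> ScalingFactorSet:
    """Quantile (upper-quartile depth) factor:
    d_j = 10^(log10 Q_j - (1/m) sum_v log10 Q_v) with Q_j the upper quartile
    of sample j's counts.  The exponents sum to 0, so the d_j have geometric
    mean 1 by construction and serve directly as divisors."""
    Q = np.array([upper_quartile(cm.counts[:, j]) for j in range(cm.n_samples)])
    if np.any(Q <= 0):
        j = int(np.flatnonzero(Q <= 0)[0])
        raise NormalizationError(
            f"upper quartile of sample {cm.sample_ids[j]!r} is 0"
        )
    log10q = np.log10(Q)
    factors = 10.0 ** (log10q - log10q.mean())
    return ScalingFactorSet(
        method="EBS",
        sample_ids=list(cm.sample_ids),
        factors=factors,
        divisors=_rescaled(factors),
    )


def poissonseq_factors(
    cm: CountMatrix,
    gof_window: tuple[float, float] = (0.25, 0.75),
    literal_window: bool = False,
    return_internals: bool = False,
):
    """PoissonSeq depth factor in a single pass.

    First the Total Count factor d_j^TC = N_j / sum_v N_v; then a per-gene
    Poisson goodness-of-fit statistic against the TC depths::

        GOF_g = sum_j (K_gj - d_j^TC S_g)^2 / (d_j^TC S_g),   S_g = sum_j K_gj

    The putatively non-differential set G'' keeps the genes whose GOF lies
    between the ``gof_window`` *quantiles* of the empirical GOF distribution
    (default the interquartile window; GOF is an unbounded chi-square-like
    statistic, so a literal value window (0.25, 0.75) would usually be nearly
    empty — it remains available via ``literal_window=True``).  Then::

        d_j^PS = sum_{g in G''} K_gj / sum_{g in G''} S_g

    The d_j^PS sum to 1 across samples; the count-scale divisor is m * d_j^PS
    rescaled to geometric mean 1.
    """
    lo, hi = gof_window
    if not (0 <= lo < hi):
        raise NormalizationError("gof_window must be an increasing pair")
    counts = cm.counts.astype(float)
    N = counts.sum(axis=0)
    total = N.sum()
    if total == 0:
        raise NormalizationError("empty count matrix")
    tc = N / total
    S = counts.sum(axis=1)
    nonzero = S > 0
    expected = S[:, None] * tc[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        gof = np.where(
            nonzero,
            np.sum(
                np.where(expected > 0, (counts - expected) ** 2 / np.where(expected > 0, expected, 1.0), 0.0),
                axis=1,
            ),
            np.nan,
        )
    if literal_window:
        selected = nonzero & (gof > lo) & (gof < hi)
    else:
        qlo, qhi = np.nanquantile(gof, [lo, hi])
        selected = nonzero & (gof >= qlo) & (gof <= qhi)
    if not selected.any():
        raise NormalizationError(
            "goodness-of-fit selection kept no gene; widen gof_window"
        )
    sub = counts[selected, :]
    factors = sub.sum(axis=0) / sub.sum()
    sfs = ScalingFactorSet(
        method="PS",
        sample_ids=list(cm.sample_ids),
        factors=factors,
        divisors=_rescaled(cm.n_samples * factors),
    )
    if return_internals:
        internals = PoissonSeqInternals(
            gof=gof,
            selected_genes=[g for g, s in zip(cm.gene_ids, selected) if s],
            tc_factors=tc,
        )
        return sfs, internals
    return sfs


def raw_factors(cm: CountMatrix) -> ScalingFactorSet:
    """Raw-data passthrough: every factor and divisor is 1."""
    ones = np.ones(cm.n_samples)
    return ScalingFactorSet(
        method="RD", sample_ids=list(cm.sample_ids), factors=ones, divisors=ones.copy()
    )


_FACTORY = {
    "TMM": tmm_factors,
    "UQ": uq_factors,
    "DES": median_ratio_factors,
    "EBS": quantile_factors,
    "PS": poissonseq_factors,
    "RD": raw_factors,
}


def compute_factors(cm: CountMatrix, method: str, **kwargs) -> ScalingFactorSet:
    """Dispatch to one method by label (TMM, UQ, DES, EBS, PS, RD)."""
    method = method.upper()
    if method not in _FACTORY:
        raise NormalizationError(f"unknown method {method!r}; expected one of {METHODS}")
    return _FACTORY[method](cm, **kwargs)


def compute_all_factors(
    cm: CountMatrix, methods: tuple[str, ...] = METHODS
) -> dict[str, ScalingFactorSet]:
    return {m: compute_factors(cm, m) for m in methods}


def normalize_counts(cm: CountMatrix, sf: ScalingFactorSet) -> np.ndarray:
    """Divide each sample's counts by its divisor: K'_gj = K_gj / s_j."""
    s = sf.aligned_divisors(cm)
    return cm.counts / s[None, :]
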