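"""Negative-binomial count simulator with known ground truth.

Counts are drawn from the generative model the whole package assumes,
K_gj ~ NB(s_j * lambda_gj, phi): per-gene baseline expression levels are
log-normal, per-sample size factors are log-normal with geometric mean 1
(library-size differences being the basic between-sample variation the
normalizations must remove), a chosen fraction of genes is differentially
expressed between the two groups with a symmetric log2 effect, and a small
set of housekeeping-like genes has a constant expression level across all
samples with a tenth of the common dispersion.

The emitted :class:`SyntheticTruth` records everything a criterion can be
scored against: the true size factors, the true DE genes with signed effects,
and the true housekeeping genes.  Three presets emulate the scale of typical
two-group human RNA-seq designs (16-41 samples, ~12,000-13,000 genes after
filtering) with a low-, high- or middle-skewed abundance distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .counts_io import CountMatrix, GeneList


class SyntheticSpecError(ValueError):
    pass


@dataclass
class SyntheticSpec:
    """Parameters of one simulated two-group experiment.

    ``baseline_log_mean``/``baseline_log_sigma`` are the natural-log
    parameters of the log-normal gene baseline means, truncated below at
    ``baseline_min_mean`` — generated matrices emulate *filtered* count
    matrices, whose minimum mean abundance the filter sets (the default 50
    matches a clinical-style filtered design; abundance-skewed presets lower
    it).  ``size_factor_sigma`` is the log-normal spread of the true
    per-sample size factors (0.4 gives roughly a 2-3x range across samples)
    unless explicit ``size_factors`` are supplied.  Housekeeping gene levels
    are drawn uniformly from ``hk_level_range``, just below the ordinary
    abundance floor: an absolute-MSE stability criterion on raw counts is
    dominated by the abundance-squared library-size term, so analytically
    stable genes live at the low-abundance end — as they do in real filtered
    data, where most such genes have well under 500 reads.
    """

    n_genes: int
    n_group1: int
    n_group2: int
    seed: int
    baseline_log_mean: float = np.log(150.0)
    baseline_log_sigma: float = 1.3
    baseline_min_mean: float = 50.0
    size_factor_sigma: float = 0.4
    size_factors: np.ndarray | None = None
    dispersion: float = 0.1
    de_fraction: float = 0.1
    log2fc_magnitude: float = 2.0
    de_up_fraction: float = 0.5
    n_housekeeping: int = 0
    hk_level_range: tuple[float, float] = (15.0, 30.0)
    hk_dispersion_scale: float = 0.1
    group_names: tuple[str, str] = ("A", "B")

    def __post_init__(self) -> None:
        if self.seed is None:
            raise SyntheticSpecError("a seed is mandatory")
        if self.n_genes < 1 or self.n_group1 < 1 or self.n_group2 < 1:
            raise SyntheticSpecError("need at least one gene and one sample per group")
        if not 0 <= self.de_fraction < 1:
            raise SyntheticSpecError("de_fraction must lie in [0, 1)")
        if self.dispersion < 0:
            raise SyntheticSpecError("dispersion must be nonnegative")
        n_de = int(round(self.de_fraction * self.n_genes))
        if self.n_housekeeping + n_de > self.n_genes:
            raise SyntheticSpecError("housekeeping + DE genes exceed n_genes")

    @property
    def n_samples(self) -> int:
        return self.n_group1 + self.n_group2


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated experiment."""

    true_size_factors: np.ndarray
    true_de_genes: GeneList
    de_log2fc: dict[str, float]
    true_housekeeping: GeneList
    spec: SyntheticSpec
    baseline_means: np.ndarray = field(default=None)  # type: ignore[assignment]


def _draw_nb(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    """NB(mean, phi) via the gamma-Poisson mixture; phi = 0 is Poisson."""
    if phi <= 0:
        return rng.poisson(mean)
    shape = 1.0 / phi
    return rng.poisson(rng.gamma(shape, mean / shape))


def generate_counts(spec: SyntheticSpec) -> tuple[CountMatrix, SyntheticTruth]:
    """Draw one experiment; identical output for identical spec (incl. seed)."""
    rng = np.random.default_rng(spec.seed)
    G, m = spec.n_genes, spec.n_samples

    if spec.size_factors is not None:
        s = np.asarray(spec.size_factors, dtype=float)
        if s.shape != (m,) or np.any(s <= 0):
            raise SyntheticSpecError("size_factors must be positive, one per sample")
    else:
        s = rng.lognormal(0.0, spec.size_factor_sigma, size=m)
    s = s / np.exp(np.mean(np.log(s)))  # geometric mean 1: truth on divisor scale

    lam = rng.lognormal(spec.baseline_log_mean, spec.baseline_log_sigma, size=G)
    if spec.baseline_min_mean > 0:
        # rejection-sample the truncated log-normal (emulates the mean-count filter)
        low = lam < spec.baseline_min_mean
        while low.any():
            lam[low] = rng.lognormal(
                spec.baseline_log_mean, spec.baseline_log_sigma, size=int(low.sum())
            )
            low = lam < spec.baseline_min_mean

    gene_ids = [f"gene_{i:05d}" for i in range(G)]
    g1, g2 = spec.group_names
    sample_ids = [f"{g1}_{j + 1:02d}" for j in range(spec.n_group1)] + [
        f"{g2}_{j + 1:02d}" for j in range(spec.n_group2)
    ]
    labels = [g1] * spec.n_group1 + [g2] * spec.n_group2
    in_group2 = np.array([lab == g2 for lab in labels])

    roles = rng.permutation(G)
    hk_idx = np.sort(roles[: spec.n_housekeeping])
    n_de = int(round(spec.de_fraction * G))
    de_idx = np.sort(roles[spec.n_housekeeping : spec.n_housekeeping + n_de])

    # housekeeping genes: constant low-to-medium level across samples and a
    # tenth of the common dispersion
    lam[hk_idx] = rng.uniform(*spec.hk_level_range, size=hk_idx.size)

    signs = np.where(rng.random(n_de) < spec.de_up_fraction, 1.0, -1.0)
    lfc = signs * spec.log2fc_magnitude

    lam_matrix = np.tile(lam[:, None], (1, m))
    lam_matrix[np.ix_(de_idx, np.flatnonzero(in_group2))] *= (
        2.0 ** lfc[:, None]
    )
    mean = lam_matrix * s[None, :]
    if spec.de_fraction > 0 and np.any(mean[de_idx, :] == 0):
        raise SyntheticSpecError("a DE gene has expected count 0; raise baseline means")

    counts = np.empty((G, m), dtype=np.int64)
    ordinary = np.ones(G, dtype=bool)
    ordinary[hk_idx] = False
    counts[ordinary, :] = _draw_nb(rng, mean[ordinary, :], spec.dispersion)
    if hk_idx.size:
        counts[hk_idx, :] = _draw_nb(
            rng, mean[hk_idx, :], spec.dispersion * spec.hk_dispersion_scale
        )

    cm = CountMatrix(
        counts=counts, gene_ids=gene_ids, sample_ids=sample_ids, group_labels=labels
    )
    truth = SyntheticTruth(
        true_size_factors=s,
        true_de_genes=GeneList(tuple(gene_ids[i] for i in de_idx), role="generic"),
        de_log2fc={gene_ids[i]: float(f) for i, f in zip(de_idx, lfc)},
        true_housekeeping=GeneList(
            tuple(gene_ids[i] for i in hk_idx), role="housekeeping"
        ),
        spec=spec,
        baseline_means=lam,
    )
    return cm, truth


def control_panel_lists(
    truth: SyntheticTruth, n_positive: int = 44, n_negative: int = 44, seed: int = 0
) -> tuple[GeneList, GeneList]:
    """Draw positive controls from the true DE genes and negative controls
    from the true non-DE, non-housekeeping genes."""
    rng = np.random.default_rng(seed)
    de = list(truth.true_de_genes.ids)
    hk = set(truth.true_housekeeping.ids)
    all_ids = [f"gene_{i:05d}" for i in range(truth.spec.n_genes)]
    non_de = [g for g in all_ids if g not in set(de) and g not in hk]
    if n_positive > len(de) or n_negative > len(non_de):
        raise SyntheticSpecError("not enough genes for the requested control panel")
    pos = sorted(rng.choice(len(de), size=n_positive, replace=False))
    neg = sorted(rng.choice(len(non_de), size=n_negative, replace=False))
    return (
        GeneList(tuple(de[i] for i in pos), role="positive_control"),
        GeneList(tuple(non_de[i] for i in neg), role="negative_control"),
    )


# Presets emulate the scale of the three study designs the package is aimed
# at: a 41-sample design dominated by weakly expressed genes, a 16-sample
# design dominated by highly expressed genes, and a 27-sample clinical-style
# design centred on medium expression with an excess of upregulated DE genes.
_PRESETS: dict[str, dict] = {
    "cheung_like": dict(
        n_genes=12410,
        n_group1=21,
        n_group2=20,
        baseline_log_mean=np.log(20.0),
        baseline_log_sigma=1.8,
        baseline_min_mean=0.02,
        n_housekeeping=150,
    ),
    "bodymap_like": dict(
        n_genes=13131,
        n_group1=8,
        n_group2=8,
        baseline_log_mean=np.log(500.0),
        baseline_log_sigma=1.2,
        baseline_min_mean=1.0,
        n_housekeeping=160,
    ),
    "aml_like": dict(
        n_genes=12749,
        n_group1=14,
        n_group2=13,
        baseline_log_mean=np.log(150.0),
        baseline_log_sigma=1.3,
        n_housekeeping=155,
        de_up_fraction=0.7,
    ),
}

PRESET_NAMES = tuple(_PRESETS)


def preset(name: str, seed: int) -> SyntheticSpec:
    """A ready-made :class:`SyntheticSpec` (``cheung_like``, ``bodymap_like``
    or ``aml_like``)."""
    if name not in _PRESETS:
        raise SyntheticSpecError(
            f"unknown preset {name!r}; expected one of {PRESET_NAMES}"
        )
    return SyntheticSpec(seed=seed, **_PRESETS[name])
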