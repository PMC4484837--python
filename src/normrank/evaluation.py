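"""Criteria that score one normalization against another, and rank aggregation.

Five criteria are available, mirroring the comparison workflow the package
implements end to end:

* sensitivity / specificity against user-supplied positive/negative control
  gene panels (fraction of positives recovered in / negatives absent from the
  DEG list);
* leave-one-out cross-validated classification error of the two groups, from
  five standard classifiers fed the most informative genes;
* the pairwise common-DEG percentage (how much of a method's DEG list other
  methods reproduce);
* hierarchical clustering of methods by the ranks they assign to the shared
  DEGs (a view, not a ranked criterion);
* and, upstream, the bias/variance criterion of :mod:`normrank.bias_variance`.

Each ranked criterion contributes a tie-averaged rank; the final rank of a
method is the unweighted mean across criteria, and the recommended method
minimizes it.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.stats
from sklearn.base import clone as sklearn_clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .bias_variance import rank_methods_by
from .counts_io import CountsValidationError, GeneList
from .de_test import DEResult


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class ControlPanel:
    """Positive (expected DE) and negative (expected non-DE) control genes."""

    positives: GeneList
    negatives: GeneList

    def __post_init__(self) -> None:
        if not self.positives.ids or not self.negatives.ids:
            raise EvaluationError("both control lists must be non-empty")
        overlap = set(self.positives.ids) & set(self.negatives.ids)
        if overlap:
            raise EvaluationError(
                f"positive and negative controls overlap: {sorted(overlap)[:5]}"
            )


def sensitivity_specificity(
    degs: GeneList, panel: ControlPanel
) -> tuple[float, float]:
    """(sensitivity %, specificity %): the percentage of positive controls
    present in, and of negative controls absent from, the DEG list."""
    deg_set = set(degs.ids)
    sens = 100.0 * sum(g in deg_set for g in panel.positives.ids) / len(panel.positives)
    spec = 100.0 * sum(g not in deg_set for g in panel.negatives.ids) / len(panel.negatives)
    return sens, spec


def select_informative_genes(
    de: DEResult, n_samples: int, fraction: float = 0.75
) -> GeneList:
    """The floor(fraction * n_samples) genes with the smallest adjusted
    p-values — the discriminative features handed to the classifiers.  Ties
    are broken by input gene order; if fewer genes are available than
    requested, all are returned with a warning."""
    if not 0 < fraction <= 1:
        raise EvaluationError("fraction must lie in (0, 1]")
    n = math.floor(fraction * n_samples)
    if n == 0:
        raise EvaluationError(f"{fraction} of {n_samples} samples selects no gene")
    adj = de.adj_p_value
    if adj is None:
        raise EvaluationError("adjust p-values before selecting informative genes")
    if n > len(de.gene_ids):
        warnings.warn(
            f"requested {n} informative genes but only {len(de.gene_ids)} available"
        )
        n = len(de.gene_ids)
    order = np.argsort(adj, kind="stable")[:n]
    return GeneList(tuple(de.gene_ids[i] for i in order), role="generic")


def default_classifiers(seed: int, n_train: int | None = None) -> dict[str, object]:
    """The five benchmark classifiers: Gaussian naive Bayes, a single-hidden-
    layer (8-unit) perceptron, 5-nearest-neighbours, an RBF support-vector
    machine, and a 500-tree random forest.  The perceptron standardizes its
    inputs (gradient training does not converge reliably on raw count
    scales); k is clamped to the training-fold size on very small designs."""
    k = 5 if n_train is None else max(1, min(5, n_train))
    return {
        "naive_bayes": GaussianNB(),
        "neural_network": make_pipeline(
            StandardScaler(),
            MLPClassifier(hidden_layer_sizes=(8,), max_iter=2000, random_state=seed),
        ),
        "knn": KNeighborsClassifier(n_neighbors=k),
        "svm": SVC(kernel="rbf"),
        "random_forest": RandomForestClassifier(n_estimators=500, random_state=seed),
    }


@dataclass
class LoocvResult:
    """Leave-one-out classification errors of one normalization method."""

    method: str
    errors_pct: dict[str, float]
    n_samples: int
    n_failed_folds: int = 0

    @property
    def mean_error(self) -> float:
        return float(np.mean(list(self.errors_pct.values())))

    @property
    def median_error(self) -> float:
        return float(np.median(list(self.errors_pct.values())))

    @property
    def ci95(self) -> tuple[float, float]:
        """t-interval for the mean over the classifier error percentages."""
        vals = np.array(list(self.errors_pct.values()))
        n = vals.size
        half = scipy.stats.t.ppf(0.975, n - 1) * vals.std(ddof=1) / math.sqrt(n)
        return (self.mean_error - half, self.mean_error + half)


def loocv_prediction_errors(
    features: np.ndarray,
    labels: np.ndarray,
    seed: int,
    classifiers: dict[str, object] | None = None,
    method: str = "",
) -> LoocvResult:
    """Leave-one-out cross-validation: n runs for n samples, each training on
    n-1 samples and predicting the held-out one.  The error of a classifier is
    the percentage of held-out samples misclassified over the n runs.  A fold
    whose training set lacks one of the classes counts as an error and is
    logged."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    n = X.shape[0]
    if n < 3:
        raise EvaluationError("LOOCV needs at least three samples")
    if len(np.unique(y)) != 2:
        raise EvaluationError("both groups must be represented")
    if classifiers is None:
        classifiers = default_classifiers(seed, n_train=n - 1)
    errors = {name: 0 for name in classifiers}
    failed = 0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        if len(np.unique(y[mask])) < 2:
            failed += 1
            for name in errors:
                errors[name] += 1
            continue
        for name, proto in classifiers.items():
            clf = sklearn_clone(proto)
            clf.fit(X[mask], y[mask])
            if clf.predict(X[~mask])[0] != y[i]:
                errors[name] += 1
    if failed:
        warnings.warn(f"{failed} LOOCV fold(s) had a single-class training set")
    return LoocvResult(
        method=method,
        errors_pct={name: 100.0 * e / n for name, e in errors.items()},
        n_samples=n,
        n_failed_folds=failed,
    )


@dataclass
class CommonDegMatrix:
    """Pairwise common-DEG percentages between methods.

    P[i, j] = 100 * D_ij / D_i (the share of method i's DEGs that method j
    also finds); P_avg symmetrizes each pair by averaging P_ij and P_ji.  A
    method's score is the mean of its symmetrized percentages with every
    partner — the method whose DEGs other methods reproduce best scores
    highest.
    """

    methods: list[str]
    deg_sizes: pd.Series
    pair_counts: pd.DataFrame
    pct: pd.DataFrame
    pct_avg: pd.DataFrame

    def method_scores(self) -> pd.Series:
        off = self.pct_avg.where(~np.eye(len(self.methods), dtype=bool))
        return off.mean(axis=1).rename("mean_common_deg_pct")


def common_deg_matrix(deg_lists: dict[str, GeneList]) -> CommonDegMatrix:
    """Pairwise common-DEG counts and percentages; methods with an empty DEG
    list are excluded with a warning (their percentage is undefined)."""
    kept = {m: set(gl.ids) for m, gl in deg_lists.items() if len(gl) > 0}
    dropped = [m for m in deg_lists if m not in kept]
    if dropped:
        warnings.warn(f"methods with empty DEG lists excluded: {dropped}")
    if len(kept) < 2:
        raise EvaluationError("need at least two methods with non-empty DEG lists")
    methods = list(kept)
    sizes = pd.Series({m: len(kept[m]) for m in methods}, name="n_deg")
    counts = pd.DataFrame(
        [[len(kept[i] & kept[j]) for j in methods] for i in methods],
        index=methods,
        columns=methods,
    )
    pct = 100.0 * counts.div(sizes, axis=0)
    pct_avg = (pct + pct.T) / 2.0
    return CommonDegMatrix(methods, sizes, counts, pct, pct_avg)


def intersect_all(deg_lists: dict[str, GeneList] | list[GeneList]) -> GeneList:
    """Genes present in every list, in the order of the first list."""
    lists = list(deg_lists.values()) if isinstance(deg_lists, dict) else list(deg_lists)
    if len(lists) < 2:
        raise EvaluationError("need at least two lists to intersect")
    common = set(lists[0].ids)
    for gl in lists[1:]:
        common &= set(gl.ids)
    return GeneList(tuple(g for g in lists[0].ids if g in common), role="generic")


@dataclass
class DendrogramResult:
    """Ward clustering of methods by the ranks they give the shared DEGs."""

    methods: list[str]
    common_genes: list[str]
    rank_vectors: pd.DataFrame
    distance_matrix: pd.DataFrame
    linkage: np.ndarray


def method_rank_dendrogram(de_results: dict[str, DEResult]) -> DendrogramResult:
    """Cluster methods by how similarly they order the DEGs common to all.

    The genes shared by every method's DEG list are ranked within each method
    by adjusted p-value (ascending, ties by gene order); methods are then
    clustered by Ward's method on the Euclidean distances between their rank
    vectors.
    """
    deg_lists = {}
    for m, de in de_results.items():
        if de.is_deg is None:
            raise EvaluationError(f"method {m!r}: call DEGs before clustering")
        order = np.argsort(de.adj_p_value, kind="stable")
        deg_lists[m] = [de.gene_ids[i] for i in order if de.is_deg[i]]
    methods = list(deg_lists)
    if len(methods) < 2:
        raise EvaluationError("need at least two methods")
    common = set(deg_lists[methods[0]])
    for m in methods[1:]:
        common &= set(deg_lists[m])
    if len(common) < 2:
        raise EvaluationError(
            "fewer than two DEGs common to all methods; consider a looser alpha"
        )
    genes = [g for g in deg_lists[methods[0]] if g in common]
    vectors = {}
    for m in methods:
        pos = {g: r + 1 for r, g in enumerate(g for g in deg_lists[m] if g in common)}
        vectors[m] = [pos[g] for g in genes]
    rank_df = pd.DataFrame(vectors, index=genes).T
    X = rank_df.to_numpy(dtype=float)
    dist = pd.DataFrame(
        np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2)),
        index=methods,
        columns=methods,
    )
    Z = sch.linkage(X, method="ward")
    return DendrogramResult(methods, genes, rank_df, dist, Z)


CRITERION_DIRECTIONS = {
    "bias": "lower_better",
    "variance": "lower_better",
    "sensitivity": "higher_better",
    "specificity": "higher_better",
    "prediction_error": "lower_better",
    "common_degs": "higher_better",
}


@dataclass
class EvaluationReport:
    """Per-method criterion values, per-criterion tie-averaged ranks, and the
    final mean rank (lower is better)."""

    values: pd.DataFrame
    ranks: pd.DataFrame
    final_rank: pd.Series

    @property
    def recommended(self) -> str:
        return str(self.final_rank.idxmin())

    def to_frame(self) -> pd.DataFrame:
        out = self.values.copy()
        out.columns = [f"{c}_value" for c in out.columns]
        for c in self.ranks.columns:
            out[f"{c}_rank"] = self.ranks[c]
        out["final_rank"] = self.final_rank
        return out.sort_values("final_rank")


def summarize_ranks(
    criteria: dict[str, dict[str, float] | pd.Series],
    directions: dict[str, str] | None = None,
) -> EvaluationReport:
    """Aggregate criterion values into the final mean rank.

    ``criteria`` maps a criterion name to one value per method; directions
    default to :data:`CRITERION_DIRECTIONS` (unknown names must be given
    explicitly).  A criterion missing any method is dropped with a warning so
    every method is ranked on the same evidence.
    """
    directions = {**CRITERION_DIRECTIONS, **(directions or {})}
    series = {name: pd.Series(vals, dtype=float) for name, vals in criteria.items()}
    if not series:
        raise EvaluationError("no criteria supplied")
    methods = sorted(set().union(*(s.index for s in series.values())))
    usable = {}
    for name, s in series.items():
        if name not in directions:
            raise EvaluationError(f"no ranking direction for criterion {name!r}")
        if set(s.index) != set(methods) or s.isna().any():
            warnings.warn(f"criterion {name!r} missing a method; dropped")
            continue
        usable[name] = s.reindex(methods)
    if not usable:
        raise EvaluationError("no criterion covers every method")
    values = pd.DataFrame(usable, index=methods)
    ranks = pd.DataFrame(
        {name: rank_methods_by(s, directions[name]) for name, s in usable.items()}
    )
    final = ranks.mean(axis=1).rename("final_rank")
    return EvaluationReport(values=values, ranks=ranks, final_rank=final)
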