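"""Diagnostic plots and the end-to-end comparison workflow.

The workflow runs, in order: mean-count filtering, all requested scaling
factors, housekeeping selection, bias/variance, the exact DE test per method,
sensitivity/specificity against control panels (when given), LOOCV
classification errors, common-DEG statistics, the method dendrogram, and the
final rank summary.  Every figure is a *view* of an already-computed result —
plots never recompute statistics, so removing a plot cannot change the
report.  Given the same inputs, configuration and seed the tabular outputs
are byte-identical across runs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch

from . import bias_variance as bv
from . import counts_io, de_test, evaluation, housekeeping, normalization, synthetic_data
from .counts_io import CountMatrix, GeneList
from .de_test import DEResult
from .evaluation import (
    CommonDegMatrix,
    ControlPanel,
    DendrogramResult,
    EvaluationReport,
    LoocvResult,
)
from .normalization import METHODS, ScalingFactorSet

log = logging.getLogger("normrank")


class ReportingError(ValueError):
    pass


class WorkflowStageError(RuntimeError):
    """A workflow stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"workflow stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


# -- plots -----------------------------------------------------------------


def _mean_count_bins(cm: CountMatrix, bins=None) -> np.ndarray:
    """Abundance bin edges; defaults to the quartiles of the per-gene mean
    raw count of the filtered matrix."""
    if bins is None:
        means = cm.counts.mean(axis=1)
        bins = np.quantile(means, [0.25, 0.5, 0.75])
    bins = np.asarray(bins, dtype=float)
    if bins.size and np.any(np.diff(bins) <= 0):
        raise ReportingError("abundance bins must be strictly increasing")
    return bins


def assign_abundance_bins(cm: CountMatrix, bins=None) -> tuple[pd.Series, list[str]]:
    """Per-gene abundance bin index by mean raw count, with bin labels."""
    edges = _mean_count_bins(cm, bins)
    means = pd.Series(cm.counts.mean(axis=1), index=cm.gene_ids)
    idx = np.searchsorted(edges, means.to_numpy(), side="right")
    labels = (
        [f"<= {edges[0]:g}"]
        + [f"({edges[i]:g}, {edges[i + 1]:g}]" for i in range(len(edges) - 1)]
        + [f"> {edges[-1]:g}"]
        if edges.size
        else ["all"]
    )
    return pd.Series(idx, index=means.index), labels


def plot_deg_abundance_bars(
    deg_lists: dict[str, GeneList], cm: CountMatrix, path: str | Path, bins=None
) -> Path:
    """Stacked bars: each method's DEG count split by mean-raw-count bin."""
    bin_idx, labels = assign_abundance_bins(cm, bins)
    fig, ax = plt.subplots(figsize=(7, 4.5))
    methods = list(deg_lists)
    bottoms = np.zeros(len(methods))
    cmap = plt.get_cmap("viridis")
    for b, lab in enumerate(labels):
        heights = [
            sum(1 for g in deg_lists[m].ids if bin_idx.get(g, -1) == b) for m in methods
        ]
        ax.bar(methods, heights, bottom=bottoms, label=lab, color=cmap(b / max(1, len(labels) - 1)))
        bottoms += np.array(heights, dtype=float)
    if all(len(gl) == 0 for gl in deg_lists.values()):
        ax.annotate("no DEGs in any list", (0.5, 0.5), xycoords="axes fraction", ha="center")
    ax.set_ylabel("number of DEGs")
    ax.set_xlabel("normalization method")
    ax.legend(title="mean raw count", fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return Path(path)


def plot_factors(factor_sets: dict[str, ScalingFactorSet], path: str | Path) -> Path:
    """One series of per-sample divisors per method; samples ordered by their
    minimum divisor across methods."""
    if not factor_sets:
        raise ReportingError("no factor sets to plot")
    first = next(iter(factor_sets.values()))
    div = pd.DataFrame(
        {m: sf.divisors for m, sf in factor_sets.items()}, index=first.sample_ids
    )
    order = div.min(axis=1).sort_values(kind="stable").index
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for m in div.columns:
        ax.plot(range(len(order)), div.loc[order, m], marker="o", ms=3, label=m)
    ax.set_xticks(range(len(order)))
    ax.set_xticklabels(order, rotation=90, fontsize=6)
    ax.set_ylabel("normalization divisor (geometric mean 1)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return Path(path)


def plot_error_ci_bars(loocv: dict[str, LoocvResult], path: str | Path) -> Path:
    """Mean LOOCV error per method with its 95% t-interval over classifiers."""
    fig, ax = plt.subplots(figsize=(6, 4))
    methods = list(loocv)
    means = [loocv[m].mean_error for m in methods]
    errs = [
        (loocv[m].mean_error - loocv[m].ci95[0], loocv[m].ci95[1] - loocv[m].mean_error)
        for m in methods
    ]
    ax.bar(methods, means, yerr=np.array(errs).T, capsize=4, color="#7fa6c9")
    ax.set_ylabel("mean classification error (%)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return Path(path)


def plot_balloon(cdm: CommonDegMatrix, path: str | Path) -> Path:
    """Balloon plot: circle size and shading = symmetrized common-DEG %."""
    fig, ax = plt.subplots(figsize=(5.5, 5))
    n = len(cdm.methods)
    for i, mi in enumerate(cdm.methods):
        for j, mj in enumerate(cdm.methods):
            if i == j:
                continue
            v = cdm.pct_avg.loc[mi, mj]
            ax.scatter(j, n - 1 - i, s=12 * v, c=[[1 - v / 100] * 3], edgecolors="k")
            ax.annotate(f"{v:.0f}", (j, n - 1 - i), ha="center", va="center", fontsize=7)
    ax.set_xticks(range(n)), ax.set_xticklabels(cdm.methods)
    ax.set_yticks(range(n)), ax.set_yticklabels(list(reversed(cdm.methods)))
    ax.set_title("average % of common DEGs")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return Path(path)


def _venn_region_counts(sets: dict[str, set]) -> dict[str, int]:
    """Exact counts of every exclusive membership region."""
    names = list(sets)
    out = {}
    for mask in range(1, 2 ** len(names)):
        inside = [names[i] for i in range(len(names)) if mask >> i & 1]
        outside = [n for n in names if n not in inside]
        region = set.intersection(*(sets[n] for n in inside))
        for n in outside:
            region -= sets[n]
        out["&".join(inside)] = len(region)
    return out


def plot_venn(deg_lists: dict[str, GeneList], path: str | Path) -> Path:
    """Venn diagram for 2-3 DEG lists (plain matplotlib circles); for 4-5
    lists an exclusive-region count table is rendered instead; more errors."""
    if len(deg_lists) > 5:
        raise ReportingError("Venn diagrams support at most 5 sets; use the table")
    sets = {m: set(gl.ids) for m, gl in deg_lists.items()}
    regions = _venn_region_counts(sets)
    fig, ax = plt.subplots(figsize=(6, 5))
    names = list(sets)
    if len(names) in (2, 3):
        centers = {2: [(-0.5, 0), (0.5, 0)], 3: [(-0.5, -0.3), (0.5, -0.3), (0, 0.55)]}[
            len(names)
        ]
        for (x, y), nme in zip(centers, names):
            ax.add_patch(plt.Circle((x, y), 1.0, alpha=0.3, label=nme))
            ax.annotate(nme, (x, y + 1.05), ha="center")
        anchors2 = {(0,): (-1.0, 0), (1,): (1.0, 0), (0, 1): (0, 0)}
        anchors3 = {
            (0,): (-1.0, -0.5),
            (1,): (1.0, -0.5),
            (2,): (0, 1.0),
            (0, 1): (0, -0.5),
            (0, 2): (-0.55, 0.3),
            (1, 2): (0.55, 0.3),
            (0, 1, 2): (0, 0),
        }
        anchors = anchors2 if len(names) == 2 else anchors3
        for combo, (x, y) in anchors.items():
            key = "&".join(names[i] for i in combo)
            ax.annotate(str(regions.get(key, 0)), (x, y), ha="center", fontsize=9)
        ax.set_xlim(-2.2, 2.2), ax.set_ylim(-2, 2.2)
        ax.set_aspect("equal")
        ax.axis("off")
    else:
        ax.axis("off")
        rows = sorted(regions.items(), key=lambda kv: (-kv[1], kv[0]))
        text = "\n".join(f"{k}: {v}" for k, v in rows if v > 0) or "(all regions empty)"
        ax.annotate(text, (0.02, 0.98), xycoords="axes fraction", va="top", fontsize=7)
        ax.set_title("exclusive region counts")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return Path(path)


def plot_dendrogram(dres: DendrogramResult, path: str | Path) -> Path:
    fig, ax = plt.subplots(figsize=(6, 4))
    sch.dendrogram(dres.linkage, labels=dres.methods, ax=ax)
    ax.set_ylabel("Ward merge height")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return Path(path)


def plot_ma(de: DEResult, path: str | Path) -> Path:
    df = de_test.ma_values(de)
    fig, ax = plt.subplots(figsize=(6, 4))
    bg = df[~df["is_deg"].astype(bool)]
    fg = df[df["is_deg"].astype(bool)]
    ax.scatter(bg["A"], bg["M"], s=3, c="0.7", label="not DE")
    ax.scatter(fg["A"], fg["M"], s=4, c="crimson", label="DEG")
    ax.axhline(0, lw=0.5, c="k")
    ax.set_xlabel("A = log10 base mean")
    ax.set_ylabel("M = log2 fold change")
    ax.set_title(f"MA plot ({de.method})")
    ax.legend(fontsize=8, markerscale=2)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return Path(path)


# -- workflow --------------------------------------------------------------


@dataclass
class WorkflowConfig:
    """Everything one end-to-end comparison run needs.

    Provide either ``counts_path`` (+ ``metadata_path``) or a synthetic
    ``preset`` name; control panels are optional and, when absent, the
    sensitivity/specificity criterion is simply dropped from the final rank.
    """

    output_dir: str | Path
    seed: int
    counts_path: str | Path | None = None
    metadata_path: str | Path | None = None
    preset: str | None = None
    filter_cutoff: float = 0.0
    methods: tuple[str, ...] = METHODS
    alpha: float = 0.05
    hg_fraction: float = 0.01
    informative_fraction: float = 0.75
    positive_controls_path: str | Path | None = None
    negative_controls_path: str | Path | None = None
    panel_from_truth: bool = False
    make_plots: bool = True
    exact_test_cap: int = 2000

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ReportingError("alpha must lie in (0, 1)")
        if (self.counts_path is None) == (self.preset is None):
            raise ReportingError("provide exactly one of counts_path or preset")


@dataclass
class WorkflowResult:
    report: EvaluationReport
    factor_sets: dict[str, ScalingFactorSet]
    de_results: dict[str, DEResult]
    loocv: dict[str, LoocvResult]
    common: CommonDegMatrix | None
    dendrogram: DendrogramResult | None
    hg: GeneList
    artifacts: dict[str, Path] = field(default_factory=dict)


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        log.info("stage %s", name)
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise WorkflowStageError(name, exc) from exc

    return wrap


def _write_tsv(df: pd.DataFrame, path: Path, **kwargs) -> Path:
    df.to_csv(path, sep="\t", float_format="%.10g", **kwargs)
    return path


def run_workflow(config: WorkflowConfig) -> WorkflowResult:
    """Execute the full comparison and write all tables/figures under
    ``config.output_dir``.  Any stage failure aborts with the stage name;
    partial outputs are retained."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    truth = None

    # load or simulate
    if config.preset is not None:
        spec = synthetic_data.preset(config.preset, seed=config.seed)
        cm, truth = _stage("simulate")(synthetic_data.generate_counts, spec)
    else:
        cm = _stage("load_counts")(counts_io.load_counts, config.counts_path)
        if config.metadata_path:
            meta = counts_io.load_sample_metadata(config.metadata_path)
            cm = cm.with_groups(meta)
    log.info("matrix: %d genes x %d samples", cm.n_genes, cm.n_samples)

    cm = _stage("filter")(counts_io.filter_by_mean_count, cm, config.filter_cutoff)
    log.info("after mean-count filter > %g: %d genes", config.filter_cutoff, cm.n_genes)

    factor_sets = _stage("normalize")(
        normalization.compute_all_factors, cm, tuple(m.upper() for m in config.methods)
    )
    factors_df = pd.concat(
        [
            pd.DataFrame(
                {
                    "method": m,
                    "sample_id": sf.sample_ids,
                    "factor": sf.factors,
                    "divisor": sf.divisors,
                }
            )
            for m, sf in factor_sets.items()
        ],
        ignore_index=True,
    )
    artifacts["factors"] = _write_tsv(factors_df, out / "factors.tsv", index=False)

    scores = _stage("housekeeping")(housekeeping.gene_stability_scores, cm)
    hg = housekeeping.select_housekeeping(scores, fraction=config.hg_fraction)
    hk_df = scores.to_frame()
    hk_df["selected"] = [g in set(hg.ids) for g in cm.gene_ids]
    artifacts["housekeeping"] = _write_tsv(hk_df, out / "housekeeping.tsv")
    log.info("selected %d housekeeping genes", len(hg))

    def _bias_variance():
        rows = {}
        for m, sf in factor_sets.items():
            norm = normalization.normalize_counts(cm, sf)
            res = bv.bias_variance_for_method(m, norm, cm.gene_ids, hg)
            rows[m] = {
                "n_control_genes_used": len(res.gene_ids),
                "mean_bias": res.method_bias,
                "mean_variance": res.method_variance,
            }
        return pd.DataFrame(rows).T

    bv_df = _stage("bias_variance")(_bias_variance)
    bv_df["rank_bias"] = bv.rank_methods_by(bv_df["mean_bias"], "lower_better")
    bv_df["rank_variance"] = bv.rank_methods_by(bv_df["mean_variance"], "lower_better")
    bv_df.index.name = "method"
    artifacts["bias_variance"] = _write_tsv(bv_df, out / "bias_variance.tsv")

    def _de_all():
        results = {}
        for m, sf in factor_sets.items():
            results[m] = de_test.run_de(
                cm, sf, alpha=config.alpha, cap=config.exact_test_cap
            )
            log.info("DE %s: %d DEGs at adj p < %g", m, results[m].n_deg, config.alpha)
        return results

    de_results = _stage("de_test")(_de_all)
    deg_lists = {m: de_test.call_degs(de, alpha=config.alpha) for m, de in de_results.items()}
    for m, de in de_results.items():
        artifacts[f"de_{m}"] = _write_tsv(de.to_frame(), out / f"de_{m}.tsv")

    # control panels
    panel = None
    if config.positive_controls_path and config.negative_controls_path:
        panel = ControlPanel(
            counts_io.load_gene_list(config.positive_controls_path, "positive_control"),
            counts_io.load_gene_list(config.negative_controls_path, "negative_control"),
        )
        panel = ControlPanel(
            panel.positives.intersection(cm.gene_ids),
            panel.negatives.intersection(cm.gene_ids),
        )
    elif config.panel_from_truth and truth is not None:
        pos, neg = synthetic_data.control_panel_lists(truth, seed=config.seed)
        panel = ControlPanel(pos, neg)

    sens_spec = None
    if panel is not None:
        sens_spec = {
            m: evaluation.sensitivity_specificity(deg_lists[m], panel)
            for m in factor_sets
        }

    def _loocv_all():
        results = {}
        for m, sf in factor_sets.items():
            informative = evaluation.select_informative_genes(
                de_results[m], cm.n_samples, fraction=config.informative_fraction
            )
            norm = normalization.normalize_counts(cm, sf)
            rows = [cm.gene_ids.index(g) for g in informative.ids]
            feats = np.log2(norm[rows, :].T + 1.0)
            results[m] = evaluation.loocv_prediction_errors(
                feats, np.asarray(cm.group_labels), seed=config.seed, method=m
            )
        return results

    loocv = _stage("loocv")(_loocv_all)
    loocv_df = pd.DataFrame(
        {
            m: {**r.errors_pct, "mean": r.mean_error, "median": r.median_error}
            for m, r in loocv.items()
        }
    ).T
    loocv_df.index.name = "method"
    artifacts["loocv"] = _write_tsv(loocv_df, out / "loocv.tsv")

    common = _stage("common_degs")(common_or_none, deg_lists)
    if common is not None:
        artifacts["common_degs"] = _write_tsv(common.pct_avg, out / "common_degs.tsv")

    dend = None
    try:
        dend = evaluation.method_rank_dendrogram(de_results)
    except evaluation.EvaluationError as exc:
        log.warning("dendrogram skipped: %s", exc)

    # assemble criteria
    criteria: dict[str, dict[str, float]] = {
        "bias": bv_df["mean_bias"].to_dict(),
        "variance": bv_df["mean_variance"].to_dict(),
        "prediction_error": {m: r.mean_error for m, r in loocv.items()},
    }
    if sens_spec is not None:
        criteria["sensitivity"] = {m: v[0] for m, v in sens_spec.items()}
        criteria["specificity"] = {m: v[1] for m, v in sens_spec.items()}
    if common is not None:
        criteria["common_degs"] = common.method_scores().to_dict()

    report = _stage("summarize")(evaluation.summarize_ranks, criteria)
    report_df = report.to_frame()
    report_df.index.name = "method"
    artifacts["report"] = _write_tsv(report_df, out / "report.tsv")
    report_json = {
        "values": {c: report.values[c].round(10).to_dict() for c in report.values},
        "ranks": {c: report.ranks[c].to_dict() for c in report.ranks},
        "final_rank": report.final_rank.round(10).to_dict(),
        "recommended": report.recommended,
        "config": {
            k: (str(v) if isinstance(v, Path) else list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
        },
    }
    (out / "report.json").write_text(json.dumps(report_json, indent=2, sort_keys=True))
    artifacts["report_json"] = out / "report.json"
    log.info("recommended method: %s", report.recommended)

    if config.make_plots:
        def _plots():
            artifacts["fig_factors"] = plot_factors(factor_sets, out / "factors.png")
            artifacts["fig_bars"] = plot_deg_abundance_bars(
                deg_lists, cm, out / "deg_abundance.png"
            )
            artifacts["fig_ci"] = plot_error_ci_bars(loocv, out / "loocv_ci.png")
            if common is not None:
                artifacts["fig_balloon"] = plot_balloon(common, out / "balloon.png")
            if dend is not None:
                artifacts["fig_dendrogram"] = plot_dendrogram(dend, out / "dendrogram.png")
            nonempty = {m: gl for m, gl in deg_lists.items() if len(gl)}
            if 2 <= len(nonempty) <= 5:
                artifacts["fig_venn"] = plot_venn(nonempty, out / "venn.png")
            for m, de in de_results.items():
                artifacts[f"fig_ma_{m}"] = plot_ma(de, out / f"ma_{m}.png")

        _stage("plots")(_plots)

    return WorkflowResult(
        report=report,
        factor_sets=factor_sets,
        de_results=de_results,
        loocv=loocv,
        common=common,
        dendrogram=dend,
        hg=hg,
        artifacts=artifacts,
    )


def common_or_none(deg_lists: dict[str, GeneList]) -> CommonDegMatrix | None:
    try:
        return evaluation.common_deg_matrix(deg_lists)
    except evaluation.EvaluationError as exc:
        log.warning("common-DEG criterion skipped: %s", exc)
        return None
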