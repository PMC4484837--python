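"""Reading, validating, filtering and writing count matrices and gene lists.

The central container is :class:`CountMatrix`: a genes x samples matrix of
nonnegative integer read counts with gene identifiers, sample identifiers and
(optionally) a two-group design attached.  All downstream modules consume this
container; gene and sample order is preserved from the input file and every
tie downstream is broken by this stable order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse


class CountsValidationError(ValueError):
    """Raised when a count matrix or gene list violates its contract."""


class CountsParseError(ValueError):
    """Raised when an input file cannot be parsed."""


GENE_LIST_ROLES = ("positive_control", "negative_control", "housekeeping", "generic")


@dataclass(frozen=True)
class GeneList:
    """An ordered, duplicate-free list of gene identifiers with a role."""

    ids: tuple[str, ...]
    role: str = "generic"

    def __post_init__(self) -> None:
        object.__setattr__(self, "ids", tuple(str(i) for i in self.ids))
        if self.role not in GENE_LIST_ROLES:
            raise CountsValidationError(
                f"unknown gene-list role {self.role!r}; expected one of {GENE_LIST_ROLES}"
            )
        if len(set(self.ids)) != len(self.ids):
            dupes = pd.Index(self.ids)[pd.Index(self.ids).duplicated()].tolist()
            raise CountsValidationError(f"duplicate gene IDs in list: {dupes[:5]}")

    def __len__(self) -> int:
        return len(self.ids)

    def __iter__(self):
        return iter(self.ids)

    def __contains__(self, gene_id: object) -> bool:
        return gene_id in set(self.ids)

    def intersection(self, other: Iterable[str]) -> "GeneList":
        """Genes of this list also present in ``other``, order preserved."""
        keep = set(other)
        return GeneList(tuple(g for g in self.ids if g in keep), role=self.role)


@dataclass
class CountMatrix:
    """Genes x samples nonnegative integer read counts with a two-group design.

    Parameters
    ----------
    counts
        Integer array of shape (G, m), genes in rows.
    gene_ids, sample_ids
        Unique string identifiers for rows and columns.
    group_labels
        One of exactly two category values per sample, or ``None`` if the
        design has not been attached yet (e.g. right after loading a bare
        matrix).  Both groups must be non-empty.
    """

    counts: np.ndarray
    gene_ids: list[str] = field(default_factory=list)
    sample_ids: list[str] = field(default_factory=list)
    group_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise CountsValidationError("counts must be a 2-D genes x samples matrix")
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_float = np.asarray(self.counts, dtype=float)
            rounded = np.rint(as_float)
            # read counts are integers; no tolerance is applied
            if not np.array_equal(as_float, rounded):
                raise CountsValidationError("counts must be integral read counts")
            self.counts = rounded.astype(np.int64)
        else:
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            g, j = np.argwhere(self.counts < 0)[0]
            raise CountsValidationError(
                f"negative count at gene {self.gene_ids[g] if self.gene_ids else g}, "
                f"sample {self.sample_ids[j] if self.sample_ids else j}"
            )
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(self.gene_ids) != self.n_genes:
            raise CountsValidationError("gene_ids length does not match counts rows")
        if len(self.sample_ids) != self.n_samples:
            raise CountsValidationError("sample_ids length does not match counts columns")
        if self.n_genes < 1:
            raise CountsValidationError("need at least one gene")
        if self.n_samples < 2:
            raise CountsValidationError("need at least two samples")
        if len(set(self.gene_ids)) != self.n_genes:
            raise CountsValidationError("duplicate gene IDs")
        if len(set(self.sample_ids)) != self.n_samples:
            raise CountsValidationError("duplicate sample IDs")
        if self.group_labels is not None:
            self.group_labels = [str(g) for g in self.group_labels]
            if len(self.group_labels) != self.n_samples:
                raise CountsValidationError("group_labels length does not match samples")
            groups = sorted(set(self.group_labels))
            if len(groups) != 2:
                raise CountsValidationError(
                    f"expected exactly two groups, got {groups}"
                )

    # -- basic properties -------------------------------------------------

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def library_sizes(self) -> np.ndarray:
        """Total read count N_j of each sample."""
        return self.counts.sum(axis=0)

    @property
    def groups(self) -> tuple[str, str]:
        if self.group_labels is None:
            raise CountsValidationError("no group labels attached")
        return tuple(sorted(set(self.group_labels)))  # type: ignore[return-value]

    def group_indices(self) -> dict[str, np.ndarray]:
        """Column indices of each of the two groups."""
        g1, g2 = self.groups
        labels = np.asarray(self.group_labels)
        return {g1: np.flatnonzero(labels == g1), g2: np.flatnonzero(labels == g2)}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)

    # -- transformations --------------------------------------------------

    def with_groups(self, metadata: pd.DataFrame | dict[str, str]) -> "CountMatrix":
        """Attach group labels from a ``sample_id -> group`` mapping or a
        metadata table with columns ``sample_id`` and ``group``."""
        if isinstance(metadata, pd.DataFrame):
            if not {"sample_id", "group"} <= set(metadata.columns):
                raise CountsValidationError(
                    "metadata table needs columns 'sample_id' and 'group'"
                )
            mapping = dict(zip(metadata["sample_id"].astype(str), metadata["group"].astype(str)))
        else:
            mapping = {str(k): str(v) for k, v in metadata.items()}
        missing = [s for s in self.sample_ids if s not in mapping]
        if missing:
            raise CountsValidationError(f"samples without group assignment: {missing[:5]}")
        return replace(self, group_labels=[mapping[s] for s in self.sample_ids])

    def subset_genes(self, keep: Sequence[str] | np.ndarray) -> "CountMatrix":
        """Restrict to the given genes (boolean mask or ID list), keeping order."""
        if isinstance(keep, np.ndarray) and keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            wanted = set(keep)
            idx = np.array([i for i, g in enumerate(self.gene_ids) if g in wanted], dtype=int)
        if idx.size == 0:
            raise CountsValidationError("gene subset is empty")
        return replace(
            self,
            counts=self.counts[idx, :],
            gene_ids=[self.gene_ids[i] for i in idx],
        )


# -- file IO ---------------------------------------------------------------


def _infer_dialect(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".tsv", ".txt", ".tab"):
        return "tsv"
    if suffix == ".csv":
        return "csv"
    if suffix == ".mtx":
        return "mtx"
    raise CountsParseError(f"cannot infer file dialect from {path.name!r}")


def load_counts(
    path: str | Path,
    dialect: str | None = None,
    genes_path: str | Path | None = None,
    samples_path: str | Path | None = None,
) -> CountMatrix:
    """Load a count matrix from TSV/CSV (header = sample IDs, first column =
    gene IDs) or MatrixMarket with sidecar one-ID-per-line gene/sample files
    (defaulting to ``<stem>.genes.txt`` / ``<stem>.samples.txt``)."""
    path = Path(path)
    if not path.exists():
        raise CountsParseError(f"no such file: {path}")
    dialect = dialect or _infer_dialect(path)
    if dialect in ("tsv", "csv"):
        sep = "\t" if dialect == "tsv" else ","
        try:
            df = pd.read_csv(path, sep=sep, index_col=0)
        except Exception as exc:  # pandas raises many flavours; re-badge with filename
            raise CountsParseError(f"failed to parse {path}: {exc}") from exc
        if df.shape[1] == 0:
            raise CountsParseError(f"{path}: no sample columns found")
        for col in df.columns:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise CountsParseError(
                    f"{path}: non-numeric entry at line {row + 2}"  # header + 1-based
                )
            df[col] = coerced
        return CountMatrix(
            counts=df.to_numpy(),
            gene_ids=[str(i) for i in df.index],
            sample_ids=[str(c) for c in df.columns],
        )
    if dialect == "mtx":
        gp = Path(genes_path) if genes_path else path.with_name(path.stem + ".genes.txt")
        sp = Path(samples_path) if samples_path else path.with_name(path.stem + ".samples.txt")
        if not gp.exists() or not sp.exists():
            raise CountsParseError(
                f"mtx requires sidecar ID files {gp.name} and {sp.name} next to {path.name}"
            )
        try:
            mat = scipy.io.mmread(str(path))
        except Exception as exc:
            raise CountsParseError(f"failed to parse {path}: {exc}") from exc
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        gene_ids = [line.strip() for line in gp.read_text().splitlines() if line.strip()]
        sample_ids = [line.strip() for line in sp.read_text().splitlines() if line.strip()]
        return CountMatrix(counts=np.asarray(mat), gene_ids=gene_ids, sample_ids=sample_ids)
    raise CountsParseError(f"unknown dialect {dialect!r}")


def save_counts(cm: CountMatrix, path: str | Path, dialect: str | None = None) -> Path:
    """Write a count matrix as TSV/CSV (or MTX with sidecar ID files)."""
    path = Path(path)
    dialect = dialect or _infer_dialect(path)
    if dialect in ("tsv", "csv"):
        cm.to_frame().to_csv(path, sep="\t" if dialect == "tsv" else ",")
    elif dialect == "mtx":
        scipy.io.mmwrite(str(path), scipy.sparse.csr_matrix(cm.counts))
        path.with_name(path.stem + ".genes.txt").write_text("\n".join(cm.gene_ids) + "\n")
        path.with_name(path.stem + ".samples.txt").write_text("\n".join(cm.sample_ids) + "\n")
    else:
        raise CountsParseError(f"unknown dialect {dialect!r}")
    return path


def load_sample_metadata(path: str | Path) -> pd.DataFrame:
    """Read a sample metadata TSV with columns ``sample_id`` and ``group``."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    if not {"sample_id", "group"} <= set(df.columns):
        raise CountsParseError(f"{path}: expected columns 'sample_id' and 'group'")
    return df


def load_gene_list(path: str | Path, role: str = "generic") -> GeneList:
    """Read a one-gene-ID-per-line text file."""
    ids = [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]
    return GeneList(tuple(ids), role=role)


def save_gene_list(gl: GeneList, path: str | Path) -> Path:
    path = Path(path)
    path.write_text("\n".join(gl.ids) + ("\n" if gl.ids else ""))
    return path


# -- filtering -------------------------------------------------------------


def filter_by_mean_count(cm: CountMatrix, cutoff: float = 0.0) -> CountMatrix:
    """Keep exactly the genes whose mean count across all samples is strictly
    greater than ``cutoff``; sample set and gene order are unchanged.

    A low-count gene carries almost no information for between-sample scaling
    or for the exact test; the default cutoff 0 drops only genes that were
    never observed.
    """
    if cutoff < 0:
        raise CountsValidationError("cutoff must be nonnegative")
    means = cm.counts.mean(axis=1)
    keep = means > cutoff
    if not keep.any():
        raise CountsValidationError(
            f"mean-count filter at cutoff {cutoff} removed every gene"
        )
    n_dropped = int((~keep).sum())
    if n_dropped:
        warnings.warn(
            f"mean-count filter (> {cutoff}) dropped {n_dropped} of {cm.n_genes} genes",
            stacklevel=2,
        )
    return cm.subset_genes(keep)
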