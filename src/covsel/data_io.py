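"""Reading, filtering and design construction for RNA-seq count data.

Counts are stored genes-in-rows / samples-in-columns.  Covariates live in a
sample-by-variable table with one designated factor of primary interest
(variable 1); every other variable is a categorical or continuous covariate.
Design matrices use reference coding (one fewer indicator column than levels,
reference = first declared level) and always carry an intercept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CountMatrix",
    "CovariateTable",
    "DesignMatrix",
    "OffsetVector",
    "read_counts",
    "write_counts",
    "read_covariates",
    "filter_genes",
    "compute_offsets",
    "design_matrix",
]


class FormatError(ValueError):
    """Raised when an input file violates the expected layout."""


@dataclass
class CountMatrix:
    """Integer read counts for ``m`` genes across ``n`` units.

    Attributes
    ----------
    counts : (m, n) int ndarray of non-negative read counts.
    gene_ids : length-m array of unique gene identifiers.
    sample_ids : length-n array of unique sample identifiers.
    """

    counts: np.ndarray
    gene_ids: np.ndarray
    sample_ids: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        if self.counts.ndim != 2:
            raise FormatError("counts must be a 2-D gene x sample matrix")
        m, n = self.counts.shape
        if m < 1 or n < 2:
            raise FormatError(f"need m >= 1 genes and n >= 2 samples, got {m} x {n}")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.counts, 1), 0)):
                bad = np.argwhere(np.mod(self.counts, 1) != 0)[0]
                raise FormatError(
                    f"non-integer count at gene {self.gene_ids[bad[0]]!r}, "
                    f"sample {self.sample_ids[bad[1]]!r}"
                )
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            bad = np.argwhere(self.counts < 0)[0]
            raise FormatError(
                f"negative count at gene {self.gene_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )
        if len(set(self.gene_ids)) != m:
            raise FormatError("duplicate gene identifiers")
        if len(set(self.sample_ids)) != n:
            raise FormatError("duplicate sample identifiers")

    @property
    def m(self) -> int:
        return self.counts.shape[0]

    @property
    def n(self) -> int:
        return self.counts.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class CovariateTable:
    """Per-unit values of ``k`` explanatory variables.

    Variable 1 (``var_names[0]``) is the factor of primary interest and must be
    categorical with at least two observed levels.  ``level_order`` maps each
    categorical variable name to its ordered levels; the first is the
    reference level.
    """

    data: pd.DataFrame  # index = sample ids, columns = var_names in order
    var_types: dict[str, str]  # name -> "categorical" | "continuous"
    primary: str
    level_order: dict[str, list] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.isna().any().any():
            raise ValueError("covariate table contains missing values")
        if self.primary != self.data.columns[0]:
            # keep the primary factor as variable 1
            cols = [self.primary] + [c for c in self.data.columns if c != self.primary]
            self.data = self.data[cols]
        for name in self.data.columns:
            t = self.var_types.get(name)
            if t not in ("categorical", "continuous"):
                raise ValueError(f"variable {name!r} has no declared type")
            if t == "categorical":
                observed = pd.unique(self.data[name])
                if name not in self.level_order:
                    self.level_order[name] = sorted(observed)
                declared = self.level_order[name]
                missing = set(observed) - set(declared)
                if missing:
                    raise ValueError(f"undeclared levels {missing} for {name!r}")
                if len(set(observed)) < 2:
                    raise ValueError(f"categorical variable {name!r} has < 2 observed levels")
            else:
                vals = np.asarray(self.data[name], dtype=float)
                if np.unique(vals).size < 2:
                    raise ValueError(f"continuous variable {name!r} is constant")
        if self.var_types[self.primary] != "categorical":
            raise ValueError("primary factor must be categorical")

    @property
    def k(self) -> int:
        return self.data.shape[1]

    @property
    def n(self) -> int:
        return self.data.shape[0]

    @property
    def var_names(self) -> list[str]:
        return list(self.data.columns)

    def name_of(self, j: int) -> str:
        """Variable name for 1-based variable index ``j`` (1 = primary)."""
        return self.data.columns[j - 1]

    def align_to(self, sample_ids) -> "CovariateTable":
        """Reorder rows to match a count matrix's sample order."""
        missing = [s for s in sample_ids if s not in self.data.index]
        if missing:
            raise ValueError(f"covariate table missing samples: {missing}")
        return CovariateTable(
            self.data.loc[list(sample_ids)].copy(),
            dict(self.var_types),
            self.primary,
            {k: list(v) for k, v in self.level_order.items()},
        )


@dataclass
class DesignMatrix:
    """Model matrix for the active variable set ``S`` (1-based indices, 1 in S).

    Column 0 is the intercept; ``column_blocks[j]`` is the slice of columns
    coding variable ``j``.
    """

    matrix: np.ndarray
    column_blocks: dict[int, slice]
    S: tuple[int, ...]
    column_names: list[str]

    @property
    def p(self) -> int:
        return self.matrix.shape[1]

    def drop(self, j: int) -> "DesignMatrix":
        """Design with variable ``j``'s block removed (for reduced-model fits)."""
        if j not in self.column_blocks:
            raise KeyError(f"variable {j} not in design")
        keep = np.ones(self.p, dtype=bool)
        keep[self.column_blocks[j]] = False
        idx = np.flatnonzero(keep)
        new_blocks: dict[int, slice] = {}
        for jj, sl in self.column_blocks.items():
            if jj == j:
                continue
            cols = [int(np.searchsorted(idx, c)) for c in range(sl.start, sl.stop)]
            new_blocks[jj] = slice(cols[0], cols[-1] + 1)
        return DesignMatrix(
            self.matrix[:, keep],
            new_blocks,
            tuple(x for x in self.S if x != j),
            [self.column_names[i] for i in idx],
        )


@dataclass
class OffsetVector:
    """Per-unit normalization offsets on the natural-log scale."""

    o: np.ndarray

    def __post_init__(self) -> None:
        self.o = np.asarray(self.o, dtype=float)
        if not np.all(np.isfinite(self.o)):
            raise ValueError("offsets must be finite")


def read_counts(path, dialect: str = "tsv") -> CountMatrix:
    """Read a gene-by-sample count table (first column = gene ids, header = sample ids)."""
    sep = {"tsv": "\t", "csv": ","}[dialect]
    df = pd.read_csv(path, sep=sep, index_col=0)
    arr = df.to_numpy()
    if arr.dtype == object or not np.issubdtype(arr.dtype, np.number):
        raise FormatError(f"{path}: non-numeric entries in count table")
    return CountMatrix(arr, df.index.to_numpy(), df.columns.to_numpy())


def write_counts(cm: CountMatrix, path, dialect: str = "tsv") -> None:
    sep = {"tsv": "\t", "csv": ","}[dialect]
    cm.to_frame().to_csv(path, sep=sep, index_label="gene_id")


def read_covariates(path, spec: dict) -> CovariateTable:
    """Read a covariate CSV (column 1 = sample id) with a typing spec.

    ``spec`` follows ``{"primary": <name>, "variables": [{"name", "type",
    "levels"?}, ...]}``.  Variables present in the file but absent from the
    spec default to continuous with a logged warning.
    """
    df = pd.read_csv(path, index_col=0)
    declared = {v["name"]: v for v in spec.get("variables", [])}
    var_types: dict[str, str] = {}
    level_order: dict[str, list] = {}
    for name in df.columns:
        if name in declared:
            var_types[name] = declared[name]["type"]
            if "levels" in declared[name]:
                level_order[name] = list(declared[name]["levels"])
        else:
            logger.warning("variable %r not declared; defaulting to continuous", name)
            var_types[name] = "continuous"
    primary = spec["primary"]
    if primary not in df.columns:
        raise ValueError(f"primary factor {primary!r} not in covariate table")
    return CovariateTable(df, var_types, primary, level_order)


def filter_genes(cm: CountMatrix, min_mean: float = 8.0,
                 max_zero_frac: float = 27 / 31) -> CountMatrix:
    """Keep genes with mean count >= ``min_mean`` and zero fraction <= ``max_zero_frac``.

    Defaults mirror the customary low-count exclusion for a 31-sample study:
    average read count at least 8 and no more than 27 zero counts.
    """
    if min_mean < 0 or not (0 <= max_zero_frac <= 1):
        raise ValueError("invalid filtering thresholds")
    means = cm.counts.mean(axis=1)
    zfrac = (cm.counts == 0).mean(axis=1)
    keep = (means >= min_mean) & (zfrac <= max_zero_frac)
    if not keep.any():
        raise ValueError(
            "gene filtering removed every gene; relax min_mean/max_zero_frac"
        )
    return CountMatrix(cm.counts[keep], cm.gene_ids[keep], cm.sample_ids)


def compute_offsets(cm: CountMatrix, q: float = 0.75) -> OffsetVector:
    """Offsets ``o_i = log(q-quantile of unit i's counts)`` (natural log).

    Uses the linear-interpolation ("type 7") quantile convention.  A zero
    quantile is an error: filter low-count genes more aggressively first.
    """
    quant = np.quantile(cm.counts, q, axis=0, method="linear")
    if (quant <= 0).any():
        bad = [str(s) for s, v in zip(cm.sample_ids, quant) if v <= 0]
        raise ValueError(
            f"zero {q}-quantile for samples {bad}; apply stronger gene filtering"
        )
    return OffsetVector(np.log(quant))


def _variable_columns(ct: CovariateTable, j: int) -> tuple[np.ndarray, list[str]]:
    """Coding columns for variable ``j``, independent of the rest of the model."""
    name = ct.name_of(j)
    if ct.var_types[name] == "continuous":
        return np.asarray(ct.data[name], dtype=float).reshape(-1, 1), [name]
    levels = ct.level_order[name]
    cols = np.column_stack(
        [(ct.data[name] == lev).to_numpy(dtype=float) for lev in levels[1:]]
    )
    return cols, [f"{name}[{lev}]" for lev in levels[1:]]


def design_matrix(ct: CovariateTable, S) -> DesignMatrix:
    """Build the model matrix for variable set ``S`` (1-based; must contain 1).

    Intercept first, then each variable's block in the order of ``S``.
    Categorical variables get reference coding; continuous variables enter
    as given.  Raises on rank deficiency, naming a dependent variable set.
    """
    S = tuple(sorted(set(int(j) for j in S)))
    if 1 not in S:
        raise ValueError("the primary factor (variable 1) must be in S")
    if any(j < 1 or j > ct.k for j in S):
        raise ValueError(f"S={S} out of range for k={ct.k} variables")
    blocks = [np.ones((ct.n, 1))]
    names = ["(Intercept)"]
    column_blocks: dict[int, slice] = {}
    start = 1
    for j in S:
        cols, cnames = _variable_columns(ct, j)
        blocks.append(cols)
        names.extend(cnames)
        column_blocks[j] = slice(start, start + cols.shape[1])
        start += cols.shape[1]
    X = np.hstack(blocks)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        culprits = []
        for j in S:
            keep = np.ones(X.shape[1], dtype=bool)
            keep[column_blocks[j]] = False
            sub = X[:, keep]
            if np.linalg.matrix_rank(sub) == sub.shape[1]:
                culprits.append(ct.name_of(j))
        raise ValueError(
            f"design matrix is rank deficient; dependent variables include {culprits}"
        )
    return DesignMatrix(X, column_blocks, S, names)
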