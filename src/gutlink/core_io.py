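"""Shared data model, table I/O and elementary statistics.

Every downstream stage (differential screening, ecology, networks, PTR,
SV profiling, mediation) works on the two containers defined here — a
samples × features abundance matrix (:class:`FeatureTable`) and a
per-sample metadata table (:class:`SampleMetadata`) — and reuses the same
small statistical toolbox: empirical normal quantile (rank-normal)
transformation, Cliff's delta effect sizes, the two-sided Wilcoxon
rank-sum test, Benjamini–Hochberg adjustment and Fisher's exact test.

Tables are exchanged as tab-separated UTF-8 text with a header row of
feature ids and sample ids in the first column.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GutlinkError",
    "DataError",
    "ValidationError",
    "FeatureTable",
    "SampleMetadata",
    "ContingencyTable2x2",
    "read_feature_table",
    "write_feature_table",
    "read_sample_metadata",
    "rank_normal_transform",
    "cliffs_delta",
    "rank_sum_test",
    "bh_adjust",
    "fisher_exact",
    "get_logger",
    "log_stage",
]

KINGDOMS = ("bacteria", "virus", "metabolite", "other")
SCALES = ("relative", "absolute", "concentration")


class GutlinkError(Exception):
    """Base class for all package errors."""


class DataError(GutlinkError):
    """Malformed or inconsistent input data."""


class ValidationError(GutlinkError):
    """Arguments or configuration violating an operation's contract."""


# --------------------------------------------------------------------------
# logging

_LOGGER = logging.getLogger("gutlink")
if not _LOGGER.handlers:  # configure once; callers may reconfigure
    _handler = logging.StreamHandler(sys.stderr)
    _handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    _LOGGER.addHandler(_handler)
    _LOGGER.setLevel(logging.INFO)


def get_logger() -> logging.Logger:
    return _LOGGER


def log_stage(stage: str, **fields) -> None:
    """Emit one structured ``key=value`` log line for a pipeline stage."""
    parts = [f"stage={stage}"] + [f"{k}={v}" for k, v in fields.items()]
    _LOGGER.info(" ".join(parts))


# --------------------------------------------------------------------------
# containers


@dataclass
class FeatureTable:
    """Samples × features abundance matrix with a kingdom and scale tag.

    Parameters
    ----------
    data:
        DataFrame indexed by sample id with feature ids as columns.
        Values must be finite and non-negative.
    kingdom:
        One of ``bacteria | virus | metabolite | other``.
    scale:
        One of ``relative | absolute | concentration``. For ``relative``
        tables every row sum must lie in ``[0, 1 + 1e-6]``.
    """

    data: pd.DataFrame
    kingdom: str = "other"
    scale: str = "absolute"

    def __post_init__(self) -> None:
        if self.kingdom not in KINGDOMS:
            raise ValidationError(f"unknown kingdom tag {self.kingdom!r}")
        if self.scale not in SCALES:
            raise ValidationError(f"unknown scale tag {self.scale!r}")
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise DataError(f"duplicate sample id {dup!r}")
        if self.data.columns.has_duplicates:
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise DataError(f"duplicate feature id {dup!r}")
        values = self.data.to_numpy(dtype=float)
        if np.isnan(values).any():
            i, j = np.argwhere(np.isnan(values))[0]
            raise DataError(
                f"missing value at sample {self.data.index[i]!r}, "
                f"feature {self.data.columns[j]!r}"
            )
        if (values < 0).any():
            i, j = np.argwhere(values < 0)[0]
            raise DataError(
                f"negative value {values[i, j]} at sample "
                f"{self.data.index[i]!r}, feature {self.data.columns[j]!r}"
            )
        if self.scale == "relative" and values.size:
            sums = values.sum(axis=1)
            if (sums > 1 + 1e-6).any():
                bad = self.data.index[int(np.argmax(sums > 1 + 1e-6))]
                raise DataError(
                    f"relative-scale row sum exceeds 1 for sample {bad!r}"
                )

    # convenience accessors -------------------------------------------------
    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    def subset_samples(self, sample_ids: Sequence) -> "FeatureTable":
        missing = [s for s in sample_ids if s not in self.data.index]
        if missing:
            raise DataError(f"unknown sample ids {missing[:3]!r}")
        return FeatureTable(self.data.loc[list(sample_ids)].copy(),
                            kingdom=self.kingdom, scale=self.scale)

    def subset_features(self, feature_ids: Sequence) -> "FeatureTable":
        missing = [f for f in feature_ids if f not in self.data.columns]
        if missing:
            raise DataError(f"unknown feature ids {missing[:3]!r}")
        return FeatureTable(self.data[list(feature_ids)].copy(),
                            kingdom=self.kingdom, scale=self.scale)


@dataclass
class SampleMetadata:
    """Per-sample status, subtype, covariates and phenotype scores.

    ``table`` is indexed by sample id and must contain a binary ``status``
    column (case=1 / control=0).  ``covariates`` and ``phenotypes`` name
    the columns playing each role; binary covariates must be coded 0/1.
    """

    table: pd.DataFrame
    covariates: list = field(default_factory=list)
    phenotypes: list = field(default_factory=list)
    subtype_col: str | None = None

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            dup = self.table.index[self.table.index.duplicated()][0]
            raise DataError(f"duplicate sample id {dup!r} in metadata")
        if "status" not in self.table.columns:
            raise DataError("metadata must contain a 'status' column")
        status = self.table["status"].to_numpy()
        if not np.isin(status, (0, 1)).all():
            raise DataError("status must be binary (case=1 / control=0)")
        for col in self.covariates + self.phenotypes:
            if col not in self.table.columns:
                raise DataError(f"metadata lacks declared column {col!r}")
            if self.table[col].isna().any():
                raise DataError(
                    f"missing values in metadata column {col!r}; "
                    "imputation is not supported"
                )
        for col in self.covariates:
            vals = self.table[col].to_numpy(dtype=float)
            uniq = np.unique(vals)
            if uniq.size <= 2 and not np.isin(uniq, (0.0, 1.0)).all():
                raise DataError(
                    f"binary covariate {col!r} must be coded 0/1"
                )

    @property
    def sample_ids(self) -> list:
        return list(self.table.index)

    @property
    def status(self) -> pd.Series:
        return self.table["status"].astype(int)

    def aligned_to(self, table: FeatureTable) -> "SampleMetadata":
        """Return metadata restricted and re-ordered to a table's samples.

        Every sample in the table must resolve to exactly one metadata row.
        """
        missing = [s for s in table.sample_ids if s not in self.table.index]
        if missing:
            raise DataError(
                f"samples absent from metadata: {missing[:3]!r}"
            )
        return SampleMetadata(
            self.table.loc[table.sample_ids].copy(),
            covariates=list(self.covariates),
            phenotypes=list(self.phenotypes),
            subtype_col=self.subtype_col,
        )


@dataclass(frozen=True)
class ContingencyTable2x2:
    """2×2 table: rows = groups, columns = significant vs not."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(int(x) != x or x < 0 for x in cells):
            raise DataError("contingency cells must be non-negative integers")
        if sum(cells) < 1:
            raise DataError("contingency table grand total must be >= 1")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


# --------------------------------------------------------------------------
# table I/O


def read_feature_table(path, kingdom: str = "other",
                       scale: str = "absolute",
                       missing_as_zero: bool = False) -> FeatureTable:
    """Read a TSV abundance matrix (first column sample id, header row).

    Row and column order are preserved from the file.  Non-numeric cells
    raise :class:`DataError` naming the offending coordinates; missing
    cells are errors unless ``missing_as_zero`` is set.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    try:
        data = raw.apply(pd.to_numeric)
    except (ValueError, TypeError):
        for j, col in enumerate(raw.columns):
            conv = pd.to_numeric(raw[col], errors="coerce")
            bad = conv.isna() & raw[col].notna()
            if bad.any():
                i = int(np.argmax(bad.to_numpy()))
                raise DataError(
                    f"non-numeric cell {raw[col].iloc[i]!r} at sample "
                    f"{raw.index[i]!r}, feature {col!r} in {path}"
                ) from None
        raise
    if missing_as_zero:
        data = data.fillna(0.0)
    return FeatureTable(data.astype(float), kingdom=kingdom, scale=scale)


def write_feature_table(table: FeatureTable, path) -> None:
    """Write the matrix as TSV (inverse of :func:`read_feature_table`)."""
    df = table.data.copy()
    df.index.name = "sample"
    df.to_csv(Path(path), sep="\t", float_format="%.10g")


def read_sample_metadata(path, covariates: Sequence[str] = (),
                         phenotypes: Sequence[str] = (),
                         subtype_col: str | None = None) -> SampleMetadata:
    """Read a per-sample metadata TSV (first column sample id)."""
    raw = pd.read_csv(Path(path), sep="\t", index_col=0)
    return SampleMetadata(raw, covariates=list(covariates),
                          phenotypes=list(phenotypes),
                          subtype_col=subtype_col)


def write_sample_metadata(meta: SampleMetadata, path) -> None:
    df = meta.table.copy()
    df.index.name = "sample"
    df.to_csv(Path(path), sep="\t", float_format="%.10g")


# --------------------------------------------------------------------------
# elementary statistics


def rank_normal_transform(x, offset: float = 0.375) -> np.ndarray:
    """Empirical normal quantile transformation.

    Maps values to ``Phi^{-1}((rank - offset) / (n + 1 - 2*offset))`` with
    average ranks for ties; the default ``offset`` uses the Blom
    constants, i.e. ``Phi^{-1}((rank - 0.375) / (n + 0.25))``.  The
    transform is strictly monotone in the input.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValidationError("rank_normal_transform needs a vector of length >= 2")
    if not np.isfinite(x).all():
        raise DataError("rank_normal_transform: non-finite values")
    if np.all(x == x[0]):
        raise DataError("rank_normal_transform undefined for constant input")
    ranks = stats.rankdata(x, method="average")
    n = x.size
    return stats.norm.ppf((ranks - offset) / (n + 1.0 - 2.0 * offset))


def cliffs_delta(x, y) -> float:
    """Cliff's delta: P(x > y) - P(x < y) over all cross pairs, in [-1, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("cliffs_delta requires non-empty vectors")
    # U counts {x > y} plus half-ties, so 2U - nxny = #{x>y} - #{x<y}
    u = stats.mannwhitneyu(x, y, alternative="two-sided").statistic
    return float((2.0 * u - x.size * y.size) / (x.size * y.size))


_EXACT_MAX_N = 12


def rank_sum_test(x, y, alternative: str = "two-sided") -> float:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) p-value.

    Uses exact enumeration for small tie-free samples
    (``len(x) + len(y) <= 12``) and the tie-corrected normal
    approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValidationError("rank_sum_test requires >= 2 observations per group")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if pooled.size <= _EXACT_MAX_N and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
    return float(min(res.pvalue, 1.0))


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (order preserved)."""
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValidationError("bh_adjust requires a non-empty vector")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise DataError("bh_adjust: p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fisher_exact(t: ContingencyTable2x2, alternative: str = "two-sided") -> float:
    """Two-sided Fisher exact p for a 2×2 table (fixed margins)."""
    if not isinstance(t, ContingencyTable2x2):
        t = ContingencyTable2x2(*np.asarray(t).ravel().tolist())
    return float(stats.fisher_exact(t.as_array(), alternative=alternative)[1])
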