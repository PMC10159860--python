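"""Diversity, distance and permutation machinery.

Alpha diversity (bias-corrected Chao1 richness, Shannon entropy), the
Canberra distance used for beta diversity throughout the pipeline, the
within-group distance comparison, and a permutation MANOVA (PERMANOVA)
computed directly from squared distances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .core_io import (
    DataError,
    FeatureTable,
    ValidationError,
    get_logger,
    log_stage,
    rank_sum_test,
)

__all__ = [
    "DistanceMatrix",
    "chao1",
    "shannon",
    "canberra",
    "distance_matrix",
    "within_group_beta",
    "permanova",
]

_LOG = get_logger()


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distance matrix with zero diagonal.

    Undefined pairs (e.g. samples sharing no profiled species) may be
    recorded as NaN; operations that cannot handle missing distances
    reject such matrices.
    """

    sample_ids: list
    matrix: np.ndarray
    metric: str = "canberra"

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValidationError("distance matrix must be square")
        if m.shape[0] != len(self.sample_ids):
            raise ValidationError("sample ids do not match matrix size")
        if not np.allclose(m, m.T, atol=1e-10, equal_nan=True):
            raise DataError("distance matrix not symmetric")
        if not np.allclose(np.diag(m), 0.0, atol=1e-10):
            raise DataError("distance matrix diagonal not zero")
        if np.nanmin(m) < 0:
            raise DataError("negative distances")
        self.matrix = m

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]


# --------------------------------------------------------------------------
# alpha diversity


def chao1(counts) -> float:
    """Bias-corrected Chao1 richness: ``S_obs + F1(F1-1) / (2(F2+1))``.

    Requires integer counts — singleton/doubleton frequencies are not
    defined on relative abundances.  An all-zero vector returns 0 with a
    warning.
    """
    c = np.asarray(counts, dtype=float)
    if c.ndim != 1 or c.size == 0:
        raise ValidationError("chao1 requires a non-empty vector")
    if (c < 0).any():
        raise DataError("chao1: negative counts")
    if not np.allclose(c, np.round(c)):
        raise DataError("chao1 requires integer counts")
    c = np.round(c).astype(int)
    s_obs = int((c > 0).sum())
    if s_obs == 0:
        warnings.warn("chao1 of an all-zero vector is 0", stacklevel=2)
        return 0.0
    f1 = int((c == 1).sum())
    f2 = int((c == 2).sum())
    return float(s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1)))


def shannon(p, base: float = np.e) -> float:
    """Shannon diversity of the renormalised positive entries (nats by
    default; pass ``base=2`` for bits)."""
    v = np.asarray(p, dtype=float)
    if v.ndim != 1 or v.size == 0:
        raise ValidationError("shannon requires a non-empty vector")
    if (v < 0).any():
        raise DataError("shannon: negative abundances")
    pos = v[v > 0]
    if pos.size == 0:
        raise DataError("shannon undefined for an all-zero vector")
    q = pos / pos.sum()
    return float(-(q * np.log(q)).sum() / np.log(base))


# --------------------------------------------------------------------------
# beta diversity


def canberra(x, y) -> float:
    """Canberra distance: sum of |x_i - y_i| / (x_i + y_i) over coordinates
    where at least one entry is positive (both-zero coordinates contribute 0)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("canberra requires equal-length vectors")
    if (x < 0).any() or (y < 0).any():
        raise DataError("canberra: negative entries")
    num = np.abs(x - y)
    den = x + y
    mask = den > 0
    return float((num[mask] / den[mask]).sum())


def distance_matrix(table: FeatureTable, metric: str = "canberra") -> DistanceMatrix:
    """All pairwise sample distances for an abundance table."""
    values = table.values
    if metric == "canberra":
        if (values < 0).any():
            raise DataError("canberra: negative entries")
        condensed = pdist(values, metric="canberra")
    else:
        condensed = pdist(values, metric=metric)
    return DistanceMatrix(table.sample_ids, squareform(condensed), metric)


def within_group_beta(d: DistanceMatrix, groups):
    """Within-group pairwise distances per group, plus a two-sided
    rank-sum comparison between the two groups' distance collections.

    ``groups`` maps each sample id (or position) to a group label; exactly
    two distinct labels are required for the test.
    """
    labels = _resolve_labels(d, groups)
    uniq = pd.unique(labels)
    out = {}
    for g in uniq:
        idx = np.flatnonzero(labels == g)
        if idx.size < 2:
            raise ValidationError(f"group {g!r} has fewer than 2 samples")
        sub = d.matrix[np.ix_(idx, idx)]
        iu = np.triu_indices(idx.size, k=1)
        vals = sub[iu]
        if np.isnan(vals).any():
            _LOG.warning("within_group_beta: dropping %d undefined distances "
                         "in group %r", int(np.isnan(vals).sum()), g)
            vals = vals[~np.isnan(vals)]
        out[g] = vals
    if len(uniq) != 2:
        raise ValidationError("within_group_beta compares exactly two groups")
    if any(len(out[g]) < 2 for g in uniq):
        _LOG.warning("within_group_beta: too few within-group distances "
                     "for a rank-sum comparison")
        return out, float("nan")
    p = rank_sum_test(out[uniq[0]], out[uniq[1]])
    return out, p


def _resolve_labels(d: DistanceMatrix, groups) -> np.ndarray:
    if isinstance(groups, pd.Series):
        missing = [s for s in d.sample_ids if s not in groups.index]
        if missing:
            raise DataError(f"unknown group for samples {missing[:3]!r}")
        return groups.loc[d.sample_ids].to_numpy()
    labels = np.asarray(groups)
    if labels.size != d.n_samples:
        raise ValidationError("groups length does not match samples")
    return labels


def permanova(d: DistanceMatrix, labels, n_perm: int = 999,
              seed: int = 0):
    """Permutational multivariate analysis of variance.

    Pseudo-F from among/within sums of squared distances
    (``SS_total = sum_{i<j} d_ij^2 / n``, ``SS_within`` summed per group);
    the p-value is ``(1 + #{F_perm >= F_obs}) / (1 + n_perm)``, so the
    smallest attainable p is ``1 / (n_perm + 1)``.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    labels = _resolve_labels(d, labels)
    uniq, inv = np.unique(labels, return_inverse=True)
    k = uniq.size
    if k < 2:
        raise ValidationError("permanova needs >= 2 groups")
    counts = np.bincount(inv)
    if (counts < 2).any():
        raise ValidationError("each group needs >= 2 samples")
    n = d.n_samples
    if np.isnan(d.matrix).any():
        raise DataError("permanova cannot handle missing distances")
    d2 = d.matrix ** 2
    ss_total = d2.sum() / (2.0 * n)
    if ss_total <= 0:
        raise DataError("all samples identical: pseudo-F undefined")

    def f_stat(group_idx: np.ndarray) -> float:
        ss_within = 0.0
        for g in range(k):
            b = (group_idx == g).astype(float)
            ss_within += b @ d2 @ b / (2.0 * counts[g])
        if ss_within <= 0:
            return np.inf
        return ((ss_total - ss_within) / (k - 1)) / (ss_within / (n - k))

    f_obs = f_stat(inv)
    rng = np.random.default_rng(seed)
    # batch the permuted within-group sums as matrix products
    perms = np.empty((n, n_perm), dtype=np.int64)
    for p_i in range(n_perm):
        perms[:, p_i] = rng.permutation(inv)
    ss_within_perm = np.zeros(n_perm)
    for g in range(k):
        b = (perms == g).astype(float)          # n × n_perm
        ss_within_perm += np.einsum("ip,ip->p", b, d2 @ b) / (2.0 * counts[g])
    with np.errstate(divide="ignore", invalid="ignore"):
        f_perm = ((ss_total - ss_within_perm) / (k - 1)) / \
                 (ss_within_perm / (n - k))
    f_perm = np.where(ss_within_perm <= 0, np.inf, f_perm)
    p = (1.0 + np.count_nonzero(f_perm >= f_obs)) / (1.0 + n_perm)
    log_stage("permanova", n_samples=n, n_features=k, seed=seed)
    return float(f_obs), float(p)
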