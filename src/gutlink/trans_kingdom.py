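"""SparCC compositional correlations and trans-kingdom networks.

Relative abundances are compositions: ordinary correlations between them
are distorted by the closure.  SparCC (sparse correlations for
compositional data) estimates correlations between the unobserved basis
variances from pairwise log-ratio variances
``t_ij = Var(log(x_i / x_j))``, solving the linear system that relates
log-ratio variance totals to basis variances under a sparsity
assumption, and iteratively excluding strongly correlated pairs that
violate it.  Uncertainty from the compositional sampling is propagated
by resampling fractions from a Dirichlet posterior with unit
pseudocounts and taking the median correlation across draws.

On top of the correlation machinery this module builds viral–bacterial
(trans-kingdom) networks thresholded on correlation magnitude and
permutation pseudo-p-values, and compares the edge counts of two groups'
networks with Fisher's exact test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .core_io import (
    ContingencyTable2x2,
    DataError,
    FeatureTable,
    ValidationError,
    fisher_exact,
    get_logger,
    log_stage,
)

__all__ = [
    "CorrelationNetwork",
    "prevalence_filter",
    "sparcc",
    "pseudo_pvalues",
    "build_network",
    "compare_networks",
    "network_to_frame",
]

_LOG = get_logger()


def prevalence_filter(table: FeatureTable, min_prev: float = 0.10,
                      min_abund: float = 0.0001) -> FeatureTable:
    """Keep features with prevalence >= ``min_prev`` AND mean relative
    abundance >= ``min_abund`` (both thresholds inclusive)."""
    if table.scale != "relative":
        raise ValidationError("prevalence_filter expects a relative-scale table")
    values = table.values
    prev = (values > 0).mean(axis=0)
    mean_ab = values.mean(axis=0)
    keep = (prev >= min_prev) & (mean_ab >= min_abund)
    if not keep.any():
        raise DataError("prevalence/abundance filter removed every feature")
    kept = [f for f, k in zip(table.feature_ids, keep) if k]
    return table.subset_features(kept)


# --------------------------------------------------------------------------
# SparCC


def _basis_correlations(t_mat: np.ndarray, exclusion_iters: int,
                        exclusion_threshold: float) -> np.ndarray:
    """Solve the SparCC basis system for one log-ratio variance matrix."""
    d = t_mat.shape[0]
    m = np.ones((d, d)) + (d - 2) * np.eye(d)
    t_vec = t_mat.sum(axis=1)
    excluded = np.zeros((d, d), dtype=bool)

    def solve_rho():
        omega = np.linalg.solve(m, t_vec)
        omega = np.maximum(omega, 1e-12)
        denom = 2.0 * np.sqrt(np.outer(omega, omega))
        rho = (omega[:, None] + omega[None, :] - t_mat) / denom
        np.fill_diagonal(rho, 1.0)
        return np.clip(rho, -1.0, 1.0)

    rho = solve_rho()
    for _ in range(exclusion_iters):
        cand = np.abs(rho.copy())
        np.fill_diagonal(cand, 0.0)
        cand[excluded] = 0.0
        # keep the system non-singular: never fully disconnect a feature
        weak = np.diag(m) <= 2
        cand[weak, :] = 0.0
        cand[:, weak] = 0.0
        i, j = np.unravel_index(np.argmax(cand), cand.shape)
        if cand[i, j] <= exclusion_threshold:
            break
        excluded[i, j] = excluded[j, i] = True
        m[i, j] -= 1.0
        m[j, i] -= 1.0
        m[i, i] -= 1.0
        m[j, j] -= 1.0
        t_vec[i] -= t_mat[i, j]
        t_vec[j] -= t_mat[i, j]
        rho = solve_rho()
    return rho


def sparcc(table: FeatureTable, n_dirichlet: int = 20,
           exclusion_iters: int = 10, exclusion_threshold: float = 0.1,
           seed: int = 0, pseudo_depth: float = 100_000.0) -> pd.DataFrame:
    """SparCC correlation matrix (median over Dirichlet draws).

    Rows are renormalised to fractions first (so the result is exactly
    invariant to per-sample scaling), mapped to an effective sequencing
    depth ``pseudo_depth`` (default 1e5, of the order of the per-sample
    species-assignable read count in shotgun cohorts; depths much below
    ~1e4 make the posterior noticeably attenuate correlations of rare
    taxa), and fractions are resampled from the Dirichlet posterior with
    a unit pseudocount per feature.
    """
    values = table.values
    n, d = values.shape
    if d < 4:
        raise ValidationError("sparcc requires >= 4 features")
    if n < 4:
        raise ValidationError("sparcc requires >= 4 samples")
    row_sums = values.sum(axis=1)
    if (row_sums <= 0).any():
        raise DataError("sparcc: sample with zero total abundance")
    alpha = values / row_sums[:, None] * pseudo_depth + 1.0

    rng = np.random.default_rng(seed)
    draws = np.empty((n_dirichlet, d, d))
    for b in range(n_dirichlet):
        g = rng.standard_gamma(alpha)
        frac = g / g.sum(axis=1, keepdims=True)
        logx = np.log(frac)
        var = logx.var(axis=0, ddof=1)
        if (var <= 0).any():
            _LOG.warning("sparcc: zero-variance feature after resampling")
            var = np.maximum(var, 1e-12)
        cov = np.cov(logx, rowvar=False)
        t_mat = var[:, None] + var[None, :] - 2.0 * cov
        np.fill_diagonal(t_mat, 0.0)
        draws[b] = _basis_correlations(t_mat, exclusion_iters,
                                       exclusion_threshold)
    rho = np.median(draws, axis=0)
    rho = np.clip((rho + rho.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    log_stage("sparcc", n_samples=n, n_features=d, seed=seed)
    return pd.DataFrame(rho, index=table.feature_ids, columns=table.feature_ids)


def pseudo_pvalues(table: FeatureTable, rho_obs: pd.DataFrame,
                   n_boot: int = 100, seed: int = 0,
                   **sparcc_kwargs) -> pd.DataFrame:
    """Permutation pseudo-p-values for SparCC correlations.

    Each permutation shuffles every feature's samples independently
    (destroying all inter-feature dependence while keeping marginals) and
    recomputes SparCC; the two-sided p is
    ``(1 + #{|rho_perm| >= |rho_obs|}) / (1 + n_boot)``.
    """
    if n_boot < 1:
        raise ValidationError("n_boot must be >= 1")
    if list(rho_obs.index) != table.feature_ids:
        raise ValidationError("rho_obs does not match the table's features")
    rng = np.random.default_rng(seed)
    abs_obs = np.abs(rho_obs.to_numpy())
    count = np.zeros_like(abs_obs)
    values = table.values
    n = values.shape[0]
    for b in range(n_boot):
        perm = np.empty_like(values)
        for j in range(values.shape[1]):
            perm[:, j] = values[rng.permutation(n), j]
        perm_table = FeatureTable(
            pd.DataFrame(perm, index=table.sample_ids,
                         columns=table.feature_ids),
            kingdom=table.kingdom, scale="absolute")
        rho_perm = sparcc(perm_table, seed=int(rng.integers(2 ** 31)),
                          **sparcc_kwargs).to_numpy()
        count += np.abs(rho_perm) >= abs_obs
    p = (1.0 + count) / (1.0 + n_boot)
    np.fill_diagonal(p, 1.0)
    p = np.minimum(p, p.T)
    return pd.DataFrame(p, index=rho_obs.index, columns=rho_obs.columns)


# --------------------------------------------------------------------------
# network construction and comparison


@dataclass
class CorrelationNetwork:
    """Thresholded correlation network over kingdom-tagged features."""

    kingdoms: dict
    #: (feature_i, feature_j, rho, p) with i before j in feature order
    edges: list
    #: every (i, j) pair that was eligible for an edge
    tested_pairs: frozenset
    rho_min: float
    p_max: float
    cross_kingdom_only: bool
    group: str = ""

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def n_positive(self) -> int:
        return sum(1 for e in self.edges if e[2] > 0)

    @property
    def n_negative(self) -> int:
        return sum(1 for e in self.edges if e[2] < 0)


def build_network(rho: pd.DataFrame, p: pd.DataFrame,
                  kingdoms: Mapping[str, str], rho_min: float = 0.2,
                  p_max: float = 0.05, cross_kingdom_only: bool = False,
                  group: str = "") -> CorrelationNetwork:
    """Edges where ``|rho| >= rho_min`` and ``p <= p_max``; optionally only
    virus–bacteria pairs."""
    features = list(rho.index)
    if list(p.index) != features or list(rho.columns) != features:
        raise ValidationError("rho and p matrices must share the feature order")
    missing = [f for f in features if f not in kingdoms]
    if missing:
        raise DataError(f"kingdom tag missing for {missing[:3]!r}")
    rho_m = rho.to_numpy()
    p_m = p.to_numpy()
    edges = []
    tested = set()
    for a in range(len(features)):
        for b in range(a + 1, len(features)):
            fa, fb = features[a], features[b]
            if cross_kingdom_only:
                pair_k = {kingdoms[fa], kingdoms[fb]}
                if pair_k != {"virus", "bacteria"}:
                    continue
            tested.add((fa, fb))
            if abs(rho_m[a, b]) >= rho_min and p_m[a, b] <= p_max:
                edges.append((fa, fb, float(rho_m[a, b]), float(p_m[a, b])))
    return CorrelationNetwork(
        kingdoms={f: kingdoms[f] for f in features}, edges=edges,
        tested_pairs=frozenset(tested), rho_min=rho_min, p_max=p_max,
        cross_kingdom_only=cross_kingdom_only, group=group)


def compare_networks(net_a: CorrelationNetwork, net_b: CorrelationNetwork):
    """Fisher comparison of edge counts over a shared tested-pair universe.

    The 2×2 table is groups × (significant edge, tested non-edge).
    Returns ``(table, p, ratios)`` where ``ratios`` holds each group's
    positive:negative edge counts.
    """
    if net_a.tested_pairs != net_b.tested_pairs:
        raise ValidationError(
            "networks were built over different tested-pair universes")
    n_tested = len(net_a.tested_pairs)
    table = ContingencyTable2x2(net_a.n_edges, n_tested - net_a.n_edges,
                                net_b.n_edges, n_tested - net_b.n_edges)
    p = fisher_exact(table)
    ratios = {
        net_a.group or "A": (net_a.n_positive, net_a.n_negative),
        net_b.group or "B": (net_b.n_positive, net_b.n_negative),
    }
    return table, p, ratios


def network_to_frame(net: CorrelationNetwork) -> pd.DataFrame:
    """Edge list as a DataFrame (node1, node2, kingdom1, kingdom2, rho, p)."""
    rows = [(a, b, net.kingdoms[a], net.kingdoms[b], r, p)
            for a, b, r, p in net.edges]
    return pd.DataFrame(
        rows, columns=["node1", "node2", "kingdom1", "kingdom2", "rho", "p"])
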