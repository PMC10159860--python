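"""Confounder-aware case/control differential abundance.

The screen follows the two-stage logic of covariate-aware differential
pipelines for microbiome data: a non-parametric univariate stage
(two-sided Wilcoxon rank-sum against status, Cliff's delta effect size,
BH correction over the features that pass a prevalence filter) followed
by nested linear-model post hoc tests on rank-normalised abundance that
decide, per feature, whether the status association survives adjustment
for each feature-associated covariate.  Every screened feature receives
exactly one status label:

``NS``
    not significant at the univariate stage;
``OK_nc``
    significant, no covariate associated with the feature;
``OK_d``
    significant and deconfounded — status adds signal on top of every
    associated covariate (likelihood-ratio test);
``C:<covariates>``
    confounded — for the named covariates, the covariate explains the
    feature while status adds nothing on top of it;
``AD``
    ambiguous (neither cleanly deconfounded nor cleanly confounded, or
    status/covariate collinearity).

:func:`association_scan` provides the covariate-adjusted linear
associations between omics features and continuous host traits used by
the mediation triplet screen.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import (
    DataError,
    FeatureTable,
    SampleMetadata,
    ValidationError,
    bh_adjust,
    cliffs_delta,
    get_logger,
    log_stage,
    rank_normal_transform,
    rank_sum_test,
)

__all__ = [
    "univariate_screen",
    "confounder_label",
    "differential_analysis",
    "association_scan",
]

_LOG = get_logger()


def _check_two_groups(status: np.ndarray) -> None:
    n_case = int((status == 1).sum())
    n_ctrl = int((status == 0).sum())
    if n_case == 0 or n_ctrl == 0:
        raise ValidationError("cohort contains a single status group")
    if n_case < 3 or n_ctrl < 3:
        raise ValidationError("need >= 3 samples per status group")


def univariate_screen(table: FeatureTable, meta: SampleMetadata,
                      min_prevalence: float = 0.10) -> pd.DataFrame:
    """Rank-sum screen of every sufficiently prevalent feature vs status.

    Returns a DataFrame with one row per retained feature: Cliff's delta
    (case vs control), raw and BH-adjusted two-sided rank-sum p, and
    prevalence overall and per group.
    """
    if not 0.0 <= min_prevalence <= 1.0:
        raise ValidationError("min_prevalence must lie in [0, 1]")
    meta = meta.aligned_to(table)
    status = meta.status.to_numpy()
    _check_two_groups(status)
    values = table.values
    case = status == 1
    prev_total = (values > 0).mean(axis=0)
    keep = prev_total >= min_prevalence
    rows = []
    for j in np.flatnonzero(keep):
        x = values[case, j]
        y = values[~case, j]
        rows.append((table.feature_ids[j],
                     cliffs_delta(x, y),
                     rank_sum_test(x, y),
                     prev_total[j],
                     float((x > 0).mean()),
                     float((y > 0).mean())))
    if not rows:
        raise DataError("no features pass the prevalence filter")
    out = pd.DataFrame(rows, columns=["feature", "effect_size", "p",
                                      "prevalence_total", "prevalence_case",
                                      "prevalence_control"])
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    log_stage("univariate_screen", n_samples=len(status),
              n_features=int(keep.sum()), seed="NA")
    return out[["feature", "effect_size", "p", "p_adj", "prevalence_total",
                "prevalence_case", "prevalence_control"]]


# --------------------------------------------------------------------------
# nested-model confounder labelling


def _gaussian_llf(resid: np.ndarray) -> float:
    n = resid.size
    sigma2 = float(resid @ resid) / n
    return -0.5 * n * (np.log(2.0 * np.pi * sigma2) + 1.0)


def _ols_resid(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def _lrt_p(y: np.ndarray, X_reduced: np.ndarray, X_full: np.ndarray) -> float:
    """Likelihood-ratio p (chi-square, df = added columns) for nested OLS."""
    llf_r = _gaussian_llf(_ols_resid(y, X_reduced))
    llf_f = _gaussian_llf(_ols_resid(y, X_full))
    df = X_full.shape[1] - X_reduced.shape[1]
    return float(stats.chi2.sf(max(0.0, 2.0 * (llf_f - llf_r)), df))


def _covariate_association_p(z: np.ndarray, cov: np.ndarray) -> float | None:
    """Univariate feature/covariate association p; None if untestable."""
    uniq = np.unique(cov)
    if uniq.size < 2:
        return None
    if uniq.size == 2:
        g0 = z[cov == uniq[0]]
        g1 = z[cov == uniq[1]]
        if g0.size < 2 or g1.size < 2:
            return None
        return rank_sum_test(g0, g1)
    return float(stats.spearmanr(z, cov).pvalue)


def confounder_label(abundance, status, covariates: pd.DataFrame,
                     alpha: float = 0.05) -> str:
    """Nested-model status label for one (screened) feature.

    The abundance is rank-normalised; covariates univariately associated
    with it (BH within covariates, at ``alpha``) are then challenged with
    two likelihood-ratio tests: does status survive on top of the
    covariate, and does the covariate survive on top of status?  See the
    module docstring for the label vocabulary.
    """
    abundance = np.asarray(abundance, dtype=float)
    status = np.asarray(status, dtype=float)
    z = rank_normal_transform(abundance)
    names, pvals = [], []
    for name in covariates.columns:
        p = _covariate_association_p(z, covariates[name].to_numpy(dtype=float))
        if p is not None:
            names.append(name)
            pvals.append(p)
    if not names:
        return "OK_nc"
    associated = [name for name, padj in zip(names, bh_adjust(pvals))
                  if padj < alpha]
    if not associated:
        return "OK_nc"

    ones = np.ones_like(status)
    status_survives_all = True
    confounders = []
    for name in associated:
        cov = covariates[name].to_numpy(dtype=float)
        if np.std(cov) > 0 and np.std(status) > 0:
            r = float(np.corrcoef(status, cov)[0, 1])
            if abs(r) > 0.99:
                _LOG.warning(
                    "confounder_label: status collinear with %s (r=%.3f)",
                    name, r)
                return "AD"
        X_z = np.column_stack([ones, cov])
        X_zs = np.column_stack([ones, cov, status])
        X_s = np.column_stack([ones, status])
        p_status_given_cov = _lrt_p(z, X_z, X_zs)
        p_cov_given_status = _lrt_p(z, X_s, X_zs)
        if p_status_given_cov >= alpha:
            status_survives_all = False
            if p_cov_given_status < alpha:
                confounders.append(name)
    if status_survives_all:
        return "OK_d"
    if confounders:
        return "C:" + ",".join(confounders)
    return "AD"


def differential_analysis(table: FeatureTable, meta: SampleMetadata,
                          min_prevalence: float = 0.10,
                          alpha: float = 0.05) -> pd.DataFrame:
    """Full differential pipeline: univariate screen plus status labels.

    Features with ``p_adj >= alpha`` are labelled ``NS``; the rest go
    through :func:`confounder_label` against the metadata covariates.
    """
    meta = meta.aligned_to(table)
    screened = univariate_screen(table, meta, min_prevalence=min_prevalence)
    status = meta.status.to_numpy()
    covs = meta.table[meta.covariates]
    labels = []
    for _, row in screened.iterrows():
        if row["p_adj"] >= alpha:
            labels.append("NS")
        else:
            abundance = table.data[row["feature"]].to_numpy(dtype=float)
            labels.append(confounder_label(abundance, status, covs,
                                           alpha=alpha))
    out = screened.copy()
    out["status_label"] = labels
    return out


# --------------------------------------------------------------------------
# covariate-adjusted linear associations


def _resolve_targets(targets, meta: SampleMetadata,
                     sample_ids: Sequence) -> pd.DataFrame:
    if isinstance(targets, FeatureTable):
        return targets.data.loc[list(sample_ids)]
    if isinstance(targets, pd.DataFrame):
        missing = [s for s in sample_ids if s not in targets.index]
        if missing:
            raise DataError(f"targets lack samples {missing[:3]!r}")
        return targets.loc[list(sample_ids)]
    # sequence of metadata phenotype column names
    cols = list(targets)
    for c in cols:
        if c not in meta.table.columns:
            raise DataError(f"unknown phenotype column {c!r}")
    return meta.table.loc[list(sample_ids), cols]


def association_scan(features: FeatureTable, meta: SampleMetadata,
                     targets, covariates: Sequence[str] | None = None,
                     adjust_bmi: bool = True) -> pd.DataFrame:
    """Covariate-adjusted linear associations feature → continuous target.

    Feature, target and continuous covariates are rank-normalised; binary
    covariates enter as 0/1.  The model is
    ``target ~ feature + age + BMI + smoking + medication`` with BMI
    dropped when ``adjust_bmi`` is false (metabolic-trait targets, where
    BMI is itself the phenotype of interest).  Returns signed
    standardised coefficients with BH adjustment within each target
    family.

    ``targets`` may be metadata phenotype column names, a samples ×
    targets DataFrame, or another :class:`FeatureTable` (e.g.
    metabolites, which are rank-normalised like features).
    """
    meta = meta.aligned_to(features)
    sample_ids = features.sample_ids
    covariates = list(meta.covariates if covariates is None else covariates)
    if not adjust_bmi and "bmi" in covariates:
        covariates = [c for c in covariates if c != "bmi"]
    target_df = _resolve_targets(targets, meta, sample_ids)

    n = len(sample_ids)
    cov_cols = []
    for c in covariates:
        if c not in meta.table.columns:
            raise DataError(f"unknown covariate {c!r}")
        v = meta.table.loc[sample_ids, c].to_numpy(dtype=float)
        uniq = np.unique(v)
        if uniq.size < 2:
            _LOG.warning("association_scan: covariate %s constant; skipped", c)
            continue
        cov_cols.append(v if uniq.size == 2 else rank_normal_transform(v))
    k = len(cov_cols) + 2  # intercept + feature
    if n <= k + 1:
        raise ValidationError(
            f"design is rank deficient: n={n} samples for {k} regressors"
        )
    X = np.column_stack([np.ones(n)] + cov_cols)
    q, _ = np.linalg.qr(X)

    def residualize(m: np.ndarray) -> np.ndarray:
        return m - q @ (q.T @ m)

    def _feature_column(v: np.ndarray) -> np.ndarray:
        uniq = np.unique(v)
        if uniq.size < 2:       # constant: skipped downstream
            return np.full(n, np.nan)
        if uniq.size == 2:      # binary (e.g. dSV presence/absence): as-is
            return v
        return rank_normal_transform(v)

    feat_z = np.column_stack([
        _feature_column(features.values[:, j])
        for j in range(features.n_features)
    ])
    rf = residualize(np.nan_to_num(feat_z))
    rf[:, np.isnan(feat_z).any(axis=0)] = np.nan
    rf_ss = np.einsum("ij,ij->j", rf, rf)

    df_resid = n - X.shape[1] - 1
    rows = []
    for target in target_df.columns:
        t = target_df[target].to_numpy(dtype=float)
        if np.isnan(t).any():
            raise DataError(f"missing values in target {target!r}")
        if np.unique(t).size < 2:
            _LOG.warning("association_scan: target %s constant; skipped", target)
            continue
        rt = residualize(rank_normal_transform(t))
        rt_ss = float(rt @ rt)
        with np.errstate(invalid="ignore", divide="ignore"):
            beta = (rf.T @ rt) / rf_ss
            sse = rt_ss - beta ** 2 * rf_ss
            se = np.sqrt(np.maximum(sse, 0.0) / df_resid / rf_ss)
            tstat = beta / se
        p = 2.0 * stats.t.sf(np.abs(tstat), df_resid)
        ok = np.isfinite(p)
        feats = np.asarray(features.feature_ids)[ok]
        p_adj = bh_adjust(p[ok])
        for f, b, praw, padj in zip(feats, beta[ok], p[ok], p_adj):
            rows.append((f, target, float(b), float(praw), float(padj)))
    out = pd.DataFrame(rows, columns=["feature", "target", "beta", "p", "p_adj"])
    log_stage("association_scan", n_samples=n,
              n_features=features.n_features, seed="NA")
    return out
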