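"""Triplet-screened bidirectional causal mediation.

Links microbial features (treatment T), serum metabolites and host
phenotypes through linear-Gaussian mediation models on the rank-normal
scale.  To limit the number of tests, only triplets whose three pairwise
covariate-adjusted associations are all significant (BH-adjusted
p < 0.1) are evaluated.  For each candidate the average causal mediation
effect (ACME), average direct effect (ADE), total effect and proportion
mediated are estimated by quasi-Bayesian simulation: coefficient vectors
are drawn from each fitted model's asymptotic normal distribution and
the causal quantities computed per draw (for linear models
ACME = a·b, ADE = c′, total = a·b + c′).

Two causal orderings are always fitted: direction 1 treats the
metabolite as the mediator of a microbe → phenotype effect; direction 2
swaps mediator and outcome (microbe → phenotype → metabolite).  The
verdict keeps direction 1 when its ACME is significant; a strict mode
additionally requires direction 2 not to be.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import (
    DataError,
    FeatureTable,
    SampleMetadata,
    ValidationError,
    get_logger,
    log_stage,
    rank_normal_transform,
)
from .deconfound import association_scan

__all__ = [
    "MediationResult",
    "mediate",
    "triplet_screen",
    "bidirectional",
    "run_mediation",
    "mediation_network",
]

_LOG = get_logger()

PROP_MEDIATED_BOUND = 5.0


@dataclass
class MediationResult:
    """One (treatment, mediator, outcome) quasi-Bayesian mediation fit."""

    treatment: str
    mediator: str
    outcome: str
    direction: int
    acme: float
    ade: float
    total: float
    prop_mediated: float
    p_acme: float
    acme_ci: tuple
    ade_ci: tuple
    n_sims: int
    seed: int
    n_obs: int
    prop_out_of_range: bool = False
    acme_mc_se: float = 0.0


# --------------------------------------------------------------------------


def _ols_fit(y: np.ndarray, X: np.ndarray):
    """OLS coefficients and their asymptotic covariance."""
    n, p = X.shape
    xtx = X.T @ X
    if np.linalg.matrix_rank(xtx) < p:
        raise ValidationError("singular design matrix in mediation model")
    xtx_inv = np.linalg.inv(xtx)
    beta = xtx_inv @ (X.T @ y)
    resid = y - X @ beta
    sigma2 = float(resid @ resid) / (n - p)
    return beta, sigma2 * xtx_inv


def _prepare(v, name: str) -> np.ndarray:
    arr = np.asarray(v, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be a vector")
    return arr


def mediate(treatment, mediator, outcome, covariates=None,
            n_sims: int = 1000, seed: int = 0,
            treatment_id: str = "T", mediator_id: str = "M",
            outcome_id: str = "Y", direction: int = 1) -> MediationResult:
    """Quasi-Bayesian linear mediation for one triplet.

    All three variables are rank-normalised (complete cases only); the
    mediator model ``M ~ T + X`` and outcome model ``Y ~ T + M + X`` are
    fitted by least squares, ``n_sims`` coefficient draws are taken from
    each model's asymptotic normal, and per draw
    ``ACME = a·b``, ``ADE = c′``, ``total = a·b + c′``.  ``p_acme`` is the
    two-sided simulation p (doubled sign-crossing fraction, floored at
    ``1/n_sims``); the proportion mediated is the simulation median of
    ``ACME/total``, clamped to ±5 with an out-of-range flag.
    """
    if n_sims < 2:
        raise ValidationError("n_sims must be >= 2")
    t = _prepare(treatment, "treatment")
    m = _prepare(mediator, "mediator")
    y = _prepare(outcome, "outcome")
    n = t.size
    if m.size != n or y.size != n:
        raise ValidationError("treatment/mediator/outcome lengths differ")
    if covariates is None:
        cov_arr = np.empty((n, 0))
        cov_cols = []
    else:
        cov_df = pd.DataFrame(covariates)
        cov_arr = cov_df.to_numpy(dtype=float)
        cov_cols = list(cov_df.columns)
        if cov_arr.shape[0] != n:
            raise ValidationError("covariates length differs from variables")
    complete = ~(np.isnan(t) | np.isnan(m) | np.isnan(y) |
                 np.isnan(cov_arr).any(axis=1))
    t, m, y, cov_arr = t[complete], m[complete], y[complete], cov_arr[complete]
    n = t.size
    p_regressors = 3 + cov_arr.shape[1]
    if n < p_regressors + 5:
        raise ValidationError(
            f"n={n} too small for {p_regressors} regressors")

    zt = rank_normal_transform(t)
    zm = rank_normal_transform(m)
    zy = rank_normal_transform(y)
    cov_z = np.column_stack([
        cov_arr[:, j] if np.unique(cov_arr[:, j]).size <= 2
        else rank_normal_transform(cov_arr[:, j])
        for j in range(cov_arr.shape[1])
    ]) if cov_arr.shape[1] else np.empty((n, 0))

    ones = np.ones(n)
    X_m = np.column_stack([ones, zt, cov_z])
    X_y = np.column_stack([ones, zt, zm, cov_z])
    beta_m, cov_m = _ols_fit(zm, X_m)
    beta_y, cov_y = _ols_fit(zy, X_y)

    rng = np.random.default_rng(seed)
    draws_m = rng.multivariate_normal(beta_m, cov_m, size=n_sims,
                                      method="cholesky")
    draws_y = rng.multivariate_normal(beta_y, cov_y, size=n_sims,
                                      method="cholesky")
    a = draws_m[:, 1]       # T -> M
    cp = draws_y[:, 1]      # direct T -> Y
    b = draws_y[:, 2]       # M -> Y
    acme_d = a * b
    total_d = acme_d + cp

    acme = float(acme_d.mean())
    ade = float(cp.mean())
    total = float(total_d.mean())
    mc_se = float(acme_d.std(ddof=1) / np.sqrt(n_sims))
    frac_neg = float(np.mean(acme_d < 0))
    frac_pos = float(np.mean(acme_d > 0))
    p_acme = max(1.0 / n_sims, min(1.0, 2.0 * min(frac_neg, frac_pos)))
    with np.errstate(divide="ignore", invalid="ignore"):
        prop_d = np.where(total_d != 0, acme_d / total_d, np.nan)
    prop = float(np.nanmedian(prop_d))
    out_of_range = bool(abs(prop) > PROP_MEDIATED_BOUND or np.isnan(prop))
    prop = float(np.clip(np.nan_to_num(prop), -PROP_MEDIATED_BOUND,
                         PROP_MEDIATED_BOUND))
    return MediationResult(
        treatment=treatment_id, mediator=mediator_id, outcome=outcome_id,
        direction=direction, acme=acme, ade=ade, total=total,
        prop_mediated=prop, p_acme=p_acme,
        acme_ci=(float(np.percentile(acme_d, 2.5)),
                 float(np.percentile(acme_d, 97.5))),
        ade_ci=(float(np.percentile(cp, 2.5)),
                float(np.percentile(cp, 97.5))),
        n_sims=n_sims, seed=seed, n_obs=n,
        prop_out_of_range=out_of_range, acme_mc_se=mc_se)


# --------------------------------------------------------------------------


def triplet_screen(features: FeatureTable, metabolites: FeatureTable,
                   meta: SampleMetadata, phenotypes: Sequence[str],
                   covariates: Sequence[str] | None = None,
                   p_gate: float = 0.1,
                   metabolic_traits: Sequence[str] = ()) -> pd.DataFrame:
    """Candidate (feature, metabolite, phenotype) triplets.

    A triplet survives when all three pairwise covariate-adjusted
    associations (feature↔metabolite, metabolite↔phenotype,
    feature↔phenotype) have BH-adjusted p below ``p_gate``.  Phenotypes
    named in ``metabolic_traits`` are modelled without BMI adjustment
    (BMI itself is a metabolic trait of the disorder).
    """
    if p_gate < 0 or p_gate > 1:
        raise ValidationError("p_gate must lie in [0, 1]")
    phenotypes = list(phenotypes)
    if not phenotypes:
        raise ValidationError("no phenotypes supplied")
    fm = association_scan(features, meta, metabolites, covariates=covariates)
    if fm.empty:
        raise DataError("empty feature-metabolite association table")
    behavioural = [ph for ph in phenotypes if ph not in metabolic_traits]
    metabolic = [ph for ph in phenotypes if ph in metabolic_traits]
    parts_mp, parts_fp = [], []
    if behavioural:
        parts_mp.append(association_scan(metabolites, meta, behavioural,
                                         covariates=covariates,
                                         adjust_bmi=True))
        parts_fp.append(association_scan(features, meta, behavioural,
                                         covariates=covariates,
                                         adjust_bmi=True))
    if metabolic:
        parts_mp.append(association_scan(metabolites, meta, metabolic,
                                         covariates=covariates,
                                         adjust_bmi=False))
        parts_fp.append(association_scan(features, meta, metabolic,
                                         covariates=covariates,
                                         adjust_bmi=False))
    mp = pd.concat(parts_mp, ignore_index=True)
    fp = pd.concat(parts_fp, ignore_index=True)

    fm_sig = fm[fm["p_adj"] < p_gate]
    mp_sig = mp[mp["p_adj"] < p_gate]
    fp_sig = fp[fp["p_adj"] < p_gate]
    fm_pairs = {(r.feature, r.target): r.p_adj for r in fm_sig.itertuples()}
    mp_pairs = {(r.feature, r.target): r.p_adj for r in mp_sig.itertuples()}
    fp_pairs = {(r.feature, r.target): r.p_adj for r in fp_sig.itertuples()}
    rows = []
    for (feat, met), p1 in fm_pairs.items():
        for ph in phenotypes:
            p2 = mp_pairs.get((met, ph))
            p3 = fp_pairs.get((feat, ph))
            if p2 is not None and p3 is not None:
                rows.append((feat, met, ph, p1, p2, p3))
    out = pd.DataFrame(rows, columns=[
        "treatment", "mediator", "outcome",
        "p_adj_feature_metabolite", "p_adj_metabolite_phenotype",
        "p_adj_feature_phenotype"])
    log_stage("triplet_screen", n_samples=features.n_samples,
              n_features=len(out), seed="NA")
    return out


def bidirectional(treatment, metabolite, phenotype, covariates=None,
                  n_sims: int = 1000, seed: int = 0,
                  alpha: float = 0.05, strict: bool = False,
                  treatment_id: str = "T", metabolite_id: str = "M",
                  phenotype_id: str = "Y"):
    """Fit both causal orderings and return (dir1, dir2, verdict).

    Direction 1: metabolite mediates microbe → phenotype.  Direction 2:
    phenotype mediates microbe → metabolite.  The verdict is
    ``"direction1"`` when dir1's ACME is significant at ``alpha``
    (``strict`` additionally requires dir2's not to be), else ``None``.
    """
    dir1 = mediate(treatment, metabolite, phenotype, covariates,
                   n_sims=n_sims, seed=seed, treatment_id=treatment_id,
                   mediator_id=metabolite_id, outcome_id=phenotype_id,
                   direction=1)
    dir2 = mediate(treatment, phenotype, metabolite, covariates,
                   n_sims=n_sims, seed=seed + 1, treatment_id=treatment_id,
                   mediator_id=phenotype_id, outcome_id=metabolite_id,
                   direction=2)
    verdict = None
    if dir1.p_acme < alpha and (not strict or dir2.p_acme >= alpha):
        verdict = "direction1"
    return dir1, dir2, verdict


def run_mediation(features: FeatureTable, metabolites: FeatureTable,
                  meta: SampleMetadata, phenotypes: Sequence[str],
                  covariates: Sequence[str] | None = None,
                  p_gate: float = 0.1, n_sims: int = 1000, seed: int = 0,
                  alpha: float = 0.05, strict: bool = False,
                  metabolic_traits: Sequence[str] = ()):
    """Screen triplets then run bidirectional mediation on the survivors.

    Returns ``(candidates, results)`` where ``results`` is a list of
    ``(dir1, dir2, verdict)``; exactly two mediation fits are performed
    per surviving triplet.
    """
    meta = meta.aligned_to(features)
    candidates = triplet_screen(features, metabolites, meta, phenotypes,
                                covariates=covariates, p_gate=p_gate,
                                metabolic_traits=metabolic_traits)
    cov_names = list(meta.covariates if covariates is None else covariates)
    cov_df = meta.table[cov_names] if cov_names else None
    results = []
    for k, row in enumerate(candidates.itertuples()):
        cov = cov_df
        if (cov is not None and row.outcome in metabolic_traits
                and "bmi" in cov.columns):
            cov = cov.drop(columns=["bmi"])
        res = bidirectional(
            features.data[row.treatment].to_numpy(dtype=float),
            metabolites.data[row.mediator].to_numpy(dtype=float),
            meta.table[row.outcome].to_numpy(dtype=float),
            cov, n_sims=n_sims, seed=seed + 2 * k, alpha=alpha,
            strict=strict, treatment_id=row.treatment,
            metabolite_id=row.mediator, phenotype_id=row.outcome)
        results.append(res)
    return candidates, results


def mediation_network(results) -> pd.DataFrame:
    """Three-layer edge list (treatment → mediator → outcome) for the
    direction-1-significant triplets; two edges per kept triplet."""
    rows = []
    for dir1, _dir2, verdict in results:
        if verdict != "direction1":
            continue
        rows.append((dir1.treatment, dir1.mediator, "treatment->mediator",
                     dir1.acme, dir1.prop_mediated, dir1.p_acme))
        rows.append((dir1.mediator, dir1.outcome, "mediator->outcome",
                     dir1.acme, dir1.prop_mediated, dir1.p_acme))
    return pd.DataFrame(rows, columns=[
        "source", "target", "layer", "acme", "prop_mediated", "p_acme"])
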