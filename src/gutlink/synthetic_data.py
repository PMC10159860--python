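"""Seeded generators for cohorts, coverage profiles and SV populations.

The study's deposited data are not needed to exercise the pipeline: this
module emulates their statistical structure with known ground truth so
that every downstream stage has an oracle.

* :func:`generate_cohort` — a case/control cohort of compositional
  bacterial and viral abundance tables, metabolite concentrations and a
  metadata table.  Case/control shifts, medication-driven confounded
  features, basis correlations (the SparCC oracle) and linear-Gaussian
  microbe → metabolite → phenotype mediation paths are all planted and
  recorded in a :class:`CohortTruth`.
* :func:`generate_coverage` — binned circular-genome coverage for a
  species replicating at a known peak-to-trough ratio (bidirectional
  replication from a single origin gives a piecewise log-linear coverage
  profile, maximal at the origin and minimal at the terminus).
* :func:`generate_sv_population` — per-sample 1-kbp coverage with
  genomic regions deleted at controlled population frequencies.

All generators consume an explicit integer seed and are deterministic at
the level of written TSV content.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import (
    DataError,
    FeatureTable,
    SampleMetadata,
    ValidationError,
    log_stage,
    rank_normal_transform,
)
from .growth_ptr import CoverageProfile

__all__ = [
    "TruthConfig",
    "CohortTruth",
    "GenomeSim",
    "SvTruth",
    "generate_cohort",
    "generate_coverage",
    "generate_sv_population",
]

MEDICATIONS = ("ssri", "antipsychotic", "benzodiazepine")
COVARIATES = ("age", "bmi", "smoking") + MEDICATIONS


# --------------------------------------------------------------------------
# configuration and truth records


@dataclass
class TruthConfig:
    """Planted structure of a synthetic cohort.

    Effect sizes are expressed on the scale the pipeline measures them:
    ``differential_delta`` is the target Cliff's delta of a planted
    case/control feature (converted internally to a log-abundance shift),
    and the mediation coefficients ``a, b, c_prime`` are path weights
    between unit-variance rank-normal variables, so the planted average
    causal mediation effect is ``a * b``.
    """

    n_differential_bacteria: int = 10
    n_differential_virus: int = 5
    differential_delta: float = 0.6
    n_confounded: int = 3
    confounder_covariate: str = "ssri"
    confounder_effect: float = 1.2
    #: (i, j, rho) over the merged bacteria-then-virus feature index
    basis_pairs: list = field(default_factory=list)
    n_mediation_paths: int = 2
    mediation_a: float = 0.5
    mediation_b: float = 0.4
    mediation_c_prime: float = 0.3
    #: 1 = microbe -> metabolite -> phenotype; 2 = microbe -> phenotype -> metabolite
    mediation_direction: int = 1
    medication_p_case: float = 0.35
    medication_p_control: float = 0.05
    n_extra_phenotypes: int = 2
    log_mean_sd: float = 1.5


@dataclass
class CohortTruth:
    """Ground truth planted by :func:`generate_cohort`."""

    #: (feature_id, direction +1/-1, target Cliff's delta)
    differential_features: list
    #: (feature_id, driving covariate name)
    confounded_features: list
    #: (feature_id_a, feature_id_b, basis correlation)
    basis_correlations: list
    #: (treatment_id, mediator_id, outcome_id, a, b, c_prime, direction)
    mediation_paths: list

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GenomeSim:
    """Parameters of a simulated replicating circular genome."""

    genome_length: int = 1_000_000
    ori_position: int = 0
    ter_position: int = 500_000
    true_ptr: float = 2.0
    read_depth: float = 200.0
    bin_size: int = 10_000

    def __post_init__(self) -> None:
        if self.true_ptr < 1:
            raise ValidationError("true_ptr must be >= 1")
        n = self.genome_length
        sep = min(abs(self.ori_position - self.ter_position),
                  n - abs(self.ori_position - self.ter_position)) / n
        if not (0.45 - 1e-9 <= sep <= 0.55 + 1e-9):
            raise ValidationError(
                f"ori/ter circular separation {sep:.3f} outside [0.45, 0.55]"
            )
        if self.genome_length < 50 * self.bin_size:
            raise ValidationError("genome must span >= 50 bins")


@dataclass
class SvTruth:
    """Planted deletions of :func:`generate_sv_population`."""

    #: ((start_bin, end_bin), planted population fraction)
    planted_regions: list
    #: samples × bins boolean matrix of truly deleted cells
    deleted: np.ndarray


# --------------------------------------------------------------------------
# cohort generator


def _delta_to_shift(delta: float) -> float:
    """Log-abundance shift giving Cliff's delta ~ `delta` between two
    unit-variance normal groups: delta = 2*Phi(shift/sqrt(2)) - 1."""
    from scipy.stats import norm

    if not -1 < delta < 1:
        raise ValidationError("differential delta must lie in (-1, 1)")
    return float(np.sqrt(2.0) * norm.ppf((delta + 1.0) / 2.0))


def _basis_covariance(n: int, pairs: Sequence, rng: np.random.Generator):
    cov = np.eye(n)
    for i, j, rho in pairs:
        if not (0 <= i < n and 0 <= j < n) or i == j:
            raise ValidationError(f"invalid basis pair ({i}, {j})")
        if abs(rho) > 1:
            raise ValidationError("basis correlation must satisfy |rho| <= 1")
        cov[i, j] = cov[j, i] = rho
    eigmin = np.linalg.eigvalsh(cov)[0]
    if eigmin <= 1e-8:
        raise ValidationError("planted basis correlations are not positive definite")
    return cov


def generate_cohort(n_cases: int = 77, n_controls: int = 70,
                    n_bacteria: int = 200, n_viruses: int = 100,
                    n_metabolites: int = 50,
                    truth_config: TruthConfig | None = None,
                    seed: int = 0):
    """Simulate a case/control multi-omics cohort with known ground truth.

    Returns ``(bacteria, viruses, metabolites, metadata, truth)`` where the
    first three are :class:`~gutlink.core_io.FeatureTable` (bacteria and
    viruses on the relative scale, closed to row sum 1; metabolites as
    positive concentrations) and ``truth`` is a :class:`CohortTruth`.

    Abundances are compositional log-normals: a latent Gaussian basis with
    the configured sparse correlation structure, case/control shifts added
    on the log scale for differential features, a medication-only
    dependency for confounded features, then closure within each kingdom.
    Mediator metabolites are built from the rank-normalised *observed*
    treatment abundance so the planted paths are exactly linear-Gaussian
    on the analysis scale.
    """
    cfg = truth_config if truth_config is not None else TruthConfig()
    if n_cases < 3 or n_controls < 3:
        raise ValidationError("need >= 3 samples per group")
    if cfg.n_differential_bacteria + cfg.n_confounded > n_bacteria:
        raise ValidationError("more planted bacterial features than features")
    if cfg.n_differential_virus > n_viruses:
        raise ValidationError("more planted viral features than viral features")
    if cfg.n_mediation_paths > n_metabolites:
        raise ValidationError("more mediation paths than metabolites")
    if cfg.confounder_covariate not in COVARIATES:
        raise ValidationError(
            f"unknown confounder covariate {cfg.confounder_covariate!r}"
        )
    if cfg.mediation_direction not in (1, 2):
        raise ValidationError("mediation_direction must be 1 or 2")

    rng = np.random.default_rng(seed)
    n = n_cases + n_controls
    status = np.concatenate([np.ones(n_cases, int), np.zeros(n_controls, int)])
    sample_ids = [f"AN{i + 1:03d}" for i in range(n_cases)] + \
                 [f"HC{i + 1:03d}" for i in range(n_controls)]
    subtype = np.where(
        status == 1,
        np.where(rng.random(n) < 0.5, "AN-RS", "AN-BP"),
        "HC",
    )

    # covariates: AN cases have severely reduced BMI; medication use is
    # enriched in cases (the confounding channel)
    age = np.clip(rng.normal(24.0, 5.0, n), 18.0, 50.0)
    bmi = np.where(status == 1,
                   rng.normal(15.5, 1.8, n),
                   rng.normal(22.0, 2.5, n))
    bmi = np.clip(bmi, 10.0, 35.0)
    smoking = (rng.random(n) < 0.2).astype(int)
    meds = {}
    for m in MEDICATIONS:
        p = np.where(status == 1, cfg.medication_p_case, cfg.medication_p_control)
        meds[m] = (rng.random(n) < p).astype(int)
    covariate_values = {"age": age, "bmi": bmi, "smoking": smoking, **meds}

    # latent microbial basis (bacteria then viruses)
    n_microbe = n_bacteria + n_viruses
    cov = _basis_covariance(n_microbe, cfg.basis_pairs, rng)
    chol = np.linalg.cholesky(cov)
    latent = rng.standard_normal((n, n_microbe)) @ chol.T
    log_mean = rng.normal(0.0, cfg.log_mean_sd, n_microbe)
    latent = latent + log_mean

    bact_ids = [f"msp_{i + 1:04d}" for i in range(n_bacteria)]
    vir_ids = [f"vir_{i + 1:04d}" for i in range(n_viruses)]
    microbe_ids = bact_ids + vir_ids

    differential = []
    shift = _delta_to_shift(cfg.differential_delta)
    diff_bact = list(range(cfg.n_differential_bacteria))
    diff_vir = [n_bacteria + i for i in range(cfg.n_differential_virus)]
    for k, idx in enumerate(diff_bact + diff_vir):
        direction = 1 if k % 2 == 0 else -1
        latent[:, idx] += direction * shift * status
        differential.append((microbe_ids[idx], direction, cfg.differential_delta))

    confounded = []
    conf_start = cfg.n_differential_bacteria
    driver = covariate_values[cfg.confounder_covariate]
    for k in range(cfg.n_confounded):
        idx = conf_start + k
        latent[:, idx] += cfg.confounder_effect * driver
        confounded.append((microbe_ids[idx], cfg.confounder_covariate))

    # closure per kingdom: each table is a composition in its own assay.
    # Note the closure of a kingdom is a single closure of its log-normal
    # basis, so within-kingdom basis correlations are what SparCC can
    # recover; cross-kingdom pairs are additionally distorted by the two
    # kingdoms' separate normalisations.
    raw = np.exp(latent)
    bacteria = raw[:, :n_bacteria]
    viruses = raw[:, n_bacteria:]
    bacteria = bacteria / bacteria.sum(axis=1, keepdims=True)
    viruses = viruses / viruses.sum(axis=1, keepdims=True)

    # metabolites: mediators first, the rest independent log-normals
    met_ids = [f"met_{i + 1:03d}" for i in range(n_metabolites)]
    met_latent = rng.standard_normal((n, n_metabolites))
    pheno = {}
    mediation_paths = []
    a, b, cp = cfg.mediation_a, cfg.mediation_b, cfg.mediation_c_prime
    resid = 1.0 - (b * b + cp * cp + 2.0 * a * b * cp)
    if cfg.n_mediation_paths and resid <= 0:
        raise ValidationError("mediation path coefficients imply variance > 1")
    for k in range(cfg.n_mediation_paths):
        # treatment features follow the planted differential bacteria so the
        # triplet screen sees status-linked treatments
        t_idx = k % n_bacteria
        z_t = rank_normal_transform(bacteria[:, t_idx])
        eps_m = rng.standard_normal(n)
        eps_y = rng.standard_normal(n)
        if cfg.mediation_direction == 1:
            m = a * z_t + np.sqrt(1.0 - a * a) * eps_m
            y = b * m + cp * z_t + np.sqrt(resid) * eps_y
        else:  # reverse wiring: treatment -> phenotype -> metabolite
            y = a * z_t + np.sqrt(1.0 - a * a) * eps_y
            m = b * y + cp * z_t + np.sqrt(resid) * eps_m
        met_latent[:, k] = m
        out_id = f"pheno_path_{k + 1}"
        pheno[out_id] = y
        mediation_paths.append(
            (microbe_ids[t_idx], met_ids[k], out_id, a, b, cp,
             cfg.mediation_direction)
        )
    for k in range(cfg.n_extra_phenotypes):
        pheno[f"pheno_null_{k + 1}"] = rng.standard_normal(n)
    metabolites = np.exp(met_latent)

    meta_df = pd.DataFrame(
        {"status": status, "subtype": subtype, **covariate_values, **pheno},
        index=pd.Index(sample_ids, name="sample"),
    )
    meta = SampleMetadata(meta_df, covariates=list(COVARIATES),
                          phenotypes=list(pheno), subtype_col="subtype")
    truth = CohortTruth(
        differential_features=differential,
        confounded_features=confounded,
        basis_correlations=[(microbe_ids[i], microbe_ids[j], float(r))
                            for i, j, r in cfg.basis_pairs],
        mediation_paths=mediation_paths,
    )
    tables = (
        FeatureTable(pd.DataFrame(bacteria, index=sample_ids, columns=bact_ids),
                     kingdom="bacteria", scale="relative"),
        FeatureTable(pd.DataFrame(viruses, index=sample_ids, columns=vir_ids),
                     kingdom="virus", scale="relative"),
        FeatureTable(pd.DataFrame(metabolites, index=sample_ids, columns=met_ids),
                     kingdom="metabolite", scale="concentration"),
    )
    log_stage("simulate", n_samples=n, n_features=n_microbe + n_metabolites,
              seed=seed)
    return (*tables, meta, truth)


# --------------------------------------------------------------------------
# coverage generator (PTR stage oracle)


def coverage_expectation(gs: GenomeSim, ptr: float | None = None) -> np.ndarray:
    """Noise-free expected per-bin coverage for a replicating genome.

    Along each replication arm the expected coverage decays log-linearly
    from the origin to the terminus: ``E[cov] ∝ ptr^(-u)`` where ``u`` is
    the fractional position along the arm.  Scaled so the mean over bins
    equals ``gs.read_depth``.
    """
    ptr = gs.true_ptr if ptr is None else float(ptr)
    if ptr < 1:
        raise ValidationError("true_ptr must be >= 1")
    n_bins = gs.genome_length // gs.bin_size
    # bins indexed by their start coordinate, so the ori bin sits exactly
    # at the peak and (for ori/ter half a genome apart) the ter bin at the
    # trough of the piecewise log-linear profile
    pos = np.arange(n_bins) * gs.bin_size
    ori, ter = gs.ori_position, gs.ter_position
    # circular distance from ori, measured toward ter along each arm
    d_cw = (pos - ori) % gs.genome_length          # clockwise from ori
    arm_cw = (ter - ori) % gs.genome_length        # clockwise arm length
    u = np.where(d_cw <= arm_cw,
                 d_cw / arm_cw,
                 (gs.genome_length - d_cw) / (gs.genome_length - arm_cw))
    expect = ptr ** (-u)
    return expect / expect.mean() * gs.read_depth


def generate_coverage(gs: GenomeSim, n_samples: int, seed: int = 0,
                      ptr_jitter: float = 0.0,
                      species_id: str = "species",
                      expectation_only: bool = False):
    """Simulate per-sample binned coverage profiles for one species.

    Observed bin counts are Poisson around the piecewise log-linear
    expectation; ``ptr_jitter`` applies a multiplicative log-normal jitter
    to each sample's true PTR (clipped at 1).  With ``expectation_only``
    the noise-free expectations are returned instead of Poisson draws.
    """
    if n_samples < 1:
        raise ValidationError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    profiles = []
    for s in range(n_samples):
        ptr_s = gs.true_ptr
        if ptr_jitter > 0:
            ptr_s = max(1.0, ptr_s * float(np.exp(rng.normal(0.0, ptr_jitter))))
        expect = coverage_expectation(gs, ptr_s)
        cov = expect if expectation_only else rng.poisson(expect).astype(float)
        profiles.append(CoverageProfile(
            species_id=species_id, sample_id=f"S{s + 1:03d}",
            bin_size=gs.bin_size, coverage=cov,
        ))
    return profiles


# --------------------------------------------------------------------------
# SV population generator


def generate_sv_population(n_samples: int, n_bins: int,
                           planted: Sequence = (), seed: int = 0,
                           depth: float = 50.0,
                           coverage_cv: float = 0.2,
                           sample_scale_sd: float = 0.3):
    """Simulate a 1-kbp coverage bin matrix with planted deletions.

    ``planted`` is a list of ``((start_bin, end_bin), fraction)`` entries:
    in each region, every sample independently carries the deletion with
    probability ``fraction`` (Bernoulli), and deleted cells have zero
    coverage.  Elsewhere coverage is log-normal around the species mean
    ``depth`` with per-sample scale variation.

    Returns ``(coverage, truth)`` — a samples × bins DataFrame and an
    :class:`SvTruth`.
    """
    if n_samples < 1 or n_bins < 1:
        raise ValidationError("n_samples and n_bins must be >= 1")
    regions = []
    for (start, end), frac in planted:
        if not (0 <= start < end <= n_bins):
            raise ValidationError(f"planted region ({start}, {end}) outside bins")
        if not 0.0 <= frac <= 1.0:
            raise ValidationError("planted fraction must lie in [0, 1]")
        regions.append(((int(start), int(end)), float(frac)))
    regions.sort()
    for (s1, e1), (s2, _) in zip(
            [r[0] for r in regions], [r[0] for r in regions[1:]]):
        if s2 < e1:
            raise ValidationError("planted regions overlap")

    rng = np.random.default_rng(seed)
    sample_scale = np.exp(rng.normal(0.0, sample_scale_sd, n_samples))
    noise = np.exp(rng.normal(0.0, coverage_cv, (n_samples, n_bins)))
    coverage = depth * sample_scale[:, None] * noise
    deleted = np.zeros((n_samples, n_bins), dtype=bool)
    for (start, end), frac in regions:
        carrier = rng.random(n_samples) < frac
        deleted[carrier, start:end] = True
    coverage[deleted] = 0.0
    df = pd.DataFrame(
        coverage,
        index=pd.Index([f"S{i + 1:03d}" for i in range(n_samples)],
                       name="sample"),
        columns=[f"bin_{j:05d}" for j in range(n_bins)],
    )
    log_stage("simulate_sv", n_samples=n_samples, n_features=n_bins, seed=seed)
    return df, SvTruth(planted_regions=regions, deleted=deleted)
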