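"""Structural-variant profiling from per-species 1-kbp coverage bins.

A genomic segment deleted in part of a bacterial population shows up as
near-zero coverage in the carrier samples.  The pipeline normalises each
sample's bin coverage by its species median, calls a (sample, bin) cell
deleted below a coverage fraction threshold, computes each bin's
population deletion rate over the samples with enough evidence, and
classifies bins by that rate:

* rate < 25% — variable SV (vSV), encoded as standardised continuous
  coverage;
* 25% ≤ rate ≤ 75% — deletion SV (dSV), encoded as presence/absence;
* rate > 75% — excluded (segment likely absent from the reference's
  population, uninformative).

Adjacent same-class bins are merged into regions.  SV-based genetic
beta diversity (Canberra) and covariate-adjusted phenotype associations
reuse the ecology and deconfound machinery.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import (
    DataError,
    FeatureTable,
    SampleMetadata,
    ValidationError,
    get_logger,
    log_stage,
)
from . import deconfound
from .ecology import DistanceMatrix, within_group_beta

__all__ = [
    "SvProfile",
    "classify_rate",
    "call_deletions",
    "classify_regions",
    "sv_profile_from_coverage",
    "sv_prevalence_filter",
    "sv_feature_table",
    "sv_beta_diversity",
    "sv_association",
]

_LOG = get_logger()

VSV_MAX_RATE = 0.25     # exclusive upper bound for variable SVs
DSV_MAX_RATE = 0.75     # inclusive upper bound for deletion SVs


def classify_rate(rate: float) -> str:
    """Map one population deletion rate to its SV class.

    ``< 0.25`` → ``vSV``; ``0.25``–``0.75`` inclusive → ``dSV``;
    ``> 0.75`` → ``excluded``.  The mapping is exhaustive and mutually
    exclusive over [0, 1].
    """
    if not 0.0 <= rate <= 1.0:
        raise ValidationError("deletion rate must lie in [0, 1]")
    if rate < VSV_MAX_RATE:
        return "vSV"
    if rate <= DSV_MAX_RATE:
        return "dSV"
    return "excluded"


@dataclass
class SvProfile:
    """Per-species SV regions and their per-sample encodings."""

    species_id: str
    #: (start_bin, end_bin, class, population deletion rate)
    regions: list
    #: unmasked samples × dSV regions, 0/1 presence of the deletion
    dsv_matrix: pd.DataFrame
    #: unmasked samples × vSV regions, z-scored normalised coverage
    vsv_matrix: pd.DataFrame
    masked_samples: list

    @property
    def unmasked_samples(self) -> list:
        return list(self.dsv_matrix.index)

    @property
    def n_unmasked(self) -> int:
        return len(self.dsv_matrix.index)


# --------------------------------------------------------------------------


def call_deletions(coverage: pd.DataFrame,
                   deletion_coverage_frac: float = 0.25,
                   min_median_coverage: float = 1.0):
    """Per-cell deletion calls from a samples × 1-kbp-bin coverage matrix.

    Each sample's bins are normalised by that sample's median bin
    coverage; a cell is deleted when its normalised coverage falls below
    ``deletion_coverage_frac``.  Samples whose median coverage is below
    ``min_median_coverage`` (default 1×) lack evidence and are masked.

    Returns ``(deleted, normalized, masked_samples)`` over the unmasked
    samples.
    """
    values = coverage.to_numpy(dtype=float)
    if (values < 0).any():
        raise DataError("coverage must be non-negative")
    medians = np.median(values, axis=1)
    masked = medians < min_median_coverage
    if masked.all():
        raise DataError(
            "all samples below the median-coverage mask; species skipped")
    if masked.any():
        _LOG.warning("call_deletions: masked %d low-coverage samples",
                     int(masked.sum()))
    keep = ~masked
    normalized = values[keep] / medians[keep, None]
    deleted = normalized < deletion_coverage_frac
    idx = coverage.index[keep]
    return (pd.DataFrame(deleted, index=idx, columns=coverage.columns),
            pd.DataFrame(normalized, index=idx, columns=coverage.columns),
            list(coverage.index[masked]))


def _merge_runs(classes: Sequence[str], gap: int = 0):
    """Merge adjacent same-class bins into (start, end, class) regions."""
    regions = []
    start = 0
    for i in range(1, len(classes) + 1):
        if i == len(classes) or classes[i] != classes[start]:
            regions.append((start, i, classes[start]))
            start = i
    if gap > 0:
        merged = [regions[0]]
        for s, e, c in regions[1:]:
            ps, pe, pc = merged[-1]
            if c == pc and s - pe <= gap:
                merged[-1] = (ps, e, c)
            else:
                merged.append((s, e, c))
        regions = merged
    return regions


def classify_regions(deleted: pd.DataFrame,
                     normalized: pd.DataFrame,
                     species_id: str = "species",
                     masked_samples: Sequence = (),
                     min_unmasked: int = 10,
                     gap: int = 0) -> SvProfile:
    """Classify bins by population deletion rate and merge into regions.

    The rate is computed over unmasked samples; bins follow the
    ``<25% / 25–75% / >75%`` rule (:func:`classify_rate`), adjacent
    same-class bins are merged, excluded runs are dropped.  A dSV region
    is deleted in a sample when more than half of its bins are deleted
    there; a vSV region's value is the z-scored normalised coverage
    averaged over its bins.
    """
    n_samples, n_bins = deleted.shape
    if n_samples < min_unmasked:
        raise DataError(
            f"{species_id}: only {n_samples} unmasked samples "
            f"(< {min_unmasked}); species skipped")
    del_m = deleted.to_numpy(dtype=bool)
    rates = del_m.mean(axis=0)
    classes = [classify_rate(r) for r in rates]
    regions = []
    dsv_cols, dsv_vals = [], []
    vsv_cols, vsv_vals = [], []
    norm = normalized.to_numpy(dtype=float)
    for start, end, cls in _merge_runs(classes, gap=gap):
        if cls == "excluded":
            continue
        rate = float(rates[start:end].mean())
        regions.append((start, end, cls, rate))
        name = f"{species_id}:{start}-{end}"
        if cls == "dSV":
            frac = del_m[:, start:end].mean(axis=1)
            dsv_cols.append(name)
            dsv_vals.append((frac > 0.5).astype(int))
        else:
            block = norm[:, start:end].mean(axis=1)
            sd = block.std(ddof=0)
            z = (block - block.mean()) / sd if sd > 0 else block - block.mean()
            vsv_cols.append(name)
            vsv_vals.append(z)
    idx = deleted.index
    dsv = pd.DataFrame(np.column_stack(dsv_vals) if dsv_vals
                       else np.empty((n_samples, 0)),
                       index=idx, columns=dsv_cols)
    vsv = pd.DataFrame(np.column_stack(vsv_vals) if vsv_vals
                       else np.empty((n_samples, 0)),
                       index=idx, columns=vsv_cols)
    log_stage("sv_classify", n_samples=n_samples, n_features=len(regions),
              seed="NA")
    return SvProfile(species_id=species_id, regions=regions,
                     dsv_matrix=dsv, vsv_matrix=vsv,
                     masked_samples=list(masked_samples))


def sv_profile_from_coverage(coverage: pd.DataFrame, species_id: str = "species",
                             deletion_coverage_frac: float = 0.25,
                             min_median_coverage: float = 1.0,
                             min_unmasked: int = 10,
                             gap: int = 0) -> SvProfile:
    """Convenience chain: :func:`call_deletions` then :func:`classify_regions`."""
    deleted, normalized, masked = call_deletions(
        coverage, deletion_coverage_frac=deletion_coverage_frac,
        min_median_coverage=min_median_coverage)
    return classify_regions(deleted, normalized, species_id=species_id,
                            masked_samples=masked,
                            min_unmasked=min_unmasked, gap=gap)


def sv_prevalence_filter(profiles: Sequence[SvProfile], cohort_size: int,
                         min_frac: float = 0.10) -> list:
    """Drop species profiled (unmasked) in fewer than ``min_frac`` of the
    cohort (inclusive threshold)."""
    if cohort_size < 10:
        raise ValidationError("cohort_size must be >= 10")
    kept = [p for p in profiles
            if p.n_unmasked >= min_frac * cohort_size - 1e-12]
    return kept


# --------------------------------------------------------------------------
# SV beta diversity and associations


def sv_feature_table(profiles: Sequence[SvProfile],
                     sample_ids: Sequence) -> pd.DataFrame:
    """Concatenated dSV/vSV feature matrix over all samples.

    dSV features are 0/1; vSV features are standardised coverage shifted
    non-negative by per-feature minimum subtraction (for Canberra).
    Cells of samples masked for a species are NaN.
    """
    blocks = []
    for prof in profiles:
        dsv = prof.dsv_matrix.astype(float)
        vsv = prof.vsv_matrix.copy()
        if vsv.shape[1]:
            vsv = vsv - vsv.min(axis=0)
        blocks.append(pd.concat([dsv, vsv], axis=1))
    if not blocks:
        raise DataError("no SV profiles provided")
    combined = pd.concat(blocks, axis=1)
    return combined.reindex(list(sample_ids))


def sv_beta_diversity(profiles: Sequence[SvProfile], meta: SampleMetadata,
                      group_col: str = "status"):
    """Canberra distances between samples' SV genotypes + group test.

    Distances are pairwise-complete: each pair is compared over the
    features of species profiled in both samples.  Pairs sharing no
    species get NaN (excluded from the test, with a warning).  Returns
    ``(DistanceMatrix, within-group distances, rank-sum p)``.
    """
    sample_ids = [s for s in meta.sample_ids
                  if any(s in p.unmasked_samples for p in profiles)]
    if len(sample_ids) < 4:
        raise DataError("too few profiled samples for SV beta diversity")
    feat = sv_feature_table(profiles, sample_ids).to_numpy(dtype=float)
    n = len(sample_ids)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = ~np.isnan(feat[i]) & ~np.isnan(feat[j])
            if not both.any():
                dist[i, j] = dist[j, i] = np.nan
                continue
            xi, xj = feat[i, both], feat[j, both]
            num = np.abs(xi - xj)
            den = xi + xj
            m = den > 0
            dist[i, j] = dist[j, i] = float((num[m] / den[m]).sum())
    if np.isnan(dist).any():
        _LOG.warning("sv_beta_diversity: %d sample pairs share no species",
                     int(np.isnan(dist).sum() // 2))
    dm = DistanceMatrix(sample_ids, dist, metric="canberra")
    groups = meta.table.loc[sample_ids, group_col]
    within, p = within_group_beta(dm, groups)
    return dm, within, p


def sv_association(profiles: Sequence[SvProfile], meta: SampleMetadata,
                   targets, covariates: Sequence[str] | None = None,
                   adjust_bmi: bool = True) -> pd.DataFrame:
    """Covariate-adjusted associations between SV features and phenotypes.

    Delegates to :func:`gutlink.deconfound.association_scan`: dSV
    features enter as binary regressors, vSV features are
    rank-normalised.  Only samples unmasked for every profiled species
    (complete cases) are used; constant features are skipped with a
    warning.
    """
    feat = sv_feature_table(profiles, meta.sample_ids)
    complete = feat.dropna(axis=0)
    if complete.shape[0] < 10:
        raise DataError("too few complete-case samples for SV association")
    # vSVs stay on the min-shifted scale: rank-normalisation downstream is
    # shift-invariant, and FeatureTable requires non-negative values
    table = FeatureTable(complete, kingdom="bacteria", scale="absolute")
    sub_meta = SampleMetadata(
        meta.table.loc[complete.index].copy(),
        covariates=list(meta.covariates), phenotypes=list(meta.phenotypes),
        subtype_col=meta.subtype_col)
    return deconfound.association_scan(table, sub_meta, targets,
                                       covariates=covariates,
                                       adjust_bmi=adjust_bmi)
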