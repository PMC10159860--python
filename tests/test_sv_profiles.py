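"""SV calling, region classification and SV-based analyses."""

import numpy as np
import pandas as pd
import pytest

import gutlink as gl
from gutlink.core_io import DataError, SampleMetadata, ValidationError
from gutlink.sv_profiles import classify_rate


# --------------------------------------------------------------------------
# the classification rule


@pytest.mark.parametrize("rate, expected", [
    (0.0, "vSV"), (0.10, "vSV"), (0.2499, "vSV"),
    (0.25, "dSV"), (0.50, "dSV"), (0.75, "dSV"),
    (0.7501, "excluded"), (0.80, "excluded"), (1.0, "excluded"),
])
def test_classification_rule_boundaries(rate, expected):
    assert classify_rate(rate) == expected


def test_classification_rule_is_exhaustive_and_exclusive():
    for rate in np.arange(0.0, 1.0001, 0.01):
        assert classify_rate(round(float(rate), 2)) in {"vSV", "dSV", "excluded"}
    with pytest.raises(ValidationError):
        classify_rate(1.2)


# --------------------------------------------------------------------------
# deletion calling


def test_planted_zero_region_called_deleted_everywhere():
    cov, truth = gl.generate_sv_population(40, 60, [((10, 20), 1.0)], seed=1)
    deleted, _norm, masked = gl.call_deletions(cov)
    assert not masked
    assert deleted.to_numpy()[:, 10:20].all()


def test_uniform_coverage_has_no_deletions():
    cov, _ = gl.generate_sv_population(30, 60, [], seed=2)
    deleted, _norm, _masked = gl.call_deletions(cov)
    assert not deleted.to_numpy().any()


def test_low_coverage_samples_are_masked():
    cov, _ = gl.generate_sv_population(20, 60, [], seed=3)
    cov.iloc[0] *= 0.001
    deleted, _norm, masked = gl.call_deletions(cov)
    assert cov.index[0] in masked
    assert cov.index[0] not in deleted.index


def test_all_samples_masked_is_an_error():
    cov, _ = gl.generate_sv_population(10, 60, [], seed=4, depth=0.01)
    with pytest.raises(DataError, match="skipped"):
        gl.call_deletions(cov)


def test_calls_agree_with_planted_truth():
    cov, truth = gl.generate_sv_population(
        200, 300, [((20, 40), 0.5), ((100, 120), 0.9), ((150, 160), 0.35)],
        seed=5)
    deleted, _norm, masked = gl.call_deletions(cov)
    keep = [i for i, s in enumerate(cov.index) if s not in masked]
    agreement = (deleted.to_numpy() == truth.deleted[keep]).mean()
    assert agreement >= 0.98


# --------------------------------------------------------------------------
# region classification


def test_classify_regions_matches_planted_classes():
    cov, truth = gl.generate_sv_population(
        200, 300, [((20, 40), 0.5), ((100, 120), 0.9), ((150, 160), 0.1)],
        seed=6)
    prof = gl.sv_profile_from_coverage(cov, "sp")
    by_class = {}
    for start, end, cls, rate in prof.regions:
        by_class.setdefault(cls, []).append((start, end, rate))
    dsv = [r for r in by_class.get("dSV", [])]
    assert any(s == 20 and e == 40 for s, e, _ in dsv)
    # the 90%-deleted region is excluded entirely
    assert all(not (s <= 100 < e) for s, e, _ in dsv)
    for s, e, _ in by_class.get("vSV", []):
        assert not (s <= 100 < e)
    # recovered population rate close to the realised truth
    realized = truth.deleted[:, 20:40].mean()
    est = next(r for s, e, r in dsv if s == 20)
    assert est == pytest.approx(realized, abs=0.05)


def test_dsv_sample_calls_use_majority_rule():
    deleted = pd.DataFrame(
        np.zeros((12, 4), dtype=bool),
        index=[f"S{i}" for i in range(12)], columns=list("abcd"))
    deleted.iloc[:6] = True              # rate 0.5 everywhere -> one dSV region
    deleted.iloc[6, 0] = True            # minority of region bins in S6
    norm = pd.DataFrame(np.ones((12, 4)), index=deleted.index,
                        columns=deleted.columns)
    prof = gl.classify_regions(deleted, norm, "sp")
    assert [cls for _s, _e, cls, _r in prof.regions] == ["dSV"]
    calls = prof.dsv_matrix.iloc[:, 0]
    assert calls.iloc[:6].all() and calls.iloc[6] == 0


def test_too_few_unmasked_samples_skips_species():
    cov, _ = gl.generate_sv_population(5, 60, [], seed=7)
    with pytest.raises(DataError, match="skipped"):
        gl.sv_profile_from_coverage(cov, "sp")


def test_no_planted_deletions_yields_no_dsv_regions():
    for rep in range(5):
        cov, _ = gl.generate_sv_population(100, 200, [], seed=800 + rep)
        prof = gl.sv_profile_from_coverage(cov, "sp")
        assert not [r for r in prof.regions if r[2] == "dSV"]


# --------------------------------------------------------------------------
# prevalence filter and beta diversity


def _profiles_pair(seed=0, disjoint=False):
    planted_a = [((10, 30), 0.9)] if disjoint else [((10, 30), 0.5)]
    cov, _ = gl.generate_sv_population(40, 120, [((10, 30), 0.5)], seed=seed)
    return cov


def test_sv_prevalence_filter_inclusive_boundary():
    cov, _ = gl.generate_sv_population(10, 60, [], seed=9)
    prof = gl.sv_profile_from_coverage(cov, "sp")
    assert gl.sv_prevalence_filter([prof], cohort_size=100, min_frac=0.10)
    assert not gl.sv_prevalence_filter([prof], cohort_size=200, min_frac=0.10)


def test_identical_profiles_give_zero_distances():
    deleted = pd.DataFrame(np.tile([True] * 2 + [False] * 2, (20, 1)),
                           index=[f"S{i}" for i in range(20)],
                           columns=list("abcd"))
    deleted.iloc[10:, :] = ~deleted.iloc[10:, :]  # two blocks, within-identical
    norm = pd.DataFrame(np.ones((20, 4)), index=deleted.index,
                        columns=deleted.columns)
    prof = gl.classify_regions(deleted, norm, "sp")
    meta = SampleMetadata(pd.DataFrame(
        {"status": [1] * 10 + [0] * 10}, index=deleted.index))
    dm, within, _p = gl.sv_beta_diversity([prof], meta)
    assert np.allclose(within[1], 0.0) and np.allclose(within[0], 0.0)


def test_disjoint_deletion_patterns_separate_groups():
    rng = np.random.default_rng(10)
    n = 40
    idx = [f"S{i}" for i in range(n)]
    # two disjoint deletion patterns separated by a never-deleted spacer
    # (otherwise adjacent same-class bins would merge into one region)
    deleted = pd.DataFrame(False, index=idx, columns=[f"b{j}" for j in range(8)])
    deleted.iloc[:20, :3] = rng.random((20, 3)) < 0.9   # group 1 pattern
    deleted.iloc[20:, 5:] = rng.random((20, 3)) < 0.9   # group 0 pattern
    norm = pd.DataFrame(rng.lognormal(0, 0.05, (n, 8)), index=idx,
                        columns=deleted.columns)
    prof = gl.classify_regions(deleted, norm, "sp")
    meta = SampleMetadata(pd.DataFrame(
        {"status": [1] * 20 + [0] * 20}, index=idx))
    dm, within, p = gl.sv_beta_diversity([prof], meta)
    st = meta.status.to_numpy()
    between = dm.matrix[np.ix_(st == 1, st == 0)].mean()
    assert between > max(np.mean(within[1]), np.mean(within[0]))


def test_sv_distance_invariant_to_feature_order():
    cov, _ = gl.generate_sv_population(30, 100, [((10, 30), 0.5)], seed=11)
    prof = gl.sv_profile_from_coverage(cov, "sp")
    meta = SampleMetadata(pd.DataFrame(
        {"status": [1] * 15 + [0] * 15}, index=cov.index))
    dm1, *_ = gl.sv_beta_diversity([prof], meta)
    shuffled = gl.SvProfile(
        species_id=prof.species_id, regions=prof.regions[::-1],
        dsv_matrix=prof.dsv_matrix.iloc[:, ::-1],
        vsv_matrix=prof.vsv_matrix.iloc[:, ::-1],
        masked_samples=prof.masked_samples)
    dm2, *_ = gl.sv_beta_diversity([shuffled], meta)
    np.testing.assert_allclose(dm1.matrix, dm2.matrix)


# --------------------------------------------------------------------------
# SV-phenotype associations


def test_planted_dsv_effect_is_top_association():
    rng = np.random.default_rng(12)
    cov, truth = gl.generate_sv_population(120, 100, [((10, 25), 0.5)],
                                           seed=13)
    prof = gl.sv_profile_from_coverage(cov, "sp")
    carrier = prof.dsv_matrix.iloc[:, 0].to_numpy(dtype=float)
    pheno = 1.0 * carrier + rng.standard_normal(len(carrier))
    meta = SampleMetadata(pd.DataFrame(
        {"status": rng.integers(0, 2, len(carrier)),
         "age": rng.normal(25, 5, len(carrier)),
         "edi": pheno}, index=prof.dsv_matrix.index),
        covariates=["age"], phenotypes=["edi"])
    res = gl.sv_association([prof], meta, ["edi"], covariates=["age"])
    best = res.sort_values("p").iloc[0]
    assert best["feature"] == prof.dsv_matrix.columns[0]
    assert best["beta"] > 0


def test_null_phenotype_gives_uniform_p(rng):
    from scipy import stats

    cov, _ = gl.generate_sv_population(150, 400, [], seed=14)
    prof = gl.sv_profile_from_coverage(cov, "sp")
    # many vSV features, pure-noise phenotype
    meta = SampleMetadata(pd.DataFrame(
        {"status": rng.integers(0, 2, 150),
         "pheno": rng.standard_normal(150)}, index=cov.index),
        phenotypes=["pheno"])
    res = gl.sv_association([prof], meta, ["pheno"], covariates=[])
    if len(res) >= 20:
        assert stats.kstest(res["p"], "uniform").pvalue > 0.001
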