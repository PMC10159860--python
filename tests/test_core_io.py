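"""Shared containers, TSV round-trips and the elementary statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

import gutlink as gl
from gutlink.core_io import ContingencyTable2x2, DataError, ValidationError


# --------------------------------------------------------------------------
# containers and I/O


def _toy_table(values, kingdom="bacteria", scale="absolute"):
    df = pd.DataFrame(values,
                      index=[f"S{i}" for i in range(len(values))],
                      columns=[f"f{j}" for j in range(len(values[0]))])
    return gl.FeatureTable(df, kingdom=kingdom, scale=scale)


def test_feature_table_round_trip(tmp_path, rng):
    table = _toy_table(rng.random((7, 5)))
    path = tmp_path / "t.tsv"
    gl.write_feature_table(table, path)
    back = gl.read_feature_table(path, kingdom="bacteria")
    assert back.sample_ids == table.sample_ids
    assert back.feature_ids == table.feature_ids
    np.testing.assert_allclose(back.values, table.values, atol=1e-12)


def test_read_rejects_negative_value_naming_cell(tmp_path):
    path = tmp_path / "bad.tsv"
    path.write_text("sample\tf0\tf1\nS0\t1.0\t2.0\nS1\t-0.5\t3.0\n")
    with pytest.raises(DataError, match="S1.*f0"):
        gl.read_feature_table(path)


def test_read_rejects_non_numeric_cell_naming_cell(tmp_path):
    path = tmp_path / "bad.tsv"
    path.write_text("sample\tf0\tf1\nS0\t1.0\toops\nS1\t0.5\t3.0\n")
    with pytest.raises(DataError, match="S0.*f1"):
        gl.read_feature_table(path)


def test_duplicate_ids_rejected():
    df = pd.DataFrame([[1.0], [2.0]], index=["S0", "S0"], columns=["f0"])
    with pytest.raises(DataError, match="duplicate sample"):
        gl.FeatureTable(df)


def test_relative_scale_row_sum_enforced():
    with pytest.raises(DataError, match="row sum"):
        _toy_table([[0.9, 0.9]], scale="relative")
    _toy_table([[0.4, 0.6]], scale="relative")  # exact closure accepted


def test_metadata_requires_resolvable_samples(rng):
    table = _toy_table(rng.random((3, 2)))
    meta = gl.SampleMetadata(pd.DataFrame(
        {"status": [1, 0]}, index=["S0", "S1"]))
    with pytest.raises(DataError, match="absent"):
        meta.aligned_to(table)


def test_contingency_table_validation():
    with pytest.raises(DataError):
        ContingencyTable2x2(-1, 0, 1, 1)
    with pytest.raises(DataError):
        ContingencyTable2x2(0, 0, 0, 0)


# --------------------------------------------------------------------------
# rank-normal transform


def test_rank_normal_blom_matches_quantile_oracle():
    # independent oracle: high-precision normal quantile at Blom positions
    out = gl.rank_normal_transform([10.0, 20.0, 30.0])
    expected = stats.norm.ppf((np.array([1, 2, 3]) - 0.375) / 3.25)
    np.testing.assert_allclose(out, expected, atol=1e-12)
    assert out[1] == pytest.approx(0.0, abs=1e-12)
    assert out[0] == pytest.approx(-out[2], abs=1e-12)


def test_rank_normal_constant_input_rejected():
    with pytest.raises(DataError):
        gl.rank_normal_transform([3.0, 3.0, 3.0])


@given(st.lists(st.floats(-1e6, 1e6), min_size=3, max_size=40, unique=True))
def test_rank_normal_is_monotone(xs):
    z = gl.rank_normal_transform(xs)
    order_in = np.argsort(xs)
    order_out = np.argsort(z)
    np.testing.assert_array_equal(order_in, order_out)


def test_rank_normal_standardizes_large_samples(rng):
    x = rng.random(200)
    z = gl.rank_normal_transform(x)
    assert -0.05 < z.mean() < 0.05
    assert 0.85 < z.var() < 1.1


# --------------------------------------------------------------------------
# Cliff's delta


def _cliffs_brute(x, y):
    gt = sum(1 for a in x for b in y if a > b)
    lt = sum(1 for a in x for b in y if a < b)
    return (gt - lt) / (len(x) * len(y))


@pytest.mark.parametrize("x, y, expected", [
    ([1, 2, 3], [4, 5, 6], -1.0),
    ([2, 2, 2], [2, 2, 2], 0.0),
    ([1, 3], [2], 0.0),
])
def test_cliffs_delta_known_values(x, y, expected):
    assert gl.cliffs_delta(x, y) == pytest.approx(expected)


def test_cliffs_delta_antisymmetric_and_matches_brute_force(rng):
    for _ in range(200):
        x = rng.integers(0, 8, rng.integers(1, 9)).astype(float)
        y = rng.integers(0, 8, rng.integers(1, 9)).astype(float)
        d = gl.cliffs_delta(x, y)
        assert d == pytest.approx(_cliffs_brute(x, y), abs=1e-12)
        assert d == pytest.approx(-gl.cliffs_delta(y, x), abs=1e-12)


def test_cliffs_delta_empty_rejected():
    with pytest.raises(ValidationError):
        gl.cliffs_delta([], [1.0])


# --------------------------------------------------------------------------
# rank-sum test


def _rank_sum_exact_oracle(x, y):
    """Enumerate all C(n, nx) assignments of pooled ranks (tie-free)."""
    from itertools import combinations

    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    nx = len(x)
    obs = ranks[:nx].sum()
    mean = nx * (len(pooled) + 1) / 2
    count = total = 0
    for comb in combinations(range(len(pooled)), nx):
        s = ranks[list(comb)].sum()
        total += 1
        if abs(s - mean) >= abs(obs - mean) - 1e-9:
            count += 1
    return count / total


def test_rank_sum_small_sample_exact_value():
    assert gl.rank_sum_test([1, 2], [3, 4]) == pytest.approx(1 / 3)


def test_rank_sum_identical_groups_p_one():
    assert gl.rank_sum_test([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)


def test_rank_sum_matches_enumeration_oracle(rng):
    for _ in range(50):
        n = int(rng.integers(4, 11))
        nx = int(rng.integers(2, n - 1))
        pooled = rng.permutation(np.arange(n, dtype=float) * 1.7 + 0.3)
        x, y = pooled[:nx], pooled[nx:]
        assert gl.rank_sum_test(x, y) == pytest.approx(
            _rank_sum_exact_oracle(x, y), abs=1e-10)


def test_rank_sum_group_size_validated():
    with pytest.raises(ValidationError):
        gl.rank_sum_test([1.0], [2.0, 3.0])


# --------------------------------------------------------------------------
# BH adjustment


def test_bh_hand_computed_example():
    np.testing.assert_allclose(
        gl.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])


def test_bh_single_and_bounds():
    assert gl.bh_adjust([1.0]) == pytest.approx([1.0])
    with pytest.raises(DataError):
        gl.bh_adjust([0.5, 1.5])


@given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
def test_bh_inflates_and_commutes_with_permutation(ps):
    adj = gl.bh_adjust(ps)
    assert (adj >= np.asarray(ps) - 1e-12).all()
    assert (adj <= 1 + 1e-12).all()
    perm = np.random.default_rng(1).permutation(len(ps))
    np.testing.assert_allclose(gl.bh_adjust(np.asarray(ps)[perm]), adj[perm])


# --------------------------------------------------------------------------
# Fisher exact


def _fisher_oracle(a, b, c, d):
    """Brute-force enumeration of all tables with the observed margins."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    obs_p = stats.hypergeom.pmf(a, n, r1, c1)
    total = 0.0
    for aa in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = stats.hypergeom.pmf(aa, n, r1, c1)
        if p <= obs_p * (1 + 1e-9):
            total += p
    return min(total, 1.0)


def test_fisher_small_table_exact_value():
    assert gl.fisher_exact(ContingencyTable2x2(2, 0, 0, 2)) == pytest.approx(1 / 3)


def test_fisher_balanced_table():
    assert gl.fisher_exact(ContingencyTable2x2(5, 5, 5, 5)) == pytest.approx(1.0)


def test_fisher_matches_hypergeometric_oracle(rng):
    for _ in range(200):
        a, b, c, d = (int(v) for v in rng.integers(0, 11, 4))
        if a + b + c + d == 0:
            continue
        t = ContingencyTable2x2(a, b, c, d)
        assert gl.fisher_exact(t) == pytest.approx(
            _fisher_oracle(a, b, c, d), rel=1e-9)
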