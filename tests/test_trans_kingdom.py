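"""SparCC, pseudo-p-values, network construction and comparison."""

import numpy as np
import pandas as pd
import pytest

import gutlink as gl
from gutlink.core_io import (ContingencyTable2x2, DataError, FeatureTable,
                             ValidationError, fisher_exact)
from gutlink.synthetic_data import TruthConfig
from conftest import null_config


def _rel_table(values, prefix="f"):
    values = np.asarray(values, dtype=float)
    df = pd.DataFrame(values, index=[f"S{i}" for i in range(len(values))],
                      columns=[f"{prefix}{j}" for j in range(values.shape[1])])
    return FeatureTable(df, kingdom="bacteria", scale="relative")


# --------------------------------------------------------------------------
# prevalence/abundance filter


def test_prevalence_filter_hand_enumeration():
    # 10 samples; prevalences 10%, 20%, 100%, 0%... with known means
    rows = np.zeros((10, 4))
    rows[0, 0] = 0.5            # prevalence 10%, mean 0.05 -> kept (inclusive)
    rows[:2, 1] = 0.0004        # prevalence 20%, mean 8e-5 -> dropped (abund)
    rows[:, 2] = 0.4            # prevalence 100% -> kept
    table = _rel_table(rows)
    kept = gl.prevalence_filter(table, min_prev=0.10, min_abund=0.0001)
    assert kept.feature_ids == ["f0", "f2"]


def test_prevalence_filter_boundary_is_inclusive():
    rows = np.zeros((20, 2))
    rows[:2, 0] = 0.5           # exactly 10% prevalence
    rows[:, 1] = 0.2
    kept = gl.prevalence_filter(_rel_table(rows), min_prev=0.10)
    assert "f0" in kept.feature_ids


def test_prevalence_filter_requires_survivors():
    rows = np.zeros((20, 2))
    rows[0, 0] = 1e-9
    rows[0, 1] = 1e-9
    with pytest.raises(DataError):
        gl.prevalence_filter(_rel_table(rows))


# --------------------------------------------------------------------------
# SparCC


def test_sparcc_output_is_symmetric_correlation_matrix(null_cohort):
    bact = null_cohort[0].subset_features(null_cohort[0].feature_ids[:12])
    rho = gl.sparcc(bact, n_dirichlet=5, seed=0).to_numpy()
    np.testing.assert_allclose(rho, rho.T, atol=1e-12)
    np.testing.assert_allclose(np.diag(rho), 1.0)
    assert (np.abs(rho) <= 1.0 + 1e-12).all()


def test_sparcc_compositional_scale_invariance(null_cohort):
    """Multiplying any sample's counts by a positive scalar is neutral."""
    bact = null_cohort[0].subset_features(null_cohort[0].feature_ids[:10])
    scaled = bact.data.copy()
    scaled.iloc[3] *= 170.0
    scaled.iloc[7] *= 0.01
    rho1 = gl.sparcc(bact, n_dirichlet=5, seed=4)
    rho2 = gl.sparcc(FeatureTable(scaled), n_dirichlet=5, seed=4)
    np.testing.assert_allclose(rho1.to_numpy(), rho2.to_numpy(), atol=1e-6)


def test_sparcc_planted_basis_pair_recovered():
    cfg = TruthConfig(basis_pairs=[(2, 17, 0.8)], n_differential_bacteria=0,
                      n_differential_virus=0, n_confounded=0,
                      n_mediation_paths=0)
    bact, *_ = gl.generate_cohort(100, 100, 50, 4, 1, truth_config=cfg,
                                  seed=21)
    rho = gl.sparcc(bact, seed=5)
    assert rho.iloc[2, 17] == pytest.approx(0.8, abs=0.15)


def test_sparcc_duplicated_feature_reports_strong_dependence(null_cohort):
    bact = null_cohort[0].subset_features(null_cohort[0].feature_ids[:8])
    data = bact.data.copy()
    data["dup"] = data[bact.feature_ids[0]]
    rho = gl.sparcc(FeatureTable(data), n_dirichlet=5, seed=6)
    assert abs(rho.loc[bact.feature_ids[0], "dup"]) > 0.9


def test_sparcc_too_few_features_rejected(null_cohort):
    bact = null_cohort[0].subset_features(null_cohort[0].feature_ids[:3])
    with pytest.raises(ValidationError):
        gl.sparcc(bact, seed=0)


# --------------------------------------------------------------------------
# pseudo-p-values


def test_pseudo_pvalues_structure_and_planted_minimum():
    cfg = TruthConfig(basis_pairs=[(0, 5, 0.85)], n_differential_bacteria=0,
                      n_differential_virus=0, n_confounded=0,
                      n_mediation_paths=0)
    bact, *_ = gl.generate_cohort(100, 100, 8, 4, 1, truth_config=cfg,
                                  seed=22)
    rho = gl.sparcc(bact, n_dirichlet=5, seed=7)
    p = gl.pseudo_pvalues(bact, rho, n_boot=19, seed=8, n_dirichlet=5)
    arr = p.to_numpy()
    np.testing.assert_allclose(arr, arr.T)
    np.testing.assert_allclose(np.diag(arr), 1.0)
    assert p.iloc[0, 5] == pytest.approx(1 / 20)
    with pytest.raises(ValidationError):
        gl.pseudo_pvalues(bact, rho, n_boot=0, seed=0)


# --------------------------------------------------------------------------
# network construction


def _toy_matrices():
    feats = ["b1", "b2", "v1"]
    rho = pd.DataFrame([[1.0, 0.5, 0.3], [0.5, 1.0, -0.05],
                        [0.3, -0.05, 1.0]], index=feats, columns=feats)
    p = pd.DataFrame([[1.0, 0.01, 0.02], [0.01, 1.0, 0.5],
                      [0.02, 0.5, 1.0]], index=feats, columns=feats)
    kingdoms = {"b1": "bacteria", "b2": "bacteria", "v1": "virus"}
    return rho, p, kingdoms


def test_build_network_matches_hand_enumeration():
    rho, p, kingdoms = _toy_matrices()
    net = gl.build_network(rho, p, kingdoms, rho_min=0.2, p_max=0.05)
    assert {(a, b) for a, b, *_ in net.edges} == {("b1", "b2"), ("b1", "v1")}
    cross = gl.build_network(rho, p, kingdoms, cross_kingdom_only=True)
    assert {(a, b) for a, b, *_ in cross.edges} == {("b1", "v1")}
    assert cross.tested_pairs == frozenset({("b1", "v1"), ("b2", "v1")})


def test_build_network_unattainable_threshold_is_empty():
    rho, p, kingdoms = _toy_matrices()
    assert gl.build_network(rho, p, kingdoms, rho_min=1.01).n_edges == 0


def test_build_network_missing_kingdom_rejected():
    rho, p, _ = _toy_matrices()
    with pytest.raises(DataError):
        gl.build_network(rho, p, {"b1": "bacteria"})


def test_edge_counts_monotone_in_thresholds():
    rho, p, kingdoms = _toy_matrices()
    n_loose = gl.build_network(rho, p, kingdoms, rho_min=0.1, p_max=0.5).n_edges
    n_tight = gl.build_network(rho, p, kingdoms, rho_min=0.4, p_max=0.02).n_edges
    assert n_tight <= n_loose


# --------------------------------------------------------------------------
# network comparison


def test_identical_networks_compare_to_p_one():
    rho, p, kingdoms = _toy_matrices()
    net = gl.build_network(rho, p, kingdoms)
    _t, fisher_p, _r = gl.compare_networks(net, net)
    assert fisher_p == pytest.approx(1.0)


def test_compare_networks_equals_hypergeometric_oracle():
    t = ContingencyTable2x2(50, 950, 10, 990)
    expected = fisher_exact(t)
    rho, p, kingdoms = _toy_matrices()
    net_a = gl.build_network(rho, p, kingdoms)
    net_b = gl.build_network(rho, p, kingdoms)
    # same universe, synthetic counts: patch edge lists directly
    net_a.edges = [("x", str(i), 0.5, 0.01) for i in range(50)]
    net_b.edges = [("x", str(i), 0.5, 0.01) for i in range(10)]
    net_a.tested_pairs = net_b.tested_pairs = frozenset(
        (("p", str(i)) for i in range(1000)))
    table, fisher_p, _ = gl.compare_networks(net_a, net_b)
    assert table.as_array().tolist() == [[50, 950], [10, 990]]
    assert fisher_p == pytest.approx(expected)


def test_compare_networks_requires_shared_universe():
    rho, p, kingdoms = _toy_matrices()
    net_a = gl.build_network(rho, p, kingdoms, cross_kingdom_only=True)
    net_b = gl.build_network(rho, p, kingdoms, cross_kingdom_only=False)
    with pytest.raises(ValidationError):
        gl.compare_networks(net_a, net_b)


def test_zeroed_cross_kingdom_correlations_shrink_the_network():
    """Group with planted virus-bacteria couplings has more edges."""
    wins = 0
    for rep in range(5):
        pairs = [(i, 20 + i, 0.8) for i in range(10)]
        cfg = TruthConfig(basis_pairs=pairs, n_differential_bacteria=0,
                          n_differential_virus=0, n_confounded=0,
                          n_mediation_paths=0)
        ba, va, *_ = gl.generate_cohort(100, 100, 20, 10, 1,
                                        truth_config=cfg, seed=600 + rep)
        bb, vb, *_ = gl.generate_cohort(100, 100, 20, 10, 1,
                                        truth_config=null_config(),
                                        seed=700 + rep)
        kingdoms = {f: "bacteria" for f in ba.feature_ids}
        kingdoms.update({f: "virus" for f in va.feature_ids})
        nets = []
        for bact, vir in [(ba, va), (bb, vb)]:
            merged = FeatureTable(pd.concat([bact.data, vir.data], axis=1))
            rho = gl.sparcc(merged, n_dirichlet=5, seed=rep)
            p = gl.pseudo_pvalues(merged, rho, n_boot=39, seed=rep,
                                  n_dirichlet=5)
            nets.append(gl.build_network(rho, p, kingdoms,
                                         cross_kingdom_only=True))
        wins += nets[0].n_edges > nets[1].n_edges
    assert wins >= 5
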