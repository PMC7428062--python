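"""Correlation-matrix assembly, eigen decomposition and the ID/G models."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import pedigreml as pg
from pedigreml.correlations import (Level, PairwiseCorrelation,
                                    assemble_matrix, eigen_summary,
                                    mean_spatial_disc, nearest_psd)


# ---------------------------------------------------------------------------
# mean spatial discrimination


def _sdisc_records(values_by_id):
    rows = []
    for iid, vals in values_by_id.items():
        for s, v in enumerate(vals, start=1):
            rows.append({"id": iid, "trait": "spatial_discrimination",
                         "session": s, "value": v, "sex": "F",
                         "rearing_group": "G1", "test_order": 0.0,
                         "cohort": 1})
    return pd.DataFrame(rows)


def test_mean_spatial_disc_averages_available_sessions():
    df = _sdisc_records({"A": [6, 7, 8], "B": [5]})
    out = mean_spatial_disc(df)
    sub = out[out.trait == "spatial_discrimination"].set_index("id")
    assert sub.loc["A", "value"] == pytest.approx(7.0)
    assert sub.loc["B", "value"] == pytest.approx(5.0)
    assert (sub["session"] == 1).all()
    assert len(sub) == 2


# ---------------------------------------------------------------------------
# matrix assembly


def _pairs(labels, vals, boundary=()):
    out = []
    k = 0
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            out.append(PairwiseCorrelation(
                labels[i], labels[j], vals[k],
                std_error=0.1, boundary=(i, j) in boundary))
            k += 1
    return out


LBL = ["a", "b", "c", "d"]


def test_assemble_full_matrix():
    m = assemble_matrix(_pairs(LBL, [0.1, 0.2, 0.3, -0.1, 0.0, 0.25]), LBL)
    assert m.values.shape == (4, 4)
    np.testing.assert_allclose(np.diag(m.values), 1.0)
    np.testing.assert_allclose(m.values, m.values.T)
    assert m.values[0, 1] == pytest.approx(0.1)


def test_boundary_estimate_is_flagged_without_se():
    m = assemble_matrix(_pairs(LBL, [0.999, 0.2, 0.3, -0.1, 0.0, 0.25],
                               boundary={(0, 1)}), LBL)
    assert m.values[0, 1] == pytest.approx(0.999)
    assert m.boundary_flags[0, 1]
    assert np.isnan(m.std_errors[0, 1])
    assert not m.boundary_flags[0, 2] and np.isfinite(m.std_errors[0, 2])


def test_duplicate_pair_is_an_error():
    pairs = _pairs(LBL, [0.1, 0.2, 0.3, -0.1, 0.0, 0.25])
    pairs.append(PairwiseCorrelation("a", "b", 0.5, 0.1, False))
    with pytest.raises(ValueError, match="duplicate"):
        assemble_matrix(pairs, LBL)


def test_missing_pair_is_an_error():
    pairs = _pairs(LBL, [0.1, 0.2, 0.3, -0.1, 0.0, 0.25])[:-1]
    with pytest.raises(ValueError, match="missing"):
        assemble_matrix(pairs, LBL)


def test_out_of_range_estimate_is_clamped_and_flagged():
    pairs = _pairs(LBL, [1.08, 0.2, 0.3, -0.1, 0.0, 0.25])
    m = assemble_matrix(pairs, LBL)
    assert m.values[0, 1] == 1.0
    assert m.boundary_flags[0, 1]


# ---------------------------------------------------------------------------
# eigen decomposition


def test_identity_matrix_has_equal_shares():
    es = eigen_summary(np.eye(4), labels=LBL)
    np.testing.assert_allclose(es.proportions, 0.25)


def test_all_ones_matrix_loads_everything_on_pc1():
    es = eigen_summary(np.ones((4, 4)), labels=LBL)
    assert es.proportions[0] == pytest.approx(1.0)
    assert es.same_sign_pc1
    assert np.all(es.loadings[:, 0] > 0)  # majority-positive convention


def test_asymmetric_input_is_rejected():
    m = np.eye(3)
    m[0, 1] = 0.5
    with pytest.raises(ValueError):
        eigen_summary(m)


@st.composite
def corr_matrices(draw):
    k = draw(st.integers(3, 5))
    rng = np.random.default_rng(draw(st.integers(0, 10_000)))
    B = rng.normal(size=(k, k + 2))
    C = B @ B.T
    d = np.sqrt(np.diag(C))
    return C / np.outer(d, d)


@given(corr_matrices())
@settings(deadline=None, derandomize=True, max_examples=30)
def test_eigen_summary_invariants(C):
    es = eigen_summary(C)
    k = C.shape[0]
    assert np.sum(es.proportions) == pytest.approx(1.0, abs=1e-8)
    assert np.sum(es.eigenvalues) == pytest.approx(k, abs=1e-8)
    assert np.all(np.diff(es.eigenvalues) <= 1e-12)
    recon = es.loadings @ np.diag(es.eigenvalues) @ es.loadings.T
    np.testing.assert_allclose(recon, C, atol=1e-8)


def test_nearest_psd_repair_is_explicit_and_unit_diagonal():
    m = np.array([[1.0, 0.95, -0.9], [0.95, 1.0, 0.9], [-0.9, 0.9, 1.0]])
    assert np.min(np.linalg.eigvalsh(m)) < 0
    rep = nearest_psd(m)
    assert np.min(np.linalg.eigvalsh(rep)) >= -1e-10
    np.testing.assert_allclose(np.diag(rep), 1.0, atol=1e-10)


# ---------------------------------------------------------------------------
# ID model on simulated structure


def _id_cfg(seed, r):
    cfg = pg.SimulationConfig(seed=seed, n_per_cohort=200, n_cohorts=2,
                              survival_rate=0.4,
                              r_G=pg.simulate._uniform_corr(r, 4),
                              r_PE=pg.simulate._uniform_corr(r, 4))
    return cfg


def _prepared(cfg):
    ds = pg.simulate_dataset(cfg)
    rec = ds.records
    for t in pg.TRAITS:
        rec = pg.scale_sessions(rec, t)
    return ds, rec


def test_id_model_null_covariance_yields_weak_correlations():
    ds, rec = _prepared(_id_cfg(101, 0.0))
    res = pg.fit_id_model(rec, compute_se=False)
    off = res.matrix.values[~np.eye(4, dtype=bool)]
    # each pairwise r_P has sampling SE near 0.08 at this size: every
    # estimate stays far below any real signal and centred on zero
    assert np.all(np.abs(off) < 0.25)
    assert np.mean(np.abs(off)) < 0.10
    assert res.matrix.to_dict()["labels"] == pg.TRAITS


def test_id_model_general_factor_dominates_pc1():
    ds, rec = _prepared(_id_cfg(103, 0.9))
    res = pg.fit_id_model(rec, compute_se=False)
    assert res.eigen.proportions[0] > 0.5
    assert res.eigen.same_sign_pc1
    # structural contract: matrix invariants hold
    m = res.matrix
    assert np.allclose(np.diag(m.values), 1.0)
    assert np.all(np.abs(m.values) <= 1.0)
    # global test df equals the number of freed covariance parameters
    assert res.global_test.null_spec == ("chisq", 13)


# ---------------------------------------------------------------------------
# partial G plan


def test_g_partial_near_zero_truth_and_structure():
    """Mean pairwise genetic correlation near zero when none was simulated;
    six pairwise estimates cover the four traits."""
    ests = []
    for seed in (301, 302, 303):
        cfg = _id_cfg(seed, 0.0)
        ds, rec = _prepared(cfg)
        A = pg.additive_relationship(ds.pedigree)
        res = pg.fit_g_partial(rec, A, compute_se=False)
        assert len(res.pairwise) == 6
        pairs = {tuple(sorted((p.trait_a, p.trait_b))) for p in res.pairwise}
        assert len(pairs) == 6
        ests.extend(p.value for p in res.pairwise)
    assert abs(np.mean(ests)) < 0.2


def test_g_bivariate_boundary_flag_under_high_rg_low_va():
    """|r_G| driven to the +1 boundary is flagged, not raised."""
    traits = {
        "inhibitory_control": pg.TraitSim(sessions=1, mu=5.0, G0=[[0.05]],
                                          P0=None, V_R=1.0,
                                          session_slope=0.0),
        "spatial_discrimination": pg.TraitSim(sessions=3, mu=6.0,
                                              G0=[[0.05]], P0=[[0.2]],
                                              V_R=1.0),
    }
    flagged = 0
    for seed in range(401, 409):
        cfg = pg.SimulationConfig(seed=seed, n_per_cohort=120, n_cohorts=2,
                                  survival_rate=0.5, traits=traits,
                                  r_G=[[1.0, 0.95], [0.95, 1.0]],
                                  r_PE=np.eye(2))
        ds, rec = _prepared(cfg)
        A = pg.additive_relationship(ds.pedigree)
        res = pg.fit_g_partial(rec, A, compute_se=False)
        assert len(res.pairwise) == 1
        p = res.pairwise[0]
        if p.boundary:
            flagged += 1
            assert p.std_error is None
    assert flagged >= 1
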