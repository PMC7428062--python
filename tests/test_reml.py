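"""REML engine: marginal covariance assembly and likelihood correctness.

The independent oracle is a brute-force evaluation of the restricted
log-likelihood through the explicit projection-matrix formula with dense
inverses — no code shared with the engine's grouped/rotated paths.
"""

import numpy as np
import pytest

import pedigreml as pg
from pedigreml.reml import (MixedModelData, RandomTerm, RemlError,
                            default_start, fit_reml, marginal_covariance,
                            reml_loglik, _ParamMap)


def brute_force_reml(V, X, y):
    """-1/2 [log|V| + log|X'V^-1 X| + y'Py] via explicit inverses."""
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    P = Vi - Vi @ X @ np.linalg.inv(XtViX) @ X.T @ Vi
    _, ld_v = np.linalg.slogdet(V)
    _, ld_x = np.linalg.slogdet(XtViX)
    return -0.5 * (ld_v + ld_x + y @ P @ y)


def toy_data(two_terms=True):
    """6 records: parent P, offspring O (other parent unknown), unrelated U,
    two sessions each at s = -1, 0."""
    rng = np.random.default_rng(42)
    inds = np.array(["P", "P", "O", "O", "U", "U"])
    s = np.array([-1.0, 0.0, -1.0, 0.0, -1.0, 0.0])
    X = np.column_stack([np.ones(6), s])
    y = rng.normal(5.0, 1.0, size=6)
    A = np.array([[1.0, 0.5, 0.0], [0.5, 1.0, 0.0], [0.0, 0.0, 1.0]])
    Zg = np.column_stack([np.ones(6), s])
    terms = [RandomTerm("genetic", ["t:int", "t:slope"], Zg, genetic=True)]
    if two_terms:
        terms.append(RandomTerm("individual", ["t:int"], np.ones((6, 1))))
    return MixedModelData(
        y=y, X=X, x_names=["intercept", "s"], individuals=inds,
        trait_codes=np.zeros(6, dtype=int), trait_names=["t"],
        residual_free=[True], terms=terms, A=A,
        unique_individuals=["P", "O", "U"],
    )


G0 = np.array([[0.8, 0.2], [0.2, 0.3]])
P0 = np.array([[0.4]])
SIGMAS = {"genetic": G0, "individual": P0}
RESID = {"t": 0.6}


# ---------------------------------------------------------------------------
# marginal covariance


def test_marginal_covariance_matches_hand_assembly():
    data = toy_data()
    V = marginal_covariance(data, SIGMAS, RESID)
    # independent element-by-element assembly
    inds = data.individuals
    A = {("P", "O"): 0.5, ("O", "P"): 0.5}
    s = np.array([-1.0, 0.0] * 3)
    expect = np.zeros((6, 6))
    for i in range(6):
        for j in range(6):
            phi_i = np.array([1.0, s[i]])
            phi_j = np.array([1.0, s[j]])
            a = 1.0 if inds[i] == inds[j] else A.get((inds[i], inds[j]), 0.0)
            expect[i, j] = a * phi_i @ G0 @ phi_j
            if inds[i] == inds[j]:
                expect[i, j] += P0[0, 0]
            if i == j:
                expect[i, j] += 0.6
    np.testing.assert_allclose(V, expect, atol=1e-12)


def test_marginal_covariance_phi_algebra_single_individual():
    # one individual, two sessions, genetic-only identity G0 -> [[2,1],[1,1]]
    data = MixedModelData(
        y=np.zeros(2), X=np.ones((2, 1)), x_names=["intercept"],
        individuals=np.array(["A", "A"]), trait_codes=np.zeros(2, dtype=int),
        trait_names=["t"], residual_free=[True],
        terms=[RandomTerm("genetic", ["t:int", "t:slope"],
                          np.array([[1.0, -1.0], [1.0, 0.0]]), genetic=True)],
        A=np.array([[1.0]]), unique_individuals=["A"],
    )
    V = marginal_covariance(data, {"genetic": np.eye(2)}, {"t": 0.0})
    np.testing.assert_allclose(V, [[2.0, 1.0], [1.0, 1.0]], atol=1e-12)


def test_marginal_covariance_unrelated_intercept_only_is_block_diagonal():
    data = toy_data(two_terms=True)
    # zero out relatedness: replace A by identity via unrelated individuals
    data.A = np.eye(3)
    V = marginal_covariance(data, {"genetic": np.diag([0.5, 0.0]),
                                   "individual": [[0.3]]}, {"t": 0.2})
    offblock = V[np.ix_([0, 1], [2, 3, 4, 5])]
    np.testing.assert_allclose(offblock, 0.0, atol=1e-15)
    np.testing.assert_allclose(np.diag(V), 0.5 + 0.3 + 0.2, atol=1e-12)


def test_marginal_covariance_rejects_non_psd():
    data = toy_data()
    bad = {"genetic": np.array([[1.0, 2.0], [2.0, 1.0]]),
           "individual": P0}
    with pytest.raises(RemlError):
        marginal_covariance(data, bad, RESID)


# ---------------------------------------------------------------------------
# likelihood correctness


def test_loglik_matches_brute_force_on_toy():
    data = toy_data()
    V = marginal_covariance(data, SIGMAS, RESID)
    expect = brute_force_reml(V, data.X, data.y)
    assert reml_loglik(data, SIGMAS, RESID) == pytest.approx(expect, abs=1e-8)
    assert reml_loglik(data, SIGMAS, RESID, dense=True) == pytest.approx(
        expect, abs=1e-8)


def test_rotated_and_dense_paths_agree_on_larger_data():
    cfg = pg.SimulationConfig(seed=7, n_per_cohort=40, n_cohorts=2,
                              survival_rate=0.6)
    ds = pg.simulate_dataset(cfg)
    rec = pg.scale_sessions(ds.records, "visual_discrimination")
    A = pg.additive_relationship(ds.pedigree)
    from pedigreml.model import _univariate_data

    data = _univariate_data(rec, "visual_discrimination", 2, 2, A)
    sig = {"genetic": np.array([[0.4, 0.05], [0.05, 0.1]]),
           "individual": np.array([[0.3, 0.0], [0.0, 0.05]])}
    res = {"visual_discrimination": 1.2}
    fast = reml_loglik(data, sig, res)
    dense = reml_loglik(data, sig, res, dense=True)
    assert fast == pytest.approx(dense, abs=1e-8)


def test_translation_invariance_with_intercept():
    data = toy_data()
    base = reml_loglik(data, SIGMAS, RESID)
    data2 = toy_data()
    data2.y = data.y + 17.3
    assert reml_loglik(data2, SIGMAS, RESID) == pytest.approx(base, abs=1e-8)


def test_zero_variance_term_equals_model_without_it():
    data = toy_data(two_terms=True)
    with_zero = reml_loglik(
        data, {"genetic": np.zeros((2, 2)), "individual": P0}, RESID)
    reduced = toy_data(two_terms=True)
    reduced.terms = [t for t in reduced.terms if t.name == "individual"]
    reduced.A = None
    reduced.unique_individuals = None
    without = reml_loglik(reduced, {"individual": P0}, RESID)
    assert with_zero == pytest.approx(without, abs=1e-8)


def test_reference_level_choice_does_not_move_loglik():
    rng = np.random.default_rng(9)
    n_ind, m = 20, 3
    inds = np.repeat([f"I{i}" for i in range(n_ind)], m)
    sex = np.repeat(rng.integers(0, 2, n_ind), m)
    y = rng.normal(0, 1, n_ind * m) + 0.5 * sex
    X1 = np.column_stack([np.ones(n_ind * m), sex])          # ref = F
    X2 = np.column_stack([np.ones(n_ind * m), 1 - sex])      # ref = M

    def make(X):
        return MixedModelData(
            y=y, X=X, x_names=["intercept", "sex"], individuals=inds,
            trait_codes=np.zeros(n_ind * m, dtype=int), trait_names=["t"],
            residual_free=[True],
            terms=[RandomTerm("individual", ["t:int"],
                              np.ones((n_ind * m, 1)))])

    sig = {"individual": [[0.5]]}
    assert reml_loglik(make(X1), sig, {"t": 1.0}) == pytest.approx(
        reml_loglik(make(X2), sig, {"t": 1.0}), abs=1e-8)


# ---------------------------------------------------------------------------
# fitting


def balanced_oneway(n_ind=40, m=4, vb=0.6, vw=1.0, seed=21):
    rng = np.random.default_rng(seed)
    b = rng.normal(0, np.sqrt(vb), n_ind)
    y = (b[:, None] + rng.normal(0, np.sqrt(vw), (n_ind, m))).ravel()
    inds = np.repeat([f"I{i}" for i in range(n_ind)], m)
    return MixedModelData(
        y=y, X=np.ones((n_ind * m, 1)), x_names=["intercept"],
        individuals=inds, trait_codes=np.zeros(n_ind * m, dtype=int),
        trait_names=["t"], residual_free=[True],
        terms=[RandomTerm("individual", ["t:int"], np.ones((n_ind * m, 1)))])


def test_balanced_intercept_fit_matches_anova_estimators():
    n_ind, m = 40, 4
    data = balanced_oneway(n_ind, m)
    fit = fit_reml(data, compute_se=False)
    Y = data.y.reshape(n_ind, m)
    ssw = ((Y - Y.mean(1, keepdims=True)) ** 2).sum()
    msw = ssw / (n_ind * (m - 1))
    msb = m * ((Y.mean(1) - Y.mean()) ** 2).sum() / (n_ind - 1)
    assert fit.resid["t"] == pytest.approx(msw, abs=1e-6)
    assert fit.sigmas["individual"][0, 0] == pytest.approx(
        (msb - msw) / m, abs=1e-6)


def test_multistart_stability():
    data = toy_data()
    pm = _ParamMap.build(data)
    s0, r0 = default_start(data)
    base = pm.pack(s0, r0, data)
    logliks = []
    for scale in (0.5, 1.0, 2.0):
        fit = fit_reml(toy_data(), start=base * scale, compute_se=False)
        logliks.append(fit.loglik)
    assert max(logliks) - min(logliks) < 1e-4


def test_zero_genetic_variance_is_flagged_at_boundary():
    # phenotypes with no genetic signal: independent individual effects only
    cfg = pg.SimulationConfig(seed=13, n_per_cohort=100, n_cohorts=2,
                              survival_rate=0.5)
    for t in cfg.traits.values():
        t.G0 = np.zeros_like(t.G0)
    cfg.r_G = np.eye(4)
    ds = pg.simulate_dataset(cfg)
    rec = pg.scale_sessions(ds.records, "visual_discrimination")
    A = pg.additive_relationship(ds.pedigree)
    fit = pg.fit_univariate(rec, "visual_discrimination", A,
                            id_dims=1, gen_dims=1, compute_se=False)
    va = fit.sigmas["genetic"][0, 0]
    vp = va + fit.sigmas["individual"][0, 0] + fit.resid["visual_discrimination"]
    assert va / vp < 0.05
    if fit.boundary_flags.get("genetic[visual_discrimination:int]"):
        assert fit.std_error("genetic[visual_discrimination:int]") is None


def test_nonconvergence_is_reported_not_silent():
    data = balanced_oneway(10, 2)
    fit = fit_reml(data, max_iter=1, compute_se=False)
    assert isinstance(fit.converged, bool)  # never raises for slow progress
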