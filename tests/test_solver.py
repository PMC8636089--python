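"""Unit tests for the proximal operators, block updates and the full solve."""

import numpy as np
import pytest
from numpy.testing import assert_allclose

from lorsen import (
    DimensionError,
    EQTLDataset,
    HyperParams,
    ModelFit,
    SolverConfig,
    column_l2_shrink,
    elastic_net_prox_exact,
    fit_lorsen,
    objective_value,
    soft_threshold,
    svt,
    update_B,
    update_L,
    update_mu,
)
from lorsen.tuning import lambda_max

from conftest import random_fit, random_instance
from oracles import nuclear_norm, scalar_prox_brute


# ---------------------------------------------------------------------------
# proximal operators: closed-form cases
# ---------------------------------------------------------------------------

def test_svt_on_diagonal_matrix_shrinks_singular_values():
    A = np.diag([3.0, 1.0, 0.5])
    assert_allclose(svt(A, 1.0), np.diag([2.0, 0.0, 0.0]), atol=1e-12)


def test_svt_identity_at_zero_threshold():
    rng = np.random.default_rng(0)
    A = rng.standard_normal((5, 3))
    assert_allclose(svt(A, 0.0), A)


def test_svt_solves_its_defining_problem_better_than_perturbations():
    # global minimizer of 1/2||A-L||^2 + tau||L||_*: any perturbation is worse
    rng = np.random.default_rng(1)
    A = rng.standard_normal((6, 4))
    tau = 0.7
    L = svt(A, tau)
    f0 = 0.5 * np.sum((A - L) ** 2) + tau * nuclear_norm(L)
    for _ in range(50):
        P = L + 0.1 * rng.standard_normal(A.shape)
        assert 0.5 * np.sum((A - P) ** 2) + tau * nuclear_norm(P) >= f0 - 1e-12


@pytest.mark.parametrize(
    "vec,tau,expected",
    [([2.0, -0.5, 0.1], 1.0, [1.0, 0.0, 0.0]), ([2.0, -0.5], 0.0, [2.0, -0.5])],
)
def test_soft_threshold_hand_cases(vec, tau, expected):
    assert_allclose(soft_threshold(np.array(vec), tau), expected)


def test_soft_threshold_matches_scalar_prox_oracle():
    rng = np.random.default_rng(2)
    for a in rng.standard_normal(25) * 3:
        x = soft_threshold(np.array([a]), 0.3)[0]
        assert abs(x - scalar_prox_brute(a, lambda z: 0.3 * abs(z))) < 1e-6


def test_column_l2_shrink_formula_and_zero_branch():
    assert_allclose(column_l2_shrink(np.array([3.0, 4.0]), 1.0), [2.4, 3.2])
    assert_allclose(column_l2_shrink(np.array([0.3, 0.4]), 1.0), [0.0, 0.0])


def test_column_l2_shrink_minimizes_group_prox_problem():
    # minimizer of 1/2||b - x||^2 + lam*||x||_2 is colinear with b; reduce to
    # the scalar length problem and solve it by bounded search
    rng = np.random.default_rng(3)
    for _ in range(20):
        b = rng.standard_normal(4) * 2
        lam = 0.8
        x = column_l2_shrink(b, lam)
        nb = np.linalg.norm(b)
        c = scalar_prox_brute(nb, lambda t: lam * abs(t), lo=0.0, hi=nb + 1)
        assert_allclose(x, (c / nb) * b, atol=1e-6)


def test_elastic_net_prox_exact_degenerate_and_scaling_cases():
    b = np.array([2.0, -4.0])
    assert_allclose(
        elastic_net_prox_exact(b, 1.0, 0.5, 0.0), soft_threshold(b, 0.5)
    )
    assert_allclose(elastic_net_prox_exact(b, 1.0, 0.0, 1.0), [1.0, -2.0])


def test_elastic_net_prox_exact_matches_scalar_oracle_grid():
    rng = np.random.default_rng(4)
    for t, lam1, lam2 in [(0.5, 0.2, 0.4), (1.0, 1.0, 1.0), (2.0, 0.1, 3.0)]:
        for a in rng.standard_normal(10) * 3:
            x = elastic_net_prox_exact(np.array([a]), t, lam1, lam2)[0]
            brute = scalar_prox_brute(
                a, lambda z: t * (lam1 * abs(z) + 0.5 * lam2 * z * z)
            )
            assert abs(x - brute) < 1e-6


# ---------------------------------------------------------------------------
# objective
# ---------------------------------------------------------------------------

def test_objective_zero_model_on_zero_data_is_zero():
    data = EQTLDataset(X=np.zeros((2, 2)), Y=np.zeros((2, 2)))
    fit = ModelFit(B=np.zeros((2, 2)), L=np.zeros((2, 2)), mu=np.zeros(2))
    assert objective_value(data, fit, HyperParams(rho=1.0, alpha=0.5, lam=2.0)) == 0


def test_objective_direct_arithmetic_1x1():
    # 1/2 (2 - 1)^2 + rho*0 + lam1*|1| + lam2/2*1 = 0.5 + 1 + 1 = 2.5
    data = EQTLDataset(X=np.array([[1.0]]), Y=np.array([[2.0]]))
    fit = ModelFit(B=np.array([[1.0]]), L=np.zeros((1, 1)), mu=np.zeros(1))
    hp = HyperParams(rho=1.0, alpha=1.0 / 3.0, lam=3.0)  # lam1=1, lam2=2
    assert objective_value(data, fit, hp) == pytest.approx(2.5, abs=1e-12)


def test_objective_matches_independent_term_by_term_formula():
    data = random_instance(5, n=5, p=8, q=4, missing=0.3)
    rng = np.random.default_rng(6)
    fit = random_fit(rng, data)
    hp = HyperParams(rho=0.7, alpha=0.4, lam=1.3)
    R = (data.X @ fit.B + fit.L + fit.mu[None, :] - np.nan_to_num(data.Y)) * data.omega
    expected = (
        0.5 * np.sum(R**2)
        + hp.rho * nuclear_norm(fit.L)
        + hp.lam1 * np.abs(fit.B).sum()
        + 0.5 * hp.lam2 * np.sum(fit.B**2)
    )
    assert objective_value(data, fit, hp) == pytest.approx(expected, abs=1e-10)


def test_objective_raises_structured_dimension_error():
    data = random_instance(7)
    fit = ModelFit(B=np.zeros((data.p + 1, data.q)), L=np.zeros((data.n, data.q)),
                   mu=np.zeros(data.q))
    with pytest.raises(DimensionError, match="B"):
        objective_value(data, fit, HyperParams(rho=1.0))


# ---------------------------------------------------------------------------
# block updates
# ---------------------------------------------------------------------------

def test_update_L_with_zero_residual_reduces_to_svt():
    data = random_instance(8, n=6, p=3, q=4)
    rng = np.random.default_rng(8)
    L = rng.standard_normal((6, 4))
    B = rng.standard_normal((3, 4))
    mu = rng.standard_normal(4)
    Y = data.X @ B + L + mu[None, :]
    d = EQTLDataset(X=data.X, Y=Y)
    fit = ModelFit(B=B, L=L, mu=mu)
    hp = HyperParams(rho=0.9)
    assert_allclose(update_L(d, fit, hp, SolverConfig()), svt(L, 0.9), atol=1e-12)


def test_update_L_rho_zero_is_plain_gradient_step():
    data = random_instance(9, missing=0.25)
    rng = np.random.default_rng(9)
    fit = random_fit(rng, data)
    G = (data.X @ fit.B + fit.L + fit.mu[None, :] - np.nan_to_num(data.Y)) * data.omega
    assert_allclose(
        update_L(data, fit, HyperParams(rho=0.0), SolverConfig()), fit.L - G,
        atol=1e-12,
    )


def test_block_gradients_match_finite_differences():
    data = random_instance(10, n=5, p=3, q=2, missing=0.3)
    rng = np.random.default_rng(10)
    fit = random_fit(rng, data)

    def loss(B, L, mu):
        R = (data.X @ B + L + mu[None, :] - np.nan_to_num(data.Y)) * data.omega
        return 0.5 * np.sum(R**2)

    eps = 1e-6
    # L gradient via the rho=0 update (step t_L = 1): L - grad
    gL = fit.L - update_L(data, fit, HyperParams(rho=0.0), SolverConfig())
    for idx in [(0, 0), (2, 1), (4, 1)]:
        Lp, Lm = fit.L.copy(), fit.L.copy()
        Lp[idx] += eps
        Lm[idx] -= eps
        fd = (loss(fit.B, Lp, fit.mu) - loss(fit.B, Lm, fit.mu)) / (2 * eps)
        assert gL[idx] == pytest.approx(fd, abs=1e-5)
    # B gradient via the lam=0 update
    cfg = SolverConfig(step_B=0.01)
    gB = (fit.B - update_B(data, fit, HyperParams(rho=0.0, lam=0.0), cfg)) / 0.01
    for idx in [(0, 0), (1, 1), (2, 0)]:
        Bp, Bm = fit.B.copy(), fit.B.copy()
        Bp[idx] += eps
        Bm[idx] -= eps
        fd = (loss(Bp, fit.L, fit.mu) - loss(Bm, fit.L, fit.mu)) / (2 * eps)
        assert gB[idx] == pytest.approx(fd, abs=1e-4)
    # mu gradient
    gmu = (fit.mu - update_mu(data, fit, SolverConfig())) * data.n
    for j in range(data.q):
        mp, mm = fit.mu.copy(), fit.mu.copy()
        mp[j] += eps
        mm[j] -= eps
        fd = (loss(fit.B, fit.L, mp) - loss(fit.B, fit.L, mm)) / (2 * eps)
        assert gmu[j] == pytest.approx(fd, abs=1e-5)


def test_update_B_zero_residual_lam2_zero_is_soft_threshold():
    data = random_instance(11, n=6, p=3, q=2)
    rng = np.random.default_rng(11)
    B = rng.standard_normal((3, 2))
    Y = data.X @ B
    d = EQTLDataset(X=data.X, Y=Y)
    fit = ModelFit(B=B, L=np.zeros((6, 2)), mu=np.zeros(2))
    hp = HyperParams(rho=1.0, alpha=1.0, lam=2.0)  # lam1=2, lam2=0
    t_B = 1.0 / np.linalg.norm(data.X, 2) ** 2
    assert_allclose(
        update_B(d, fit, hp, SolverConfig()), soft_threshold(B, t_B * 2.0),
        atol=1e-10,
    )


def test_update_B_as_printed_equals_hand_composed_chain():
    data = random_instance(12, n=7, p=4, q=3, missing=0.2)
    rng = np.random.default_rng(12)
    fit = random_fit(rng, data)
    hp = HyperParams(rho=1.0, alpha=0.6, lam=1.1)
    t_B = 1.0 / np.linalg.norm(data.X, 2) ** 2
    R = (data.X @ fit.B + fit.L + fit.mu[None, :] - np.nan_to_num(data.Y)) * data.omega
    Ba = fit.B - t_B * data.X.T @ R
    Bb = soft_threshold(Ba, t_B * hp.lam1)
    expected = np.column_stack(
        [column_l2_shrink(Bb[:, j], t_B * hp.lam2) for j in range(data.q)]
    )
    assert_allclose(update_B(data, fit, hp, SolverConfig()), expected, atol=1e-12)


def test_update_mu_zero_residual_is_identity_and_mean_step():
    data = random_instance(13, n=5, p=2, q=3)
    mu = np.array([0.3, -1.0, 2.0])
    Y = np.broadcast_to(mu, (5, 3)).copy()
    d = EQTLDataset(X=data.X, Y=Y)
    fit = ModelFit(B=np.zeros((2, 3)), L=np.zeros((5, 3)), mu=mu)
    assert_allclose(update_mu(d, fit, SolverConfig()), mu, atol=1e-12)
    # from mu=0 with B=L=0 and full omega, one step at t=1/n lands on col means
    fit0 = ModelFit(B=np.zeros((2, 3)), L=np.zeros((5, 3)), mu=np.zeros(3))
    assert_allclose(update_mu(d, fit0, SolverConfig()), Y.mean(axis=0), atol=1e-12)


# ---------------------------------------------------------------------------
# full solver behavior
# ---------------------------------------------------------------------------

def test_trace_monotone_with_restart_and_final_below_initial_without():
    data = random_instance(14, n=10, p=5, q=4, missing=0.2, latent_rank=2)
    hp = HyperParams(rho=1.0, alpha=0.5, lam=0.5)
    fit = fit_lorsen(data, hp, SolverConfig(tol=1e-10, max_outer_iter=500))
    tr = np.array(fit.objective_trace)
    assert np.all(np.diff(tr) <= 1e-10)
    fit2 = fit_lorsen(
        data, hp, SolverConfig(tol=1e-10, max_outer_iter=500, fista_restart=False)
    )
    assert fit2.objective_trace[-1] <= fit2.objective_trace[0]


def test_line_search_reaches_same_objective_as_constant_steps():
    data = random_instance(15, n=9, p=4, q=3, latent_rank=1)
    hp = HyperParams(rho=0.8, alpha=0.5, lam=0.6)
    f_const = fit_lorsen(
        data, hp, SolverConfig(tol=1e-12, max_outer_iter=3000)
    ).objective_trace[-1]
    f_ls = fit_lorsen(
        data, hp,
        SolverConfig(tol=1e-12, max_outer_iter=3000, use_line_search=True,
                     step_B=1.0, step_L=2.0),
    ).objective_trace[-1]
    assert f_ls == pytest.approx(f_const, rel=1e-6)


def test_lasso_mode_is_column_separable():
    # lam2=0, L frozen at 0, full mask: joint fit equals per-column fits
    data = random_instance(16, n=12, p=5, q=3)
    hp = HyperParams(rho=1.0, alpha=1.0, lam=0.8)
    cfg = SolverConfig(tol=1e-13, max_outer_iter=8000)
    joint = fit_lorsen(data, hp, cfg, freeze_L=True)
    for j in range(data.q):
        dj = EQTLDataset(X=data.X, Y=data.Y[:, [j]])
        single = fit_lorsen(dj, hp, cfg, freeze_L=True)
        assert np.max(np.abs(joint.B[:, j] - single.B[:, 0])) < 1e-6


def test_masked_entries_cannot_influence_the_fit():
    data = random_instance(17, n=8, p=4, q=3, missing=0.3)
    hp = HyperParams(rho=0.5, alpha=0.5, lam=0.4)
    cfg = SolverConfig(tol=1e-10, max_outer_iter=400)
    fit1 = fit_lorsen(data, hp, cfg)
    Y2 = np.where(data.omega == 1, np.nan_to_num(data.Y), 123.456)
    data2 = EQTLDataset(X=data.X, Y=Y2, omega=data.omega)
    fit2 = fit_lorsen(data2, hp, cfg)
    assert np.array_equal(fit1.B, fit2.B)
    assert np.array_equal(fit1.L, fit2.L)
    assert np.array_equal(fit1.mu, fit2.mu)


def test_nonconvergence_is_flagged_with_warning():
    data = random_instance(18, n=10, p=4, q=3, latent_rank=2)
    hp = HyperParams(rho=0.1, alpha=0.5, lam=0.01)
    with pytest.warns(RuntimeWarning, match="did not converge"):
        fit = fit_lorsen(data, hp, SolverConfig(tol=1e-14, max_outer_iter=3))
    assert not fit.converged
    assert fit.n_iter == 3


def test_elastic_net_selects_beyond_n_while_l1_saturates():
    # correlated predictor groups, more true effects than samples: the mixed
    # penalty keeps groups, the pure L1 can keep at most n predictors/column
    rng = np.random.default_rng(19)
    n, p, q, k_true = 20, 100, 2, 40
    Z = rng.standard_normal((n, 10))
    X = np.repeat(Z, 10, axis=1) + 0.1 * rng.standard_normal((n, p))
    X = (X - X.mean(axis=0)) / X.std(axis=0)
    B = np.zeros((p, q))
    B[:k_true] = rng.uniform(0.5, 1.0, size=(k_true, q))
    Y = X @ B + 0.1 * rng.standard_normal((n, q))
    data = EQTLDataset(X=X, Y=Y)
    cfg = SolverConfig(tol=1e-10, max_outer_iter=4000,
                       penalty_variant="exact_elastic_net")
    lam = 0.1 * lambda_max(X, Y, 1.0)
    fit_en = fit_lorsen(data, HyperParams(rho=1e6, alpha=0.5, lam=lam), cfg)
    fit_l1 = fit_lorsen(data, HyperParams(rho=1e6, alpha=1.0, lam=lam), cfg)
    assert int((np.abs(fit_en.B).max(axis=1) > 1e-10).sum()) > 20
    for j in range(q):
        assert int((np.abs(fit_l1.B[:, j]) > 1e-8).sum()) <= n
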