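"""Independent reference implementations used only as test oracles.

These deliberately avoid the package's alternating solver: the composite
convex program is minimized over the stacked variable (B, L, mu) by a
single-block proximal-gradient iteration with a conservative global step,
and the proximal operators are checked against direct numerical
minimization of their defining problems.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize


def nuclear_norm(A: np.ndarray) -> float:
    return float(np.linalg.svd(A, compute_uv=False).sum())


def program_objective(X, Yz, omega, B, L, mu, rho, lam1, lam2, variant):
    """The convex program the alternating solver targets (see solver docs)."""
    R = (X @ B + L + mu[None, :] - Yz) * omega
    val = 0.5 * float(np.sum(R * R)) + rho * nuclear_norm(L)
    val += lam1 * float(np.abs(B).sum())
    if variant == "exact_elastic_net":
        val += 0.5 * lam2 * float(np.sum(B * B))
    else:  # group-L2 columnwise penalty implied by the printed shrink
        val += lam2 * float(np.linalg.norm(B, axis=0).sum())
    return val


def _prox_joint(B, L, t, rho, lam1, lam2, variant):
    # penalty is separable across blocks -> joint prox is blockwise
    U, s, Vt = np.linalg.svd(L, full_matrices=False)
    L_new = (U * np.maximum(s - t * rho, 0.0)) @ Vt
    Bs = np.sign(B) * np.maximum(np.abs(B) - t * lam1, 0.0)
    if variant == "exact_elastic_net":
        B_new = Bs / (1.0 + t * lam2)
    else:
        nrm = np.linalg.norm(Bs, axis=0)
        B_new = Bs * (1.0 - (t * lam2) / np.maximum(nrm, t * lam2)) if lam2 > 0 else Bs
    return B_new, L_new


def solve_joint_fista(
    X,
    Yz,
    omega,
    rho,
    lam1,
    lam2,
    variant,
    max_iter=30000,
    tol=1e-14,
):
    """Monolithic FISTA on the stacked variable; a different decomposition
    from the package's alternating block scheme, run to high precision."""
    n, p = X.shape
    q = Yz.shape[1]
    # conservative global Lipschitz bound for the stacked linear map
    ell = float(np.linalg.norm(X, 2) ** 2 + 1.0 + n)
    t = 1.0 / ell
    B = np.zeros((p, q))
    L = np.zeros((n, q))
    mu = np.zeros(q)
    yB, yL, ymu = B.copy(), L.copy(), mu.copy()
    tk = 1.0
    f_prev = program_objective(X, Yz, omega, B, L, mu, rho, lam1, lam2, variant)
    for _ in range(max_iter):
        R = (X @ yB + yL + ymu[None, :] - Yz) * omega
        gB = X.T @ R
        gL = R
        gmu = R.sum(axis=0)
        B_new, L_new = _prox_joint(yB - t * gB, yL - t * gL, t, rho, lam1, lam2, variant)
        mu_new = ymu - t * gmu
        f_new = program_objective(
            X, Yz, omega, B_new, L_new, mu_new, rho, lam1, lam2, variant
        )
        if f_new > f_prev:  # adaptive restart
            yB, yL, ymu, tk = B.copy(), L.copy(), mu.copy(), 1.0
            R = (X @ yB + yL + ymu[None, :] - Yz) * omega
            B_new, L_new = _prox_joint(
                yB - t * (X.T @ R), yL - t * R, t, rho, lam1, lam2, variant
            )
            mu_new = ymu - t * R.sum(axis=0)
            f_new = program_objective(
                X, Yz, omega, B_new, L_new, mu_new, rho, lam1, lam2, variant
            )
        tk_new = 0.5 * (1 + np.sqrt(1 + 4 * tk * tk))
        coef = (tk - 1) / tk_new
        yB = B_new + coef * (B_new - B)
        yL = L_new + coef * (L_new - L)
        ymu = mu_new + coef * (mu_new - mu)
        B, L, mu, tk = B_new, L_new, mu_new, tk_new
        if abs(f_new - f_prev) <= tol * max(1.0, abs(f_prev)):
            f_prev = f_new
            break
        f_prev = f_new
    return B, L, mu, f_prev


# ---------------------------------------------------------------------------
# brute-force proximal-operator minimizers
# ---------------------------------------------------------------------------

def scalar_prox_brute(a: float, weight_fn, lo=-50.0, hi=50.0) -> float:
    """argmin_x 1/2 (a - x)^2 + weight_fn(x) by bounded scalar minimization."""
    res = optimize.minimize_scalar(
        lambda x: 0.5 * (a - x) ** 2 + weight_fn(x),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-12},
    )
    return float(res.x)


def matrix_prox_numeric(A: np.ndarray, penalty_fn, x0=None, restarts=3, seed=0):
    """Minimize 1/2||A - Z||_F^2 + penalty_fn(Z) with a derivative-free
    solver from several starts; returns the best objective found."""
    rng = np.random.default_rng(seed)
    shape = A.shape

    def f(z):
        Z = z.reshape(shape)
        return 0.5 * float(np.sum((A - Z) ** 2)) + penalty_fn(Z)

    best = np.inf
    starts = [np.zeros(A.size), A.ravel()]
    for _ in range(restarts):
        starts.append(A.ravel() + 0.3 * rng.standard_normal(A.size))
    for z0 in starts:
        res = optimize.minimize(
            f, z0, method="Powell", options={"xtol": 1e-12, "ftol": 1e-14,
                                             "maxiter": 20000}
        )
        best = min(best, float(res.fun))
    return best


def pairwise_auc_brute(scores: np.ndarray, labels: np.ndarray) -> float:
    """O(P*N) average of 1{s+ > s-} + 1/2 * 1{s+ = s-}."""
    pos = scores[labels]
    neg = scores[~labels]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))


def hc_brute(pvalues, alpha0=0.5) -> float:
    """Direct evaluation of the higher-criticism maximand."""
    p = np.clip(np.sort(np.asarray(pvalues, float)), 1e-15, 1 - 1e-15)
    q = len(p)
    vals = []
    upper = max(int(np.floor(alpha0 * q)), 1)
    for j in range(1, upper + 1):
        pj = p[j - 1]
        vals.append(np.sqrt(q) * (j / q - pj) / np.sqrt(pj * (1 - pj)))
    return float(max(vals))
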