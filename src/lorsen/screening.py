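"""SNP pre-screening ahead of the joint multi-SNP model.

Two rankings are provided.  LORS-Screening fits, for every SNP separately,
the single-predictor low-rank model

    min_{beta_i, L, mu} 1/2 ||Y - X_i beta_i^T - L - 1 mu^T||_F^2 + rho ||L||_*,

keeps each gene's top-n SNPs by absolute coefficient and returns the union.
HC-Screening converts each SNP's standardized coefficient vector into
two-sided normal p-values, summarizes them with the higher-criticism
statistic, and keeps the top min(n, p) SNPs.  The shared nuclear-norm
weight rho is chosen once on the no-SNP confounder model and reused.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import stats

from .datatypes import EQTLDataset, HyperParams, SolverConfig
from .solver import fit_lorsen
from .tuning import default_rho_candidates, select_rho, split_omega

__all__ = [
    "ScreeningResult",
    "lors_screen",
    "hc_statistic",
    "hc_screen",
    "single_snp_coefficients",
]

_P_CLIP = 1e-15


@dataclass
class ScreeningResult:
    """Retained SNP indices (ascending) with per-SNP scores and the method tag.

    ``scores`` is indexed by original SNP position: the largest per-gene
    |coefficient| for method "lors", the HC statistic for method "hc".
    """

    kept_indices: np.ndarray
    scores: np.ndarray
    method: str


def _select_screening_rho(data: EQTLDataset, cfg: SolverConfig) -> float:
    split = split_omega(data.omega, cfg.seed)
    cands = default_rho_candidates(data.Y, split.omega1)
    return select_rho(data, split, cands, cfg)


def single_snp_coefficients(
    data: EQTLDataset,
    cfg: Optional[SolverConfig] = None,
    rho: Optional[float] = None,
    estimator: str = "single_snp",
) -> Tuple[np.ndarray, np.ndarray]:
    """Per-SNP coefficient vectors beta_i and their standard errors.

    estimator "single_snp": each SNP gets its own low-rank fit (the
    screening program above); the coefficient standard error is the OLS
    standard error of the single-SNP regression after removing that fit's
    L and mu from Y.  estimator "marginal": one no-SNP confounder fit is
    computed, Y is residualized once, and all p simple-regression
    coefficients follow from a single matrix product — an order-preserving
    fast path suited to large p.

    Returns (coef, se), both p x q.
    """
    cfg = cfg or SolverConfig()
    if rho is None:
        rho = _select_screening_rho(data, cfg)
    n, p, q = data.n, data.p, data.q
    omega = data.omega
    coef = np.zeros((p, q))
    se = np.zeros((p, q))
    dof = max(n - 2, 1)

    if estimator == "marginal":
        null_fit = fit_lorsen(
            data, HyperParams(rho=rho, alpha=1.0, lam=0.0), cfg, freeze_B=True
        )
        Ytil = (data.Y_observed - null_fit.L - null_fit.mu[None, :]) * omega
        Xc = data.X - data.X.mean(axis=0, keepdims=True)
        cnt = omega.sum(axis=0)
        ymean = np.divide(Ytil.sum(axis=0), cnt, out=np.zeros(q), where=cnt > 0)
        Yc = (Ytil - ymean[None, :]) * omega
        xnorm2 = np.maximum(np.sum(Xc * Xc, axis=0), 1e-300)
        coef = (Xc.T @ Yc) / xnorm2[:, None]
        rss = np.maximum(
            np.sum(Yc * Yc, axis=0)[None, :] - coef**2 * xnorm2[:, None], 0.0
        )
        se = np.sqrt(rss / dof) / np.sqrt(xnorm2)[:, None]
        return coef, se

    if estimator != "single_snp":
        raise ValueError(f"unknown estimator {estimator!r}")

    hp0 = HyperParams(rho=rho, alpha=1.0, lam=0.0)
    for i in range(p):
        sub = EQTLDataset(X=data.X[:, [i]], Y=data.Y, omega=omega)
        try:
            fit = fit_lorsen(sub, hp0, cfg)
        except Exception as exc:  # pragma: no cover - defensive
            raise RuntimeError(f"single-SNP fit failed for SNP index {i}") from exc
        coef[i] = fit.B[0]
        resid = (
            data.Y_observed - data.X[:, [i]] @ fit.B - fit.L - fit.mu[None, :]
        ) * omega
        xc = data.X[:, i] - data.X[:, i].mean()
        xnorm2 = max(float(xc @ xc), 1e-300)
        rss = np.sum(resid * resid, axis=0)
        se[i] = np.sqrt(rss / dof) / np.sqrt(xnorm2)
    return coef, se


def lors_screen(
    data: EQTLDataset,
    cfg: Optional[SolverConfig] = None,
    rho: Optional[float] = None,
    estimator: str = "single_snp",
) -> ScreeningResult:
    """Union over genes of each gene's top-n SNPs by |coefficient|."""
    cfg = cfg or SolverConfig()
    coef, _ = single_snp_coefficients(data, cfg, rho=rho, estimator=estimator)
    n, p = data.n, data.p
    top = min(n, p)
    absc = np.abs(coef)
    kept = set()
    for j in range(data.q):
        # stable ranking: descending |coef|, SNP index breaks ties
        order = np.lexsort((np.arange(p), -absc[:, j]))
        kept.update(order[:top].tolist())
    kept_idx = np.array(sorted(kept), dtype=int)
    return ScreeningResult(
        kept_indices=kept_idx, scores=absc.max(axis=1), method="lors"
    )


def hc_statistic(pvalues) -> float:
    """Higher-criticism statistic of a p-value vector.

    With order statistics p_(1) <= ... <= p_(q), returns

        max_{1 <= j <= q/2} sqrt(q) * (j/q - p_(j)) / sqrt(p_(j) (1 - p_(j))).

    Values numerically equal to 0 or 1 are clipped before the formula;
    values outside [0, 1] are rejected.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("pvalues must be nonempty")
    if np.any(p < 0) or np.any(p > 1) or not np.all(np.isfinite(p)):
        raise ValueError("pvalues must lie in (0, 1)")
    p = np.clip(np.sort(p), _P_CLIP, 1 - _P_CLIP)
    q = p.size
    j = np.arange(1, q + 1)
    z = np.sqrt(q) * (j / q - p) / np.sqrt(p * (1 - p))
    upper = max(q // 2, 1)
    return float(z[:upper].max())


def hc_screen(
    data: EQTLDataset,
    cfg: Optional[SolverConfig] = None,
    rho: Optional[float] = None,
    estimator: str = "single_snp",
) -> ScreeningResult:
    """Top min(n, p) SNPs by descending higher-criticism statistic.

    Each SNP's q standardized coefficients (beta / se) are converted to
    two-sided normal p-values and summarized by ``hc_statistic``; ranking
    by the statistic itself is order-equivalent to ranking by any monotone
    p-value transform of it.
    """
    cfg = cfg or SolverConfig()
    coef, se = single_snp_coefficients(data, cfg, rho=rho, estimator=estimator)
    n, p = data.n, data.p
    z = np.divide(coef, se, out=np.zeros_like(coef), where=se > 0)
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    hc = np.array([hc_statistic(pvals[i]) for i in range(p)])
    keep = min(n, p)
    order = np.lexsort((np.arange(p), -hc))
    kept_idx = np.array(sorted(order[:keep].tolist()), dtype=int)
    return ScreeningResult(kept_indices=kept_idx, scores=hc, method="hc")
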