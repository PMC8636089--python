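"""Synthetic eQTL data generator.

Expression is built as Y = X B + U + e: sparse genotype effects, a
low-rank hidden-confounder contribution and unit-variance Gaussian noise.
Hidden structure follows the k-factor recipe: H is n x k standard normal,
Sigma = H H^T, and each gene's confounder column is drawn N(0, 0.1 Sigma).
Effect sizes come from uniform laws — "weak" U(0.25, 0.75) paired with
m = 50 target genes per causal SNP (the weak-dense regime) or "strong"
U(1.5, 2) with m = 10 (strong-sparse) — with mixed and sign-mixed
variants.  Genotypes are synthetic additive 0/1/2 codes with
Gaussian-copula AR(1) linkage disequilibrium within blocks, standing in
for real reference-panel genotypes so that nothing needs downloading.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import stats

from .datatypes import ConfigError

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "scenario_preset",
    "simulate_genotypes",
    "simulate_expression",
    "simulate_dataset",
    "make_missing",
]

_EFFECT_LAWS = {"weak": (0.25, 0.75), "strong": (1.5, 2.0)}


@dataclass
class SimulationConfig:
    """Study-design parameters for one synthetic dataset.

    Defaults mirror the reference simulation design: n = 165 samples,
    p = 2000 SNPs, q = 200 genes, k = 15 hidden factors, 60 causal SNPs.
    ``effect_law`` is "weak", "strong", "mixed" (half the causal SNPs weak,
    half strong) or "mixed_sign" (magnitudes from ``mixed_sign_law``, half
    the causal SNPs' effects negated).  ``rare_fraction`` of SNPs get a
    minor-allele frequency below the rare-variant cutoff 0.03.
    """

    n: int = 165
    p: int = 2000
    q: int = 200
    k: int = 15
    n_causal: int = 60
    m: int = 10
    effect_law: str = "strong"
    mixed_sign_law: str = "weak"
    rare_fraction: float = 0.0
    genotype_source: str = "synthetic"
    ld_block_size: int = 20
    ld_rho: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_causal > self.p:
            raise ConfigError(f"n_causal={self.n_causal} exceeds p={self.p}")
        if self.m > self.q:
            raise ConfigError(f"m={self.m} exceeds q={self.q}")
        if not (0 <= self.rare_fraction <= 1):
            raise ConfigError("rare_fraction must lie in [0, 1]")
        if self.effect_law not in ("weak", "strong", "mixed", "mixed_sign"):
            raise ConfigError(f"unknown effect_law {self.effect_law!r}")
        if self.mixed_sign_law not in _EFFECT_LAWS:
            raise ConfigError(f"unknown mixed_sign_law {self.mixed_sign_law!r}")
        if self.ld_block_size < 1:
            raise ConfigError("ld_block_size must be >= 1")


@dataclass
class SimulationTruth:
    """Ground truth behind one simulated expression matrix."""

    B_true: np.ndarray
    causal_set: np.ndarray
    U: np.ndarray
    e: np.ndarray
    H: np.ndarray
    Sigma: np.ndarray


_PRESETS = {
    # canonical regimes: dense weak effects vs sparse strong effects
    "weak-dense": {"m": 50, "effect_law": "weak"},
    "strong-sparse": {"m": 10, "effect_law": "strong"},
}


def scenario_preset(name: str, **overrides) -> SimulationConfig:
    """Named scenario ("weak-dense" or "strong-sparse") with overrides."""
    if name not in _PRESETS:
        raise ConfigError(f"unknown scenario {name!r}; choose from {sorted(_PRESETS)}")
    kw = dict(_PRESETS[name])
    kw.update(overrides)
    return SimulationConfig(**kw)


def _draw_block(rng, n: int, size: int, rho: float) -> np.ndarray:
    """Latent Gaussian block with AR(1) correlation rho^{|i-j|}."""
    if size == 1 or rho == 0:
        return rng.standard_normal((n, size))
    Z = rng.standard_normal((n, size))
    out = np.empty_like(Z)
    out[:, 0] = Z[:, 0]
    c = np.sqrt(1.0 - rho * rho)
    for j in range(1, size):
        out[:, j] = rho * out[:, j - 1] + c * Z[:, j]
    return out


def simulate_genotypes(cfg: SimulationConfig, rng=None) -> np.ndarray:
    """Additive 0/1/2 genotypes with blockwise AR(1) copula LD.

    Per-SNP minor-allele frequencies are U(0.05, 0.5), except a
    ``rare_fraction`` of SNPs drawn U(0.005, 0.03).  Genotypes follow
    Hardy-Weinberg proportions through the Gaussian copula; monomorphic
    columns are redrawn.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    n, p = cfg.n, cfg.p
    maf = rng.uniform(0.05, 0.5, size=p)
    n_rare = int(round(cfg.rare_fraction * p))
    if n_rare:
        rare_idx = rng.choice(p, size=n_rare, replace=False)
        maf[rare_idx] = rng.uniform(0.005, 0.03, size=n_rare)
    X = np.empty((n, p))
    for start in range(0, p, cfg.ld_block_size):
        stop = min(start + cfg.ld_block_size, p)
        Z = _draw_block(rng, n, stop - start, cfg.ld_rho)
        U = stats.norm.cdf(Z)
        f = maf[start:stop]
        p0 = (1.0 - f) ** 2  # P(0 minor alleles) under HWE
        X[:, start:stop] = (U > p0) + (U > p0 + 2 * f * (1 - f))
    # redraw monomorphic columns independently (rare-MAF columns may fixate)
    for _ in range(100):
        mono = np.flatnonzero(X.std(axis=0) == 0)
        if mono.size == 0:
            break
        Z = rng.standard_normal((n, mono.size))
        U = stats.norm.cdf(Z)
        f = maf[mono]
        p0 = (1.0 - f) ** 2
        X[:, mono] = (U > p0) + (U > p0 + 2 * f * (1 - f))
    return X


def _draw_effects(rng, law: Tuple[float, float], size: int) -> np.ndarray:
    lo, hi = law
    return rng.uniform(lo, hi, size=size)


def simulate_expression(
    X: np.ndarray, cfg: SimulationConfig, rng=None, H: Optional[np.ndarray] = None
) -> Tuple[np.ndarray, SimulationTruth]:
    """Expression Y = X B + U + e with the configured effect structure.

    Causal SNPs are drawn uniformly without replacement; each influences
    exactly ``m`` uniformly chosen genes (gene sets may overlap across
    SNPs).  U's columns are i.i.d. N(0, 0.1 Sigma) with Sigma = H H^T;
    noise is standard normal.  Passing ``H`` conditions on a fixed factor
    matrix (e.g. to draw replicates sharing the same hidden structure).
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    X = np.asarray(X, dtype=float)
    if X.shape[0] != cfg.n:
        raise ConfigError(f"X has {X.shape[0]} rows, config expects n={cfg.n}")
    n, p, q, k = cfg.n, X.shape[1], cfg.q, cfg.k
    if cfg.n_causal > p:
        raise ConfigError(f"n_causal={cfg.n_causal} exceeds p={p}")

    if H is None:
        H = rng.standard_normal((n, k))
    else:
        H = np.asarray(H, dtype=float)
        if H.shape != (n, k):
            raise ConfigError(f"H must be {n} x {k}, got {H.shape}")
    Sigma = H @ H.T
    # U_j = sqrt(0.1) H z_j with z_j ~ N(0, I_k) gives Cov(U_j) = 0.1 Sigma
    U = np.sqrt(0.1) * H @ rng.standard_normal((k, q))
    e = rng.standard_normal((n, q))

    causal = np.sort(rng.choice(p, size=cfg.n_causal, replace=False))
    B = np.zeros((p, q))
    if cfg.effect_law == "mixed":
        # half the causal SNPs carry weak effects, half strong (split by SNP)
        shuffled = rng.permutation(causal)
        half = cfg.n_causal // 2
        law_of = {int(s): "weak" for s in shuffled[:half]}
        law_of.update({int(s): "strong" for s in shuffled[half:]})
    elif cfg.effect_law == "mixed_sign":
        shuffled = rng.permutation(causal)
        half = cfg.n_causal // 2
        negated = set(int(s) for s in shuffled[:half])
    for s in causal:
        genes = rng.choice(q, size=cfg.m, replace=False)
        if cfg.effect_law == "mixed":
            law = _EFFECT_LAWS[law_of[int(s)]]
        elif cfg.effect_law == "mixed_sign":
            law = _EFFECT_LAWS[cfg.mixed_sign_law]
        else:
            law = _EFFECT_LAWS[cfg.effect_law]
        eff = _draw_effects(rng, law, cfg.m)
        if cfg.effect_law == "mixed_sign" and int(s) in negated:
            eff = -eff
        B[s, genes] = eff

    Y = X @ B + U + e
    truth = SimulationTruth(B_true=B, causal_set=causal, U=U, e=e, H=H, Sigma=Sigma)
    return Y, truth


def simulate_dataset(cfg: SimulationConfig):
    """Genotypes + expression + truth from one seeded stream.

    Returns (X, Y, truth); a convenience wrapper used by the CLI and tests.
    """
    rng = np.random.default_rng(cfg.seed)
    X = simulate_genotypes(cfg, rng)
    Y, truth = simulate_expression(X, cfg, rng)
    return X, Y, truth


def make_missing(
    Y: np.ndarray, rate: float, seed: int
) -> Tuple[np.ndarray, np.ndarray]:
    """Hide a uniform random fraction of entries; returns (Y_obs, omega).

    Hidden entries of the returned expression matrix are NaN and omega is
    0 there.
    """
    if not (0 <= rate < 1):
        raise ValueError(f"rate must lie in [0, 1), got {rate}")
    Y = np.asarray(Y, dtype=float)
    rng = np.random.default_rng(seed)
    hidden = rng.random(Y.shape) < rate
    omega = (~hidden).astype(float)
    Y_obs = Y.copy()
    Y_obs[hidden] = np.nan
    return Y_obs, omega
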