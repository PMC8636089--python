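"""Shared containers for eQTL model fitting.

The central objects are a genotype/expression dataset with an observation
mask, the penalty configuration (nuclear-norm weight ``rho``, elastic-net
mixing ``alpha`` and overall sparsity weight ``lam``), solver controls, and
the fitted model (coefficients ``B``, hidden-factor contribution ``L`` and
per-gene intercepts ``mu``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np


class LorsenError(Exception):
    """Base class for structured errors raised by this package."""


class DimensionError(LorsenError, ValueError):
    """Raised when an operand's shape is inconsistent with the dataset."""

    def __init__(self, operand: str, expected, got) -> None:
        self.operand = operand
        super().__init__(
            f"dimension mismatch for {operand!r}: expected {expected}, got {got}"
        )


class ConfigError(LorsenError, ValueError):
    """Raised for invalid solver or simulation configuration."""


@dataclass
class EQTLDataset:
    """Genotypes ``X`` (n x p, additive 0/1/2 codes), expression ``Y`` (n x q).

    ``omega`` is the binary observation mask over ``Y``: 1 marks an observed
    entry, 0 a missing one.  Missing entries of ``Y`` never enter any loss;
    they may hold NaN or any finite placeholder.  Optional genomic positions
    (``(chromosome, bp)`` per SNP / probe midpoint) enable local/distant
    classification downstream.
    """

    X: np.ndarray
    Y: np.ndarray
    omega: Optional[np.ndarray] = None
    snp_positions: Optional[Sequence[Tuple]] = None
    probe_positions: Optional[Sequence[Tuple]] = None
    snp_ids: Optional[Sequence[str]] = None
    probe_ids: Optional[Sequence[str]] = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float)
        if self.X.ndim != 2:
            raise DimensionError("X", "2-d matrix", self.X.shape)
        if self.Y.ndim != 2:
            raise DimensionError("Y", "2-d matrix", self.Y.shape)
        if self.X.shape[0] != self.Y.shape[0]:
            raise DimensionError("Y", f"({self.X.shape[0]}, q)", self.Y.shape)
        if not np.all(np.isfinite(self.X)):
            raise ValueError("X must not contain missing or non-finite entries")
        if self.omega is None:
            self.omega = np.ones(self.Y.shape)
            # NaNs in Y are taken as missing when no mask is given
            self.omega[np.isnan(self.Y)] = 0.0
        self.omega = np.asarray(self.omega, dtype=float)
        if self.omega.shape != self.Y.shape:
            raise DimensionError("omega", self.Y.shape, self.omega.shape)
        if not np.all((self.omega == 0) | (self.omega == 1)):
            raise ValueError("omega entries must be 0 or 1")
        if np.any(self.omega[~np.isfinite(self.Y)] == 1):
            raise ValueError("Y must be defined (finite) wherever omega == 1")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def q(self) -> int:
        return self.Y.shape[1]

    @property
    def Y_observed(self) -> np.ndarray:
        """Y with unobserved entries replaced by 0 (safe for masked algebra)."""
        return np.where(self.omega == 1, self.Y, 0.0)

    def with_omega(self, omega: np.ndarray) -> "EQTLDataset":
        """Same data under a different (sub-)mask, e.g. a training split."""
        return EQTLDataset(
            X=self.X,
            Y=np.where(np.asarray(omega) == 1, self.Y, np.nan),
            omega=omega,
            snp_positions=self.snp_positions,
            probe_positions=self.probe_positions,
            snp_ids=self.snp_ids,
            probe_ids=self.probe_ids,
        )


@dataclass
class HyperParams:
    """Penalty weights: ``lam1 = lam * alpha`` (L1), ``lam2 = lam * (1 - alpha)``."""

    rho: float
    alpha: float = 1.0
    lam: float = 0.0

    def __post_init__(self) -> None:
        if self.rho < 0:
            raise ConfigError(f"rho must be nonnegative, got {self.rho}")
        if not (0 < self.alpha <= 1):
            raise ConfigError(f"alpha must be in (0, 1], got {self.alpha}")
        if self.lam < 0:
            raise ConfigError(f"lam must be nonnegative, got {self.lam}")

    @property
    def lam1(self) -> float:
        return self.lam * self.alpha

    @property
    def lam2(self) -> float:
        return self.lam * (1.0 - self.alpha)


@dataclass
class SolverConfig:
    """Controls for the alternating FISTA solver.

    ``step_*`` may be "auto" (reciprocal Lipschitz constants: t_L = 1,
    t_B = 1/||X||_2^2, t_mu = 1/n) or explicit positive floats.
    ``penalty_variant`` selects how the B-block prox treats the elastic-net
    term: "as_printed" composes elementwise soft-thresholding with a
    columnwise L2 shrink (a sparse-group prox), "exact_elastic_net" applies
    the exact prox of lam1*|.|_1 + (lam2/2)*|.|^2.  With
    ``as_printed_threshold`` the shrinkage levels are used literally
    (unscaled by the step size).
    """

    step_L: object = "auto"
    step_B: object = "auto"
    step_mu: object = "auto"
    use_line_search: bool = False
    max_outer_iter: int = 500
    max_inner_iter: int = 30
    tol: float = 1e-5
    penalty_variant: str = "as_printed"
    as_printed_threshold: bool = False
    fista_restart: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tol <= 0:
            raise ConfigError(f"tol must be positive, got {self.tol}")
        if self.penalty_variant not in ("as_printed", "exact_elastic_net"):
            raise ConfigError(f"unknown penalty_variant {self.penalty_variant!r}")
        for name in ("step_L", "step_B", "step_mu"):
            v = getattr(self, name)
            if v != "auto" and (not np.isscalar(v) or float(v) <= 0):
                raise ConfigError(f"{name} must be 'auto' or a positive number")
        if self.max_outer_iter < 1:
            raise ConfigError("max_outer_iter must be >= 1")


@dataclass
class ModelFit:
    """Result of a solve: coefficients, confounders, intercepts, diagnostics."""

    B: np.ndarray
    L: np.ndarray
    mu: np.ndarray
    objective_trace: list = field(default_factory=list)
    converged: bool = False
    n_iter: int = 0

    def __post_init__(self) -> None:
        self.B = np.asarray(self.B, dtype=float)
        self.L = np.asarray(self.L, dtype=float)
        self.mu = np.asarray(self.mu, dtype=float)
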