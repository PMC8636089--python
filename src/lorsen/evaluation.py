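"""Scoring fitted effect matrices against simulation truth.

Every (SNP, gene) pair is one classification instance: score
|B_hat[i, j]|, label 1{B_true[i, j] != 0}.  Detection power is the
Mann-Whitney AUC with midrank tie handling (the mass of exact zeros in a
sparse estimate all ties at score 0 and contributes 1/2 per pair).  False
positive rates are reported at fixed absolute-coefficient thresholds, and
replicate AUCs are summarized by a t-interval.  SNP-gene pairs are
classified as local (cis) or distant (trans) from genomic coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Sequence, Tuple

import numpy as np
from scipy import stats

__all__ = [
    "EvalResult",
    "pairwise_auc",
    "fpr_at_thresholds",
    "replicate_ci",
    "classify_cis_trans",
    "DEFAULT_FPR_THRESHOLDS",
    "LOCAL_MAX_BP",
    "DISTANT_MIN_BP",
]

DEFAULT_FPR_THRESHOLDS = (0.0, 1e-12, 1e-6, 1e-4)
LOCAL_MAX_BP = 250_000       # < 250 kb on the same chromosome -> local
DISTANT_MIN_BP = 5_000_000   # > 5 Mb or different chromosome -> distant


@dataclass
class EvalResult:
    """Summary over replicates: mean AUC with 95% CI, FPR by threshold."""

    auc: float
    fpr_by_threshold: Dict[float, float]
    n_replicates: int
    ci95: Tuple[float, float]


def pairwise_auc(B_hat: np.ndarray, B_true: np.ndarray) -> float:
    """Mann-Whitney AUC of |B_hat| against the nonzero pattern of B_true.

    Midrank tie correction: tied scores (including the zero mass)
    contribute 1/2 per (positive, negative) pair.
    """
    B_hat = np.asarray(B_hat, dtype=float)
    B_true = np.asarray(B_true, dtype=float)
    if B_hat.shape != B_true.shape:
        raise ValueError(
            f"shape mismatch: B_hat {B_hat.shape} vs B_true {B_true.shape}"
        )
    labels = (B_true != 0).ravel()
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0:
        raise ValueError("degenerate truth: no nonzero (positive) entries")
    if n_neg == 0:
        raise ValueError("degenerate truth: no zero (negative) entries")
    ranks = stats.rankdata(np.abs(B_hat).ravel(), method="average")
    r_pos = ranks[labels].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def fpr_at_thresholds(
    B_hat: np.ndarray,
    B_true: np.ndarray,
    thresholds: Sequence[float] = DEFAULT_FPR_THRESHOLDS,
) -> Dict[float, float]:
    """False positive rate #{|B_hat| > tau, B_true = 0} / #{B_true = 0}."""
    B_hat = np.asarray(B_hat, dtype=float)
    B_true = np.asarray(B_true, dtype=float)
    if B_hat.shape != B_true.shape:
        raise ValueError(
            f"shape mismatch: B_hat {B_hat.shape} vs B_true {B_true.shape}"
        )
    null = B_true == 0
    n_null = int(null.sum())
    if n_null == 0:
        raise ValueError("no true-negative entries: every pair is causal")
    a = np.abs(B_hat[null])
    return {float(t): float(np.mean(a > t)) for t in thresholds}


def replicate_ci(values: Sequence[float]) -> Tuple[float, float, float]:
    """(mean, low, high): mean +/- t_{0.975, r-1} * sd / sqrt(r)."""
    v = np.asarray(list(values), dtype=float)
    if v.size < 2:
        raise ValueError(f"need at least 2 replicate values, got {v.size}")
    mean = float(v.mean())
    half = float(stats.t.ppf(0.975, v.size - 1) * v.std(ddof=1) / np.sqrt(v.size))
    return mean, mean - half, mean + half


def classify_cis_trans(
    snp_pos: Tuple[object, float], probe_mid: Tuple[object, float]
) -> str:
    """"local", "distant" or "unclassified" for one SNP-probe pair.

    Local: same chromosome and distance < 250 kb to the probe midpoint.
    Distant: different chromosome, or distance > 5 Mb.  Pairs in between
    are unclassified.
    """
    chrom_s, bp_s = snp_pos
    chrom_p, bp_p = probe_mid
    if bp_s < 0 or bp_p < 0:
        raise ValueError("genomic coordinates must be nonnegative")
    if str(chrom_s) != str(chrom_p):
        return "distant"
    d = abs(float(bp_s) - float(bp_p))
    if d < LOCAL_MAX_BP:
        return "local"
    if d > DISTANT_MIN_BP:
        return "distant"
    return "unclassified"


def evaluate_replicates(
    pairs: Sequence[Tuple[np.ndarray, np.ndarray]],
    thresholds: Sequence[float] = DEFAULT_FPR_THRESHOLDS,
) -> EvalResult:
    """Per-replicate AUC averaged with a 95% t-interval; FPRs averaged."""
    aucs = [pairwise_auc(bh, bt) for bh, bt in pairs]
    fprs = [fpr_at_thresholds(bh, bt, thresholds) for bh, bt in pairs]
    mean_fpr = {
        float(t): float(np.mean([f[float(t)] for f in fprs])) for t in thresholds
    }
    if len(aucs) >= 2:
        mean, lo, hi = replicate_ci(aucs)
    else:
        mean, lo, hi = aucs[0], aucs[0], aucs[0]
    return EvalResult(
        auc=mean, fpr_by_threshold=mean_fpr, n_replicates=len(aucs), ci95=(lo, hi)
    )
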