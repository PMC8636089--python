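"""Readers and writers for genotype, expression and result tables.

Genotypes enter as PLINK .bed/.bim/.fam triples (SNP-major binary bed) or
as delimited text matrices; expression as a samples x probes TSV with NA
for missing cells.  Results leave as ranked SNP-probe tables.  Genotype
coding counts minor-allele copies; by default the minor allele is
recomputed from sample frequencies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .datatypes import EQTLDataset, LorsenError, ModelFit
from .evaluation import classify_cis_trans

logger = logging.getLogger("lorsen")

__all__ = [
    "GenotypeData",
    "read_genotypes",
    "write_genotypes_tsv",
    "read_plink",
    "write_plink",
    "read_expression",
    "ExpressionData",
    "align_samples",
    "ranked_pairs",
    "write_ranked_pairs",
]

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])
# 2-bit codes in a SNP-major .bed byte, LSB first:
#   00 -> homozygous A1 (2 copies), 01 -> missing, 10 -> het, 11 -> hom A2
_BED_CODE_TO_DOSAGE = {0: 2.0, 1: np.nan, 2: 1.0, 3: 0.0}


@dataclass
class GenotypeData:
    X: np.ndarray
    snp_ids: list
    chromosomes: list
    positions: list  # 1-based bp
    sample_ids: list


@dataclass
class ExpressionData:
    Y: np.ndarray
    omega: np.ndarray
    probe_ids: list
    sample_ids: list


# ---------------------------------------------------------------------------
# PLINK binary
# ---------------------------------------------------------------------------

def read_plink(prefix) -> GenotypeData:
    """Read a .bed/.bim/.fam triple; returns additive dosages with metadata.

    SNPs containing any missing call are dropped (with a logged count).
    The returned dosage counts A1 alleles as stored; allele orientation is
    handled by the caller (see ``read_genotypes``).
    """
    prefix = Path(prefix)
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "snp", "cm", "bp", "a1", "a2"],
        dtype={"chrom": str, "snp": str},
    )
    fam = pd.read_csv(
        prefix.with_suffix(".fam"),
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"],
        dtype=str,
    )
    n, p = len(fam), len(bim)
    raw = prefix.with_suffix(".bed").read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise LorsenError(
            f"{prefix.with_suffix('.bed')} lacks the SNP-major PLINK magic bytes"
        )
    bytes_per_snp = (n + 3) // 4
    body = raw[3:]
    if len(body) != bytes_per_snp * p:
        raise LorsenError(
            f".bed payload has {len(body)} bytes; expected {bytes_per_snp * p} "
            f"for {n} samples x {p} SNPs (.bim/.fam mismatch or truncation)"
        )
    data = np.frombuffer(body, dtype=np.uint8).reshape(p, bytes_per_snp)
    # unpack 2-bit fields, LSB first
    codes = np.stack(
        [(data >> shift) & 0b11 for shift in (0, 2, 4, 6)], axis=-1
    ).reshape(p, -1)[:, :n]
    lut = np.array([2.0, np.nan, 1.0, 0.0])
    X = lut[codes].T  # n x p
    missing = np.isnan(X).any(axis=0)
    if missing.any():
        logger.warning(
            "dropping %d SNP(s) with missing genotype calls", int(missing.sum())
        )
    keep = ~missing
    return GenotypeData(
        X=X[:, keep],
        snp_ids=bim.loc[keep, "snp"].tolist(),
        chromosomes=bim.loc[keep, "chrom"].tolist(),
        positions=bim.loc[keep, "bp"].astype(int).tolist(),
        sample_ids=fam["iid"].tolist(),
    )


def write_plink(
    prefix,
    X: np.ndarray,
    snp_ids: Sequence[str],
    chromosomes: Sequence,
    positions: Sequence[int],
    sample_ids: Sequence[str],
    a1: str = "A",
    a2: str = "B",
) -> None:
    """Write additive 0/1/2 dosages as a SNP-major .bed/.bim/.fam triple.

    The dosage is interpreted as the count of allele A1.
    """
    prefix = Path(prefix)
    X = np.asarray(X)
    n, p = X.shape
    if not np.all(np.isin(X, (0, 1, 2))):
        raise LorsenError("PLINK output requires genotype codes in {0, 1, 2}")
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for j in range(p):
            fh.write(
                f"{chromosomes[j]}\t{snp_ids[j]}\t0\t{int(positions[j])}\t{a1}\t{a2}\n"
            )
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for s in sample_ids:
            fh.write(f"{s}\t{s}\t0\t0\t0\t-9\n")
    dosage_to_code = {2: 0b00, 1: 0b10, 0: 0b11}
    buf = bytearray(_BED_MAGIC)
    for j in range(p):
        for start in range(0, n, 4):
            byte = 0
            for k, i in enumerate(range(start, min(start + 4, n))):
                byte |= dosage_to_code[int(X[i, j])] << (2 * k)
            buf.append(byte)
    prefix.with_suffix(".bed").write_bytes(bytes(buf))


# ---------------------------------------------------------------------------
# delimited text
# ---------------------------------------------------------------------------

def write_genotypes_tsv(
    path,
    X: np.ndarray,
    snp_ids: Sequence[str],
    sample_ids: Sequence[str],
    chromosomes: Optional[Sequence] = None,
    positions: Optional[Sequence[int]] = None,
) -> None:
    """Samples x SNPs TSV (first column = sample id, header = SNP ids).

    Positions, when given, are written alongside as ``<path>.pos.tsv``.
    """
    df = pd.DataFrame(np.asarray(X), index=list(sample_ids), columns=list(snp_ids))
    df.index.name = "sample"
    df.to_csv(path, sep="\t")
    if chromosomes is not None and positions is not None:
        pos = pd.DataFrame(
            {"snp": list(snp_ids), "chrom": list(chromosomes),
             "bp": [int(b) for b in positions]}
        )
        pos.to_csv(str(path) + ".pos.tsv", sep="\t", index=False)


def _read_matrix_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise LorsenError(f"{path}: duplicate sample IDs")
    if df.columns.has_duplicates:
        raise LorsenError(f"{path}: duplicate column IDs")
    return df


def read_genotypes(
    path, format: str = "plink_bed", minor_allele: str = "recompute"
) -> GenotypeData:
    """Load genotypes from PLINK binary ("plink_bed") or TSV ("tsv").

    ``minor_allele="recompute"`` flips columns whose stored allele is the
    sample-major one so that codes count minor-allele copies;
    ``"trust_bim"`` keeps the stored orientation.
    """
    if format == "plink_bed":
        g = read_plink(path)
    elif format == "tsv":
        df = _read_matrix_tsv(path)
        X = df.to_numpy(dtype=float)
        if np.isnan(X).any():
            bad = np.isnan(X).any(axis=0)
            logger.warning(
                "dropping %d SNP(s) with missing genotype calls", int(bad.sum())
            )
            df = df.loc[:, ~bad]
            X = df.to_numpy(dtype=float)
        chroms, pos = [None] * df.shape[1], [0] * df.shape[1]
        pos_path = Path(str(path) + ".pos.tsv")
        if pos_path.exists():
            pdf = pd.read_csv(pos_path, sep="\t", dtype={"chrom": str}).set_index("snp")
            pdf = pdf.loc[[c for c in df.columns if c in pdf.index]]
            chroms = pdf["chrom"].tolist()
            pos = pdf["bp"].astype(int).tolist()
        g = GenotypeData(
            X=X,
            snp_ids=list(df.columns),
            chromosomes=chroms,
            positions=pos,
            sample_ids=list(df.index.astype(str)),
        )
    else:
        raise LorsenError(f"unknown genotype format {format!r}")
    if not np.all(np.isin(g.X, (0, 1, 2))):
        raise LorsenError("genotype codes must be additive 0/1/2")
    if minor_allele == "recompute":
        flip = g.X.mean(axis=0) / 2.0 > 0.5
        g.X = np.where(flip[None, :], 2.0 - g.X, g.X)
    elif minor_allele != "trust_bim":
        raise LorsenError(f"unknown minor_allele policy {minor_allele!r}")
    return g


def read_expression(path) -> ExpressionData:
    """Samples x probes TSV; empty or NA cells become unobserved entries."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA", "NaN", ""])
    if df.index.has_duplicates:
        raise LorsenError(f"{path}: duplicate sample IDs")
    if df.columns.has_duplicates:
        raise LorsenError(f"{path}: duplicate probe IDs")
    try:
        Y = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise LorsenError(f"{path}: non-numeric expression cell ({exc})") from exc
    omega = (~np.isnan(Y)).astype(float)
    return ExpressionData(
        Y=Y,
        omega=omega,
        probe_ids=list(df.columns),
        sample_ids=list(df.index.astype(str)),
    )


def align_samples(g: GenotypeData, e: ExpressionData) -> EQTLDataset:
    """Join genotype and expression matrices on shared sample IDs.

    Samples present in only one input are dropped with a logged count;
    order follows the genotype file.
    """
    gidx = {s: i for i, s in enumerate(g.sample_ids)}
    eidx = {s: i for i, s in enumerate(e.sample_ids)}
    shared = [s for s in g.sample_ids if s in eidx]
    dropped = (len(g.sample_ids) - len(shared)) + (len(e.sample_ids) - len(shared))
    if dropped:
        logger.warning("dropped %d sample(s) missing from one input", dropped)
    if not shared:
        raise LorsenError("no shared sample IDs between genotypes and expression")
    gi = [gidx[s] for s in shared]
    ei = [eidx[s] for s in shared]
    snp_pos = None
    if g.chromosomes and g.chromosomes[0] is not None:
        snp_pos = list(zip(g.chromosomes, g.positions))
    return EQTLDataset(
        X=g.X[gi],
        Y=e.Y[ei],
        omega=e.omega[ei],
        snp_positions=snp_pos,
        snp_ids=g.snp_ids,
        probe_ids=e.probe_ids,
    )


def prepare_dataset(
    data: EQTLDataset, standardize_x: bool = True, center_y: bool = True
) -> EQTLDataset:
    """Column-standardize X (mean 0, variance 1) and center Y on observed
    entries.  Standardizing X makes one sparsity weight comparable across
    SNPs of different allele frequency; the intercept still absorbs any
    residual Y offset, so centering is a conditioning aid, not a model
    change."""
    X = data.X
    if standardize_x:
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    Y = data.Y
    if center_y:
        cnt = data.omega.sum(axis=0)
        Yz = data.Y_observed
        means = np.divide(Yz.sum(axis=0), cnt, out=np.zeros(data.q), where=cnt > 0)
        Y = np.where(data.omega == 1, Yz - means[None, :], np.nan)
    return EQTLDataset(
        X=X,
        Y=Y,
        omega=data.omega,
        snp_positions=data.snp_positions,
        probe_positions=data.probe_positions,
        snp_ids=data.snp_ids,
        probe_ids=data.probe_ids,
    )


# ---------------------------------------------------------------------------
# ranked results
# ---------------------------------------------------------------------------

def _fmt_distance(bp: float) -> str:
    if bp >= 1_000_000:
        return f"{bp / 1_000_000:.2f} mb"
    return f"{bp / 1_000:.2f} kb"


def ranked_pairs(
    B: np.ndarray,
    snp_ids: Sequence[str],
    probe_ids: Sequence[str],
    top_k: int,
    snp_positions: Optional[Sequence[Tuple]] = None,
    probe_positions: Optional[Sequence[Tuple]] = None,
) -> pd.DataFrame:
    """Top-k SNP-probe pairs by |coefficient| with dense 1-based ranks.

    Ties in |coefficient| break lexicographically on (snp, probe).  When
    positions are available the pair is classified local/distant/
    unclassified; otherwise "unknown".
    """
    if top_k <= 0:
        raise LorsenError(f"top_k must be positive, got {top_k}")
    B = np.asarray(B, dtype=float)
    p, q = B.shape
    nz = np.argwhere(B != 0)
    if nz.size == 0:
        nz = np.argwhere(np.ones_like(B, dtype=bool))
    recs = []
    for i, j in nz:
        coef = float(B[i, j])
        snp, probe = str(snp_ids[i]), str(probe_ids[j])
        if snp_positions is not None and probe_positions is not None:
            cls = classify_cis_trans(snp_positions[i], probe_positions[j])
            chrom_s, bp_s = snp_positions[i]
            chrom_p, bp_p = probe_positions[j]
            dist = abs(float(bp_s) - float(bp_p)) if str(chrom_s) == str(chrom_p) else np.nan
        else:
            cls, dist = "unknown", np.nan
        recs.append((snp, probe, coef, abs(coef), dist, cls))
    df = pd.DataFrame(
        recs, columns=["snp", "probe", "coefficient", "abs_coef", "distance_bp", "class"]
    )
    df = df.sort_values(
        by=["abs_coef", "snp", "probe"], ascending=[False, True, True], kind="mergesort"
    ).head(top_k)
    df["abs_rank"] = np.arange(1, len(df) + 1)
    df["distance"] = [
        _fmt_distance(d) if np.isfinite(d) else "" for d in df["distance_bp"]
    ]
    return df.drop(columns=["abs_coef"]).reset_index(drop=True)


def write_ranked_pairs(
    fit: ModelFit,
    snp_ids: Sequence[str],
    probe_ids: Sequence[str],
    path,
    top_k: int = 100,
    snp_positions: Optional[Sequence[Tuple]] = None,
    probe_positions: Optional[Sequence[Tuple]] = None,
) -> pd.DataFrame:
    """Write the ranked-pair table as TSV; returns the DataFrame written."""
    df = ranked_pairs(
        fit.B, snp_ids, probe_ids, top_k, snp_positions, probe_positions
    )
    df.to_csv(path, sep="\t", index=False)
    return df
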