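"""Sample- and variant-level genotype QC with a Hardy-Weinberg exact test.

Filtering order and defaults follow standard array-QC practice: samples with
low call rate are dropped first, then — on the retained samples — variants
failing missingness, Hardy-Weinberg equilibrium (exact conditional test,
p < 1e-6), minor-allele frequency (< 0.01) or imputation quality (R2 < 0.3).
Inequalities are strict: boundary values are kept.  HWE is computed on all
retained samples pooled; per-population analyses happen downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from enum import Enum

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix


class QCConfigError(Exception):
    pass


class FailReason(str, Enum):
    """First failing check, in evaluation order."""

    MISSINGNESS = "MISSINGNESS"
    HWE = "HWE"
    MAF = "MAF"
    R2 = "R2"
    CALL_RATE = "CALL_RATE"  # samples only


@dataclass(frozen=True)
class QCThresholds:
    max_sample_missing: float = 0.05
    max_variant_missing: float = 0.05
    hwe_p_floor: float = 1e-6
    min_maf: float = 0.01
    min_impute_r2: float = 0.3
    min_call_rate: float = 0.98

    def __post_init__(self) -> None:
        for name, val in asdict(self).items():
            if not (0.0 <= val <= 1.0):
                raise QCConfigError(f"threshold {name}={val} outside [0, 1]")


@dataclass
class QCReport:
    """Per-item pass/fail decisions plus before/after counts."""

    sample_stats: pd.DataFrame  # sample_id, call_rate, missing, passed, reason
    variant_stats: pd.DataFrame  # rsid, missingness, hwe_p, maf, impute_r2, passed, reason
    counts: dict = field(default_factory=dict)

    def summary(self) -> dict:
        return dict(self.counts)

    def write(self, sample_path, variant_path) -> None:
        self.sample_stats.to_csv(sample_path, sep="\t", index=False)
        self.variant_stats.to_csv(variant_path, sep="\t", index=False)


def hwe_exact_p(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact test of Hardy-Weinberg proportions.

    Conditions on the sample size N and the minor-allele count, and sums the
    probabilities of all heterozygote counts (same parity as the minor-allele
    count) whose conditional probability does not exceed that of the observed
    count.  Monomorphic samples return exactly 1.0.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("at least one genotyped individual required")
    n1 = 2 * n_AA + n_Aa  # copies of allele A
    n2 = 2 * n_aa + n_Aa
    rare = min(n1, n2)
    if rare == 0:
        return 1.0

    # log P(het = h | N, rare) up to a shared constant:
    #   log C(N; hom1, h, hom2) + h*log 2  with hom counts determined by h
    def logw(h: int) -> float:
        hom_rare = (rare - h) // 2
        hom_common = n - h - hom_rare
        return (
            math.lgamma(n + 1)
            - math.lgamma(hom_rare + 1)
            - math.lgamma(h + 1)
            - math.lgamma(hom_common + 1)
            + h * math.log(2.0)
        )

    h_obs = n_Aa
    hs = range(rare % 2, rare + 1, 2)
    logs = np.array([logw(h) for h in hs])
    logs -= logs.max()
    weights = np.exp(logs)
    probs = weights / weights.sum()
    p_obs = probs[(h_obs - rare % 2) // 2]
    # tiny relative guard so mathematically tied counts land on the same side
    p = float(probs[probs <= p_obs * (1.0 + 1e-12)].sum())
    return min(p, 1.0)


def variant_missingness(matrix: GenotypeMatrix) -> np.ndarray:
    """Fraction of missing calls per variant column."""
    if matrix.n_samples == 0:
        raise ValueError("empty matrix")
    return np.isnan(matrix.dosage).mean(axis=0)


def sample_call_rate(matrix: GenotypeMatrix) -> np.ndarray:
    """1 - missing fraction per sample row."""
    if matrix.n_variants == 0:
        raise ValueError("empty matrix")
    return 1.0 - np.isnan(matrix.dosage).mean(axis=1)


def risk_allele_frequency(matrix: GenotypeMatrix) -> np.ndarray:
    """Risk-allele frequency per variant among non-missing calls (NaN if none)."""
    called = (~np.isnan(matrix.dosage)).sum(axis=0)
    total = np.nansum(matrix.dosage, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(called > 0, total / (2 * called), np.nan)


def maf(matrix: GenotypeMatrix) -> np.ndarray:
    """Minor-allele frequency per variant; NaN for all-missing columns."""
    f = risk_allele_frequency(matrix)
    return np.minimum(f, 1.0 - f)


def variant_hwe_p(matrix: GenotypeMatrix) -> np.ndarray:
    """Exact HWE p per variant over pooled non-missing samples (NaN if none)."""
    out = np.full(matrix.n_variants, np.nan)
    for j in range(matrix.n_variants):
        col = matrix.dosage[:, j]
        col = col[~np.isnan(col)]
        if col.size == 0:
            continue
        out[j] = hwe_exact_p(
            int((col == 2).sum()), int((col == 1).sum()), int((col == 0).sum())
        )
    return out


def apply_qc(matrix: GenotypeMatrix,
             thresholds: QCThresholds | None = None) -> tuple[GenotypeMatrix, QCReport]:
    """Filter samples then variants; every decision is recorded in the report.

    Step 1 drops samples with call rate below ``min_call_rate`` or missing
    fraction at or above ``max_sample_missing``.  Step 2, on the remaining
    samples, drops variants by first failing reason in the order
    missingness -> HWE -> MAF -> R2.  The operation is idempotent.
    """
    thresholds = thresholds or QCThresholds()

    call = sample_call_rate(matrix)
    smiss = 1.0 - call
    sample_pass = (call >= thresholds.min_call_rate) & (smiss < thresholds.max_sample_missing)
    sample_reason = np.where(sample_pass, "", FailReason.CALL_RATE.value)
    sample_stats = pd.DataFrame({
        "sample_id": matrix.sample_ids,
        "call_rate": call,
        "missing": smiss,
        "passed": sample_pass,
        "reason": sample_reason,
    })

    kept = matrix.subset(sample_idx=np.flatnonzero(sample_pass))

    vmiss = variant_missingness(kept)
    hwe_p = variant_hwe_p(kept)
    vmaf = maf(kept)
    r2 = kept.impute_r2 if kept.impute_r2 is not None else np.full(kept.n_variants, np.nan)

    reasons = np.full(kept.n_variants, "", dtype=object)
    fail_miss = vmiss >= thresholds.max_variant_missing
    fail_hwe = ~fail_miss & (np.nan_to_num(hwe_p, nan=1.0) < thresholds.hwe_p_floor)
    # all-missing columns have undefined MAF; they always trip the missingness check
    fail_maf = ~fail_miss & ~fail_hwe & (np.nan_to_num(vmaf, nan=1.0) < thresholds.min_maf)
    with np.errstate(invalid="ignore"):
        bad_r2 = np.where(np.isnan(r2), False, r2 < thresholds.min_impute_r2)
    fail_r2 = ~fail_miss & ~fail_hwe & ~fail_maf & bad_r2
    reasons[fail_miss] = FailReason.MISSINGNESS.value
    reasons[fail_hwe] = FailReason.HWE.value
    reasons[fail_maf] = FailReason.MAF.value
    reasons[fail_r2] = FailReason.R2.value
    variant_pass = reasons == ""

    variant_stats = pd.DataFrame({
        "rsid": kept.rsids,
        "missingness": vmiss,
        "hwe_p": hwe_p,
        "maf": vmaf,
        "impute_r2": r2,
        "passed": variant_pass,
        "reason": reasons.astype(str),
    })

    filtered = kept.subset(variant_idx=np.flatnonzero(variant_pass))
    counts = {
        "samples_in": matrix.n_samples,
        "samples_out": filtered.n_samples,
        "variants_in": matrix.n_variants,
        "variants_out": filtered.n_variants,
        "samples_removed": int((~sample_pass).sum()),
        "variants_removed_by_reason": {
            r.value: int((reasons == r.value).sum())
            for r in (FailReason.MISSINGNESS, FailReason.HWE, FailReason.MAF, FailReason.R2)
        },
    }
    return filtered, QCReport(sample_stats=sample_stats, variant_stats=variant_stats,
                              counts=counts)
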