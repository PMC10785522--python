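"""Weir & Cockerham (1984) variance-components Fst over the panel loci.

Per locus and per population the estimator needs the diploid sample size n_i
(non-missing calls), the allele frequency p_i and the observed heterozygote
proportion h_i.  From these it forms the among-population (a), among-
individual-within-population (b) and within-individual (c) variance
components; theta = a/(a+b+c).  The multi-locus "weighted" estimate is the
ratio of sums sum(a) / sum(a+b+c), which weights loci by information content,
not the mean of per-locus ratios.  Negative estimates are legal (sampling
noise around zero differentiation) and are reported as computed.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix

logger = logging.getLogger(__name__)


class FstError(Exception):
    pass


@dataclass
class LocusPopStats:
    """Per-locus per-population allele statistics; arrays shaped (r, n_loci)."""

    populations: list[str]
    loci: list[str]
    n: np.ndarray  # diploid sample counts with non-missing calls
    p: np.ndarray  # risk-allele frequency
    h: np.ndarray  # observed heterozygote proportion


@dataclass
class FstComponents:
    """WC variance components per locus; arrays shaped (n_loci,).

    ``theta`` is NaN where a+b+c == 0 (locus monomorphic across the
    populations) or where a population had no calls.
    """

    loci: list[str]
    a: np.ndarray
    b: np.ndarray
    c: np.ndarray

    @property
    def denominator(self) -> np.ndarray:
        return self.a + self.b + self.c

    @property
    def theta(self) -> np.ndarray:
        den = self.denominator
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(den != 0, self.a / den, np.nan)

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.a) & np.isfinite(self.b) & np.isfinite(self.c) \
            & (self.denominator != 0)


@dataclass
class PairwiseFstMatrix:
    populations: list[str]
    values: pd.DataFrame  # symmetric, NaN diagonal
    n_loci: pd.DataFrame  # loci used per pair

    def long_form(self, clip_at_zero: bool = False) -> pd.DataFrame:
        rows = []
        for p1, p2 in itertools.combinations(self.populations, 2):
            theta = self.values.loc[p1, p2]
            row = {"pop1": p1, "pop2": p2, "fst": theta,
                   "n_loci": int(self.n_loci.loc[p1, p2])}
            if clip_at_zero:
                row["fst_clipped"] = max(theta, 0.0) if np.isfinite(theta) else theta
            rows.append(row)
        return pd.DataFrame(rows)


def locus_pop_stats(matrix: GenotypeMatrix, samples: pd.DataFrame,
                    populations: list[str]) -> LocusPopStats:
    """Sample size, allele frequency and heterozygosity per locus per population."""
    pop_of = dict(zip(samples["sample_id"], samples["population"]))
    unknown = [p for p in populations if p not in set(pop_of.values())]
    if unknown:
        raise FstError(f"unknown population labels: {unknown}")
    r, L = len(populations), matrix.n_variants
    n = np.zeros((r, L))
    p = np.full((r, L), np.nan)
    h = np.full((r, L), np.nan)
    for i, pop in enumerate(populations):
        idx = [k for k, sid in enumerate(matrix.sample_ids) if pop_of.get(sid) == pop]
        dose = matrix.dosage[idx, :]
        called = ~np.isnan(dose)
        ni = called.sum(axis=0)
        n[i] = ni
        with np.errstate(invalid="ignore", divide="ignore"):
            p[i] = np.where(ni > 0, np.nansum(dose, axis=0) / (2 * ni), np.nan)
            h[i] = np.where(ni > 0, (dose == 1).sum(axis=0) / ni, np.nan)
    return LocusPopStats(populations=list(populations), loci=matrix.rsids, n=n, p=p, h=h)


def wc_components(stats: LocusPopStats) -> FstComponents:
    """Weir-Cockerham a, b, c per locus for r >= 2 populations.

    Loci where any population has zero calls, or where the mean sample size
    n_bar <= 1, are flagged undefined (NaN components).
    """
    n, p, h = stats.n, stats.p, stats.h
    r = n.shape[0]
    if r < 2:
        raise FstError("need at least 2 populations")
    valid = (n > 0).all(axis=0)
    n_bar = n.sum(axis=0) / r
    if not (n_bar[valid] > 1).any() and valid.any():
        raise FstError("mean sample size must exceed 1")
    valid &= n_bar > 1

    with np.errstate(invalid="ignore", divide="ignore"):
        n_c = (r * n_bar - (n ** 2).sum(axis=0) / (r * n_bar)) / (r - 1)
        p_bar = (n * p).sum(axis=0) / (r * n_bar)
        s2 = (n * (p - p_bar) ** 2).sum(axis=0) / ((r - 1) * n_bar)
        h_bar = (n * h).sum(axis=0) / (r * n_bar)

        inner = p_bar * (1 - p_bar) - ((r - 1) / r) * s2
        a = (n_bar / n_c) * (s2 - (inner - h_bar / 4.0) / (n_bar - 1))
        b = (n_bar / (n_bar - 1)) * (inner - ((2 * n_bar - 1) / (4 * n_bar)) * h_bar)
        c = h_bar / 2.0

    a = np.where(valid, a, np.nan)
    b = np.where(valid, b, np.nan)
    c = np.where(valid, c, np.nan)
    n_skipped = int((~valid).sum())
    if n_skipped:
        logger.info("%d loci skipped (no calls in a population or n_bar <= 1)", n_skipped)
    return FstComponents(loci=list(stats.loci), a=a, b=b, c=c)


def weighted_fst(components: FstComponents) -> float:
    """Multi-locus ratio-of-sums estimate sum(a) / sum(a+b+c)."""
    ok = components.defined
    if not ok.any():
        raise FstError("no locus with a defined denominator")
    return float(components.a[ok].sum() / components.denominator[ok].sum())


def mean_of_ratios_fst(components: FstComponents) -> float:
    """Unweighted mean of per-locus theta values, for comparison only."""
    theta = components.theta
    ok = np.isfinite(theta)
    if not ok.any():
        raise FstError("no locus with a defined theta")
    return float(theta[ok].mean())


def pairwise_fst(matrix: GenotypeMatrix, samples: pd.DataFrame,
                 populations: list[str] | None = None) -> PairwiseFstMatrix:
    """Weighted Fst for every unordered population pair over the panel loci."""
    if populations is None:
        populations = sorted(samples["population"].unique())
    if len(populations) < 2:
        raise FstError("need at least 2 populations")
    pop_sizes = samples["population"].value_counts()
    values = pd.DataFrame(np.nan, index=populations, columns=populations, dtype=float)
    n_loci = pd.DataFrame(0, index=populations, columns=populations, dtype=int)
    for p1, p2 in itertools.combinations(populations, 2):
        if min(pop_sizes.get(p1, 0), pop_sizes.get(p2, 0)) < 2:
            logger.warning("pair (%s, %s) skipped: a population has < 2 samples", p1, p2)
            continue
        stats = locus_pop_stats(matrix, samples, [p1, p2])
        comp = wc_components(stats)
        try:
            theta = weighted_fst(comp)
        except FstError:
            logger.warning("pair (%s, %s): all loci undefined", p1, p2)
            continue
        values.loc[p1, p2] = values.loc[p2, p1] = theta
        n_loci.loc[p1, p2] = n_loci.loc[p2, p1] = int(comp.defined.sum())
    return PairwiseFstMatrix(populations=list(populations), values=values, n_loci=n_loci)
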