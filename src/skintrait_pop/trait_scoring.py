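"""Per-trait genetic scores and the three-status population landscape.

Two scoring modes are provided.  The risk-allele-counting score ("Top SNP",
GRS-RAC) codes each genotype as 2 for homozygous risk (RR), 1 for
heterozygous (RN) and 0 for no risk allele (NN), summed over the trait's
panel SNPs.  The polygenic-score alternative weights each dosage by the
variant's beta.  Missing genotypes contribute the cohort mean dosage of that
variant, the standard PRS fill, so carriers of missing calls are not biased
toward the low-score status.

Score ranges of a designated reference cohort are cut into three equal-width
intervals — "better-than-average", "average", "worse-than-average" — and the
same boundaries are applied to every comparison population, so that status
proportions are comparable across populations.  For protective-direction
traits the outer labels are reversed (more protective alleles = better).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix
from .panel_model import TraitPanel

logger = logging.getLogger(__name__)

BETTER = "better-than-average"
AVERAGE = "average"
WORSE = "worse-than-average"
STATUSES = (BETTER, AVERAGE, WORSE)

SCORE_COLUMNS = ["sample_id", "trait", "score", "n_variants_used"]


class ScoringError(Exception):
    pass


@dataclass(frozen=True)
class IntervalBoundaries:
    """Equal-width three-interval cuts over a reference cohort's score range."""

    trait: str
    low_cut: float
    high_cut: float
    reference_min: float
    reference_max: float
    direction: str = "risk"

    def __post_init__(self) -> None:
        if not (self.reference_min <= self.low_cut <= self.high_cut <= self.reference_max):
            raise ScoringError(
                f"{self.trait}: boundaries must satisfy min <= low <= high <= max"
            )


def _trait_scores(matrix: GenotypeMatrix, panel: TraitPanel,
                  betas: np.ndarray | None) -> tuple[np.ndarray, int] | None:
    """Score one trait; returns (scores, n_variants_used) or None if no variants."""
    cols, weights = [], []
    for i, v in enumerate(panel.variants):
        try:
            col = matrix.column(v.rsid)
        except KeyError:
            continue
        cols.append(col)
        weights.append(1.0 if betas is None else betas[i])
    if not cols:
        return None
    dose = np.column_stack(cols)
    miss = np.isnan(dose)
    if miss.any():
        col_means = np.nanmean(np.where(np.isnan(dose), np.nan, dose), axis=0)
        col_means = np.nan_to_num(col_means, nan=0.0)  # all-missing column scores 0
        dose = np.where(miss, col_means, dose)
        logger.info("trait %r: filled %d missing genotypes with cohort mean dosage",
                    panel.trait, int(miss.sum()))
    return dose @ np.asarray(weights), dose.shape[1]


def grs_rac_scores(matrix: GenotypeMatrix, panels: Sequence[TraitPanel]) -> pd.DataFrame:
    """Risk-allele-count ("Top SNP") score per sample per trait.

    Returns a long table (sample_id, trait, score, n_variants_used).  Traits
    with no genotyped variants are skipped with a warning.
    """
    frames = []
    for panel in panels:
        res = _trait_scores(matrix, panel, betas=None)
        if res is None:
            logger.warning("trait %r skipped: no genotyped variants", panel.trait)
            continue
        scores, m = res
        frames.append(pd.DataFrame({
            "sample_id": matrix.sample_ids, "trait": panel.trait,
            "score": scores, "n_variants_used": m,
        }))
    if not frames:
        raise ScoringError("no trait had any genotyped variants")
    return pd.concat(frames, ignore_index=True)[SCORE_COLUMNS]


def prs_scores(matrix: GenotypeMatrix, panels: Sequence[TraitPanel]) -> pd.DataFrame:
    """Beta-weighted polygenic score; traits lacking betas fall back to GRS-RAC."""
    frames = []
    for panel in panels:
        betas = [v.beta for v in panel.variants]
        if any(b is None for b in betas):
            logger.warning("trait %r lacks betas; falling back to GRS-RAC", panel.trait)
            res = _trait_scores(matrix, panel, betas=None)
        else:
            res = _trait_scores(matrix, panel, betas=np.asarray(betas, dtype=float))
        if res is None:
            logger.warning("trait %r skipped: no genotyped variants", panel.trait)
            continue
        scores, m = res
        frames.append(pd.DataFrame({
            "sample_id": matrix.sample_ids, "trait": panel.trait,
            "score": scores, "n_variants_used": m,
        }))
    if not frames:
        raise ScoringError("no trait had any genotyped variants")
    return pd.concat(frames, ignore_index=True)[SCORE_COLUMNS]


def interval_boundaries(reference_scores: Sequence[float], trait: str,
                        direction: str = "risk") -> IntervalBoundaries:
    """Equal-width thirds of the reference cohort's observed score range."""
    scores = np.asarray(reference_scores, dtype=float)
    scores = scores[~np.isnan(scores)]
    if scores.size < 3 or np.unique(scores).size < 2:
        raise ScoringError(
            f"{trait}: need >= 3 reference scores spanning a non-zero range"
        )
    lo, hi = float(scores.min()), float(scores.max())
    w = (hi - lo) / 3.0
    return IntervalBoundaries(trait=trait, low_cut=lo + w, high_cut=lo + 2 * w,
                              reference_min=lo, reference_max=hi, direction=direction)


def assign_status(scores: Sequence[float], boundaries: IntervalBoundaries) -> list[str]:
    """Map scores to the three statuses; boundary scores go to the riskier side.

    Risk-direction traits: score < low_cut is better-than-average,
    [low_cut, high_cut) is average, >= high_cut is worse-than-average.
    Protective traits reverse the outer labels.  Scores outside the reference
    range clamp into the outer intervals.
    """
    arr = np.asarray(scores, dtype=float)
    if boundaries.direction == "protective":
        outer_low, outer_high = WORSE, BETTER
    else:
        outer_low, outer_high = BETTER, WORSE
    out = np.where(arr < boundaries.low_cut, outer_low,
                   np.where(arr < boundaries.high_cut, AVERAGE, outer_high))
    return list(out)


def boundaries_from_reference(scores: pd.DataFrame, samples: pd.DataFrame,
                              reference_pop: str,
                              directions: dict[str, str] | None = None,
                              ) -> dict[str, IntervalBoundaries]:
    """Per-trait boundaries computed on the reference population's scores."""
    ref_ids = set(samples.loc[samples["population"] == reference_pop, "sample_id"])
    if not ref_ids:
        raise ScoringError(f"reference population {reference_pop!r} has no samples")
    directions = directions or {}
    out = {}
    for trait, grp in scores.groupby("trait", sort=False):
        ref = grp.loc[grp["sample_id"].isin(ref_ids), "score"]
        try:
            out[trait] = interval_boundaries(ref, trait,
                                             directions.get(trait, "risk"))
        except ScoringError as exc:
            logger.warning("trait %r: no boundaries (%s)", trait, exc)
    return out


def build_landscape(scores: pd.DataFrame, samples: pd.DataFrame,
                    boundaries: dict[str, IntervalBoundaries]) -> pd.DataFrame:
    """Per-(population, trait) proportions of the three statuses.

    Rows are sorted by (population, trait); the three proportions sum to 1.
    """
    merged = scores.merge(samples[["sample_id", "population"]], on="sample_id",
                          how="left", validate="many_to_one")
    if merged["population"].isna().any():
        bad = merged.loc[merged["population"].isna(), "sample_id"].unique()
        raise ScoringError(f"samples not in sample table: {list(bad)[:10]}")
    rows = []
    for (pop, trait), grp in merged.groupby(["population", "trait"], sort=True):
        b = boundaries.get(trait)
        if b is None:
            continue
        if grp.empty:
            logger.warning("empty population %r for trait %r omitted", pop, trait)
            continue
        statuses = assign_status(grp["score"].to_numpy(), b)
        n = len(statuses)
        rows.append({
            "population": pop, "trait": trait,
            BETTER: statuses.count(BETTER) / n,
            AVERAGE: statuses.count(AVERAGE) / n,
            WORSE: statuses.count(WORSE) / n,
            "n": n,
        })
    return pd.DataFrame(rows, columns=["population", "trait", *STATUSES, "n"])


def write_boundaries(boundaries: dict[str, IntervalBoundaries], path) -> None:
    with open(path, "w") as fh:
        json.dump({t: asdict(b) for t, b in sorted(boundaries.items())}, fh, indent=1)


def read_boundaries(path) -> dict[str, IntervalBoundaries]:
    with open(path) as fh:
        raw = json.load(fh)
    return {t: IntervalBoundaries(**d) for t, d in raw.items()}
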