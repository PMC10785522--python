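"""Synthetic cohorts with known ground truth for every pipeline stage.

Population structure follows the Balding-Nichols model: each locus has an
ancestral frequency p drawn uniformly from a configured range, and each
population draws its own frequency from Beta(p(1-F)/F, (1-p)(1-F)/F), so the
across-population variance of the frequency is F*p*(1-p).  The Weir-
Cockerham theta is a consistent estimator of this F, which gives the
pipeline a clean parameter-recovery check.  Genotypes are Hardy-Weinberg
within each population (dosage ~ Binomial(2, p_pop)); no linkage
disequilibrium is simulated — the trait panel is sparse and its SNPs are
treated as independent.

The questionnaire generator plants correlations between metadata variables
and trait scores at configured target rho values; binary variables are
produced by thresholding the latent Gaussian at a configured prevalence
(which attenuates the observed point-biserial correlation, as it would in
real data).

The default configuration mirrors the study design this package models:
a Vietnamese-like reference population (n=100) and an East-Asian comparison
population (n=96) differentiated at F=0.05, a 25-trait / 85-SNP panel split
across the pigmentation, dermatitis, nutrition and aging categories, and a
96-respondent questionnaire.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .genotype_io import GenotypeMatrix
from .panel_model import PanelVariant, TraitPanel, unique_variants, write_panel

NUCS = np.array(["A", "C", "G", "T"])


class SimulationError(Exception):
    pass


# (trait, category, direction) — 25 traits, the four categories of the domain;
# antioxidant response is framed as a protective capacity.
DEFAULT_TRAITS: list[tuple[str, str, str]] = [
    ("freckles", "pigmentation", "risk"),
    ("tanning response", "pigmentation", "risk"),
    ("UV sensitivity", "pigmentation", "risk"),
    ("hyperpigmentation", "pigmentation", "risk"),
    ("melasma", "pigmentation", "risk"),
    ("dark circles", "pigmentation", "risk"),
    ("acne", "dermatitis", "risk"),
    ("atopic dermatitis", "dermatitis", "risk"),
    ("rosacea", "dermatitis", "risk"),
    ("inflammatory cytokines", "dermatitis", "risk"),
    ("sebum production", "dermatitis", "risk"),
    ("vitamin A level", "nutrition", "risk"),
    ("vitamin B9 level", "nutrition", "risk"),
    ("vitamin B12 level", "nutrition", "risk"),
    ("vitamin C level", "nutrition", "risk"),
    ("vitamin D level", "nutrition", "risk"),
    ("vitamin E level", "nutrition", "risk"),
    ("omega-3 level", "nutrition", "risk"),
    ("skin aging", "aging", "risk"),
    ("wrinkles", "aging", "risk"),
    ("collagen degradation", "aging", "risk"),
    ("elasticity", "aging", "risk"),
    ("moisturizing", "aging", "risk"),
    ("glycation", "aging", "risk"),
    ("antioxidant response", "aging", "protective"),
]

# binary questionnaire items with realistic prevalences for an adult cohort
DEFAULT_BINARY_ITEMS: dict[str, float] = {
    "exercise": 0.57, "smoke_exposure": 0.15, "stress": 0.62,
    "sweet_eating": 0.43, "fruit_eating": 0.80, "alcohol_use": 0.26,
    "sunscreen": 0.55, "moisturizer_use": 0.56, "skin_satisfaction": 0.25,
}


@dataclass(frozen=True)
class PopulationSpec:
    label: str
    n_samples: int
    F: float  # Balding-Nichols differentiation from the ancestral pool

    def __post_init__(self) -> None:
        if not (0.0 <= self.F < 1.0):
            raise SimulationError(f"{self.label}: F must lie in [0, 1), got {self.F}")
        if self.n_samples < 1:
            raise SimulationError(f"{self.label}: n_samples must be >= 1")


@dataclass(frozen=True)
class PlantedCorrelation:
    variable: str
    trait: str
    rho: float
    kind: str = "continuous"  # or "binary"
    prevalence: float = 0.5  # binary threshold only

    def __post_init__(self) -> None:
        if not (-1.0 < self.rho < 1.0):
            raise SimulationError(f"{self.variable}: |rho| must be < 1")


@dataclass
class SimulationConfig:
    seed: int  # mandatory: all randomness flows from here
    n_traits: int = 25
    variants_per_trait: Sequence[int] | None = None  # default: 85 over 25 traits
    populations: list[PopulationSpec] = field(default_factory=lambda: [
        PopulationSpec("VN", 100, 0.05),
        PopulationSpec("JPT", 96, 0.05),
    ])
    ancestral_range: tuple[float, float] = (0.1, 0.9)
    missing_rate: float = 0.002
    r2_range: tuple[float, float] = (0.85, 1.0)
    survey_population: str = "VN"
    survey_n: int = 96
    planted: list[PlantedCorrelation] = field(default_factory=lambda: [
        PlantedCorrelation("wrinkle_severity", "wrinkles", 0.45),
        PlantedCorrelation("supplement_use", "vitamin D level", 0.30, kind="binary",
                           prevalence=0.17),
    ])

    def __post_init__(self) -> None:
        lo, hi = self.ancestral_range
        if not (0.0 < lo <= hi < 1.0):
            raise SimulationError("ancestral_range must lie inside (0, 1)")
        if not (0.0 <= self.missing_rate < 1.0):
            raise SimulationError("missing_rate must lie in [0, 1)")
        names = [p.variable for p in self.planted]
        if len(names) != len(set(names)):
            raise SimulationError("duplicate planted variable names")


def _default_variant_counts(n_traits: int, total: int = 85) -> list[int]:
    """Split ``total`` variants over traits as evenly as possible (3-4 each at 25/85)."""
    base = total // n_traits
    extra = total - base * n_traits
    return [base + 1 if i < extra else base for i in range(n_traits)]


def simulate_panel(rng: np.random.Generator, n_traits: int = 25,
                   variants_per_trait: Sequence[int] | None = None,
                   traits: Sequence[tuple[str, str, str]] | None = None,
                   shared: Sequence[tuple[str, str]] = ()) -> list[TraitPanel]:
    """Generate a synthetic trait->SNP panel (a stand-in, not any real panel).

    ``shared`` lists (trait_a, trait_b) pairs whose traits share trait_a's
    first SNP, planting trait co-occurrence through shared variants.
    """
    traits = list(traits or DEFAULT_TRAITS)[:n_traits]
    if len(traits) < n_traits:
        traits += [(f"trait_{i}", "aging", "risk") for i in range(len(traits), n_traits)]
    counts = list(variants_per_trait or _default_variant_counts(n_traits))
    panels = []
    locus = 0
    for t, (trait, category, direction) in enumerate(traits):
        variants = []
        for _ in range(counts[t]):
            a1, a2 = rng.choice(4, size=2, replace=False)
            variants.append(PanelVariant(
                rsid=f"rs{1000001 + 13 * locus}",
                chrom=str(locus % 22 + 1),
                pos=100_000 + 1_000 * locus,
                risk_allele=str(NUCS[a1]), other_allele=str(NUCS[a2]),
                trait=trait, category=category, direction=direction,
                beta=float(np.round(rng.uniform(0.05, 0.5), 4)),
                source_pvalue=float(10.0 ** rng.uniform(-20, -8)),
                source="synthetic",
            ))
            locus += 1
        panels.append(TraitPanel(trait=trait, category=category, variants=variants))
    by_trait = {p.trait: p for p in panels}
    for t_from, t_to in shared:
        src = by_trait[t_from].variants[0]
        dst = by_trait[t_to]
        dst.variants.append(PanelVariant(**{**asdict(src), "trait": dst.trait,
                                            "category": dst.category,
                                            "direction": dst.direction}))
    return panels


def simulate_frequencies(n_loci: int, F: Sequence[float] | dict[str, float],
                         ancestral_range: tuple[float, float] = (0.1, 0.9),
                         seed: int | None = None,
                         rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Balding-Nichols per-population allele-frequency table.

    Returns a DataFrame with an ``ancestral`` column and one column per
    population (keyed by label, or ``pop0..`` for a plain sequence of F
    values).  F=0 copies the ancestral frequency exactly.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if isinstance(F, dict):
        labels, fvals = list(F.keys()), list(F.values())
    else:
        labels, fvals = [f"pop{i}" for i in range(len(F))], list(F)
    for f in fvals:
        if not (0.0 <= f < 1.0):
            raise SimulationError(f"F must lie in [0, 1), got {f}")
    lo, hi = ancestral_range
    p = rng.uniform(lo, hi, size=n_loci)
    out = {"ancestral": p}
    for label, f in zip(labels, fvals):
        if f == 0.0:
            out[label] = p.copy()
        else:
            scale = (1.0 - f) / f
            out[label] = rng.beta(p * scale, (1.0 - p) * scale)
    return pd.DataFrame(out)


def simulate_genotypes(frequencies: pd.DataFrame, n_per_pop: dict[str, int],
                       missing_rate: float = 0.0,
                       panels: Sequence[TraitPanel] | None = None,
                       seed: int | None = None,
                       rng: np.random.Generator | None = None,
                       vcf_path: str | Path | None = None,
                       r2_range: tuple[float, float] | None = None,
                       ) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Draw HWE genotypes per population and optionally write a matching VCF.

    Returns the dosage matrix (risk-allele counts, NaN for injected missing
    calls) and a sample table.  When ``panels`` is given the matrix columns
    are the deduplicated panel loci; otherwise anonymous loci are created.
    ``vcf_path`` requires ``panels``; the emitted VCF reproduces the matrix
    exactly under :func:`skintrait_pop.genotype_io.read_vcf_panel`.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    pops = [c for c in frequencies.columns if c != "ancestral"]
    missing_pops = [p for p in n_per_pop if p not in pops]
    if missing_pops:
        raise SimulationError(f"no frequencies for populations {missing_pops}")
    n_loci = len(frequencies)
    if panels is not None:
        loci = unique_variants(panels)
        if len(loci) != n_loci:
            raise SimulationError(
                f"panel has {len(loci)} loci but frequency table has {n_loci}")
    else:
        loci = [PanelVariant(rsid=f"rs{9000001 + i}", chrom="1", pos=1000 + i,
                             risk_allele="A", other_allele="G",
                             trait="locus", category="aging")
                for i in range(n_loci)]

    blocks, sample_ids, sample_rows = [], [], []
    for pop in pops:
        if pop not in n_per_pop:
            continue
        n = n_per_pop[pop]
        freqs = frequencies[pop].to_numpy()
        dose = rng.binomial(2, freqs, size=(n, n_loci)).astype(float)
        if missing_rate > 0:
            dose[rng.uniform(size=dose.shape) < missing_rate] = np.nan
        blocks.append(dose)
        ids = [f"{pop}_{i:04d}" for i in range(n)]
        sample_ids.extend(ids)
        sample_rows.extend({"sample_id": s, "population": pop, "cohort": "synthetic"}
                           for s in ids)
    dosage = np.vstack(blocks)
    r2 = None
    if r2_range is not None:
        r2 = rng.uniform(r2_range[0], r2_range[1], size=n_loci).round(4)
    matrix = GenotypeMatrix(sample_ids=sample_ids, variants=loci, dosage=dosage,
                            impute_r2=r2)
    samples = pd.DataFrame(sample_rows)
    if vcf_path is not None:
        risk_is_alt = rng.uniform(size=n_loci) < 0.5
        write_vcf(matrix, vcf_path, risk_is_alt=risk_is_alt)
    return matrix, samples


def write_vcf(matrix: GenotypeMatrix, path: str | Path,
              risk_is_alt: np.ndarray | None = None) -> None:
    """Emit an uncompressed VCF 4.2 matching the dosage matrix.

    ``risk_is_alt[j]`` puts the risk allele of locus j in the ALT column
    (GT codes then count the risk allele directly); otherwise the risk
    allele is the REF and GT codes count the other allele.
    """
    if risk_is_alt is None:
        risk_is_alt = np.ones(matrix.n_variants, dtype=bool)
    chroms = []
    for v in matrix.variants:
        if v.chrom not in chroms:
            chroms.append(v.chrom)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=R2,Number=1,Type=Float,Description='
                 '"Imputation quality score">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(matrix.sample_ids) + "\n")
        for j, v in enumerate(matrix.variants):
            if risk_is_alt[j]:
                ref, alt = v.other_allele, v.risk_allele
            else:
                ref, alt = v.risk_allele, v.other_allele
            info = "."
            if matrix.impute_r2 is not None and np.isfinite(matrix.impute_r2[j]):
                info = f"R2={matrix.impute_r2[j]:g}"
            gts = []
            for d in matrix.dosage[:, j]:
                if np.isnan(d):
                    gts.append("./.")
                else:
                    alt_count = int(d) if risk_is_alt[j] else 2 - int(d)
                    gts.append(("0/0", "0/1", "1/1")[alt_count])
            fh.write(f"{v.chrom}\t{v.pos}\t{v.rsid}\t{ref}\t{alt}\t.\tPASS\t"
                     f"{info}\tGT\t" + "\t".join(gts) + "\n")


def simulate_questionnaire(scores: pd.DataFrame, planted: Sequence[PlantedCorrelation],
                           sample_ids: Sequence[str],
                           rng: np.random.Generator | None = None,
                           seed: int | None = None,
                           binary_items: dict[str, float] | None = None,
                           ) -> tuple[pd.DataFrame, dict]:
    """Generate raw questionnaire rows plus the codebook that encodes them.

    Planted continuous variables are rho*z + sqrt(1-rho^2)*noise on the
    standardized trait score; planted binary variables threshold that latent
    at the configured prevalence.  Unplanted demographic and lifestyle items
    are independent of the scores.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    names = [p.variable for p in planted]
    if len(names) != len(set(names)):
        raise SimulationError("duplicate planted variable names")
    binary_items = DEFAULT_BINARY_ITEMS if binary_items is None else binary_items
    sample_ids = list(sample_ids)
    n = len(sample_ids)
    wide = scores.pivot(index="sample_id", columns="trait", values="score")

    df = pd.DataFrame({"sample_id": sample_ids})
    age = np.clip(rng.normal(37.0, 9.0, size=n), 25, 60).round(0)
    df["age"] = age
    df["bmi"] = np.clip(rng.normal(22.0, 3.0, size=n), 15, 35).round(1)
    df["gender"] = np.where(rng.uniform(size=n) < 0.29, "male", "female")
    codebook: dict = {
        "age": {"type": "continuous"},
        "bmi": {"type": "continuous"},
        "gender": {"type": "binary", "mapping": {"male": 0, "female": 1}},
    }
    for item, prev in binary_items.items():
        df[item] = np.where(rng.uniform(size=n) < prev, "yes", "no")
        codebook[item] = {"type": "binary", "mapping": {"yes": 1, "no": 0}}
    for pc in planted:
        if pc.trait not in wide.columns:
            raise SimulationError(f"planted trait {pc.trait!r} has no scores")
        z = wide.loc[sample_ids, pc.trait].to_numpy(dtype=float)
        sd = z.std()
        if sd == 0:
            raise SimulationError(f"planted trait {pc.trait!r} has constant scores")
        z = (z - z.mean()) / sd
        latent = pc.rho * z + np.sqrt(1.0 - pc.rho ** 2) * rng.normal(size=n)
        if pc.kind == "binary":
            cut = np.quantile(latent, 1.0 - pc.prevalence)
            df[pc.variable] = np.where(latent >= cut, "yes", "no")
            codebook[pc.variable] = {"type": "binary", "mapping": {"yes": 1, "no": 0}}
        else:
            df[pc.variable] = np.round(latent, 6)
            codebook[pc.variable] = {"type": "continuous"}
    return df, codebook


def make_fixture_suite(config: SimulationConfig, outdir: str | Path,
                       force: bool = False) -> dict[str, Path]:
    """Write a self-describing fixture directory for the whole pipeline.

    Produces panel.tsv, genotypes.vcf, samples.tsv, metadata.tsv,
    codebook.yaml and truth.json (the planted ground truth: per-population F,
    planted correlations, per-trait score bounds).  Refuses to write into a
    non-empty directory unless ``force``.
    """
    from .trait_scoring import grs_rac_scores  # local import to avoid cycle

    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise SimulationError(f"output directory {outdir} is not empty (use force)")
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    panels = simulate_panel(rng, n_traits=config.n_traits,
                            variants_per_trait=config.variants_per_trait)
    loci = unique_variants(panels)
    freqs = simulate_frequencies(
        len(loci), {p.label: p.F for p in config.populations},
        ancestral_range=config.ancestral_range, rng=rng)
    matrix, samples = simulate_genotypes(
        freqs, {p.label: p.n_samples for p in config.populations},
        missing_rate=config.missing_rate, panels=panels, rng=rng,
        vcf_path=outdir / "genotypes.vcf", r2_range=config.r2_range)

    scores = grs_rac_scores(matrix, panels)
    survey_ids = [s for s in matrix.sample_ids
                  if s.startswith(config.survey_population + "_")][:config.survey_n]
    if not survey_ids:
        raise SimulationError(
            f"survey population {config.survey_population!r} not simulated")
    metadata, codebook = simulate_questionnaire(scores, config.planted, survey_ids,
                                                rng=rng)

    paths = {
        "panel": outdir / "panel.tsv",
        "vcf": outdir / "genotypes.vcf",
        "samples": outdir / "samples.tsv",
        "metadata": outdir / "metadata.tsv",
        "codebook": outdir / "codebook.yaml",
        "truth": outdir / "truth.json",
    }
    write_panel(panels, paths["panel"])
    samples.to_csv(paths["samples"], sep="\t", index=False)
    metadata.to_csv(paths["metadata"], sep="\t", index=False)
    with open(paths["codebook"], "w") as fh:
        yaml.safe_dump(codebook, fh, sort_keys=False)
    truth = {
        "seed": config.seed,
        "populations": [asdict(p) for p in config.populations],
        "planted_correlations": [asdict(p) for p in config.planted],
        "missing_rate": config.missing_rate,
        "n_traits": len(panels),
        "n_variants": len(loci),
        "survey_population": config.survey_population,
        "survey_n": len(survey_ids),
        "score_bounds": {p.trait: [0, 2 * len(p.variants)] for p in panels},
    }
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=1)
    return paths
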