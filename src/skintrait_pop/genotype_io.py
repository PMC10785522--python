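"""Cohort genotype IO: VCF reading restricted to panel loci, dosage coding.

Genotypes are held as a samples x variants matrix of risk-allele dosages
(0, 1, 2 copies of the risk allele; NaN for missing calls).  Variants are
matched to the panel primarily by rsID (the VCF ID column), falling back to
(chrom, pos) when the ID is ".".  REF/ALT must equal the panel's
{risk, other} allele pair in either orientation; mismatching records are
excluded with a warning rather than strand-flipped.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .panel_model import PanelVariant, TraitPanel, unique_variants

logger = logging.getLogger(__name__)

MISSING = np.nan

SAMPLE_COLUMNS = ["sample_id", "population", "cohort"]


class GenotypeIOError(Exception):
    pass


@dataclass
class GenotypeMatrix:
    """Samples x panel-variants risk-allele dosage matrix.

    ``dosage[i, j]`` counts copies of ``variants[j].risk_allele`` carried by
    ``sample_ids[i]``; NaN marks a missing call.  ``impute_r2`` holds the
    per-variant imputation quality score when the VCF provided one.
    ``not_found`` lists panel rsIDs absent from the source VCF and
    ``excluded`` the rsIDs dropped for REF/ALT-vs-panel allele mismatch.
    """

    sample_ids: list[str]
    variants: list[PanelVariant]
    dosage: np.ndarray  # float array, shape (n_samples, n_variants)
    impute_r2: np.ndarray | None = None  # shape (n_variants,), NaN when absent
    not_found: list[str] = field(default_factory=list)
    excluded: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.sample_ids), len(self.variants)):
            raise GenotypeIOError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variants)} variants"
            )
        ok = np.isnan(self.dosage) | np.isin(self.dosage, (0.0, 1.0, 2.0))
        if not ok.all():
            bad = np.argwhere(~ok)[0]
            raise GenotypeIOError(
                f"dosage entry at sample {self.sample_ids[bad[0]]}, "
                f"variant {self.variants[bad[1]].rsid} is not in {{0,1,2,NaN}}"
            )
        if self.impute_r2 is not None:
            self.impute_r2 = np.asarray(self.impute_r2, dtype=float)
            if self.impute_r2.shape != (len(self.variants),):
                raise GenotypeIOError("impute_r2 length does not match variants")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def rsids(self) -> list[str]:
        return [v.rsid for v in self.variants]

    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.dosage)

    def column(self, rsid: str) -> np.ndarray:
        try:
            j = self.rsids.index(rsid)
        except ValueError:
            raise KeyError(rsid) from None
        return self.dosage[:, j]

    def subset(self, sample_idx: np.ndarray | None = None,
               variant_idx: np.ndarray | None = None) -> "GenotypeMatrix":
        si = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        vi = np.arange(self.n_variants) if variant_idx is None else np.asarray(variant_idx)
        return GenotypeMatrix(
            sample_ids=[self.sample_ids[i] for i in si],
            variants=[self.variants[j] for j in vi],
            dosage=self.dosage[np.ix_(si, vi)],
            impute_r2=None if self.impute_r2 is None else self.impute_r2[vi],
            not_found=list(self.not_found),
            excluded=list(self.excluded),
        )


def read_vcf_panel(vcf_path: str | Path, panels: Sequence[TraitPanel],
                   r2_field: str = "R2") -> GenotypeMatrix:
    """Read the panel loci of a VCF into a :class:`GenotypeMatrix`.

    Only diploid GT calls are accepted.  Multi-allelic records contribute
    their first ALT only; a record whose {REF, first ALT} pair differs from
    the panel's {risk, other} pair is excluded with a warning.
    """
    loci = unique_variants(panels)
    by_rsid = {v.rsid: v for v in loci}
    by_pos = {(v.chrom, v.pos): v for v in loci}
    try:
        vcf = VCF(str(vcf_path))
    except Exception as exc:
        raise GenotypeIOError(f"cannot open VCF {vcf_path}: {exc}") from exc
    sample_ids = list(vcf.samples)

    found: dict[str, tuple[np.ndarray, float]] = {}
    excluded: list[str] = []
    for rec in vcf:
        pv = by_rsid.get(rec.ID) if rec.ID and rec.ID != "." else None
        if pv is None:
            pv = by_pos.get((str(rec.CHROM), int(rec.POS)))
        if pv is None or pv.rsid in found or pv.rsid in excluded:
            continue
        alt = rec.ALT[0] if rec.ALT else None
        if alt is None or {rec.REF, alt} != set(pv.alleles):
            excluded.append(pv.rsid)
            logger.warning(
                "variant %s excluded: VCF alleles %s/%s do not match panel %s/%s",
                pv.rsid, rec.REF, alt, pv.risk_allele, pv.other_allele,
            )
            continue
        col = np.full(len(sample_ids), MISSING)
        for i, gt in enumerate(rec.genotypes):
            alleles = gt[:-1]  # last element is the phased flag
            if len(alleles) != 2:
                raise GenotypeIOError(
                    f"non-diploid genotype for sample {sample_ids[i]} at {pv.rsid}"
                )
            if -1 in alleles:
                continue
            alt_count = sum(1 for a in alleles if a != 0)
            col[i] = alt_count if pv.risk_allele == alt else 2 - alt_count
        r2 = rec.INFO.get(r2_field)
        found[pv.rsid] = (col, float(r2) if r2 is not None else np.nan)

    kept = [v for v in loci if v.rsid in found]
    not_found = [v.rsid for v in loci if v.rsid not in found and v.rsid not in excluded]
    if not_found:
        logger.warning("%d panel variants not found in %s: %s",
                       len(not_found), vcf_path, ", ".join(not_found[:10]))
    if kept:
        dosage = np.column_stack([found[v.rsid][0] for v in kept])
        r2s = np.array([found[v.rsid][1] for v in kept])
    else:
        dosage = np.empty((len(sample_ids), 0))
        r2s = np.empty(0)
    impute_r2 = None if np.isnan(r2s).all() else r2s
    return GenotypeMatrix(sample_ids=sample_ids, variants=kept, dosage=dosage,
                          impute_r2=impute_r2, not_found=not_found, excluded=excluded)


def read_sample_table(path: str | Path) -> pd.DataFrame:
    """Read the sample->population table (TSV: sample_id, population, cohort)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in SAMPLE_COLUMNS[:2] if c not in df.columns]
    if missing:
        raise GenotypeIOError(f"{path}: missing sample-table columns {missing}")
    if "cohort" not in df.columns:
        df["cohort"] = ""
    dup = df["sample_id"][df["sample_id"].duplicated()]
    if not dup.empty:
        raise GenotypeIOError(f"{path}: duplicate sample_id values: {sorted(set(dup))}")
    return df[SAMPLE_COLUMNS]


def check_samples_covered(matrix: GenotypeMatrix, samples: pd.DataFrame) -> None:
    """Every genotyped sample must appear in the sample table."""
    known = set(samples["sample_id"])
    absent = [s for s in matrix.sample_ids if s not in known]
    if absent:
        raise GenotypeIOError(f"samples missing from sample table: {absent}")


def write_matrix(matrix: GenotypeMatrix, path: str | Path,
                 header_comments: Sequence[str] = ()) -> None:
    """Write a dosage matrix as self-describing TSV (## lines carry variant metadata)."""
    path = Path(path)
    with open(path, "w") as fh:
        for comment in header_comments:
            fh.write(f"# {comment}\n")
        for j, v in enumerate(matrix.variants):
            meta = {
                "rsid": v.rsid, "chrom": v.chrom, "pos": v.pos,
                "risk_allele": v.risk_allele, "other_allele": v.other_allele,
                "trait": v.trait, "category": v.category, "direction": v.direction,
                "beta": v.beta, "source_pvalue": v.source_pvalue, "source": v.source,
            }
            if matrix.impute_r2 is not None and np.isfinite(matrix.impute_r2[j]):
                meta["impute_r2"] = float(matrix.impute_r2[j])
            fh.write("## variant " + json.dumps(meta) + "\n")
        fh.write("sample_id\t" + "\t".join(matrix.rsids) + "\n")
        for i, sid in enumerate(matrix.sample_ids):
            vals = ["NA" if np.isnan(d) else str(int(d)) for d in matrix.dosage[i]]
            fh.write(sid + "\t" + "\t".join(vals) + "\n")


def read_matrix(path: str | Path) -> GenotypeMatrix:
    """Inverse of :func:`write_matrix`; preserves dosages, NA markers, column order."""
    variants: list[PanelVariant] = []
    r2s: list[float] = []
    rows: list[tuple[str, list[float]]] = []
    header: list[str] | None = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("## variant "):
                meta = json.loads(line[len("## variant "):])
                r2s.append(meta.pop("impute_r2", np.nan))
                variants.append(PanelVariant(**meta))
            elif line.startswith("#") and header is None:
                continue  # other header comments (e.g. run-manifest hash)
            elif header is None:
                header = line.split("\t")
                if header[0] != "sample_id":
                    raise GenotypeIOError(f"{path}: malformed matrix header")
            else:
                parts = line.split("\t")
                rows.append((parts[0],
                             [MISSING if p == "NA" else float(p) for p in parts[1:]]))
    if header is None:
        raise GenotypeIOError(f"{path}: empty matrix file")
    r2arr = np.asarray(r2s)
    return GenotypeMatrix(
        sample_ids=[r[0] for r in rows],
        variants=variants,
        dosage=np.array([r[1] for r in rows]) if rows else np.empty((0, len(variants))),
        impute_r2=None if r2arr.size == 0 or np.isnan(r2arr).all() else r2arr,
    )
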