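"""Curated trait->SNP panel: data model, TSV/JSON IO, validation, summaries.

A panel maps each skin-related trait (grouped into pigmentation, dermatitis,
nutrition and aging categories) to the SNPs reported to influence it, with the
risk allele, an optional per-allele effect size (beta) and the source study.
The panel drives risk-allele scoring and selects the loci over which pairwise
population Fst is computed.  A SNP may legitimately appear under more than one
trait (shared variants are one explanation for trait co-occurrence); the
(rsid, trait) pair must be unique.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

CATEGORIES = frozenset({"pigmentation", "dermatitis", "nutrition", "aging"})
DIRECTIONS = frozenset({"risk", "protective"})
NUCLEOTIDES = frozenset({"A", "C", "G", "T"})

PANEL_COLUMNS = [
    "rsid", "chrom", "pos", "risk_allele", "other_allele",
    "trait", "category", "direction", "beta", "source_pvalue", "source",
]
_REQUIRED_COLUMNS = PANEL_COLUMNS[:7]


class PanelError(Exception):
    """Base class for panel problems."""


class PanelFormatError(PanelError):
    """The file cannot be parsed or required columns are absent."""


class PanelValidationError(PanelError):
    """A parsed row violates a panel invariant."""


@dataclass(frozen=True)
class PanelVariant:
    """One SNP entry of the trait panel.

    ``risk_allele`` is the allele the source association study reports as
    increasing the adverse phenotype probability; ``direction`` flips the
    landscape orientation for traits framed as protective capacities
    (e.g. antioxidant response).
    """

    rsid: str
    chrom: str
    pos: int
    risk_allele: str
    other_allele: str
    trait: str
    category: str
    direction: str = "risk"
    beta: float | None = None
    source_pvalue: float | None = None
    source: str = ""

    def __post_init__(self) -> None:
        if self.risk_allele not in NUCLEOTIDES or self.other_allele not in NUCLEOTIDES:
            raise PanelValidationError(
                f"{self.rsid}: alleles must be single nucleotides A/C/G/T, "
                f"got {self.risk_allele!r}/{self.other_allele!r}"
            )
        if self.risk_allele == self.other_allele:
            raise PanelValidationError(
                f"{self.rsid}: risk_allele equals other_allele ({self.risk_allele})"
            )
        if self.pos < 1:
            raise PanelValidationError(f"{self.rsid}: pos must be >= 1, got {self.pos}")
        if self.category not in CATEGORIES:
            raise PanelValidationError(
                f"{self.rsid}: category {self.category!r} not one of {sorted(CATEGORIES)}"
            )
        if self.direction not in DIRECTIONS:
            raise PanelValidationError(
                f"{self.rsid}: direction {self.direction!r} not one of {sorted(DIRECTIONS)}"
            )
        if self.source_pvalue is not None and not (0.0 < self.source_pvalue <= 1.0):
            raise PanelValidationError(
                f"{self.rsid}: source_pvalue must lie in (0, 1], got {self.source_pvalue}"
            )

    @property
    def alleles(self) -> frozenset[str]:
        return frozenset((self.risk_allele, self.other_allele))


@dataclass
class TraitPanel:
    """All panel variants of one trait."""

    trait: str
    category: str
    variants: list[PanelVariant] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.variants:
            raise PanelValidationError(f"trait {self.trait!r}: empty variant list")
        for v in self.variants:
            if v.trait != self.trait:
                raise PanelValidationError(
                    f"variant {v.rsid} carries trait {v.trait!r}, expected {self.trait!r}"
                )

    @property
    def direction(self) -> str:
        # trait-level orientation: protective iff all its variants say so
        return "protective" if all(v.direction == "protective" for v in self.variants) else "risk"


def _variant_from_row(row: dict, rownum: int) -> PanelVariant:
    def _opt_float(key: str) -> float | None:
        val = row.get(key)
        if val is None or (isinstance(val, float) and pd.isna(val)) or val == "":
            return None
        return float(val)

    direction = row.get("direction")
    if direction is None or (isinstance(direction, float) and pd.isna(direction)) or direction == "":
        direction = "risk"
    try:
        return PanelVariant(
            rsid=str(row["rsid"]),
            chrom=str(row["chrom"]),
            pos=int(row["pos"]),
            risk_allele=str(row["risk_allele"]).upper(),
            other_allele=str(row["other_allele"]).upper(),
            trait=str(row["trait"]),
            category=str(row["category"]),
            direction=str(direction),
            beta=_opt_float("beta"),
            source_pvalue=_opt_float("source_pvalue"),
            source="" if pd.isna(row.get("source", "")) else str(row.get("source", "")),
        )
    except PanelValidationError as exc:
        raise PanelValidationError(f"row {rownum}: {exc}") from None


def _panels_from_variants(variants: Iterable[PanelVariant]) -> list[TraitPanel]:
    seen: set[tuple[str, str]] = set()
    by_trait: dict[str, list[PanelVariant]] = {}
    for v in variants:
        key = (v.rsid, v.trait)
        if key in seen:
            raise PanelValidationError(f"duplicate (rsid, trait) pair {key}")
        seen.add(key)
        by_trait.setdefault(v.trait, []).append(v)
    return [TraitPanel(trait=t, category=vs[0].category, variants=vs) for t, vs in by_trait.items()]


def load_panel(path: str | Path, format: str | None = None) -> list[TraitPanel]:
    """Read a panel file (TSV with header, or the JSON mirror schema).

    Returns one :class:`TraitPanel` per distinct trait, in first-appearance
    order; loading is deterministic and order-preserving within each trait.
    """
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "tsv"
    if format == "tsv":
        try:
            df = pd.read_csv(path, sep="\t", dtype=str)
        except Exception as exc:  # pragma: no cover - pandas error text varies
            raise PanelFormatError(f"cannot parse {path}: {exc}") from exc
        missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise PanelFormatError(f"{path}: missing required columns {missing}")
        variants = [
            _variant_from_row(row, i + 2)  # +2: header line + 1-based
            for i, row in enumerate(df.to_dict(orient="records"))
        ]
    elif format == "json":
        with open(path) as fh:
            try:
                data = json.load(fh)
            except json.JSONDecodeError as exc:
                raise PanelFormatError(f"cannot parse {path}: {exc}") from exc
        variants = []
        for tobj in data:
            if "trait" not in tobj or "variants" not in tobj:
                raise PanelFormatError(f"{path}: trait object lacks 'trait'/'variants'")
            for i, vobj in enumerate(tobj["variants"]):
                row = {"trait": tobj["trait"], "category": tobj.get("category"), **vobj}
                variants.append(_variant_from_row(row, i))
    else:
        raise PanelFormatError(f"unknown panel format {format!r}")
    return _panels_from_variants(variants)


def write_panel(panels: Sequence[TraitPanel], path: str | Path, format: str | None = None) -> None:
    """Write panels back to TSV or JSON; ``load_panel`` round-trips the output."""
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "tsv"
    if format == "tsv":
        rows = [asdict(v) for p in panels for v in p.variants]
        df = pd.DataFrame(rows, columns=PANEL_COLUMNS)
        df.to_csv(path, sep="\t", index=False)
    elif format == "json":
        out = []
        for p in panels:
            vs = []
            for v in p.variants:
                d = asdict(v)
                d.pop("trait")
                d.pop("category")
                vs.append(d)
            out.append({"trait": p.trait, "category": p.category, "variants": vs})
        with open(path, "w") as fh:
            json.dump(out, fh, indent=1)
    else:
        raise PanelFormatError(f"unknown panel format {format!r}")


def iter_variants(panels: Sequence[TraitPanel]) -> Iterable[PanelVariant]:
    for p in panels:
        yield from p.variants


def unique_variants(panels: Sequence[TraitPanel]) -> list[PanelVariant]:
    """Distinct panel loci by rsID, first occurrence wins (shared SNPs dedup)."""
    seen: dict[str, PanelVariant] = {}
    for v in iter_variants(panels):
        seen.setdefault(v.rsid, v)
    return list(seen.values())


def panel_summary(panels: Sequence[TraitPanel]) -> dict:
    """Per-trait / per-category variant counts and totals.

    ``n_variants`` counts panel rows (a SNP shared by two traits counts once
    per trait); ``n_distinct_rsids`` deduplicates across traits.
    """
    if not panels:
        raise PanelError("empty panel list")
    per_trait = {p.trait: len(p.variants) for p in panels}
    per_category: dict[str, int] = {}
    for p in panels:
        per_category[p.category] = per_category.get(p.category, 0) + len(p.variants)
    rsids = {v.rsid for v in iter_variants(panels)}
    return {
        "n_traits": len(panels),
        "n_variants": sum(per_trait.values()),
        "n_distinct_rsids": len(rsids),
        "per_trait": per_trait,
        "per_category": per_category,
    }
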