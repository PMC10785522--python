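"""Pearson correlation screen over trait scores and questionnaire variables.

Questionnaire columns are encoded to numbers through an explicit codebook
(binary yes/no to 0/1, ordinal levels to integer codes, continuous passed
through); Pearson correlation on a 0/1 code is the point-biserial
coefficient, so a single method covers all variable types.  Each unordered
variable pair is tested on its pairwise-complete cases with a two-sided
t-test p-value; |R| strength bands are 0.1 (weak), 0.3 (moderate) and 0.5
(strong), left-closed.  P-values are reported unadjusted; an optional
Benjamini-Hochberg column is available.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

STRENGTHS = ("none", "weak", "moderate", "strong")

RESULT_COLUMNS = ["var1", "var2", "R", "p", "n", "strength", "significant"]


class CodebookError(Exception):
    pass


class CorrelationError(Exception):
    pass


@dataclass(frozen=True)
class CorrelationResult:
    var1: str
    var2: str
    R: float
    p: float
    n: int
    strength: str
    significant: bool


def encode_questionnaire(records: pd.DataFrame, codebook: dict) -> pd.DataFrame:
    """Encode raw questionnaire rows into a numeric variable table.

    ``codebook`` maps each retained column to ``{"type": ..., "mapping": ...}``
    with type one of binary / ordinal / continuous / drop.  Values absent from
    a binary/ordinal mapping become missing, with a warning.  ``sample_id``
    is carried through unmapped.
    """
    out = pd.DataFrame({"sample_id": records["sample_id"].astype(str)})
    for col in records.columns:
        if col == "sample_id":
            continue
        if col not in codebook:
            raise CodebookError(f"codebook lacks an entry for column {col!r}")
        entry = codebook[col]
        ctype = entry.get("type")
        if ctype == "drop":
            continue
        if ctype == "continuous":
            out[col] = pd.to_numeric(records[col], errors="coerce")
        elif ctype in ("binary", "ordinal"):
            mapping = {str(k): float(v) for k, v in entry.get("mapping", {}).items()}
            if not mapping:
                raise CodebookError(f"column {col!r}: {ctype} type needs a mapping")
            raw = records[col].astype(str)
            out[col] = raw.map(mapping)
            unmapped = raw[~raw.isin(mapping) & ~records[col].isna()]
            if not unmapped.empty:
                logger.warning("column %r: %d unmapped values (e.g. %r) set to missing",
                               col, len(unmapped), unmapped.iloc[0])
        else:
            raise CodebookError(f"column {col!r}: unknown type {ctype!r}")
    return out


def pearson_with_p(x, y) -> tuple[float, float, int]:
    """Sample Pearson R with two-sided t-test p on pairwise-complete cases.

    p is derived from t = R*sqrt((n-2)/(1-R^2)) on n-2 degrees of freedom.
    Raises :class:`CorrelationError` for n < 3 or a constant vector.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~np.isnan(x) & ~np.isnan(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        raise CorrelationError(f"need >= 3 complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise CorrelationError("constant vector: correlation undefined")
    xc, yc = x - x.mean(), y - y.mean()
    r = float(xc @ yc / np.sqrt((xc @ xc) * (yc @ yc)))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0, n
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = float(2.0 * sps.t.sf(abs(t), df=n - 2))
    return r, p, n


def classify_strength(R: float) -> str:
    """|R| bands: <0.1 none, [0.1,0.3) weak, [0.3,0.5) moderate, >=0.5 strong."""
    a = abs(R)
    if a > 1.0 + 1e-12:
        raise CorrelationError(f"|R| = {a} exceeds 1")
    if a < 0.1:
        return "none"
    if a < 0.3:
        return "weak"
    if a < 0.5:
        return "moderate"
    return "strong"


def correlation_screen(table: pd.DataFrame,
                       pairs: list[tuple[str, str]] | None = None,
                       alpha: float = 0.05,
                       bh: bool = False) -> pd.DataFrame:
    """Pearson screen over variable pairs, sorted by p ascending.

    Variables with fewer than two distinct non-missing values are excluded;
    pairs failing the pairwise-complete preconditions are dropped.  Set
    ``bh=True`` to append a Benjamini-Hochberg adjusted-p column (the
    primary ``significant`` flag stays unadjusted).
    """
    variables = [c for c in table.columns if c != "sample_id"]
    eligible = []
    for c in variables:
        col = table[c].dropna()
        if col.nunique() >= 2:
            eligible.append(c)
        else:
            logger.warning("variable %r excluded: fewer than 2 distinct values", c)
    if len(eligible) < 2:
        raise CorrelationError("need >= 2 eligible variables")
    if pairs is None:
        pairs = list(itertools.combinations(eligible, 2))
    rows = []
    for v1, v2 in pairs:
        if v1 not in eligible or v2 not in eligible:
            continue
        try:
            r, p, n = pearson_with_p(table[v1], table[v2])
        except CorrelationError as exc:
            logger.warning("pair (%s, %s) excluded: %s", v1, v2, exc)
            continue
        rows.append({"var1": v1, "var2": v2, "R": r, "p": p, "n": n,
                     "strength": classify_strength(r), "significant": p < alpha})
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    if bh and not df.empty:
        df["p_bh"] = multipletests(df["p"], method="fdr_bh")[1]
    return df.sort_values(["p", "var1", "var2"], kind="mergesort").reset_index(drop=True)
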