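"""Pooling and reporting strata.

Per-digestion bioaccessibility results are pooled at the levels the study
reports: product x diet, chemical form x diet, chemical form alone,
pharmaceutical form alone, and the diet-only reference models.  Because
every product x diet cell carries the same number of replicates, the
pooled mean at a coarser level equals the unweighted mean of the
constituent cell means (which equals the grand mean over samples).

The pharmaceutical-form grouping used for reporting pools product 3 with
the coated tablets even though its label says "tablet": only that
grouping is arithmetically consistent with the published pooled means
(coated tablets n = 135, tablets n = 27).  The catalog label is left
untouched; the reporting rule lives in ``REPORTING_PHARMA_GROUPS``.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._round import round_half_up
from .design import ChemicalForm, Diet, PharmaForm, StudyDesign
from .stats import ComparisonResult, GroupSummary, compare_groups, descriptive

__all__ = [
    "StratumLevel", "StratumKey", "PooledTableRow",
    "REPORTING_PHARMA_GROUPS", "assign_strata", "pool_mean_of_group_means",
    "summarize_strata", "render_table",
]


class StratumLevel(str, Enum):
    PRODUCT_DIET = "product_diet"
    CHEMFORM_DIET = "chemform_diet"
    CHEMFORM = "chemform"
    PHARMAFORM = "pharmaform"
    DIET_ONLY = "diet_only"


#: product_id -> pharmaceutical form used for pooled reporting.
REPORTING_PHARMA_GROUPS: dict[int, PharmaForm] = {
    1: PharmaForm.COATED_TABLET,
    2: PharmaForm.COATED_TABLET,
    3: PharmaForm.COATED_TABLET,  # labeled "tablet"; pooled with coated
    4: PharmaForm.COATED_TABLET,
    5: PharmaForm.TABLET,
    6: PharmaForm.CAPSULE,
    7: PharmaForm.COATED_TABLET,
    8: PharmaForm.EXTENDED_RELEASE_TABLET,
}


@dataclass(frozen=True)
class StratumKey:
    level: StratumLevel
    product_id: Optional[int] = None
    chemical_form: Optional[ChemicalForm] = None
    pharma_form: Optional[PharmaForm] = None
    diet: Optional[Diet] = None

    def label(self) -> str:
        parts = []
        if self.product_id is not None:
            parts.append(f"product {self.product_id}")
        if self.chemical_form is not None:
            parts.append(f"iron {self.chemical_form.value}")
        if self.pharma_form is not None:
            parts.append(self.pharma_form.value.replace("_", " "))
        if self.level is StratumLevel.DIET_ONLY:
            parts.append("diet without preparation")
        if self.diet is not None:
            parts.append(self.diet.value.replace("_", "-"))
        return ", ".join(parts)


@dataclass(frozen=True)
class PooledTableRow:
    key: StratumKey
    summary: GroupSummary
    comparison: Optional[ComparisonResult] = None


def _reporting_pharma(design: StudyDesign, product_id: int) -> PharmaForm:
    if product_id in REPORTING_PHARMA_GROUPS:
        return REPORTING_PHARMA_GROUPS[product_id]
    return design.product(product_id).pharma_form


def assign_strata(results: pd.DataFrame, design: StudyDesign,
                  level: StratumLevel) -> dict[StratumKey, np.ndarray]:
    """Map each stratum at *level* to its member B% values.

    *results* is a per-digestion table with ``product_id`` (nullable),
    ``diet`` and ``B_percent`` columns.  Diet-only rows form their own
    strata and never join a product-based stratum.
    """
    level = StratumLevel(level)
    known = {p.product_id for p in design.products}
    with_product = results[results["product_id"].notna()]
    unknown = set(with_product["product_id"].astype(int)) - known
    if unknown:
        raise KeyError(f"unknown product_id values {sorted(unknown)}")
    diet_only = results[results["product_id"].isna() & results["diet"].notna()]

    def key_for(row: pd.Series) -> Optional[StratumKey]:
        pid = int(row["product_id"])
        product = design.product(pid)
        diet = Diet(row["diet"])
        if level is StratumLevel.PRODUCT_DIET:
            return StratumKey(level, product_id=pid, diet=diet)
        if level is StratumLevel.CHEMFORM_DIET:
            return StratumKey(level, chemical_form=product.chemical_form,
                              diet=diet)
        if level is StratumLevel.CHEMFORM:
            return StratumKey(level, chemical_form=product.chemical_form)
        if level is StratumLevel.PHARMAFORM:
            return StratumKey(level,
                              pharma_form=_reporting_pharma(design, pid))
        return None

    out: dict[StratumKey, list[float]] = {}
    if level is StratumLevel.DIET_ONLY:
        for diet_value, grp in diet_only.groupby("diet", sort=False):
            key = StratumKey(level, diet=Diet(diet_value))
            out[key] = grp["B_percent"].tolist()
    else:
        for _, row in with_product.iterrows():
            key = key_for(row)
            out.setdefault(key, []).append(float(row["B_percent"]))
        if level in (StratumLevel.CHEMFORM, StratumLevel.PHARMAFORM) \
                and not diet_only.empty:
            # the diet-only pool is reported alongside these tables
            key = StratumKey(StratumLevel.DIET_ONLY)
            out[key] = diet_only["B_percent"].tolist()
    return {k: np.asarray(v, dtype=float) for k, v in out.items()}


def pool_mean_of_group_means(per_group_means: Sequence[float]) -> float:
    """Unweighted mean of equal-n group means (equals the grand mean)."""
    arr = np.asarray(per_group_means, dtype=float)
    if arr.size == 0:
        raise ValueError("need at least one group mean")
    return float(arr.mean())


_LEVEL_ORDER = {
    StratumLevel.PRODUCT_DIET: ("product_id", "diet"),
    StratumLevel.CHEMFORM_DIET: ("chemical_form", "diet"),
    StratumLevel.CHEMFORM: ("chemical_form",),
    StratumLevel.PHARMAFORM: ("pharma_form",),
    StratumLevel.DIET_ONLY: ("diet",),
}

_CHEMFORM_ORDER = [f.value for f in ChemicalForm]
_PHARMA_ORDER = [f.value for f in PharmaForm]
_DIET_ORDER = [d.value for d in Diet]


def _sort_key(key: StratumKey) -> tuple:
    return (
        key.level is StratumLevel.DIET_ONLY,  # diet-only pool renders last
        key.product_id if key.product_id is not None else -1,
        _CHEMFORM_ORDER.index(key.chemical_form.value)
        if key.chemical_form else -1,
        _PHARMA_ORDER.index(key.pharma_form.value) if key.pharma_form else -1,
        _DIET_ORDER.index(key.diet.value) if key.diet else -1,
    )


def summarize_strata(results: pd.DataFrame, design: StudyDesign,
                     level: StratumLevel,
                     compare_across: bool = False) -> list[PooledTableRow]:
    """Descriptive summary per stratum, optionally with the omnibus +
    post hoc comparison across the strata of this level."""
    strata = assign_strata(results, design, level)
    keys = sorted(strata, key=_sort_key)
    comparison = None
    if compare_across and len(keys) >= 2:
        comparison = compare_groups([strata[k] for k in keys],
                                    labels=[k.label() for k in keys])
    return [PooledTableRow(k, descriptive(strata[k]), comparison)
            for k in keys]


_SUMMARY_COLS = ["n", "M", "Me", "Min", "Max", "IQR", "SD"]


def rows_to_frame(rows: Sequence[PooledTableRow]) -> pd.DataFrame:
    """Tabular view of pooled rows with 2-decimal display rounding."""
    records = []
    for row in rows:
        s = row.summary
        rec = {
            "stratum": row.key.label(),
            "n": s.n,
            "M": round_half_up(s.mean),
            "Me": round_half_up(s.median),
            "Min": round_half_up(s.minimum),
            "Max": round_half_up(s.maximum),
            "IQR": round_half_up(s.iqr),
            "SD": round_half_up(s.sd) if np.isfinite(s.sd) else np.nan,
        }
        if row.comparison is not None:
            rec["test"] = row.comparison.test_used.value
            rec["statistic"] = round_half_up(row.comparison.statistic)
            rec["p"] = row.comparison.p_omnibus
        records.append(rec)
    return pd.DataFrame(records)


def render_table(rows: Sequence[PooledTableRow], title: str = "") -> str:
    """Deterministic fixed-width text rendering of pooled rows."""
    frame = rows_to_frame(rows)
    if frame.empty:
        header = "stratum  " + "  ".join(_SUMMARY_COLS)
        return (title + "\n" if title else "") + header + "\n"
    text = frame.to_string(index=False, float_format=lambda v: f"{v:.2f}")
    return (title + "\n" if title else "") + text + "\n"
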