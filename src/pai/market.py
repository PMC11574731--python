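"""Hospital-market concentration (Herfindahl-Hirschman index) per category.

The market for a procedure category pools every hospital in the data
extent; a hospital's share is its fraction of the category's volume. On the
default percent-share scale the index runs over (0, 10000]: equal volumes
across 40 hospitals give exactly 250, across 80 hospitals exactly 125, and
a monopoly gives 10000.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .core import EmptyCategoryError, EncounterTable

HHI_COLUMNS = ("category_id", "year", "n_hospitals", "hhi")

Scale = Literal["percent", "fraction"]


@dataclass(frozen=True)
class HHIResult:
    category_id: str
    year: int
    n_hospitals: int
    hhi: float


def _hhi_from_counts(counts: np.ndarray, scale: Scale) -> float:
    shares = counts / counts.sum()
    if scale == "percent":
        shares = shares * 100.0
    elif scale != "fraction":
        raise ValueError(f"unknown scale {scale!r}")
    return float(np.dot(shares, shares))


def hhi(enc: EncounterTable, category_id: str, year: int,
        scale: Scale = "percent") -> HHIResult:
    """Sum of squared hospital market shares for one category-year."""
    sub = enc.subset(category_id, year)
    if sub.empty:
        raise EmptyCategoryError(
            f"no encounters for category {category_id!r} in {year}"
        )
    counts = sub.groupby("hospital_id").size().to_numpy(dtype=float)
    return HHIResult(category_id=category_id, year=year,
                     n_hospitals=int(len(counts)),
                     hhi=_hhi_from_counts(counts, scale))


def hhi_by_category_year(enc: EncounterTable,
                         scale: Scale = "percent") -> pd.DataFrame:
    """HHI table over every (category, year) present in the encounters."""
    rows = []
    grouped = enc.frame.groupby(["category_id", "year", "hospital_id"]).size()
    for (category_id, year), counts in grouped.groupby(level=[0, 1]):
        arr = counts.to_numpy(dtype=float)
        rows.append({
            "category_id": category_id,
            "year": int(year),
            "n_hospitals": int(len(arr)),
            "hhi": _hhi_from_counts(arr, scale),
        })
    out = pd.DataFrame(rows, columns=list(HHI_COLUMNS))
    return out.sort_values(["year", "category_id"],
                           kind="stable").reset_index(drop=True)
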