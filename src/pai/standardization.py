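"""Indirect age-sex standardization: expected utilization per zip.

The reference distribution against which a procedure's observed geography is
judged is built by applying sample-wide stratum-specific utilization rates
to each zip's age-band x sex population, then normalizing the resulting
expected counts to shares. Two rate modes are supported: rates from all
hospitalizations (the default reference) and rates restricted to a single
procedure category (a condition-prevalence proxy).
"""

from __future__ import annotations

import logging
from typing import Literal

import pandas as pd

from .core import (
    AgeBands,
    DegenerateInputError,
    EncounterTable,
    PopulationTable,
    SchemaError,
    ShareVector,
)

logger = logging.getLogger("pai")

ReferenceMode = Literal["all_hospitalizations", "category_specific"]
REFERENCE_MODES: tuple[str, ...] = ("all_hospitalizations", "category_specific")

_STRATUM = ["age_band", "sex"]


def _event_counts(enc: EncounterTable, bands: AgeBands,
                  category_id: str | None) -> pd.DataFrame:
    frame = enc.frame if category_id is None else enc.subset(category_id)
    if frame.empty:
        counts = pd.DataFrame(columns=_STRATUM + ["events"])
    else:
        counts = (
            frame.assign(age_band=bands.assign(frame["age"].to_numpy()))
            .groupby(_STRATUM, observed=True)
            .size()
            .rename("events")
            .reset_index()
        )
    counts["age_band"] = counts["age_band"].astype(str)
    return counts


def stratum_rates(enc: EncounterTable, pop: PopulationTable,
                  mode: ReferenceMode = "all_hospitalizations",
                  category_id: str | None = None,
                  age_bands: AgeBands | None = None,
                  min_events: int | None = None) -> pd.DataFrame:
    """Per-stratum utilization rates (events per person per year-equivalent).

    rate(a, s) = events in stratum (a, s) across all zips / population in
    stratum (a, s). Strata present in the population table but without
    events get rate 0. A stratum with events but zero population is an
    error, named in the message.

    With ``mode="category_specific"`` the numerator is restricted to
    ``category_id``; ``min_events`` (optional) falls strata with fewer
    category events back to the all-hospitalizations rate.
    """
    if mode not in REFERENCE_MODES:
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "category_specific" and category_id is None:
        raise ValueError("category_specific mode requires category_id")
    bands = age_bands or AgeBands()

    totals = pop.stratum_totals()
    totals["age_band"] = totals["age_band"].astype(str)
    counts = _event_counts(enc, bands,
                           category_id if mode == "category_specific" else None)

    merged = totals.merge(counts, on=_STRATUM, how="outer")
    orphan = merged["population"].isna() & (merged["events"] > 0)
    merged["events"] = merged["events"].fillna(0)
    merged["population"] = merged["population"].fillna(0)
    starved = merged[(merged["events"] > 0) & (merged["population"] <= 0)]
    if orphan.any() or not starved.empty:
        bad = merged.loc[orphan | ((merged["events"] > 0) &
                                   (merged["population"] <= 0)), _STRATUM]
        strata = [f"({r.age_band}, {r.sex})" for r in bad.itertuples()]
        raise DegenerateInputError(
            f"stratum(s) with events but zero population: {', '.join(strata)}"
        )
    merged["rate"] = merged["events"].where(merged["population"] > 0, 0) \
        / merged["population"].where(merged["population"] > 0, 1)

    if mode == "category_specific" and min_events is not None:
        fallback = stratum_rates(enc, pop, "all_hospitalizations",
                                 age_bands=bands)
        merged = merged.merge(
            fallback.rename(columns={"rate": "rate_all"}), on=_STRATUM,
            how="left",
        )
        thin = merged["events"] < min_events
        if thin.any():
            logger.info("stratum_rates: %d stratum(s) below min_events=%d, "
                        "using all-hospitalizations rates", int(thin.sum()),
                        min_events)
        merged["rate"] = merged["rate"].where(~thin, merged["rate_all"])

    out = merged[_STRATUM + ["rate"]].copy()
    out = out.sort_values(_STRATUM, kind="stable").reset_index(drop=True)
    return out


def expected_counts(rates: pd.DataFrame, pop: PopulationTable) -> pd.DataFrame:
    """Expected events per zip: sum over strata of population x stratum rate.

    Every stratum present in the population table must carry a rate.
    """
    merged = pop.frame.assign(age_band=pop.frame["age_band"].astype(str)) \
        .merge(rates, on=_STRATUM, how="left")
    if merged["rate"].isna().any():
        bad = merged.loc[merged["rate"].isna(), _STRATUM].drop_duplicates()
        strata = [f"({r.age_band}, {r.sex})" for r in bad.itertuples()]
        raise SchemaError(f"no rate for stratum(s): {', '.join(strata)}")
    merged["expected"] = merged["population"] * merged["rate"]
    out = merged.groupby("zip")["expected"].sum().reset_index()
    return out.sort_values("zip", kind="stable").reset_index(drop=True)


def reference_shares(expected: pd.DataFrame) -> ShareVector:
    """Normalize expected counts to a reference share vector over zips."""
    if "expected" not in expected.columns or "zip" not in expected.columns:
        raise SchemaError("expected-counts frame needs columns zip, expected")
    total = float(expected["expected"].sum())
    if total <= 0:
        raise DegenerateInputError(
            "total expected count is zero; cannot form reference shares"
        )
    return ShareVector.from_counts(
        pd.Series(expected["expected"].to_numpy(),
                  index=pd.Index(expected["zip"], name="zip"))
    )


def build_reference(enc: EncounterTable, pop: PopulationTable,
                    mode: ReferenceMode = "all_hospitalizations",
                    category_id: str | None = None,
                    age_bands: AgeBands | None = None,
                    min_events: int | None = None) -> ShareVector:
    """Convenience pipeline: stratum rates -> expected counts -> shares."""
    rates = stratum_rates(enc, pop, mode, category_id, age_bands, min_events)
    return reference_shares(expected_counts(rates, pop))
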