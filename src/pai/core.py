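"""Domain tables, schema handling, and delimited-text I/O.

The three inputs are plain delimited tables (comma or tab, header row
required): encounter-level discharge records, zip-level population counts
stratified by age band and sex, and a procedure-category metadata table.
Column names can be remapped through a schema config so that differently
labelled extracts load without editing the files.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("pai")

ENCOUNTER_REQUIRED: tuple[str, ...] = (
    "year", "zip", "age", "sex", "category_id", "hospital_id",
)
ENCOUNTER_OPTIONAL: tuple[str, ...] = (
    "payer", "race", "cost", "los_days", "died", "elective",
)
SEXES: tuple[str, ...] = ("F", "M")
PAYERS: tuple[str, ...] = ("medicare", "medicaid", "private", "self", "other")
RACES: tuple[str, ...] = ("white", "black", "hispanic", "other")

_TRUE = {"true", "1", "t", "yes", "y"}
_FALSE = {"false", "0", "f", "no", "n"}


class SchemaError(ValueError):
    """A required column is missing or a table violates its schema."""


class DegenerateInputError(ValueError):
    """An input is structurally valid but degenerate (e.g. all-zero totals)."""


class EmptyCategoryError(ValueError):
    """No encounters exist for the requested category/year."""


# ---------------------------------------------------------------------------
# Age bands
# ---------------------------------------------------------------------------

DEFAULT_AGE_BAND_EDGES: tuple[tuple[int, int | None], ...] = (
    (0, 17), (18, 44), (45, 64), (65, 74), (75, None),
)


def _band_label(lo: int, hi: int | None) -> str:
    return f"{lo}+" if hi is None else f"{lo}-{hi}"


@dataclass(frozen=True)
class AgeBands:
    """Contiguous, ordered age intervals used for stratification.

    Parameters
    ----------
    edges
        Sequence of ``(lo, hi)`` inclusive bounds; the last band must be
        open-ended (``hi is None``) and bands must tile the nonnegative
        integers without gaps.
    """

    edges: tuple[tuple[int, int | None], ...] = DEFAULT_AGE_BAND_EDGES

    def __post_init__(self) -> None:
        if not self.edges:
            raise SchemaError("at least one age band is required")
        if self.edges[0][0] != 0:
            raise SchemaError("first age band must start at 0")
        if self.edges[-1][1] is not None:
            raise SchemaError("last age band must be open-ended")
        for (lo, hi), (nlo, _) in zip(self.edges, self.edges[1:]):
            if hi is None or nlo != hi + 1:
                raise SchemaError(
                    f"age bands must be contiguous; gap between {hi} and {nlo}"
                )

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(_band_label(lo, hi) for lo, hi in self.edges)

    def assign(self, ages: Sequence[int] | np.ndarray | pd.Series) -> pd.Categorical:
        """Map integer ages to band labels (ordered categorical)."""
        lowers = np.array([lo for lo, _ in self.edges])
        arr = np.asarray(ages)
        idx = np.searchsorted(lowers, arr, side="right") - 1
        if (idx < 0).any():
            raise ValueError("negative age encountered in band assignment")
        labels = np.asarray(self.labels, dtype=object)[idx]
        return pd.Categorical(labels, categories=self.labels, ordered=True)

    def sample_ages(self, labels: Sequence[str], rng: np.random.Generator,
                    open_band_width: int = 20) -> np.ndarray:
        """Draw a uniform integer age within each band label (simulation aid)."""
        bounds = {}
        for lo, hi in self.edges:
            hi_eff = lo + open_band_width if hi is None else hi
            bounds[_band_label(lo, hi)] = (lo, hi_eff)
        lohi = np.array([bounds[l] for l in labels])
        if len(lohi) == 0:
            return np.array([], dtype=int)
        return rng.integers(lohi[:, 0], lohi[:, 1] + 1)


# ---------------------------------------------------------------------------
# Share vectors
# ---------------------------------------------------------------------------

SHARE_SUM_TOL = 1e-9


@dataclass(frozen=True)
class ShareVector:
    """Nonnegative weights over zip codes summing to one.

    Used for both the observed utilization distribution of a procedure and
    the expected (reference) distribution; zero-share zips are retained so
    that observed and reference vectors live on the same zip universe.
    """

    shares: pd.Series

    def __post_init__(self) -> None:
        s = self.shares
        if s.index.has_duplicates:
            raise SchemaError("duplicate zip in share vector")
        vals = s.to_numpy(dtype=float)
        if len(vals) == 0:
            raise DegenerateInputError("empty share vector")
        if not np.isfinite(vals).all():
            raise SchemaError("non-finite share")
        if (vals < 0).any():
            raise SchemaError("negative share")
        if abs(vals.sum() - 1.0) > SHARE_SUM_TOL:
            raise SchemaError(f"shares sum to {vals.sum()!r}, not 1")

    @classmethod
    def from_counts(cls, counts: Mapping[str, float] | pd.Series,
                    universe: Sequence[str] | None = None) -> "ShareVector":
        """Normalize nonnegative counts; optionally reindex onto ``universe``
        (absent zips get share zero)."""
        s = pd.Series(counts, dtype=float)
        if universe is not None:
            extra = s.index.difference(pd.Index(universe))
            if len(extra):
                raise SchemaError(f"counts outside universe: {sorted(extra)[:5]}")
            s = s.reindex(pd.Index(universe, name="zip"), fill_value=0.0)
        total = float(s.sum())
        if total <= 0:
            raise DegenerateInputError("total count is zero; cannot form shares")
        out = s / total
        out.index.name = "zip"
        out.name = "share"
        return cls(out)

    @property
    def zips(self) -> pd.Index:
        return self.shares.index

    @property
    def values(self) -> np.ndarray:
        return self.shares.to_numpy(dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return self.shares.rename("share").rename_axis("zip").reset_index()

    def same_universe(self, other: "ShareVector") -> bool:
        return set(self.zips) == set(other.zips)


# ---------------------------------------------------------------------------
# Input tables
# ---------------------------------------------------------------------------

@dataclass
class EncounterTable:
    """One row per hospital discharge; the atomic observational unit."""

    frame: pd.DataFrame
    n_rejected: int = 0
    rejections: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in ENCOUNTER_REQUIRED if c not in self.frame.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    def __len__(self) -> int:
        return len(self.frame)

    def subset(self, category_id: str | None = None,
               year: int | None = None) -> pd.DataFrame:
        f = self.frame
        if category_id is not None:
            f = f[f["category_id"] == category_id]
        if year is not None:
            f = f[f["year"] == year]
        return f


@dataclass
class PopulationTable:
    """Zip x age-band x sex population counts (standardization denominator)."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        need = ("zip", "age_band", "sex", "population")
        missing = [c for c in need if c not in self.frame.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
        if self.frame.duplicated(["zip", "age_band", "sex"]).any():
            raise SchemaError("duplicate (zip, age_band, sex) rows in population table")
        if (self.frame["population"] < 0).any():
            raise SchemaError("negative population count")

    @property
    def zips(self) -> pd.Index:
        return pd.Index(sorted(self.frame["zip"].unique()), name="zip")

    def zip_totals(self) -> pd.Series:
        return self.frame.groupby("zip")["population"].sum()

    def stratum_totals(self) -> pd.DataFrame:
        return (self.frame.groupby(["age_band", "sex"], observed=True)["population"]
                .sum().reset_index())


@dataclass
class CategoryMetadata:
    """Procedure-category metadata: label plus approach/era/device flags."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        need = ("category_id", "label", "minimally_invasive", "era_new",
                "device_implant")
        missing = [c for c in need if c not in self.frame.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
        if self.frame["category_id"].duplicated().any():
            raise SchemaError("duplicate category_id in metadata")

    @property
    def category_ids(self) -> pd.Index:
        return pd.Index(self.frame["category_id"], name="category_id")

    def labels(self) -> pd.Series:
        return self.frame.set_index("category_id")["label"]


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def load_schema_config(path: str | Path) -> dict[str, str]:
    """Load a YAML mapping of canonical column name -> file column name."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict) or not all(
        isinstance(k, str) and isinstance(v, str) for k, v in cfg.items()
    ):
        raise SchemaError("schema config must map column names to column names")
    return cfg


def _read_delimited(path: str | Path) -> pd.DataFrame:
    # sep=None sniffs the dialect, making comma and tab inputs equivalent
    return pd.read_csv(path, sep=None, engine="python", dtype=str,
                       keep_default_na=False)


def _apply_schema(frame: pd.DataFrame,
                  schema_config: Mapping[str, str] | None) -> pd.DataFrame:
    if not schema_config:
        return frame
    rename = {v: k for k, v in schema_config.items() if v in frame.columns}
    return frame.rename(columns=rename)


def _parse_bool(raw: pd.Series) -> pd.Series:
    low = raw.str.strip().str.lower()
    out = pd.Series(pd.NA, index=raw.index, dtype="boolean")
    out[low.isin(_TRUE)] = True
    out[low.isin(_FALSE)] = False
    return out


def read_encounters(path: str | Path,
                    schema_config: Mapping[str, str] | None = None,
                    ) -> EncounterTable:
    """Read and validate an encounter table.

    Rows failing row-level validation (unparseable age, unknown sex code,
    blank required field) are dropped, counted per reason, and logged; a
    missing required column raises :class:`SchemaError` naming the column.
    """
    raw = _apply_schema(_read_delimited(path), schema_config)
    missing = [c for c in ENCOUNTER_REQUIRED if c not in raw.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )

    reasons: Counter[str] = Counter()
    keep = pd.Series(True, index=raw.index)

    for col in ("zip", "category_id", "hospital_id"):
        bad = raw[col].str.strip() == ""
        reasons[f"blank {col}"] += int((bad & keep).sum())
        keep &= ~bad

    year = pd.to_numeric(raw["year"].str.strip(), errors="coerce")
    bad = year.isna() | (year != year.round())
    reasons["unparseable year"] += int((bad & keep).sum())
    keep &= ~bad

    age = pd.to_numeric(raw["age"].str.strip(), errors="coerce")
    bad = age.isna() | (age != age.round()) | (age < 0)
    reasons["unparseable age"] += int((bad & keep).sum())
    keep &= ~bad

    sex = raw["sex"].str.strip().str.upper()
    bad = ~sex.isin(SEXES)
    reasons["unknown sex"] += int((bad & keep).sum())
    keep &= ~bad

    out = pd.DataFrame({
        "year": year[keep].astype(int),
        "zip": raw.loc[keep, "zip"].str.strip(),
        "age": age[keep].astype(int),
        "sex": sex[keep],
        "category_id": raw.loc[keep, "category_id"].str.strip(),
        "hospital_id": raw.loc[keep, "hospital_id"].str.strip(),
    })

    # Optional columns are coerced leniently: invalid entries become missing
    # (logged), not row rejections.
    n_coerced = 0
    for col in ENCOUNTER_OPTIONAL:
        if col not in raw.columns:
            continue
        sub = raw.loc[keep, col]
        if col in ("cost",):
            vals = pd.to_numeric(sub.str.strip(), errors="coerce")
            vals[vals < 0] = np.nan
        elif col in ("los_days",):
            vals = pd.to_numeric(sub.str.strip(), errors="coerce")
            vals[(vals < 0) | (vals != vals.round())] = np.nan
        elif col in ("died", "elective"):
            vals = _parse_bool(sub)
        else:  # payer / race enums
            low = sub.str.strip().str.lower()
            allowed = PAYERS if col == "payer" else RACES
            vals = low.where(low.isin(allowed))
        n_coerced += int(vals.isna().sum() - (sub.str.strip() == "").sum())
        out[col] = vals

    n_rejected = int((~keep).sum())
    if n_rejected:
        logger.warning("read_encounters(%s): rejected %d row(s): %s",
                       path, n_rejected, dict(reasons))
    if n_coerced > 0:
        logger.warning("read_encounters(%s): %d optional value(s) coerced to "
                       "missing", path, n_coerced)
    return EncounterTable(out.reset_index(drop=True), n_rejected,
                          {k: v for k, v in reasons.items() if v})


def read_population(path: str | Path,
                    age_bands: AgeBands | None = None,
                    schema_config: Mapping[str, str] | None = None,
                    ) -> PopulationTable:
    """Read a zip x age-band x sex population table."""
    bands = age_bands or AgeBands()
    raw = _apply_schema(_read_delimited(path), schema_config)
    need = ("zip", "age_band", "sex", "population")
    missing = [c for c in need if c not in raw.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )
    band = raw["age_band"].str.strip()
    unknown = set(band) - set(bands.labels)
    if unknown:
        raise SchemaError(f"{path}: unknown age band(s): {sorted(unknown)}")
    pop = pd.to_numeric(raw["population"].str.strip(), errors="coerce")
    if pop.isna().any() or (pop < 0).any() or (pop != pop.round()).any():
        raise SchemaError(f"{path}: population must be a nonnegative integer")
    frame = pd.DataFrame({
        "zip": raw["zip"].str.strip(),
        "age_band": pd.Categorical(band, categories=bands.labels, ordered=True),
        "sex": raw["sex"].str.strip().str.upper(),
        "population": pop.astype(int),
    })
    if not frame["sex"].isin(SEXES).all():
        raise SchemaError(f"{path}: sex must be one of {SEXES}")
    return PopulationTable(frame)


def read_category_metadata(path: str | Path,
                           schema_config: Mapping[str, str] | None = None,
                           ) -> CategoryMetadata:
    raw = _apply_schema(_read_delimited(path), schema_config)
    need = ("category_id", "label", "minimally_invasive", "era_new",
            "device_implant")
    missing = [c for c in need if c not in raw.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )
    frame = pd.DataFrame({
        "category_id": raw["category_id"].str.strip(),
        "label": raw["label"].str.strip(),
    })
    for col in ("minimally_invasive", "era_new", "device_implant"):
        vals = _parse_bool(raw[col])
        if vals.isna().any():
            raise SchemaError(f"{path}: column {col} must be boolean")
        frame[col] = vals.astype(bool)
    return CategoryMetadata(frame)


# ---------------------------------------------------------------------------
# Consistency
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConsistencyReport:
    """Cross-table referential check: zips and categories must resolve."""

    unknown_zips: tuple[str, ...]
    unknown_categories: tuple[str, ...]

    @property
    def ok(self) -> bool:
        return not self.unknown_zips and not self.unknown_categories

    def __str__(self) -> str:
        if self.ok:
            return "consistent"
        parts = []
        if self.unknown_zips:
            parts.append(f"zips not in population table: "
                         f"{', '.join(self.unknown_zips)}")
        if self.unknown_categories:
            parts.append(f"categories not in metadata: "
                         f"{', '.join(self.unknown_categories)}")
        return "; ".join(parts)


def validate_consistency(enc: EncounterTable, pop: PopulationTable,
                         meta: CategoryMetadata) -> ConsistencyReport:
    """Report encounter zips absent from the population table and encounter
    categories absent from the metadata table; empty report iff consistent."""
    enc_zips = set(enc.frame["zip"].unique())
    enc_cats = set(enc.frame["category_id"].unique())
    unknown_zips = tuple(sorted(enc_zips - set(pop.zips)))
    unknown_cats = tuple(sorted(enc_cats - set(meta.category_ids)))
    zero_pop = [z for z, t in pop.zip_totals().items()
                if t <= 0 and z in enc_zips]
    if zero_pop:
        raise DegenerateInputError(
            f"zip(s) with encounters but zero total population: {zero_pop}"
        )
    return ConsistencyReport(unknown_zips, unknown_cats)


# ---------------------------------------------------------------------------
# Result-table I/O (exact float round trip)
# ---------------------------------------------------------------------------

def write_table(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as RFC-4180 CSV with round-trippable floats."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False)


def read_table(path: str | Path, string_cols: Sequence[str] = ("category_id",
               "zip", "hospital_id", "label")) -> pd.DataFrame:
    dtype = {c: str for c in string_cols}
    return pd.read_csv(path, dtype=dtype, float_precision="round_trip")
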