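"""The access-inequality score: normalized gap between two dispersions.

For each procedure category and year we compute

* a **baseline dispersion** ``D_base`` — dispersion of the age-sex-adjusted
  expected utilization distribution over zip codes, and
* a **realized dispersion** ``D_real`` — dispersion of the observed
  distribution of procedure recipients over the same zips,

and report ``pai = (D_real - D_base) / (D_max - D_base)`` where ``D_max`` is
the dispersion of the most concentrated distribution possible. The score is
0 when the procedure follows the reference exactly, 1 when every recipient
lives in a single zip code, and may dip below 0 when the observed
distribution is *more* uniform than the reference.

The default dispersion functional is share concentration (sum of squared
shares, the Simpson/Herfindahl form); Gini- and Theil-style functionals
measured against the reference are available as drop-in alternatives.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .core import (
    AgeBands,
    CategoryMetadata,
    DegenerateInputError,
    EmptyCategoryError,
    EncounterTable,
    PopulationTable,
    SchemaError,
    ShareVector,
)
from .standardization import REFERENCE_MODES, build_reference

logger = logging.getLogger("pai")

Functional = Literal["share_concentration", "gini_vs_reference",
                     "theil_vs_reference"]
FUNCTIONALS: tuple[str, ...] = ("share_concentration", "gini_vs_reference",
                                "theil_vs_reference")

PAI_COLUMNS = ("category_id", "year", "n_procedures", "n_zips", "d_baseline",
               "d_realized", "pai", "functional", "reference_mode")


def observed_shares(enc: EncounterTable, category_id: str, year: int,
                    universe: pd.Index | None = None) -> ShareVector:
    """Observed recipient shares over zip codes for one category-year.

    When ``universe`` (typically the population table's zips) is given,
    encounters from zips outside it are dropped from the share computation
    (logged) and zero-share zips inside it are retained.
    """
    sub = enc.subset(category_id, year)
    if sub.empty:
        raise EmptyCategoryError(
            f"no encounters for category {category_id!r} in {year}"
        )
    counts = sub.groupby("zip").size().astype(float)
    if universe is not None:
        unknown = counts.index.difference(universe)
        if len(unknown):
            dropped = counts.loc[unknown].sum()
            logger.warning(
                "observed_shares(%s, %s): dropping %d encounter(s) in %d "
                "zip(s) absent from population table", category_id, year,
                int(dropped), len(unknown))
            counts = counts.drop(unknown)
            if counts.sum() <= 0:
                raise EmptyCategoryError(
                    f"all encounters for {category_id!r}/{year} fall outside "
                    "the population-zip universe")
        counts = counts.reindex(universe, fill_value=0.0)
    counts.index.name = "zip"
    return ShareVector.from_counts(counts)


# ---------------------------------------------------------------------------
# Dispersion functionals
# ---------------------------------------------------------------------------

def _check_reference(reference: ShareVector | None,
                     functional: str) -> ShareVector:
    if reference is None:
        raise ValueError(f"{functional} requires a reference share vector")
    if (reference.values <= 0).any():
        raise DegenerateInputError(
            f"{functional} requires a strictly positive reference"
        )
    return reference


def _align(v: ShareVector, reference: ShareVector) -> tuple[np.ndarray, np.ndarray]:
    if not v.same_universe(reference):
        raise SchemaError("share vectors are on different zip universes")
    r = reference.shares.reindex(v.zips)
    return v.values, r.to_numpy(dtype=float)


def dispersion(v: ShareVector, functional: Functional = "share_concentration",
               reference: ShareVector | None = None) -> float:
    """Dispersion of a share vector.

    ``share_concentration`` is the sum of squared shares: 1/K for the
    uniform distribution on K zips, 1 for a point mass. The reference-
    relative functionals return the (weighted) Gini coefficient or the
    Theil-T index of the ratio v/r under reference weights r; both are 0
    when ``v == reference``.
    """
    if functional == "share_concentration":
        x = v.values
        return float(np.dot(x, x))
    if functional == "gini_vs_reference":
        ref = _check_reference(reference, functional)
        vv, rr = _align(v, ref)
        x = vv / rr
        # weighted mean of x under weights rr is exactly 1
        diff = np.abs(x[:, None] - x[None, :])
        return float(0.5 * rr @ diff @ rr)
    if functional == "theil_vs_reference":
        ref = _check_reference(reference, functional)
        vv, rr = _align(v, ref)
        pos = vv > 0
        return float(np.sum(vv[pos] * np.log(vv[pos] / rr[pos])))
    raise ValueError(f"unknown dispersion functional {functional!r}")


def max_dispersion(functional: Functional,
                   reference: ShareVector | None = None) -> float:
    """Dispersion of the most concentrated share vector.

    For the reference-relative functionals this is the dispersion of the
    worst-case point mass (the zip with the smallest reference share).
    """
    if functional == "share_concentration":
        return 1.0
    ref = _check_reference(reference, functional)
    rmin = float(ref.values.min())
    if functional == "gini_vs_reference":
        return 1.0 - rmin
    if functional == "theil_vs_reference":
        return float(np.log(1.0 / rmin))
    raise ValueError(f"unknown dispersion functional {functional!r}")


# ---------------------------------------------------------------------------
# Score
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PAIScore:
    d_baseline: float
    d_realized: float
    pai: float


def _finite_sample_correction(d: float, n: int) -> float:
    # (sum v^2 - 1/n) / (1 - 1/n): removes the multinomial plug-in bias
    if n <= 1:
        raise DegenerateInputError("bias correction needs n > 1")
    return (d - 1.0 / n) / (1.0 - 1.0 / n)


def compute_pai(observed: ShareVector, reference: ShareVector,
                functional: Functional = "share_concentration",
                bias_correction_n: int | None = None) -> PAIScore:
    """Normalized dispersion gap between observed and reference shares.

    ``pai = (D_real - D_base) / (D_max - D_base)``; exactly 0 when
    ``observed == reference`` and exactly 1 when observed is a point mass.
    Raises :class:`DegenerateInputError` when the reference itself is a
    point mass (the normalizing gap vanishes).
    """
    if not observed.same_universe(reference):
        raise SchemaError("observed and reference shares are on different "
                          "zip universes")
    d_real = dispersion(observed, functional, reference)
    if functional == "share_concentration":
        d_base = dispersion(reference, functional)
    else:
        d_base = 0.0  # reference against itself
    d_max = max_dispersion(functional, reference)
    if bias_correction_n is not None:
        if functional != "share_concentration":
            raise ValueError("finite-sample correction applies only to "
                             "share_concentration")
        d_real = _finite_sample_correction(d_real, bias_correction_n)
        d_base = _finite_sample_correction(d_base, bias_correction_n)
    if d_max - d_base <= 0:
        raise DegenerateInputError(
            "degenerate normalization: baseline dispersion equals the "
            "maximum (reference is a point mass)"
        )
    pai = (d_real - d_base) / (d_max - d_base)
    return PAIScore(d_baseline=d_base, d_realized=d_real, pai=pai)


# ---------------------------------------------------------------------------
# Batch computation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PAIConfig:
    """Knobs for the batch score computation.

    ``reference_mode`` chooses what the baseline standardizes to:
    all hospitalizations (default) or the category's own age-sex profile.
    """

    functional: Functional = "share_concentration"
    reference_mode: str = "all_hospitalizations"
    min_volume: int = 1
    bias_correction: bool = False
    min_stratum_events: int | None = None
    age_bands: AgeBands = field(default_factory=AgeBands)

    def __post_init__(self) -> None:
        if self.functional not in FUNCTIONALS:
            raise ValueError(f"unknown functional {self.functional!r}")
        if self.reference_mode not in REFERENCE_MODES:
            raise ValueError(f"unknown reference mode {self.reference_mode!r}")
        if self.min_volume < 1:
            raise ValueError("min_volume must be >= 1")


def pai_by_category_year(enc: EncounterTable, pop: PopulationTable,
                         meta: CategoryMetadata | None = None,
                         config: PAIConfig | None = None) -> pd.DataFrame:
    """One score row per (category, year) meeting the volume threshold.

    Columns: category_id, year, n_procedures, n_zips, d_baseline,
    d_realized, pai, functional, reference_mode. ``n_procedures`` counts
    all encounters including those with unresolvable zips (which are
    excluded from the shares themselves); ``n_zips`` is the number of zips
    with at least one recipient. Skipped category-years are logged.
    """
    cfg = config or PAIConfig()
    universe = pop.zips
    if meta is not None:
        missing = set(enc.frame["category_id"]) - set(meta.category_ids)
        if missing:
            logger.warning("pai_by_category_year: %d categorie(s) absent "
                           "from metadata: %s", len(missing),
                           sorted(missing)[:5])

    rows: list[dict] = []
    for year, year_frame in enc.frame.groupby("year"):
        year_enc = EncounterTable(year_frame)
        reference = None
        if cfg.reference_mode == "all_hospitalizations":
            reference = build_reference(year_enc, pop, "all_hospitalizations",
                                        age_bands=cfg.age_bands)
        for category_id, cat_frame in year_frame.groupby("category_id"):
            n_proc = len(cat_frame)
            if n_proc < cfg.min_volume:
                logger.info("pai_by_category_year: skipping %s/%s "
                            "(volume %d < %d)", category_id, year, n_proc,
                            cfg.min_volume)
                continue
            if cfg.reference_mode == "category_specific":
                ref = build_reference(year_enc, pop, "category_specific",
                                      category_id=str(category_id),
                                      age_bands=cfg.age_bands,
                                      min_events=cfg.min_stratum_events)
            else:
                ref = reference
            obs = observed_shares(year_enc, str(category_id), int(year),
                                  universe)
            score = compute_pai(
                obs, ref, cfg.functional,
                bias_correction_n=n_proc if cfg.bias_correction else None,
            )
            rows.append({
                "category_id": category_id,
                "year": int(year),
                "n_procedures": n_proc,
                "n_zips": int((obs.values > 0).sum()),
                "d_baseline": score.d_baseline,
                "d_realized": score.d_realized,
                "pai": score.pai,
                "functional": cfg.functional,
                "reference_mode": cfg.reference_mode,
            })
    out = pd.DataFrame(rows, columns=list(PAI_COLUMNS))
    return out.sort_values(["year", "category_id"],
                           kind="stable").reset_index(drop=True)


def bootstrap_pai(enc: EncounterTable, pop: PopulationTable, category_id: str,
                  year: int, config: PAIConfig | None = None,
                  n_boot: int = 200, alpha: float = 0.05,
                  seed: int = 0) -> tuple[float, float]:
    """Percentile bootstrap CI for one category-year score.

    Encounter rows of the category-year are resampled with replacement;
    the reference is held fixed at its full-sample value.
    """
    cfg = config or PAIConfig()
    universe = pop.zips
    year_enc = EncounterTable(enc.subset(year=year))
    ref = build_reference(
        year_enc, pop, cfg.reference_mode,
        category_id=category_id if cfg.reference_mode == "category_specific"
        else None,
        age_bands=cfg.age_bands, min_events=cfg.min_stratum_events)
    sub = enc.subset(category_id, year)
    if sub.empty:
        raise EmptyCategoryError(
            f"no encounters for category {category_id!r} in {year}")
    rng = np.random.default_rng(seed)
    stats = np.empty(n_boot)
    zips = sub["zip"].to_numpy()
    for b in range(n_boot):
        sample = rng.choice(zips, size=len(zips), replace=True)
        counts = pd.Series(sample).value_counts().astype(float)
        counts = counts[counts.index.isin(universe)]
        counts = counts.reindex(universe, fill_value=0.0)
        counts.index.name = "zip"
        obs = ShareVector.from_counts(counts)
        stats[b] = compute_pai(
            obs, ref, cfg.functional,
            bias_correction_n=len(zips) if cfg.bias_correction else None).pai
    lo, hi = np.quantile(stats, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)
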