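"""Synthetic encounter-data generator with a planted access mechanism.

Zips are placed uniformly on the unit square with log-normal populations
split across age-sex strata by a fixed national profile. Each procedure
category is offered by a random subset of hospitals; per-zip demand is
Poisson with mean proportional to the zip's stratum populations and
category-specific stratum rates, attenuated by ``exp(-access_decay * d)``
where ``d`` is the distance to the nearest offering hospital. Suppressed
demand is lost, not redistributed (forgone care), so with ``access_decay=0``
and full offering the realized utilization is exactly proportional to
expected demand and the downstream inequality score is ~0; gating access
plants recoverable inequality with known ground truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .core import (
    AgeBands,
    CategoryMetadata,
    EncounterTable,
    PAYERS,
    PopulationTable,
    RACES,
)

# Share of total population per (age_band, sex) for the default bands;
# loosely mirrors the US pyramid and sums to 1.
DEFAULT_AGE_SEX_PROFILE: dict[tuple[str, str], float] = {
    ("0-17", "F"): 0.108, ("0-17", "M"): 0.113,
    ("18-44", "F"): 0.180, ("18-44", "M"): 0.182,
    ("45-64", "F"): 0.128, ("45-64", "M"): 0.123,
    ("65-74", "F"): 0.055, ("65-74", "M"): 0.049,
    ("75+", "F"): 0.037, ("75+", "M"): 0.025,
}

DEFAULT_PAYER_PROBS = {"medicare": 0.40, "medicaid": 0.20, "private": 0.30,
                       "self": 0.05, "other": 0.05}
DEFAULT_RACE_PROBS = {"white": 0.62, "black": 0.15, "hispanic": 0.15,
                      "other": 0.08}


def _as_per_category(value: float | Sequence[float], n: int,
                     name: str) -> np.ndarray:
    arr = np.atleast_1d(np.asarray(value, dtype=float))
    if arr.size == 1:
        arr = np.repeat(arr, n)
    if arr.size != n:
        raise ValueError(f"{name} must be a scalar or length-{n} sequence")
    return arr


@dataclass
class SimConfig:
    """Configuration for one synthetic study.

    ``offering_fraction`` and ``access_decay`` may be scalars or
    per-category sequences. ``volume_per_category`` is the expected number
    of encounters per category per year when access is ungated.
    """

    n_zips: int = 200
    n_hospitals: int = 40
    n_categories: int = 6
    years: tuple[int, ...] = (2019,)
    zip_pop_median: float = 5000.0
    zip_pop_sigma: float = 0.8
    volume_per_category: float = 2000.0
    offering_fraction: float | Sequence[float] = 1.0
    access_decay: float | Sequence[float] = 0.0
    age_profile_jitter: float = 0.0
    rate_profile_spread: float = 0.5
    stratum_rate_profiles: Mapping[str, Mapping[tuple[str, str], float]] | None = None
    payer_probs: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PAYER_PROBS))
    race_probs: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RACE_PROBS))
    mean_cost: float = 12_000.0
    cost_sigma: float = 0.6
    mean_los: float = 4.0
    death_rate: float = 0.02
    elective_rate: float = 0.5
    seed: int = 0
    age_bands: AgeBands = field(default_factory=AgeBands)

    def __post_init__(self) -> None:
        for name in ("n_zips", "n_hospitals", "n_categories"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not self.years:
            raise ValueError("at least one year is required")
        off = _as_per_category(self.offering_fraction, self.n_categories,
                               "offering_fraction")
        if ((off <= 0) | (off > 1)).any():
            raise ValueError("offering_fraction must lie in (0, 1]")
        decay = _as_per_category(self.access_decay, self.n_categories,
                                 "access_decay")
        if (decay < 0).any():
            raise ValueError("access_decay must be >= 0")
        if self.volume_per_category <= 0:
            raise ValueError("volume_per_category must be > 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)} - {"age_bands"}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown simulation config key(s): "
                             f"{sorted(unknown)}")
        if "years" in raw:
            raw["years"] = tuple(int(y) for y in raw["years"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("age_bands", None)
        d["years"] = list(self.years)
        d["offering_fraction"] = np.atleast_1d(
            np.asarray(self.offering_fraction, float)).tolist()
        d["access_decay"] = np.atleast_1d(
            np.asarray(self.access_decay, float)).tolist()
        d["payer_probs"] = dict(self.payer_probs)
        d["race_probs"] = dict(self.race_probs)
        return d


@dataclass
class SimOutput:
    """Simulated tables plus the latent ground truth that produced them."""

    encounters: EncounterTable
    population: PopulationTable
    metadata: CategoryMetadata
    truth: dict[str, pd.DataFrame]

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "encounters": outdir / "encounters.csv",
            "population": outdir / "population.csv",
            "categories": outdir / "categories.csv",
        }
        self.encounters.frame.to_csv(paths["encounters"], index=False)
        self.population.frame.to_csv(paths["population"], index=False)
        self.metadata.frame.to_csv(paths["categories"], index=False)
        for name, frame in self.truth.items():
            p = outdir / f"truth_{name}.csv"
            frame.to_csv(p, index=False)
            paths[f"truth_{name}"] = p
        return paths


def _split_population(totals: np.ndarray, profile: np.ndarray,
                      jitter: float, rng: np.random.Generator) -> np.ndarray:
    """(n_zips, n_strata) integer populations whose rows sum to ~totals."""
    n_zips = len(totals)
    if jitter > 0:
        noise = rng.normal(0.0, jitter, size=(n_zips, len(profile)))
        weights = profile[None, :] * np.exp(noise)
        weights /= weights.sum(axis=1, keepdims=True)
    else:
        weights = np.broadcast_to(profile, (n_zips, len(profile)))
    pop = np.floor(totals[:, None] * weights + 0.5).astype(int)
    # guarantee every stratum is populated so stratum rates stay defined
    return np.maximum(pop, 1)


def simulate(config: SimConfig) -> SimOutput:
    """Generate (encounters, population, metadata, ground truth).

    Deterministic: a fixed seed yields bit-identical tables.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    bands = cfg.age_bands
    strata = [(b, s) for b in bands.labels for s in ("F", "M")]
    n_strata = len(strata)

    if set(DEFAULT_AGE_SEX_PROFILE) >= set(strata):
        profile = np.array([DEFAULT_AGE_SEX_PROFILE[k] for k in strata])
    else:  # non-default bands: flat profile
        profile = np.full(n_strata, 1.0 / n_strata)
    profile = profile / profile.sum()

    zip_ids = np.array([f"Z{i:05d}" for i in range(cfg.n_zips)])
    zip_xy = rng.uniform(0.0, 1.0, size=(cfg.n_zips, 2))
    totals = cfg.zip_pop_median * np.exp(
        cfg.zip_pop_sigma * rng.standard_normal(cfg.n_zips))
    pop = _split_population(totals, profile, cfg.age_profile_jitter, rng)

    hospital_ids = np.array([f"H{j:03d}" for j in range(cfg.n_hospitals)])
    hosp_xy = rng.uniform(0.0, 1.0, size=(cfg.n_hospitals, 2))

    category_ids = [f"C{c:03d}" for c in range(cfg.n_categories)]
    offering = _as_per_category(cfg.offering_fraction, cfg.n_categories,
                                "offering_fraction")
    decay = _as_per_category(cfg.access_decay, cfg.n_categories,
                             "access_decay")

    # per-category stratum rate shapes, scaled to the target expected volume
    stratum_pop_totals = pop.sum(axis=0)
    rates = np.empty((cfg.n_categories, n_strata))
    for c, cid in enumerate(category_ids):
        if cfg.stratum_rate_profiles and cid in cfg.stratum_rate_profiles:
            prof = cfg.stratum_rate_profiles[cid]
            shape = np.array([float(prof[k]) for k in strata])
        else:
            shape = np.exp(cfg.rate_profile_spread
                           * rng.standard_normal(n_strata))
        scale = cfg.volume_per_category / float(shape @ stratum_pop_totals)
        rates[c] = shape * scale

    dist_all = np.linalg.norm(zip_xy[:, None, :] - hosp_xy[None, :, :], axis=2)

    offer_sets: list[np.ndarray] = []
    nearest_idx = np.empty((cfg.n_categories, cfg.n_zips), dtype=int)
    nearest_dist = np.empty((cfg.n_categories, cfg.n_zips))
    for c in range(cfg.n_categories):
        n_off = max(1, int(round(offering[c] * cfg.n_hospitals)))
        chosen = np.sort(rng.choice(cfg.n_hospitals, size=n_off,
                                    replace=False))
        offer_sets.append(chosen)
        sub = dist_all[:, chosen]
        arg = sub.argmin(axis=1)
        nearest_idx[c] = chosen[arg]
        nearest_dist[c] = sub[np.arange(cfg.n_zips), arg]

    payer_names, payer_p = zip(*cfg.payer_probs.items())
    race_names, race_p = zip(*cfg.race_probs.items())
    if set(payer_names) - set(PAYERS) or set(race_names) - set(RACES):
        raise ValueError("payer/race probability keys outside allowed enums")
    payer_p = np.asarray(payer_p) / np.sum(payer_p)
    race_p = np.asarray(race_p) / np.sum(race_p)

    chunks: list[pd.DataFrame] = []
    expected_rows: list[dict] = []
    for year in cfg.years:
        for c, cid in enumerate(category_ids):
            atten = np.exp(-decay[c] * nearest_dist[c])
            lam = pop * rates[c][None, :] * atten[:, None]
            counts = rng.poisson(lam)
            n = int(counts.sum())
            for z in range(cfg.n_zips):
                expected_rows.append({
                    "category_id": cid, "year": year, "zip": zip_ids[z],
                    "expected_demand": float((pop[z] * rates[c]).sum()),
                    "attenuated_mean": float(lam[z].sum()),
                    "distance_nearest": float(nearest_dist[c, z]),
                    "nearest_hospital": hospital_ids[nearest_idx[c, z]],
                })
            if n == 0:
                continue
            zi, si = np.nonzero(counts)
            reps = counts[zi, si]
            zi = np.repeat(zi, reps)
            si = np.repeat(si, reps)
            band_labels = np.array([strata[k][0] for k in si], dtype=object)
            frame = pd.DataFrame({
                "year": year,
                "zip": zip_ids[zi],
                "age": bands.sample_ages(band_labels, rng),
                "sex": np.array([strata[k][1] for k in si], dtype=object),
                "category_id": cid,
                "hospital_id": hospital_ids[nearest_idx[c][zi]],
                "payer": rng.choice(payer_names, size=n, p=payer_p),
                "race": rng.choice(race_names, size=n, p=race_p),
                "cost": np.round(cfg.mean_cost * np.exp(
                    cfg.cost_sigma * rng.standard_normal(n)), 2),
                "los_days": rng.poisson(cfg.mean_los, size=n),
                "died": rng.random(n) < cfg.death_rate,
                "elective": rng.random(n) < cfg.elective_rate,
            })
            chunks.append(frame)

    if chunks:
        enc_frame = pd.concat(chunks, ignore_index=True)
    else:
        enc_frame = pd.DataFrame(columns=["year", "zip", "age", "sex",
                                          "category_id", "hospital_id"])
    encounters = EncounterTable(enc_frame)

    pop_frame = pd.DataFrame({
        "zip": np.repeat(zip_ids, n_strata),
        "age_band": pd.Categorical(
            np.tile([b for b, _ in strata], cfg.n_zips),
            categories=bands.labels, ordered=True),
        "sex": np.tile([s for _, s in strata], cfg.n_zips),
        "population": pop.reshape(-1),
    })
    population = PopulationTable(pop_frame)

    meta_frame = pd.DataFrame({
        "category_id": category_ids,
        "label": [f"Synthetic procedure category {c}" for c in
                  range(cfg.n_categories)],
        "minimally_invasive": rng.random(cfg.n_categories) < 0.5,
        "era_new": rng.random(cfg.n_categories) < 0.4,
        "device_implant": rng.random(cfg.n_categories) < 0.3,
    })
    metadata = CategoryMetadata(meta_frame)

    truth = {
        "zips": pd.DataFrame({"zip": zip_ids, "x": zip_xy[:, 0],
                              "y": zip_xy[:, 1],
                              "population": pop.sum(axis=1)}),
        "hospitals": pd.DataFrame({"hospital_id": hospital_ids,
                                   "x": hosp_xy[:, 0], "y": hosp_xy[:, 1]}),
        "offerings": pd.DataFrame(
            [{"category_id": cid, "hospital_id": hospital_ids[h]}
             for c, cid in enumerate(category_ids) for h in offer_sets[c]]),
        "expected_demand": pd.DataFrame(expected_rows),
        "stratum_rates": pd.DataFrame(
            [{"category_id": cid, "age_band": strata[k][0],
              "sex": strata[k][1], "rate": rates[c, k]}
             for c, cid in enumerate(category_ids)
             for k in range(n_strata)]),
    }
    return SimOutput(encounters, population, metadata, truth)
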