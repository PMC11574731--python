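from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from pai import (
    AgeBands,
    CategoryMetadata,
    EncounterTable,
    PopulationTable,
)


def make_encounters(rows: list[dict]) -> EncounterTable:
    """Build a validated encounter table from row dicts with defaults."""
    defaults = {"year": 2019, "zip": "Z1", "age": 70, "sex": "F",
                "category_id": "C1", "hospital_id": "H1"}
    frame = pd.DataFrame([{**defaults, **r} for r in rows])
    return EncounterTable(frame)


def make_population(rows: list[dict]) -> PopulationTable:
    bands = AgeBands()
    frame = pd.DataFrame(rows)
    frame["age_band"] = pd.Categorical(frame["age_band"],
                                       categories=bands.labels, ordered=True)
    return PopulationTable(frame)


@pytest.fixture
def toy_population() -> PopulationTable:
    """Three zips, uniform composition, populations 1000/2000/3000."""
    rows = []
    bands = AgeBands()
    for z, total in (("Z1", 1000), ("Z2", 2000), ("Z3", 3000)):
        for band in bands.labels:
            for sex in ("F", "M"):
                rows.append({"zip": z, "age_band": band, "sex": sex,
                             "population": total // 10})
    return make_population(rows)


@pytest.fixture
def toy_metadata() -> CategoryMetadata:
    frame = pd.DataFrame({
        "category_id": ["C1", "C2"],
        "label": ["Toy category one", "Toy category two"],
        "minimally_invasive": [True, False],
        "era_new": [True, False],
        "device_implant": [False, False],
    })
    return CategoryMetadata(frame)


@pytest.fixture
def toy_encounters() -> EncounterTable:
    rows = []
    for zip_, n in (("Z1", 4), ("Z2", 3), ("Z3", 3)):
        rows += [{"zip": zip_, "category_id": "C1"}] * n
    rows += [{"zip": "Z2", "category_id": "C2", "hospital_id": "H2"}] * 5
    return make_encounters(rows)


@pytest.fixture(scope="session")
def small_sim():
    from pai import SimConfig, simulate
    cfg = SimConfig(n_zips=60, n_hospitals=12, n_categories=4,
                    volume_per_category=800.0, years=(2016, 2019), seed=7)
    return simulate(cfg)
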