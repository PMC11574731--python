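from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pai import (
    EmptyCategoryError,
    PAIConfig,
    ShareVector,
    bootstrap_pai,
    compute_pai,
    dispersion,
    max_dispersion,
    observed_shares,
    pai_by_category_year,
)
from pai.core import DegenerateInputError, SchemaError
from pai.index import PAI_COLUMNS

from conftest import make_encounters


def sv(values, zips=None) -> ShareVector:
    zips = zips or [f"Z{i}" for i in range(len(values))]
    return ShareVector(pd.Series(values, index=pd.Index(zips, name="zip"),
                                 dtype=float))


# ---------------------------------------------------------------------------
# Independent long-hand oracle (pure python, no numpy)
# ---------------------------------------------------------------------------

def oracle_pai(counts: dict[str, int], ref_weights: dict[str, float]) -> float:
    """Brute-force evaluation of the score from integer zip counts."""
    total = sum(counts.values())
    obs = {z: c / total for z, c in counts.items()}
    ref_total = sum(ref_weights.values())
    ref = {z: w / ref_total for z, w in ref_weights.items()}
    d_real = sum(v * v for v in obs.values())
    d_base = sum(v * v for v in ref.values())
    return (d_real - d_base) / (1.0 - d_base)


# ---------------------------------------------------------------------------
# observed_shares
# ---------------------------------------------------------------------------

def test_observed_shares_simple():
    enc = make_encounters([{"zip": "Z1"}] * 2 + [{"zip": "Z2"}] * 2)
    got = observed_shares(enc, "C1", 2019,
                          universe=pd.Index(["Z1", "Z2", "Z3"]))
    assert got.shares.tolist() == [0.5, 0.5, 0.0]


def test_observed_shares_point_mass():
    enc = make_encounters([{"zip": "Z2"}] * 7)
    got = observed_shares(enc, "C1", 2019)
    assert got.shares.tolist() == [1.0]


def test_observed_shares_hand_normalization():
    rows = []
    for z, n in (("Z1", 1), ("Z2", 2), ("Z3", 3), ("Z4", 4)):
        rows += [{"zip": z}] * n
    got = observed_shares(make_encounters(rows), "C1", 2019)
    assert np.allclose(sorted(got.values), [0.1, 0.2, 0.3, 0.4])


def test_observed_shares_empty_category_errors():
    enc = make_encounters([{"category_id": "C1"}])
    with pytest.raises(EmptyCategoryError):
        observed_shares(enc, "C2", 2019)


def test_observed_shares_drops_zips_outside_universe():
    enc = make_encounters([{"zip": "Z1"}] * 3 + [{"zip": "UNKNOWN"}])
    got = observed_shares(enc, "C1", 2019, universe=pd.Index(["Z1", "Z2"]))
    assert got.shares["Z1"] == 1.0
    assert "UNKNOWN" not in got.zips


# ---------------------------------------------------------------------------
# dispersion
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("k", [2, 3, 10, 50])
def test_share_concentration_uniform(k):
    assert dispersion(sv([1.0 / k] * k)) == pytest.approx(1.0 / k)


def test_share_concentration_point_mass():
    assert dispersion(sv([0.0, 1.0, 0.0])) == 1.0


def test_share_concentration_hand_value():
    assert dispersion(sv([0.5, 0.5, 0.0])) == pytest.approx(0.5)


def test_reference_functionals_zero_at_equality():
    r = sv([0.2, 0.3, 0.5])
    for f in ("gini_vs_reference", "theil_vs_reference"):
        assert dispersion(r, f, reference=r) == pytest.approx(0.0, abs=1e-12)


def test_reference_functionals_require_positive_reference():
    r = sv([0.5, 0.5, 0.0])
    v = sv([0.4, 0.6, 0.0])
    for f in ("gini_vs_reference", "theil_vs_reference"):
        with pytest.raises(DegenerateInputError):
            dispersion(v, f, reference=r)
        with pytest.raises(ValueError):
            dispersion(v, f)  # missing reference


def test_gini_point_mass_closed_form():
    # Gini of a point mass at z under reference weights r is 1 - r_z
    r = sv([0.2, 0.3, 0.5])
    v = sv([1.0, 0.0, 0.0])
    assert dispersion(v, "gini_vs_reference", r) == pytest.approx(0.8)
    assert max_dispersion("gini_vs_reference", r) == pytest.approx(0.8)


def test_theil_point_mass_closed_form():
    r = sv([0.2, 0.3, 0.5])
    v = sv([1.0, 0.0, 0.0])
    assert dispersion(v, "theil_vs_reference", r) == pytest.approx(
        np.log(1 / 0.2))


# ---------------------------------------------------------------------------
# compute_pai
# ---------------------------------------------------------------------------

def test_pai_zero_at_equality():
    r = sv([0.1, 0.2, 0.3, 0.4])
    assert compute_pai(r, r).pai == 0.0


def test_pai_one_at_point_mass():
    k = 5
    o = sv([1.0] + [0.0] * (k - 1))
    r = sv([1.0 / k] * k)
    assert compute_pai(o, r).pai == pytest.approx(1.0)


def test_pai_hand_value_quarter():
    o = sv([0.5, 0.5, 0.0])
    r = sv([1 / 3] * 3)
    score = compute_pai(o, r)
    assert score.pai == pytest.approx(0.25)
    assert score.d_realized == pytest.approx(0.5)
    assert score.d_baseline == pytest.approx(1 / 3)


def test_pai_negative_regime():
    # observed more uniform than the reference -> score below zero
    o = sv([1 / 3] * 3)
    r = sv([0.5, 0.5, 0.0])
    assert compute_pai(o, r).pai == pytest.approx(-1 / 3)


def test_pai_degenerate_reference_point_mass():
    o = sv([0.5, 0.5])
    r = sv([1.0, 0.0])
    with pytest.raises(DegenerateInputError):
        compute_pai(o, r)


def test_pai_universe_mismatch():
    with pytest.raises(SchemaError):
        compute_pai(sv([0.5, 0.5], ["a", "b"]), sv([0.5, 0.5], ["a", "c"]))


def test_pai_with_bias_correction_preserves_endpoints():
    k, n = 4, 50
    r = sv([1.0 / k] * k)
    assert compute_pai(r, r, bias_correction_n=n).pai == pytest.approx(0.0)
    o = sv([1.0] + [0.0] * (k - 1))
    assert compute_pai(o, r, bias_correction_n=n).pai == pytest.approx(1.0)


def test_pai_reference_relative_functionals_normalized():
    r = sv([0.2, 0.3, 0.5])
    o = sv([0.5, 0.3, 0.2])
    for f in ("gini_vs_reference", "theil_vs_reference"):
        assert compute_pai(r, r, f).pai == pytest.approx(0.0, abs=1e-12)
        worst = sv([1.0, 0.0, 0.0])  # point mass at the smallest ref share
        assert compute_pai(worst, r, f).pai == pytest.approx(1.0)
        mid = compute_pai(o, r, f).pai
        assert 0.0 < mid < 1.0


# ---------------------------------------------------------------------------
# Properties
# ---------------------------------------------------------------------------

count_lists = st.lists(st.integers(min_value=0, max_value=20), min_size=2,
                       max_size=6).filter(lambda c: sum(c) > 0)
weight_lists = st.lists(st.integers(min_value=1, max_value=20), min_size=2,
                        max_size=6)


@settings(max_examples=200, deadline=None)
@given(st.data())
def test_oracle_equivalence_small_instances(data):
    counts = data.draw(count_lists)
    weights = data.draw(weight_lists.filter(
        lambda w: len(w) >= 1))
    n = max(len(counts), len(weights), 2)
    counts = (counts + [0] * n)[:n]
    weights = (weights + [1] * n)[:n]
    if sum(counts) == 0:
        counts[0] = 1
    zips = [f"Z{i}" for i in range(n)]
    o = ShareVector.from_counts(pd.Series(counts, index=zips, dtype=float))
    r = ShareVector.from_counts(pd.Series(weights, index=zips, dtype=float))
    want = oracle_pai(dict(zip(zips, counts)), dict(zip(zips, weights)))
    assert compute_pai(o, r).pai == pytest.approx(want, abs=1e-12)


@settings(max_examples=100, deadline=None)
@given(counts=count_lists, seed=st.integers(0, 10_000))
def test_permutation_equivariance(counts, seed):
    n = len(counts)
    weights = list(range(1, n + 1))
    zips = [f"Z{i}" for i in range(n)]
    perm = np.random.default_rng(seed).permutation(n)
    o1 = ShareVector.from_counts(pd.Series(counts, index=zips, dtype=float))
    r1 = ShareVector.from_counts(pd.Series(weights, index=zips, dtype=float))
    o2 = ShareVector.from_counts(
        pd.Series([counts[i] for i in perm], index=zips, dtype=float))
    r2 = ShareVector.from_counts(
        pd.Series([weights[i] for i in perm], index=zips, dtype=float))
    assert compute_pai(o1, r1).pai == pytest.approx(compute_pai(o2, r2).pai,
                                                    abs=1e-12)


@settings(max_examples=100, deadline=None)
@given(counts=count_lists, weights=weight_lists)
def test_pai_upper_bound_and_attainment(counts, weights):
    n = max(len(counts), len(weights))
    counts = (counts + [0] * n)[:n]
    weights = (weights + [1] * n)[:n]
    if n < 2:
        return
    zips = [f"Z{i}" for i in range(n)]
    o = ShareVector.from_counts(pd.Series(counts, index=zips, dtype=float))
    r = ShareVector.from_counts(pd.Series(weights, index=zips, dtype=float))
    pai = compute_pai(o, r).pai
    assert pai <= 1.0 + 1e-12
    is_point_mass = sum(c > 0 for c in counts) == 1
    if is_point_mass:
        assert pai == pytest.approx(1.0)
    else:
        assert pai < 1.0


@settings(max_examples=100, deadline=None)
@given(counts=st.lists(st.integers(0, 20), min_size=3, max_size=8).filter(
    lambda c: sum(c) > 0))
def test_merge_monotonicity_share_concentration(counts):
    """Merging two zips never decreases the concentration of a vector."""
    zips = [f"Z{i}" for i in range(len(counts))]
    v = ShareVector.from_counts(pd.Series(counts, index=zips, dtype=float))
    merged = [counts[0] + counts[1]] + counts[2:]
    mz = zips[1:]
    vm = ShareVector.from_counts(pd.Series(merged, index=mz, dtype=float))
    assert dispersion(vm) >= dispersion(v) - 1e-12


# ---------------------------------------------------------------------------
# Batch computation
# ---------------------------------------------------------------------------

def _two_by_two_encounters():
    rows = []
    for year in (2018, 2019):
        for cat in ("C1", "C2"):
            for z, n in (("Z1", 3), ("Z2", 2), ("Z3", 2)):
                rows += [{"year": year, "category_id": cat, "zip": z}] * n
    return make_encounters(rows)


def test_pai_by_category_year_cardinality(toy_population, toy_metadata):
    enc = _two_by_two_encounters()
    res = pai_by_category_year(enc, toy_population, toy_metadata)
    assert len(res) == 4
    assert list(res.columns) == list(PAI_COLUMNS)
    assert set(res["year"]) == {2018, 2019}
    assert (res["n_procedures"] == 7).all()
    assert (res["n_zips"] == 3).all()


def test_pai_by_category_year_min_volume(toy_population, toy_metadata,
                                         caplog):
    enc = _two_by_two_encounters()
    with caplog.at_level("INFO", logger="pai"):
        res = pai_by_category_year(enc, toy_population, toy_metadata,
                                   PAIConfig(min_volume=50))
    assert res.empty
    assert "volume" in caplog.text


def test_pai_by_category_year_category_specific(toy_population,
                                                toy_metadata):
    enc = _two_by_two_encounters()
    res = pai_by_category_year(
        enc, toy_population, toy_metadata,
        PAIConfig(reference_mode="category_specific"))
    assert (res["reference_mode"] == "category_specific").all()
    assert len(res) == 4


def test_pai_by_category_year_deterministic(toy_population, toy_metadata):
    enc = _two_by_two_encounters()
    a = pai_by_category_year(enc, toy_population, toy_metadata)
    b = pai_by_category_year(enc, toy_population, toy_metadata)
    pd.testing.assert_frame_equal(a, b)


def test_bootstrap_pai_brackets_estimate(toy_population):
    rng = np.random.default_rng(0)
    rows = [{"zip": z} for z in rng.choice(["Z1", "Z2", "Z3"], size=300,
                                           p=[0.5, 0.3, 0.2])]
    enc = make_encounters(rows)
    res = pai_by_category_year(enc, toy_population)
    est = res["pai"].iloc[0]
    lo, hi = bootstrap_pai(enc, toy_population, "C1", 2019, n_boot=100,
                           seed=42)
    assert lo <= est <= hi
    # deterministic under the same seed
    assert (lo, hi) == bootstrap_pai(enc, toy_population, "C1", 2019,
                                     n_boot=100, seed=42)
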