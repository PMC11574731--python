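"""Study-level analytics: rankings, fits, longitudinal change, terciles.

These operations consume the score and concentration tables produced by
:mod:`pai.index` and :mod:`pai.market` and reproduce the standard analysis
surfaces: a volume-filtered ranking by score, ordinary-least-squares fits
of score on hospital count (cross-sectional and in changes), pairwise
percent differences, and tercile summaries of category characteristics
with a top-versus-bottom significance test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    CategoryMetadata,
    DegenerateInputError,
    EncounterTable,
    SchemaError,
)

logger = logging.getLogger("pai")


# ---------------------------------------------------------------------------
# Percent differences
# ---------------------------------------------------------------------------

def percent_difference(pai_a: float, pai_b: float) -> float:
    """Percent by which ``pai_a`` exceeds ``pai_b``: 100*(a/b - 1), rounded
    to one decimal."""
    if pai_b == 0:
        raise DegenerateInputError(
            "percent difference undefined against a zero score"
        )
    return round(100.0 * (pai_a / pai_b - 1.0), 1)


# ---------------------------------------------------------------------------
# Ranked table
# ---------------------------------------------------------------------------

def ranked_table(pai_results: pd.DataFrame, hhi_results: pd.DataFrame,
                 year: int, top_n: int = 40,
                 meta: CategoryMetadata | None = None) -> pd.DataFrame:
    """Top-``top_n`` categories by volume, ranked by score descending.

    Ties in score break by volume descending. Columns: rank, category_id,
    (label,) pai, n_procedures, n_hospitals, hhi.
    """
    p = pai_results[pai_results["year"] == year]
    if p.empty:
        raise ValueError(f"no score results for year {year}")
    h = hhi_results.loc[hhi_results["year"] == year,
                        ["category_id", "n_hospitals", "hhi"]]
    merged = p.merge(h, on="category_id", how="left")
    if top_n > len(merged):
        logger.warning("ranked_table: top_n=%d exceeds %d available "
                       "categories; truncating", top_n, len(merged))
        top_n = len(merged)
    top = merged.nlargest(top_n, "n_procedures", keep="first")
    top = top.sort_values(["pai", "n_procedures"], ascending=[False, False],
                          kind="stable").reset_index(drop=True)
    top.insert(0, "rank", np.arange(1, len(top) + 1))
    cols = ["rank", "category_id", "pai", "n_procedures", "n_hospitals", "hhi"]
    out = top[cols]
    if meta is not None:
        out = out.merge(meta.frame[["category_id", "label"]],
                        on="category_id", how="left")
        out = out[["rank", "category_id", "label", "pai", "n_procedures",
                   "n_hospitals", "hhi"]]
    return out


# ---------------------------------------------------------------------------
# Fits
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LinearFit:
    slope: float
    stderr: float
    intercept: float
    correlation: float
    n: int


def _ols(x: np.ndarray, y: np.ndarray) -> LinearFit:
    if len(x) < 3:
        raise DegenerateInputError("need at least 3 points for a fit")
    if np.ptp(x) == 0:
        raise DegenerateInputError("degenerate regressor: x is constant")
    res = stats.linregress(x, y)
    return LinearFit(slope=float(res.slope), stderr=float(res.stderr),
                     intercept=float(res.intercept),
                     correlation=float(res.rvalue), n=len(x))


def pai_hospitals_fit(pai_results: pd.DataFrame, hhi_results: pd.DataFrame,
                      year: int, volume_quantile: float = 0.2) -> LinearFit:
    """OLS of score on offering-hospital count over high-volume categories.

    ``volume_quantile`` keeps the top fraction of categories by volume
    (0.2 = top quintile). Returns slope per hospital, its standard error,
    and the Pearson correlation.
    """
    if not 0 < volume_quantile <= 1:
        raise ValueError("volume_quantile must lie in (0, 1]")
    p = pai_results[pai_results["year"] == year]
    h = hhi_results.loc[hhi_results["year"] == year,
                        ["category_id", "n_hospitals"]]
    merged = p.merge(h, on="category_id", how="inner")
    if merged.empty:
        raise ValueError(f"no joined results for year {year}")
    thresh = merged["n_procedures"].quantile(1.0 - volume_quantile)
    kept = merged[merged["n_procedures"] >= thresh]
    return _ols(kept["n_hospitals"].to_numpy(dtype=float),
                kept["pai"].to_numpy(dtype=float))


def longitudinal_change(pai_results: pd.DataFrame, hhi_results: pd.DataFrame,
                        year0: int, year1: int,
                        ) -> tuple[pd.DataFrame, LinearFit]:
    """Per-category change between two years, plus an OLS fit.

    Percent changes are 100*(x1/x0 - 1). The fit regresses the *absolute*
    change in score on the percent change in hospital count (so the slope
    reads as score change per percentage point of hospital growth).
    Categories missing in either year are excluded and logged.
    """
    p = pai_results.pivot_table(index="category_id", columns="year",
                                values="pai", aggfunc="first")
    h = hhi_results.pivot_table(index="category_id", columns="year",
                                values="n_hospitals", aggfunc="first")
    for frame, need in ((p, (year0, year1)), (h, (year0, year1))):
        for y in need:
            if y not in frame.columns:
                raise ValueError(f"year {y} absent from results")
    joined = pd.DataFrame({
        "pai0": p[year0], "pai1": p[year1],
        "hosp0": h[year0], "hosp1": h[year1],
    })
    dropped = joined[joined.isna().any(axis=1)].index
    if len(dropped):
        logger.info("longitudinal_change: excluding %d categorie(s) missing "
                    "in one year: %s", len(dropped), list(dropped)[:5])
    joined = joined.dropna()
    out = pd.DataFrame({
        "category_id": joined.index,
        "delta_pai": (joined["pai1"] - joined["pai0"]).to_numpy(),
        "pct_change_pai": np.where(
            joined["pai0"] != 0,
            100.0 * (joined["pai1"] / joined["pai0"] - 1.0), np.nan),
        "pct_change_hospitals": 100.0 * (joined["hosp1"] / joined["hosp0"]
                                         - 1.0).to_numpy(),
    }).reset_index(drop=True)
    fit = _ols(out["pct_change_hospitals"].to_numpy(),
               out["delta_pai"].to_numpy())
    return out, fit


# ---------------------------------------------------------------------------
# Terciles
# ---------------------------------------------------------------------------

TERCILES = ("low", "mid", "high")


def tercile_assignments(pai: pd.Series) -> pd.Series:
    """Partition categories into score terciles of near-equal size.

    Sizes differ by at most one; remainder items go to the *lower*
    terciles, so 356 categories split 119/119/118 (low/mid/high).
    """
    n = len(pai)
    if n < 3:
        raise ValueError("need at least 3 categories for terciles")
    base, rem = divmod(n, 3)
    sizes = [base + (1 if i < rem else 0) for i in range(3)]
    order = pai.sort_values(kind="stable").index
    labels = pd.Series(index=pai.index, dtype=object)
    start = 0
    for name, size in zip(TERCILES, sizes):
        labels.loc[order[start:start + size]] = name
        start += size
    return labels


_ENCOUNTER_CHARACTERISTICS: dict[str, tuple[str, ...]] = {
    # name -> columns required on the encounter table
    "mean_age": ("age",),
    "pct_female": ("sex",),
    "pct_white": ("race",),
    "pct_black": ("race",),
    "pct_hispanic": ("race",),
    "pct_medicare": ("payer",),
    "pct_medicaid": ("payer",),
    "mean_cost": ("cost",),
    "mean_los_days": ("los_days",),
    "pct_died": ("died",),
    "pct_elective": ("elective",),
}
_META_CHARACTERISTICS = ("pct_minimally_invasive", "pct_era_new",
                         "pct_device_implant")
_RESULT_CHARACTERISTICS = ("n_procedures", "n_hospitals", "hhi")


def _category_characteristics(enc_frame: pd.DataFrame,
                              names: Sequence[str]) -> pd.DataFrame:
    g = enc_frame.groupby("category_id")
    cols = {}
    for name in names:
        if name == "mean_age":
            cols[name] = g["age"].mean()
        elif name == "pct_female":
            cols[name] = g["sex"].apply(lambda s: 100.0 * (s == "F").mean())
        elif name.startswith("pct_") and name[4:] in ("white", "black",
                                                      "hispanic"):
            race = name[4:]
            cols[name] = g["race"].apply(
                lambda s, r=race: 100.0 * (s == r).mean())
        elif name in ("pct_medicare", "pct_medicaid"):
            payer = name[4:]
            cols[name] = g["payer"].apply(
                lambda s, p=payer: 100.0 * (s == p).mean())
        elif name == "mean_cost":
            cols[name] = g["cost"].mean()
        elif name == "mean_los_days":
            cols[name] = g["los_days"].mean()
        elif name in ("pct_died", "pct_elective"):
            col = name[4:]
            cols[name] = g[col].apply(lambda s: 100.0 * s.astype(float).mean())
    return pd.DataFrame(cols)


def _welch_p(top: np.ndarray, bottom: np.ndarray) -> float:
    top = top[~np.isnan(top)]
    bottom = bottom[~np.isnan(bottom)]
    if len(top) < 2 or len(bottom) < 2:
        return float("nan")
    if np.ptp(top) == 0 and np.ptp(bottom) == 0:
        # no variation anywhere: identical means -> 1 by convention
        return 1.0 if top[0] == bottom[0] else 0.0
    return float(stats.ttest_ind(top, bottom, equal_var=False).pvalue)


@dataclass
class TercileSummary:
    """Per-characteristic tercile means/SDs and top-vs-bottom p-values."""

    table: pd.DataFrame
    sizes: dict[str, int]
    assignments: pd.Series


def tercile_summary(pai_results: pd.DataFrame,
                    enc: EncounterTable | None = None,
                    meta: CategoryMetadata | None = None,
                    hhi_results: pd.DataFrame | None = None,
                    year: int | None = None,
                    characteristics: Sequence[str] | None = None,
                    ) -> TercileSummary:
    """Summarize category characteristics by score tercile.

    Each category is one observation: patient-level characteristics are
    first averaged within category, then means and SDs are taken over the
    categories of each tercile. The p-value compares the high and low
    terciles with a Welch two-sample t-test. Characteristics whose source
    columns are unavailable are skipped with a warning.
    """
    p = pai_results if year is None else \
        pai_results[pai_results["year"] == year]
    if p["category_id"].duplicated().any():
        raise SchemaError("one score row per category required "
                          "(pass year= to disambiguate)")
    pai = p.set_index("category_id")["pai"]
    labels = tercile_assignments(pai)

    feats = pd.DataFrame(index=pai.index)
    feats["pai"] = pai
    feats["n_procedures"] = p.set_index("category_id")["n_procedures"]

    if enc is not None:
        enc_frame = enc.frame if year is None else enc.subset(year=year)
        wanted = [n for n, req in _ENCOUNTER_CHARACTERISTICS.items()
                  if all(c in enc_frame.columns
                         and enc_frame[c].notna().any() for c in req)]
        skipped = set(_ENCOUNTER_CHARACTERISTICS) - set(wanted)
        if skipped:
            logger.warning("tercile_summary: skipping characteristics with "
                           "missing columns: %s", sorted(skipped))
        feats = feats.join(_category_characteristics(enc_frame, wanted))
    if meta is not None:
        m = meta.frame.set_index("category_id")
        feats["pct_minimally_invasive"] = 100.0 * m["minimally_invasive"] \
            .astype(float)
        feats["pct_era_new"] = 100.0 * m["era_new"].astype(float)
        feats["pct_device_implant"] = 100.0 * m["device_implant"].astype(float)
    if hhi_results is not None:
        h = hhi_results if year is None else \
            hhi_results[hhi_results["year"] == year]
        hset = h.set_index("category_id")
        feats["n_hospitals"] = hset["n_hospitals"]
        feats["hhi"] = hset["hhi"]

    if characteristics is not None:
        missing = [c for c in characteristics if c not in feats.columns]
        if missing:
            logger.warning("tercile_summary: requested characteristics "
                           "unavailable: %s", missing)
        keep = [c for c in characteristics if c in feats.columns]
    else:
        keep = list(feats.columns)

    rows = []
    for name in keep:
        vals = feats[name].astype(float)
        row: dict[str, object] = {"characteristic": name}
        for terc in TERCILES:
            grp = vals[labels == terc]
            row[f"mean_{terc}"] = float(grp.mean())
            row[f"sd_{terc}"] = float(grp.std(ddof=1))
        row["p_value"] = _welch_p(vals[labels == "high"].to_numpy(),
                                  vals[labels == "low"].to_numpy())
        rows.append(row)
    table = pd.DataFrame(rows)
    sizes = {t: int((labels == t).sum()) for t in TERCILES}
    return TercileSummary(table=table, sizes=sizes, assignments=labels)


# ---------------------------------------------------------------------------
# Plots
# ---------------------------------------------------------------------------

def plot_pai_vs_hospitals(pai_results: pd.DataFrame, hhi_results: pd.DataFrame,
                          year: int, path: str | Path,
                          volume_quantile: float = 0.2) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    p = pai_results[pai_results["year"] == year]
    h = hhi_results.loc[hhi_results["year"] == year,
                        ["category_id", "n_hospitals"]]
    merged = p.merge(h, on="category_id", how="inner")
    thresh = merged["n_procedures"].quantile(1.0 - volume_quantile)
    kept = merged[merged["n_procedures"] >= thresh]
    fit = _ols(kept["n_hospitals"].to_numpy(dtype=float),
               kept["pai"].to_numpy(dtype=float))
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(kept["n_hospitals"], kept["pai"], s=18, alpha=0.7)
    xs = np.linspace(kept["n_hospitals"].min(), kept["n_hospitals"].max(), 50)
    ax.plot(xs, fit.intercept + fit.slope * xs, color="crimson",
            label=f"slope={fit.slope:.2e}, r={fit.correlation:.2f}")
    ax.set_xlabel("hospitals offering the category")
    ax.set_ylabel("access-inequality score")
    ax.set_title(f"Score vs hospital count, {year}")
    ax.legend(frameon=False)
    fig.tight_layout()
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_change_vs_change(change: pd.DataFrame, fit: LinearFit,
                          path: str | Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(change["pct_change_hospitals"], change["delta_pai"], s=18,
               alpha=0.7)
    xs = np.linspace(change["pct_change_hospitals"].min(),
                     change["pct_change_hospitals"].max(), 50)
    ax.plot(xs, fit.intercept + fit.slope * xs, color="crimson",
            label=f"slope={fit.slope:.2e}")
    ax.axhline(0, lw=0.5, color="gray")
    ax.set_xlabel("% change in hospitals offering")
    ax.set_ylabel("change in score")
    ax.legend(frameon=False)
    fig.tight_layout()
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=150)
    plt.close(fig)
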