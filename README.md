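# pai — procedure access-inequality analytics

`pai` quantifies geographic inequality in inpatient-procedure utilization
from encounter-level discharge data. For each procedure category and year
it computes a standardized score on a 0–1 scale: the normalized gap between
the dispersion of the observed recipient distribution over zip codes and
the dispersion of an age–sex-adjusted expected-utilization baseline
(indirect standardization against zip-level population counts). A score of
0 means the procedure's recipients follow the overall hospitalization
distribution exactly; 1 means every recipient lives in a single zip code;
values below 0 indicate a distribution *more* uniform than the baseline.

The package also provides:

- **Hospital-market concentration** — per-category Herfindahl–Hirschman
  index on the percent-share scale (0–10 000); equal volumes across 40
  hospitals give exactly 250, across 80 exactly 125.
- **Study analytics** — volume-filtered rankings, OLS fits of score on
  offering-hospital count (cross-sectional and in changes), pairwise
  percent differences, and tercile summaries of category characteristics
  with a Welch top-vs-bottom test.
- **A synthetic-data simulator** — zips on a unit square with log-normal
  populations, category-specific stratum rates, hospital offering subsets,
  and exponential distance-gating of demand, with full ground truth, so the
  entire pipeline is testable without restricted discharge data.

## Input formats

Three delimited tables (comma or tab, header row, UTF-8; column names
remappable via a YAML schema config):

1. **Encounters** — `year, zip, age, sex, category_id, hospital_id` plus
   optional `payer, race, cost, los_days, died, elective`. One row per
   discharge. Zip codes are opaque strings (leading zeros preserved).
2. **Population** — `zip, age_band, sex, population` with age bands
   defaulting to `0-17, 18-44, 45-64, 65-74, 75+`.
3. **Category metadata** — `category_id, label, minimally_invasive,
   era_new, device_implant`.

## CLI

```sh
pai simulate --config sim.yaml --outdir fixtures/
pai compute  --encounters enc.csv --population pop.csv --meta meta.csv --out pai.csv
pai hhi      --encounters enc.csv --out hhi.csv
pai report   --pai pai.csv --hhi hhi.csv --encounters enc.csv --meta meta.csv \
             --year 2019 --top 40 --out report/
pai run-all  --config run.yaml --outdir run/
```

`run-all` chains all stages from one YAML config and writes a
`manifest.json` with the config echo, package version, and input checksums;
runs are bit-for-bit reproducible given a seed. `pai --help` documents all
defaults.

The score configuration selects the dispersion functional
(`share_concentration` by default, with `gini_vs_reference` and
`theil_vs_reference` as alternatives), the reference mode
(`all_hospitalizations` or `category_specific`), a minimum category volume,
and an optional finite-sample correction (off by default). Both the
functional and the reference mode are recorded in every output row.

## Python API

```python
import pai

sim = pai.simulate(pai.SimConfig(n_zips=200, n_hospitals=40,
                                 n_categories=8, seed=0))
scores = pai.pai_by_category_year(sim.encounters, sim.population,
                                  sim.metadata)
markets = pai.hhi_by_category_year(sim.encounters)
fit = pai.pai_hospitals_fit(scores, markets, year=2019)
```

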