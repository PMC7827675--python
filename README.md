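# safascore

Multicriteria sustainability assessment for cattle farming systems, built on
the FAO SAFA structure (Sustainability Assessment of Food and Agriculture
systems). The package is aimed at researchers comparing production systems —
for example Native Silvopastoral (NS), Intensive Silvopastoral (IS) and grass
Monoculture (MS) cattle farms in the Mexican tropics — who need a reproducible
path from raw field data to theme ratings, farm rankings and sustainability
polygons.

## What it computes

The assessment hierarchy has 4 dimensions (Good Governance, Environmental
Integrity, Economic Resilience, Social Well-Being), 21 themes, 58 subthemes
and 116 indicators. Every indicator is scored as a percent and rated on five
levels over the bands

```
unacceptable [0, 20)   limited [20, 40)   moderate [40, 60)   good [60, 80)   best [80, 100]
```

Most indicators are questionnaire percents consumed directly; the rest are
computed by adapters from field data:

* **Animal welfare** — Welfare Quality® principle scores (0–100) pass through
  unchanged to the five animal-welfare indicators.
* **Wildlife diversity** — per taxon group (birds, bats, rodents) the
  Shannon–Wiener index H′ = −Σ pᵢ ln pᵢ is computed from capture counts and
  normalised so the cohort maximum is 100 %; the number of endemic species
  maps to a rating (≥5 → best … 1 → unacceptable); a configurable weighted
  key-species score rewards endemic and at-risk species and penalises
  introduced ones.
* **Soil quality** — each soil property is expressed as
  min(measured/reference, 1) against undisturbed reference soils, averaged
  per indicator.

Scores aggregate upward as unweighted means (excluded subthemes omitted from
scores and accuracy totals), themes are rated from their aggregated percent,
and each farm is condensed to a **positive valuation** (percent of its 21
themes rated best or good) and a **negative valuation** (percent rated
limited or unacceptable; moderate themes are dropped). Percentages use a
custom rounding rule (fractional part ≤ 0.5 down, > 0.5 up). Farms are ranked
by positive valuation (ties broken by lower negative valuation), and the
cohort maxima define five contiguous integer rating bands (max/5 scaled by
factors 1–5) used to categorise every valuation.

## Worked example

```python
import safascore as s

fw = s.apply_exclusions(s.load_framework(), s.DEFAULT_EXCLUSIONS)
study = s.simulate_study(seed=1)                    # 9 synthetic farms (3 NS, 3 IS, 3 MS)
assessments = s.assess_study(study.farms, fw)
results, pos_bands, neg_bands = s.valuate_study(assessments)
for r in results:
    print(r.rank, r.farm_id, f"+{r.positive_pct}% -{r.negative_pct}%",
          r.positive_category.label, r.negative_category.label)
```

prints

```
1 NS2 +62% -14% best limited
2 NS1 +52% -14% best limited
3 NS3 +52% -14% best limited
4 IS2 +43% -14% good limited
5 IS1 +38% -14% good limited
6 IS3 +38% -14% good limited
7 MS2 +33% -14% moderate limited
8 MS1 +24% -14% limited limited
9 MS3 +19% -19% limited unacceptable
```

Each row is a farm's rank, its positive/negative valuation percentages, and
the categories those valuations receive against the cohort-relative bands
(here built from the maxima +62 and −19). The native silvopastoral farms
lead the ranking, the monocultures trail it — the qualitative contrast the
synthetic archetypes encode.

The same pipeline is available from the shell:

```
safascore run --seed 1 --out study/
```

which writes `ranking.csv`, `bands.json`, `theme_results.csv`,
`assessments.json` and one sustainability polygon SVG per farm.

## Layout

* `src/safascore/framework.py` — hierarchy types, rating scale, config loading
* `src/safascore/adapters.py` — WQ / diversity / soil indicator converters
* `src/safascore/aggregation.py` — subtheme/theme aggregation, farm assembly
* `src/safascore/valuation.py` — valuations, rating bands, ranking
* `src/safascore/reporting.py` — polygons and report export
* `src/safascore/synthetic.py` — seeded archetype data generator
* `src/safascore/cli.py` — `safascore simulate|assess|rank|plot|run`

See `docs/methods.md` for the modelling choices and their rationale.
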