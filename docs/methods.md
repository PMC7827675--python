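# Methods

This note records the model, the numerical conventions, and the design
choices made where the underlying procedure left the design open.

## Assessment model

A farm assessment is a four-level hierarchy: 4 dimensions → 21 themes → 58
subthemes → 116 indicators. Indicators carry percent scores in [0, 100] and
are rated on five ordered levels (unacceptable < limited < moderate < good <
best) over percent bands. Band boundaries are **lower-inclusive,
upper-exclusive, with the top band closed at 100**: [0,20), [20,40), [40,60),
[60,80), [80,100]. The published band descriptions overlap at their
endpoints; this convention gives a unique assignment consistent with every
printed band pair.

The bundled default framework carries the 21 published theme names with
their per-dimension indicator counts (19 + 52 + 26 + 19 = 116). Only the
subthemes and indicators that are individually named in the source material
are carried verbatim (the five excludable subthemes, the animal-welfare,
biodiversity and soil-quality indicators); the remaining slots are
placeholder entries marked `placeholder: true`, distributed round-robin so
the counts hold and every subtheme has at least one indicator. The placeholders
deliberately avoid inventing guideline content that the package cannot verify.

### Subtheme exclusion

A subtheme may be excluded with a written justification; an excluded
subtheme contributes to neither the score aggregation nor the accuracy
totals. The five default exclusions (Stability of Production, Air Quality,
Water Quality, Material Use, Product Information) leave 53 active subthemes.
`apply_exclusions` is validated to be idempotent and inert: attaching scores
to excluded subthemes cannot change any theme result.

## Indicator adapters

* **Welfare Quality**: principle scores already live on 0–100 and pass
  through unchanged (Good Feeding → Animal Health Practices, Good Health →
  Animal Health, Appropriate Behavior → Appropriate Animal Husbandry,
  overall → Freedom of Stress). The handling-practices indicator is defined
  as a combination of welfare criteria without a stated combiner; we use the
  unweighted mean of the provided criterion scores, falling back to the
  overall score — symmetric and free of invented weights.
* **Shannon–Wiener diversity**: H′ = −Σ pᵢ ln pᵢ with the natural log (the
  conventional form; the base cancels in the normalisation anyway). Per
  taxon group, each farm's H′ is divided by the **cohort maximum** for that
  group (the cohort is the set of farms in one assessment run), and a farm's
  indicator percent is the unweighted mean of its group percentages. Whether
  the groups were averaged, summed or rated separately in the original
  workflow is not stated; the unweighted mean is the simplest symmetric
  pooling and is isolated in one function.
* **Endemic species count**: ≥5 species → best, 4 → good, 3 → moderate,
  2 → limited, ≤1 → unacceptable. Counts of 0 and counts above 5 are clamped
  to the nearest defined rating so the function is total over observable
  counts.
* **Key species**: the original calculation lives in an inaccessible thesis,
  so the score is made explicit and configurable: each species earns
  `w_endemic`·endemic + `w_at_risk`·at-risk − `w_introduced`·introduced,
  floored at 0, and the farm score is the total as a fraction of
  `max_weight` per species, clamped to [0, 100]. Defaults: all weights 1,
  `max_weight` 2.
* **Soil**: per property, ratio = min(measured/reference, 1) — references
  are stated as maxima from undisturbed soils, so over-reference values
  saturate rather than exceed 100 %. The indicator percent is the mean ratio
  over the indicator's properties (physical structure: texture + organic
  matter; chemical quality: NO₃:NH₄ ratio + organic P; biological quality:
  NO₃:NH₄ ratio + organic C; organic matter: organic C). The source table
  writes "NO3–NO4 relation"; the field is named `no3_nh4_ratio` on the
  presumption that the nitrate:ammonium ratio was meant.

Rating-valued adapters (the endemic count) enter percent aggregation as the
midpoint of their rating band (10/30/50/70/90): the original workflow feeds
ratings to closed-source software whose internal handling is unknown, and
the band midpoint is the unbiased percent representative of a rating.

## Aggregation

Subtheme score = unweighted mean of its indicators' percents; theme score =
unweighted mean of its evaluated subthemes; not-evaluated children are
omitted from numerator and denominator. The original aggregation is
delegated to closed-source software and never stated; the unweighted
arithmetic mean is the only defensible default and is isolated so
alternative combiners can be swapped in. Ratings are derived from percents
**after** aggregation, never by averaging ordinals, which preserves
information. Aggregation is validated against an independent recursive-mean
oracle on randomized small hierarchies and is monotone: raising one
indicator never lowers an ancestor.

Each indicator score carries accuracy metadata (timeframe, data type,
methodology); one point per satisfied criterion (current / primary /
guideline-conform) gives 0–3 points per indicator. A theme's 1/2/3
information-quality label comes from thirds of that range: mean ≥ 2.5 → 1
(high), ≥ 1.5 → 2 (medium), else 3 (low). Adapter-computed indicators are
assigned (current, primary, other): they are current primary field
measurements collected with non-SAFA protocols (Welfare Quality, mist
netting, soil assays).

## Valuation and ranking

Per farm, themes are tallied by rating; positive = best + good counts,
negative = limited + unacceptable, moderate dropped. Percentages are
computed **sum-then-round** — every published percentage equals
round(100·k/21) for an integer theme count k, which per-class rounding would
contradict. The rounding rule rounds fractional parts ≤ 0.5 down; the stated
rule is silent on (0.5, 0.6), and rounding those up is the unique choice
consistent with the published value arising from 2 of 21 themes
(9.52 → 10 %) and with all eight published band cut points.

Bands: the cohort's maximum valuation is divided by 5 and scaled by factors
1–5, each cut point rounded with the same rule; intervals are [0,c₁],
[c₁+1,c₂], …, [c₄+1,max], labelled toward best for positive valuations and
toward unacceptable for negative ones. Bands are cohort-relative by
default (`--fixed-scale` builds them from 100 for cross-study comparison).
A degenerate cohort whose maximum valuation is 0 also falls back to the
100-based scale. Ranking sorts descending by positive valuation, ascending
by negative on ties, and keeps input order on full ties (stable sort —
reproducible without inventing an extra criterion).

## Reporting

The polygon is a polar chart with one spoke per theme (ring order: published
table order within dimensions, dimensions in published order), spoke radius
= rating ordinal + 1 on a 1–5 scale, a closed black rating line, dimension
arcs (blue / green / yellow / grey), rating-coloured markers (dark green /
light green / yellow / orange / red) and the 1/2/3 quality label beside each
theme name. SVG output carries no timestamp and uses a fixed hash salt, so
rendering is byte-deterministic.

## Synthetic data generator

The generator emulates the four raw input streams of a nine-farm field
study: generic questionnaire indicator percents, capture tables, soil
measurements with references, and WQ principle scores, for three archetypes
(NS, IS, MS; default three farms each). Generic percents are truncated
normals on [0, 100] around per-theme archetype means (sd 8); captures use a
Poisson total and Poisson species-pool size with multinomial allocation and
Bernoulli endemic/at-risk/introduced flags (endemic and introduced mutually
exclusive); soil ratios are Beta-distributed with concentration 40 around
the archetype mean; WQ principles are truncated normals (sd 6).

The archetype theme means are synthetic calibration constants chosen once to
encode the qualitative contrast the package is designed to detect — NS high
on Participation (85), Land (80), Biodiversity (78) and Cultural Diversity
(72); IS high on Holistic Management (72); every archetype low on Atmosphere
(10–25) and Water (30); silvopastoral archetypes low on Decent Livelihood
(~30); capture abundance/richness and soil ratios decline from NS to MS.
They are not measured values. Randomness derives from one root seed via
counter-based per-farm sub-seeds, so any farm regenerates identically
whether simulated alone or within a cohort.

What passing tests show — and do not show — about real data: the generator
reproduces the pipeline's input *formats* and the expected *ordering* of
archetypes, but real farm surveys have correlated indicators within themes,
non-normal score distributions, capture-effort differences between farms,
and inter-annual variation, none of which are emulated. Passing the
end-to-end tests demonstrates the pipeline's arithmetic and plumbing, not
field validity of the archetype parameters.

## Problem sizes and numerical conventions

The test suite and the acceptance script use the default nine-farm study;
the archetype contrast (NS mean positive valuation above MS) is measured
over 200 seeds as a sample-mean comparison with a 5-point margin — a
design-level sanity check, not a significance test. Aggregation oracle
checks run 1000 randomized hierarchies. Percent comparisons in tests use
absolute tolerances of 1e−9 (aggregation) and 1e−12 (Shannon closed forms).
Degenerate inputs are defined explicitly: zero-dispersion generators return
the mean; empty capture tables score 0 % with a warning; subthemes with no
scored indicators are not evaluated; themes with no evaluable content are a
hard error because the valuation procedure requires all 21 themes.

## Known limitations

* The unweighted-mean aggregation and the band-midpoint handling of
  rating-valued indicators are stated conventions, not reverse-engineered
  behaviour of the original closed-source tool; absolute theme percents may
  differ from that tool even when orderings agree.
* The key-species score is a transparent stand-in for an unpublished
  calculation and should be recalibrated before substantive use.
* No capture-effort correction or rarefaction is applied to diversity
  indices; cohort normalisation assumes comparable sampling effort.
* Community-survey microdata (respondent-level questionnaires) are out of
  scope; generic indicator scores are consumed as given.
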