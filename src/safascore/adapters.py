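"""Indicator adapters: convert raw field measurements into percent scores.

Three kinds of field data feed computed indicators:

* Welfare Quality (WQ) principle scores (0-100) map directly onto the
  animal-welfare indicators.
* Capture tables of birds, bats and rodents yield Shannon-Wiener diversity
  (normalised against the cohort maximum per taxon group), endemic species
  counts, and a weighted key-species score.
* Soil property measurements are expressed as fractions of reference values
  measured in undisturbed soils of the same area (references are maxima, so
  ratios are capped at 1).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .framework import Rating, RatingScale, DEFAULT_SCALE, percent_to_rating

logger = logging.getLogger(__name__)

__all__ = [
    "TAXON_GROUPS",
    "WQScoreSet",
    "CaptureTable",
    "DiversityStats",
    "SoilMeasurementSet",
    "KeySpeciesWeights",
    "shannon_index",
    "diversity_to_percent",
    "diversity_stats",
    "genetic_diversity_rating",
    "endemic_count_to_rating",
    "key_species_score",
    "soil_indicator_percent",
    "SOIL_INDICATOR_PROPERTIES",
    "wq_to_indicator_scores",
    "WQ_INDICATOR_MAP",
]

TAXON_GROUPS = ("birds", "bats", "rodents")

CAPTURE_COLUMNS = ["taxon_group", "species", "count", "endemic", "at_risk", "introduced"]


@dataclass
class WQScoreSet:
    """Welfare Quality principle (and optionally criterion) scores for one farm."""

    farm_id: str
    principle_scores: dict[str, float]
    criterion_scores: dict[str, float] | None = None

    def __post_init__(self) -> None:
        for name, value in list(self.principle_scores.items()) + list(
            (self.criterion_scores or {}).items()
        ):
            if not 0.0 <= value <= 100.0:
                raise ValueError(f"WQ score {name!r} out of [0, 100]: {value}")


@dataclass
class CaptureTable:
    """Per-farm wildlife capture records (one row per species per taxon group)."""

    farm_id: str
    rows: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in CAPTURE_COLUMNS if c not in self.rows.columns]
        if missing:
            raise ValueError(f"capture table missing columns: {missing}")
        if (self.rows["count"] < 0).any():
            raise ValueError("capture counts must be non-negative")
        bad = set(self.rows["taxon_group"]) - set(TAXON_GROUPS)
        if bad:
            raise ValueError(f"unknown taxon groups: {sorted(bad)}")
        if self.rows.duplicated(subset=["taxon_group", "species"]).any():
            raise ValueError("species must be unique within a taxon group")

    @classmethod
    def empty(cls, farm_id: str) -> "CaptureTable":
        return cls(farm_id, pd.DataFrame(columns=CAPTURE_COLUMNS))

    def group(self, taxon_group: str) -> pd.DataFrame:
        return self.rows[self.rows["taxon_group"] == taxon_group]


@dataclass(frozen=True)
class DiversityStats:
    taxon_group: str
    abundance: int
    richness: int
    shannon_h: float


@dataclass
class SoilMeasurementSet:
    """Soil properties as (measured, reference, units); references are maxima
    observed in undisturbed soils and must be positive."""

    farm_id: str
    properties: dict[str, tuple[float, float, str]]

    def __post_init__(self) -> None:
        for prop, (measured, reference, _units) in self.properties.items():
            if measured < 0:
                raise ValueError(f"soil property {prop!r}: measured value < 0")
            if reference <= 0:
                raise ValueError(f"soil property {prop!r}: reference must be > 0")


@dataclass(frozen=True)
class KeySpeciesWeights:
    """Configurable weights for the key-species score; defaults give one point
    each for endemic and at-risk status, a one-point penalty for introduced
    species, against a two-point per-species maximum."""

    w_endemic: float = 1.0
    w_at_risk: float = 1.0
    w_introduced: float = 1.0
    max_weight: float = 2.0


# ---------------------------------------------------------------------------
# Diversity


def shannon_index(counts: Sequence[int] | Iterable[int]) -> float:
    """Shannon-Wiener diversity index H' = -sum p_i ln p_i (natural log).

    Zero counts are omitted; all-zero or empty input is an error.
    """
    arr = np.asarray(list(counts), dtype=float)
    if arr.size and (arr < 0).any():
        raise ValueError("counts must be non-negative")
    arr = arr[arr > 0]
    if arr.size == 0:
        raise ValueError("shannon_index undefined for empty / all-zero counts")
    p = arr / arr.sum()
    return float(-(p * np.log(p)).sum())


def diversity_to_percent(h: float, h_max: float) -> float:
    """Express an index as a percent of the cohort maximum (100% at the max)."""
    if h_max <= 0:
        raise ValueError("h_max must be positive")
    if not 0.0 <= h <= h_max + 1e-12:
        raise ValueError(f"h={h} outside [0, h_max={h_max}]")
    return min(100.0 * h / h_max, 100.0)


def diversity_stats(table: CaptureTable, taxon_group: str) -> DiversityStats:
    """Abundance, richness and H' for one taxon group of one farm."""
    grp = table.group(taxon_group)
    grp = grp[grp["count"] > 0]
    abundance = int(grp["count"].sum())
    richness = int(len(grp))
    h = shannon_index(grp["count"]) if richness > 0 else 0.0
    return DiversityStats(taxon_group, abundance, richness, h)


def genetic_diversity_rating(
    tables: Mapping[str, CaptureTable],
    scale: RatingScale = DEFAULT_SCALE,
) -> dict[str, tuple[float, Rating]]:
    """Per-farm wild-species diversity percent and rating, cohort-normalised.

    For each taxon group, every farm's H' is divided by the cohort maximum
    for that group; a farm's indicator percent is the unweighted mean of its
    group percentages.  Groups absent from every farm are skipped with a
    warning.
    """
    if not tables:
        raise ValueError("at least one farm required")
    per_group_h: dict[str, dict[str, float]] = {}
    for group in TAXON_GROUPS:
        hs = {fid: diversity_stats(t, group).shannon_h for fid, t in tables.items()}
        if max(hs.values()) <= 0.0:
            logger.warning("taxon group %r absent in every farm; skipped", group)
            continue
        per_group_h[group] = hs
    if not per_group_h:
        raise ValueError("no taxon group has positive abundance cohort-wide")
    out: dict[str, tuple[float, Rating]] = {}
    for fid in tables:
        pcts = [
            diversity_to_percent(hs[fid], max(hs.values()))
            for hs in per_group_h.values()
        ]
        pct = float(np.mean(pcts))
        out[fid] = (pct, percent_to_rating(pct, scale))
    return out


# ---------------------------------------------------------------------------
# Endemic species count and key species

_ENDEMIC_RATING = {1: Rating.UNACCEPTABLE, 2: Rating.LIMITED, 3: Rating.MODERATE,
                   4: Rating.GOOD, 5: Rating.BEST}


def endemic_count_to_rating(n: int) -> Rating:
    """Rating from the number of endemic species: 5 or more -> best, 4 -> good,
    3 -> moderate, 2 -> limited, 1 or 0 -> unacceptable (counts outside the
    1-5 table are clamped to the nearest defined rating)."""
    if n < 0:
        raise ValueError(f"endemic species count must be non-negative: {n}")
    return _ENDEMIC_RATING[min(max(n, 1), 5)]


def key_species_score(
    table: CaptureTable, weights: KeySpeciesWeights = KeySpeciesWeights()
) -> float:
    """Weighted percent score over a farm's species list.

    Each species earns ``w_endemic`` if endemic plus ``w_at_risk`` if at risk,
    minus ``w_introduced`` if introduced, floored at zero; the farm score is
    the total as a percentage of the per-species maximum, clamped to [0, 100].
    """
    rows = table.rows
    if len(rows) == 0:
        logger.warning("key_species_score: empty capture table for %s", table.farm_id)
        return 0.0
    w = (
        weights.w_endemic * rows["endemic"].astype(float)
        + weights.w_at_risk * rows["at_risk"].astype(float)
        - weights.w_introduced * rows["introduced"].astype(float)
    ).clip(lower=0.0)
    score = 100.0 * w.sum() / (len(rows) * weights.max_weight)
    return float(min(max(score, 0.0), 100.0))


# ---------------------------------------------------------------------------
# Soil

#: Soil properties entering each soil-quality indicator.  The nitrate:ammonium
#: ratio field is named no3_nh4_ratio (the source table's "NO3-NO4 relation"
#: is presumed a typo for NO3-NH4).
SOIL_INDICATOR_PROPERTIES: dict[str, tuple[str, ...]] = {
    "soil-physical-structure": ("texture_score", "organic_matter_pct"),
    "soil-chemical-quality": ("no3_nh4_ratio", "total_organic_p"),
    "soil-biological-quality": ("no3_nh4_ratio", "total_organic_c"),
    "soil-organic-matter": ("total_organic_c",),
}


def soil_indicator_percent(ms: SoilMeasurementSet, indicator: str) -> float:
    """Percent score for one soil-quality indicator.

    Each required property contributes min(measured/reference, 1); the
    indicator percent is 100 times the mean of those ratios.
    """
    try:
        props = SOIL_INDICATOR_PROPERTIES[indicator]
    except KeyError:
        raise KeyError(f"unknown soil indicator: {indicator!r}") from None
    ratios = []
    for prop in props:
        if prop not in ms.properties:
            raise ValueError(
                f"soil property {prop!r} required by indicator {indicator!r} "
                f"missing for farm {ms.farm_id!r}"
            )
        measured, reference, _units = ms.properties[prop]
        ratios.append(min(measured / reference, 1.0))
    return float(100.0 * np.mean(ratios))


# ---------------------------------------------------------------------------
# Welfare Quality

#: Animal-welfare indicator <- WQ principle feeding it.
WQ_INDICATOR_MAP: dict[str, str] = {
    "animal-health-practices": "good_feeding",
    "animal-health": "good_health",
    "appropriate-animal-husbandry": "appropriate_behavior",
    "freedom-of-stress": "overall",
}


def wq_to_indicator_scores(wq: WQScoreSet) -> dict[str, float]:
    """Map WQ principle scores onto the five animal-welfare indicators.

    Principle scores pass through unchanged (both live on 0-100).  The
    handling-practices indicator combines the listed welfare criteria as an
    unweighted mean when criterion scores are given, else it falls back to
    the overall farm score.
    """
    out: dict[str, float] = {}
    for indicator, principle in WQ_INDICATOR_MAP.items():
        if principle not in wq.principle_scores:
            raise ValueError(
                f"WQ principle {principle!r} missing for farm {wq.farm_id!r}; "
                f"blocks indicator {indicator!r}"
            )
        out[indicator] = float(wq.principle_scores[principle])
    if wq.criterion_scores:
        out["humane-animal-handling-practices"] = float(
            np.mean(list(wq.criterion_scores.values()))
        )
    else:
        if "overall" not in wq.principle_scores:
            raise ValueError(
                f"WQ overall score missing for farm {wq.farm_id!r}; blocks "
                "indicator 'humane-animal-handling-practices'"
            )
        out["humane-animal-handling-practices"] = float(wq.principle_scores["overall"])
    return out
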