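"""Upward aggregation: indicators -> subthemes -> themes -> farm assessment.

Scores climb the hierarchy as unweighted arithmetic means of percent scores,
with excluded subthemes and not-evaluated children omitted from both the
numerator and the denominator.  Ratings are derived from percents only after
aggregation (never by averaging ordinal ratings), and each theme carries an
information-quality label (1 = high, 2 = medium, 3 = low) summarising the
accuracy of the data behind its indicators.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .adapters import (
    CaptureTable,
    KeySpeciesWeights,
    SoilMeasurementSet,
    WQScoreSet,
    endemic_count_to_rating,
    genetic_diversity_rating,
    key_species_score,
    soil_indicator_percent,
    wq_to_indicator_scores,
)
from .framework import Framework, Rating, percent_to_rating

logger = logging.getLogger(__name__)

__all__ = [
    "Accuracy",
    "IndicatorScore",
    "ThemeResult",
    "FarmAssessment",
    "FarmInputs",
    "subtheme_score",
    "theme_score",
    "accuracy_quality",
    "assess_farm",
    "assess_study",
]

TIMEFRAMES = ("current", "outdated")
DATA_TYPES = ("primary", "secondary", "estimate")
METHODOLOGIES = ("safa_conform", "other")


@dataclass(frozen=True)
class Accuracy:
    """Data-accuracy metadata for one indicator score.

    One point is earned for each satisfied criterion: the data is current,
    it is primary, and it was collected following the assessment guidelines.
    """

    timeframe: str = "current"
    data_type: str = "primary"
    methodology: str = "safa_conform"

    def __post_init__(self) -> None:
        if self.timeframe not in TIMEFRAMES:
            raise ValueError(f"timeframe must be one of {TIMEFRAMES}")
        if self.data_type not in DATA_TYPES:
            raise ValueError(f"data_type must be one of {DATA_TYPES}")
        if self.methodology not in METHODOLOGIES:
            raise ValueError(f"methodology must be one of {METHODOLOGIES}")

    @property
    def points(self) -> int:
        return (
            (self.timeframe == "current")
            + (self.data_type == "primary")
            + (self.methodology == "safa_conform")
        )


#: Accuracy assigned to adapter-computed indicators: current primary field
#: measurements collected with non-SAFA protocols (WQ, mist nets, soil assays).
ADAPTER_ACCURACY = Accuracy("current", "primary", "other")


@dataclass(frozen=True)
class IndicatorScore:
    farm_id: str
    indicator_id: str
    percent: float
    accuracy: Accuracy = Accuracy()

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent <= 100.0:
            raise ValueError(
                f"indicator {self.indicator_id!r}: percent out of [0, 100]: {self.percent}"
            )


@dataclass(frozen=True)
class ThemeResult:
    theme_id: str
    percent: float
    rating: Rating
    accuracy_quality: int


@dataclass
class FarmAssessment:
    """One farm's complete assessment: indicator, subtheme and theme scores."""

    farm_id: str
    system_type: str
    theme_results: dict[str, ThemeResult]
    subtheme_scores: dict[str, float | None]
    indicator_scores: dict[str, IndicatorScore]

    def theme_ratings(self) -> dict[str, Rating]:
        return {tid: tr.rating for tid, tr in self.theme_results.items()}

    def to_dict(self) -> dict:
        return {
            "farm_id": self.farm_id,
            "system_type": self.system_type,
            "themes": {
                tid: {
                    "percent": tr.percent,
                    "rating": tr.rating.label,
                    "accuracy_quality": tr.accuracy_quality,
                }
                for tid, tr in self.theme_results.items()
            },
            "subthemes": self.subtheme_scores,
            "indicators": {
                iid: {
                    "percent": sc.percent,
                    "accuracy": {
                        "timeframe": sc.accuracy.timeframe,
                        "data_type": sc.accuracy.data_type,
                        "methodology": sc.accuracy.methodology,
                    },
                }
                for iid, sc in self.indicator_scores.items()
            },
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kwargs)

    @classmethod
    def from_dict(cls, doc: Mapping) -> "FarmAssessment":
        themes = {
            tid: ThemeResult(
                tid, t["percent"], Rating.from_label(t["rating"]), t["accuracy_quality"]
            )
            for tid, t in doc["themes"].items()
        }
        indicators = {
            iid: IndicatorScore(
                doc["farm_id"], iid, i["percent"], Accuracy(**i["accuracy"])
            )
            for iid, i in doc["indicators"].items()
        }
        return cls(
            doc["farm_id"], doc["system_type"], themes, dict(doc["subthemes"]), indicators
        )


# ---------------------------------------------------------------------------
# Aggregation primitives


def subtheme_score(
    percents: Sequence[float], framework: Framework, subtheme_id: str
) -> float | None:
    """Mean indicator percent for a subtheme, or None if not evaluated.

    Excluded subthemes are never evaluated regardless of attached scores; a
    non-excluded subtheme with no scored indicators is not evaluated either
    (with a warning).
    """
    sub = framework.subtheme(subtheme_id)
    if sub.excluded:
        return None
    if len(percents) == 0:
        logger.warning("subtheme %r has no scored indicators; not evaluated", subtheme_id)
        return None
    return float(np.mean(percents))


def theme_score(subtheme_percents: Sequence[float | None]) -> float:
    """Mean of the evaluated subtheme percents (None entries omitted)."""
    vals = [p for p in subtheme_percents if p is not None]
    if not vals:
        raise ValueError("theme has no evaluated subthemes")
    return float(np.mean(vals))


def accuracy_quality(accuracies: Sequence[Accuracy]) -> int:
    """Summarise indicator accuracies as a 1/2/3 quality label for a theme.

    Mean accuracy points >= 2.5 -> 1 (high), >= 1.5 -> 2 (medium), else 3 (low).
    """
    if not accuracies:
        raise ValueError("at least one accuracy tuple required")
    mean_pts = float(np.mean([a.points for a in accuracies]))
    if mean_pts >= 2.5:
        return 1
    if mean_pts >= 1.5:
        return 2
    return 3


# ---------------------------------------------------------------------------
# Whole-farm assessment


@dataclass
class FarmInputs:
    """Raw inputs for one farm: generic scores plus adapter field data."""

    farm_id: str
    system_type: str  # NS | IS | MS
    generic_scores: list[IndicatorScore] = field(default_factory=list)
    captures: CaptureTable | None = None
    soil: SoilMeasurementSet | None = None
    wq: WQScoreSet | None = None


def _adapter_scores(
    inputs: FarmInputs,
    framework: Framework,
    diversity_percents: Mapping[str, float],
    key_weights: KeySpeciesWeights,
) -> list[IndicatorScore]:
    """Compute scores for every adapter indicator in the framework."""
    out: list[IndicatorScore] = []
    wq_scores = wq_to_indicator_scores(inputs.wq) if inputs.wq is not None else {}
    for ind in framework.adapter_indicators():
        kind = ind.adapter_kind
        if kind == "wq":
            if ind.id not in wq_scores:
                continue
            pct = wq_scores[ind.id]
        elif kind == "diversity":
            if inputs.farm_id not in diversity_percents:
                continue
            pct = diversity_percents[inputs.farm_id]
        elif kind == "endemic_count":
            if inputs.captures is None:
                continue
            rows = inputs.captures.rows
            n_endemic = int(rows.loc[rows["count"] > 0, "endemic"].sum())
            pct = endemic_count_to_rating(n_endemic).midpoint_percent()
        elif kind == "key_species":
            if inputs.captures is None:
                continue
            pct = key_species_score(inputs.captures, key_weights)
        elif kind == "soil":
            if inputs.soil is None:
                continue
            pct = soil_indicator_percent(inputs.soil, ind.id)
        else:  # generic adapter: expect a directly supplied score
            continue
        out.append(IndicatorScore(inputs.farm_id, ind.id, pct, ADAPTER_ACCURACY))
    return out


def assess_farm(
    inputs: FarmInputs,
    framework: Framework,
    diversity_percents: Mapping[str, float] | None = None,
    key_weights: KeySpeciesWeights = KeySpeciesWeights(),
) -> FarmAssessment:
    """Assemble a FarmAssessment: run adapters, aggregate, derive ratings.

    ``diversity_percents`` carries the cohort-normalised wild-species
    diversity percent per farm (computed at study level, since normalisation
    needs every farm's capture table); pass None for a single-farm run
    without the diversity indicator.
    """
    scores: dict[str, IndicatorScore] = {}
    for sc in inputs.generic_scores:
        framework.indicator(sc.indicator_id)  # raises for unknown ids
        scores[sc.indicator_id] = sc
    for sc in _adapter_scores(inputs, framework, diversity_percents or {}, key_weights):
        scores[sc.indicator_id] = sc

    sub_scores: dict[str, float | None] = {}
    for sub in framework.subthemes:
        pcts = [
            scores[i.id].percent for i in framework.indicators_of(sub.id) if i.id in scores
        ]
        sub_scores[sub.id] = subtheme_score(pcts, framework, sub.id)

    theme_results: dict[str, ThemeResult] = {}
    failed: list[str] = []
    for theme in framework.themes:
        subs = framework.subthemes_of(theme.id)
        child_pcts = [sub_scores[s.id] for s in subs]
        try:
            pct = theme_score(child_pcts)
        except ValueError:
            failed.append(theme.id)
            continue
        accs = [
            scores[i.id].accuracy
            for s in subs
            if not s.excluded
            for i in framework.indicators_of(s.id)
            if i.id in scores
        ]
        theme_results[theme.id] = ThemeResult(
            theme.id,
            pct,
            percent_to_rating(pct, framework.rating_scale),
            accuracy_quality(accs),
        )
    if failed:
        raise ValueError(f"themes with no evaluable content: {failed}")
    return FarmAssessment(
        inputs.farm_id, inputs.system_type, theme_results, sub_scores, scores
    )


def assess_study(
    farms: Sequence[FarmInputs],
    framework: Framework,
    key_weights: KeySpeciesWeights = KeySpeciesWeights(),
) -> list[FarmAssessment]:
    """Assess a cohort of farms, normalising diversity against the cohort."""
    if not farms:
        raise ValueError("at least one farm required")
    tables = {f.farm_id: f.captures for f in farms if f.captures is not None}
    diversity: Mapping[str, float] = {}
    if tables:
        try:
            diversity = {
                fid: pct
                for fid, (pct, _rating) in genetic_diversity_rating(
                    tables, framework.rating_scale
                ).items()
            }
        except ValueError:
            logger.warning("no positive abundance cohort-wide; diversity indicator skipped")
    return [assess_farm(f, framework, diversity, key_weights) for f in farms]
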