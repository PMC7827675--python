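"""Positive/negative valuation of farm assessments and cohort ranking.

The procedure condenses each farm's 21 theme ratings into two integer
percentages and ranks the cohort:

I.   count themes per rating level (the 21 themes are 100%);
II.  label best+good counts "positive" and limited+unacceptable "negative",
     dropping moderate themes;
III. convert the summed counts to percentages, rounded once with the custom
     rule (fractional part <= 0.5 rounds down, > 0.5 rounds up);
IV.  rank farms by positive percentage, ties broken by lower negative
     percentage, remaining ties keeping input order;
V/VI. build five contiguous integer bands from the cohort's maximum positive
     (and, mirrored, maximum negative) valuation by scaling max/5 by factors
     1..5, and categorise every farm's valuations against those bands.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

from .aggregation import FarmAssessment
from .framework import Rating

__all__ = [
    "ValuationResult",
    "RatingBands",
    "round_percent",
    "theme_tally",
    "valuation",
    "build_bands",
    "categorize",
    "rank_farms",
    "valuate_study",
]

POSITIVE_RATINGS = (Rating.BEST, Rating.GOOD)
NEGATIVE_RATINGS = (Rating.LIMITED, Rating.UNACCEPTABLE)


def round_percent(x: float) -> int:
    """Round with the custom rule: fractional part <= 0.5 down, > 0.5 up."""
    if x < 0:
        raise ValueError(f"round_percent requires x >= 0, got {x}")
    frac = x - math.floor(x)
    return math.floor(x) if frac <= 0.5 else math.ceil(x)


def theme_tally(assessment: FarmAssessment, expected_themes: int = 21) -> Counter:
    """Count themes per rating level; must cover all expected themes."""
    ratings = assessment.theme_ratings()
    if len(ratings) != expected_themes:
        raise ValueError(
            f"farm {assessment.farm_id!r}: {len(ratings)} theme results, "
            f"expected {expected_themes}"
        )
    tally = Counter(ratings.values())
    for level in Rating:
        tally.setdefault(level, 0)
    return tally


def valuation(tally: Mapping[Rating, int], n_themes: int = 21) -> tuple[int, int]:
    """Positive and negative valuation percentages from a theme tally.

    Counts are summed first and rounded once (sum-then-round); moderate
    themes are dropped.
    """
    total = sum(tally.values())
    if total != n_themes:
        raise ValueError(f"tally sums to {total}, expected {n_themes}")
    n_pos = sum(tally.get(r, 0) for r in POSITIVE_RATINGS)
    n_neg = sum(tally.get(r, 0) for r in NEGATIVE_RATINGS)
    return (
        round_percent(100.0 * n_pos / n_themes),
        round_percent(100.0 * n_neg / n_themes),
    )


@dataclass(frozen=True)
class RatingBands:
    """Five contiguous integer intervals partitioning 0..max_value.

    For positive valuations the top interval is "best"; for negative
    valuations the scale is mirrored and the top interval is "unacceptable".
    """

    direction: str  # "positive" | "negative"
    max_value: int
    intervals: tuple[tuple[int, int, Rating], ...]  # (lo, hi, label), inclusive

    def interval_for(self, label: Rating) -> tuple[int, int]:
        for lo, hi, lab in self.intervals:
            if lab is label:
                return lo, hi
        raise KeyError(label)


def build_bands(max_value: int, direction: str) -> RatingBands:
    """Construct valuation bands from the cohort maximum.

    The maximum is divided by five and scaled by factors 1..5 (each cut point
    rounded with the custom rule); the resulting intervals
    [0, c1], [c1+1, c2], ..., [c4+1, max] are labelled ascending toward
    "best" for positive valuations and toward "unacceptable" for negative.
    """
    if direction not in ("positive", "negative"):
        raise ValueError(f"direction must be 'positive' or 'negative': {direction!r}")
    if max_value <= 0:
        raise ValueError(f"max_value must be positive: {max_value}")
    step = max_value / 5.0
    cuts = [round_percent(k * step) for k in range(1, 6)]
    if direction == "positive":
        labels = [Rating.UNACCEPTABLE, Rating.LIMITED, Rating.MODERATE, Rating.GOOD, Rating.BEST]
    else:
        labels = [Rating.BEST, Rating.GOOD, Rating.MODERATE, Rating.LIMITED, Rating.UNACCEPTABLE]
    intervals = []
    lo = 0
    for cut, label in zip(cuts, labels):
        intervals.append((lo, cut, label))
        lo = cut + 1
    return RatingBands(direction, max_value, tuple(intervals))


def categorize(v: int, bands: RatingBands) -> Rating:
    """Label of the unique band interval containing the valuation v."""
    if not 0 <= v <= bands.max_value:
        raise ValueError(f"valuation {v} outside [0, {bands.max_value}]")
    for lo, hi, label in bands.intervals:
        if lo <= v <= hi:
            return label
    raise AssertionError("bands do not partition the range")  # pragma: no cover


def rank_farms(
    valuations: Sequence[tuple[str, int, int]]
) -> list[tuple[int, str, int, int]]:
    """Rank farms by valuation pair: ``(farm_id, positive, negative)`` in,
    ``(rank, farm_id, positive, negative)`` out.

    Descending by positive percentage; ties broken ascending by negative
    percentage; full ties keep input order (stable sort).
    """
    if not valuations:
        raise ValueError("at least one farm required")
    ordered = sorted(valuations, key=lambda t: (-t[1], t[2]))
    return [(i + 1, fid, pos, neg) for i, (fid, pos, neg) in enumerate(ordered)]


@dataclass(frozen=True)
class ValuationResult:
    farm_id: str
    positive_pct: int
    negative_pct: int
    positive_category: Rating
    negative_category: Rating
    rank: int

    def to_dict(self) -> dict:
        return {
            "rank": self.rank,
            "farm_id": self.farm_id,
            "positive_pct": self.positive_pct,
            "negative_pct": self.negative_pct,
            "positive_category": self.positive_category.label,
            "negative_category": self.negative_category.label,
        }


def valuate_study(
    assessments: Sequence[FarmAssessment],
    n_themes: int = 21,
    fixed_scale: bool = False,
) -> tuple[list[ValuationResult], RatingBands, RatingBands]:
    """Run the full valuation procedure on a cohort of assessments.

    Returns the ranked valuation results plus the positive and negative
    bands used for categorisation.  With ``fixed_scale=True`` the bands are
    built from 100 instead of the cohort maxima (for cross-study
    comparison); otherwise bands are cohort-relative.
    """
    pairs = [
        (a.farm_id, *valuation(theme_tally(a, n_themes), n_themes)) for a in assessments
    ]
    ranked = rank_farms(pairs)
    if fixed_scale:
        pos_max = neg_max = 100
    else:
        pos_max = max(p for _, p, _ in pairs)
        neg_max = max(n for _, _, n in pairs)
    # degenerate cohorts (all-zero valuations) fall back to the full scale
    pos_bands = build_bands(pos_max if pos_max > 0 else 100, "positive")
    neg_bands = build_bands(neg_max if neg_max > 0 else 100, "negative")
    results = [
        ValuationResult(
            fid,
            pos,
            neg,
            categorize(pos, pos_bands),
            categorize(neg, neg_bands),
            rank,
        )
        for rank, fid, pos, neg in ranked
    ]
    return results, pos_bands, neg_bands
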