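"""Hierarchical assessment framework: dimensions, themes, subthemes, indicators.

The framework follows the FAO SAFA structure: four sustainability dimensions
(Good Governance, Environmental Integrity, Economic Resilience, Social
Well-Being) divided into 21 themes, 58 subthemes and 116 indicators, each
indicator rated on a five-level percent-banded scale.  The default framework
bundled with the package carries the published theme structure; subthemes and
indicators that are not individually named in the source material are
placeholders (``placeholder: true``) distributed to honour the per-dimension
indicator counts.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

__all__ = [
    "Rating",
    "RatingScale",
    "DEFAULT_SCALE",
    "Dimension",
    "Theme",
    "Subtheme",
    "Indicator",
    "Framework",
    "FrameworkStructureError",
    "FrameworkValidationError",
    "DEFAULT_EXCLUSIONS",
    "load_framework",
    "apply_exclusions",
    "percent_to_rating",
    "serialize_framework",
]


class FrameworkStructureError(ValueError):
    """A cross-reference in the framework config does not resolve."""


class FrameworkValidationError(ValueError):
    """The framework violates a declared invariant (counts, justifications...)."""


class Rating(enum.IntEnum):
    """The five ordered SAFA performance levels."""

    UNACCEPTABLE = 0
    LIMITED = 1
    MODERATE = 2
    GOOD = 3
    BEST = 4

    @property
    def label(self) -> str:
        return self.name.lower()

    @classmethod
    def from_label(cls, label: str) -> "Rating":
        try:
            return cls[label.upper()]
        except KeyError:
            raise ValueError(f"unknown rating label: {label!r}") from None

    def midpoint_percent(self) -> float:
        """Centre of this rating's percent band (10, 30, 50, 70, 90)."""
        return self.value * 20.0 + 10.0


@dataclass(frozen=True)
class RatingScale:
    """Five contiguous percent bands over [0, 100], one per rating level.

    Bands are lower-inclusive and upper-exclusive except the top band, which
    is closed at 100, so every percent maps to exactly one level.
    """

    cuts: tuple[float, ...] = (20.0, 40.0, 60.0, 80.0)

    def __post_init__(self) -> None:
        if len(self.cuts) != 4 or list(self.cuts) != sorted(self.cuts):
            raise ValueError("RatingScale needs four increasing interior cut points")
        if not (0.0 < self.cuts[0] and self.cuts[-1] < 100.0):
            raise ValueError("interior cut points must lie strictly inside (0, 100)")

    def rating(self, percent: float) -> Rating:
        if not 0.0 <= percent <= 100.0:
            raise ValueError(f"percent out of range [0, 100]: {percent}")
        for i, cut in enumerate(self.cuts):
            if percent < cut:
                return Rating(i)
        return Rating.BEST

    def band(self, rating: Rating) -> tuple[float, float]:
        edges = (0.0, *self.cuts, 100.0)
        return edges[rating.value], edges[rating.value + 1]


DEFAULT_SCALE = RatingScale()


def percent_to_rating(percent: float, scale: RatingScale = DEFAULT_SCALE) -> Rating:
    """Map a percent score to its rating level under the band convention."""
    return scale.rating(percent)


@dataclass(frozen=True)
class Dimension:
    id: str
    name: str
    declared_indicator_count: int


@dataclass(frozen=True)
class Theme:
    id: str
    name: str
    dimension_id: str


@dataclass(frozen=True)
class Subtheme:
    id: str
    name: str
    theme_id: str
    excluded: bool = False
    exclusion_justification: str | None = None


# Indicator types: performance / practice / target are entered directly
# (questionnaire scores); "adapter" indicators are computed by the
# indicator_adapters module from field measurements.
INDICATOR_TYPES = frozenset({"performance", "practice", "target", "adapter"})
ADAPTER_KINDS = frozenset(
    {"generic", "wq", "diversity", "endemic_count", "key_species", "soil"}
)


@dataclass(frozen=True)
class Indicator:
    id: str
    name: str
    subtheme_id: str
    indicator_type: str = "performance"
    adapter_kind: str | None = None
    placeholder: bool = False


@dataclass(frozen=True)
class Framework:
    dimensions: tuple[Dimension, ...]
    themes: tuple[Theme, ...]
    subthemes: tuple[Subtheme, ...]
    indicators: tuple[Indicator, ...]
    rating_scale: RatingScale = field(default_factory=RatingScale)

    # -- lookups -----------------------------------------------------------
    def dimension(self, dim_id: str) -> Dimension:
        return _get(self.dimensions, dim_id, "dimension")

    def theme(self, theme_id: str) -> Theme:
        return _get(self.themes, theme_id, "theme")

    def subtheme(self, subtheme_id: str) -> Subtheme:
        return _get(self.subthemes, subtheme_id, "subtheme")

    def indicator(self, indicator_id: str) -> Indicator:
        return _get(self.indicators, indicator_id, "indicator")

    def themes_of(self, dim_id: str) -> tuple[Theme, ...]:
        return tuple(t for t in self.themes if t.dimension_id == dim_id)

    def subthemes_of(self, theme_id: str) -> tuple[Subtheme, ...]:
        return tuple(s for s in self.subthemes if s.theme_id == theme_id)

    def indicators_of(self, subtheme_id: str) -> tuple[Indicator, ...]:
        return tuple(i for i in self.indicators if i.subtheme_id == subtheme_id)

    def active_subthemes(self) -> tuple[Subtheme, ...]:
        return tuple(s for s in self.subthemes if not s.excluded)

    def adapter_indicators(self) -> tuple[Indicator, ...]:
        return tuple(i for i in self.indicators if i.indicator_type == "adapter")

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        for coll, label in (
            (self.dimensions, "dimension"),
            (self.themes, "theme"),
            (self.subthemes, "subtheme"),
            (self.indicators, "indicator"),
        ):
            ids = [x.id for x in coll]
            dupes = {i for i in ids if ids.count(i) > 1}
            if dupes:
                raise FrameworkValidationError(f"duplicate {label} ids: {sorted(dupes)}")
        dim_ids = {d.id for d in self.dimensions}
        theme_ids = {t.id for t in self.themes}
        sub_ids = {s.id for s in self.subthemes}
        for t in self.themes:
            if t.dimension_id not in dim_ids:
                raise FrameworkStructureError(
                    f"theme {t.id!r} references missing dimension {t.dimension_id!r}"
                )
        for s in self.subthemes:
            if s.theme_id not in theme_ids:
                raise FrameworkStructureError(
                    f"subtheme {s.id!r} references missing theme {s.theme_id!r}"
                )
            if s.excluded and not (s.exclusion_justification or "").strip():
                raise FrameworkValidationError(
                    f"excluded subtheme {s.id!r} lacks a justification"
                )
        for i in self.indicators:
            if i.subtheme_id not in sub_ids:
                raise FrameworkStructureError(
                    f"indicator {i.id!r} references missing subtheme {i.subtheme_id!r}"
                )
            if i.indicator_type not in INDICATOR_TYPES:
                raise FrameworkValidationError(
                    f"indicator {i.id!r}: unknown indicator_type {i.indicator_type!r}"
                )
            if i.adapter_kind is not None and i.adapter_kind not in ADAPTER_KINDS:
                raise FrameworkValidationError(
                    f"indicator {i.id!r}: unknown adapter_kind {i.adapter_kind!r}"
                )
        # declared per-dimension counts must match the actual hierarchy
        for d in self.dimensions:
            found = sum(
                1
                for i in self.indicators
                if self.theme(self.subtheme(i.subtheme_id).theme_id).dimension_id == d.id
            )
            if found != d.declared_indicator_count:
                raise FrameworkValidationError(
                    f"dimension {d.id!r}: declared {d.declared_indicator_count} "
                    f"indicators, found {found}"
                )


def _get(coll, item_id: str, label: str):
    for item in coll:
        if item.id == item_id:
            return item
    raise KeyError(f"unknown {label} id: {item_id!r}")


# ---------------------------------------------------------------------------
# Config (de)serialization

FORMAT_VERSION = 1


def _framework_from_dict(doc: Mapping) -> Framework:
    if not isinstance(doc, Mapping):
        raise FrameworkStructureError("framework config must be a mapping")
    version = doc.get("format_version")
    if version != FORMAT_VERSION:
        raise FrameworkValidationError(
            f"unsupported format_version: {version!r} (expected {FORMAT_VERSION})"
        )
    scale = RatingScale(tuple(doc.get("rating_scale", {}).get("cuts", (20, 40, 60, 80))))
    dims = tuple(
        Dimension(d["id"], d["name"], int(d["indicator_count"]))
        for d in doc.get("dimensions", [])
    )
    themes = tuple(
        Theme(t["id"], t["name"], t["dimension"]) for t in doc.get("themes", [])
    )
    subs = tuple(
        Subtheme(
            s["id"],
            s["name"],
            s["theme"],
            bool(s.get("excluded", False)),
            s.get("exclusion_justification"),
        )
        for s in doc.get("subthemes", [])
    )
    inds = tuple(
        Indicator(
            i["id"],
            i["name"],
            i["subtheme"],
            i.get("type", "performance"),
            i.get("adapter_kind"),
            bool(i.get("placeholder", False)),
        )
        for i in doc.get("indicators", [])
    )
    fw = Framework(dims, themes, subs, inds, scale)
    fw.validate()
    return fw


def _framework_to_dict(fw: Framework) -> dict:
    def _sub(s: Subtheme) -> dict:
        d = {"id": s.id, "name": s.name, "theme": s.theme_id}
        if s.excluded:
            d["excluded"] = True
            d["exclusion_justification"] = s.exclusion_justification
        return d

    def _ind(i: Indicator) -> dict:
        d = {"id": i.id, "name": i.name, "subtheme": i.subtheme_id, "type": i.indicator_type}
        if i.adapter_kind is not None:
            d["adapter_kind"] = i.adapter_kind
        if i.placeholder:
            d["placeholder"] = True
        return d

    return {
        "format_version": FORMAT_VERSION,
        "rating_scale": {"cuts": [float(c) for c in fw.rating_scale.cuts]},
        "dimensions": [
            {"id": d.id, "name": d.name, "indicator_count": d.declared_indicator_count}
            for d in fw.dimensions
        ],
        "themes": [
            {"id": t.id, "name": t.name, "dimension": t.dimension_id} for t in fw.themes
        ],
        "subthemes": [_sub(s) for s in fw.subthemes],
        "indicators": [_ind(i) for i in fw.indicators],
    }


def serialize_framework(fw: Framework) -> str:
    """Render a framework as the YAML config dialect accepted by load_framework."""
    return yaml.safe_dump(_framework_to_dict(fw), sort_keys=False, allow_unicode=True)


def load_framework(source: str | Path | None = None) -> Framework:
    """Load and validate a framework from YAML text, a path, or the bundled default.

    Parameters
    ----------
    source
        A path to a YAML config, a YAML string, or ``None`` for the default
        framework shipped with the package.
    """
    if source is None:
        text = (
            resources.files("safascore").joinpath("data/default_framework.yaml").read_text()
        )
    elif isinstance(source, Path):
        text = source.read_text()
    else:
        candidate = Path(source)
        try:
            is_file = candidate.is_file()
        except OSError:  # e.g. name too long: treat as inline YAML
            is_file = False
        text = candidate.read_text() if is_file else source
    doc = yaml.safe_load(text)
    return _framework_from_dict(doc)


def apply_exclusions(
    fw: Framework, exclusions: Iterable[tuple[str, str]] | Sequence[Mapping]
) -> Framework:
    """Return a framework with the given subthemes flagged as excluded.

    Each entry is ``(subtheme_id, justification)`` or a mapping with those
    keys.  Excluded subthemes contribute to no downstream score or accuracy
    total.  Idempotent for a fixed exclusion list.
    """
    pairs: list[tuple[str, str]] = []
    for entry in exclusions:
        if isinstance(entry, Mapping):
            pairs.append((entry["subtheme_id"], entry["justification"]))
        else:
            sid, just = entry
            pairs.append((sid, just))
    known = {s.id for s in fw.subthemes}
    for sid, just in pairs:
        if sid not in known:
            raise KeyError(f"unknown subtheme id: {sid!r}")
        if not (just or "").strip():
            raise FrameworkValidationError(
                f"exclusion of subtheme {sid!r} requires a non-empty justification"
            )
    by_id = dict(pairs)
    subs = tuple(
        replace(s, excluded=True, exclusion_justification=by_id[s.id])
        if s.id in by_id
        else s
        for s in fw.subthemes
    )
    out = replace(fw, subthemes=subs)
    out.validate()
    return out


#: The five default subtheme exclusions applied during contextualization for
#: smallholder cattle farms in Yucatán (justifications summarised).
DEFAULT_EXCLUSIONS: tuple[tuple[str, str], ...] = (
    (
        "stability-of-production",
        "Farms act as their own forage providers; external supply stability "
        "is not informative.",
    ),
    (
        "air-quality",
        "No formal air-contaminant reduction plans exist and standard "
        "pollution values could not be measured on-farm.",
    ),
    (
        "water-quality",
        "Empirical water-quality preservation measures are unfeasible and "
        "residual water samples could not be obtained.",
    ),
    (
        "material-use",
        "Construction material use is minimal and nutrient-balance inputs "
        "could not be reconstructed from farm records.",
    ),
    (
        "product-information",
        "The final product (calves) lacks post-sale traceability under the "
        "regional rural trading system.",
    ),
)
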