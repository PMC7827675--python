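"""Synthetic field-data generator for the three cattle-system archetypes.

Emulates the four raw input streams of a nine-farm Yucatán-style study —
generic questionnaire indicator scores, wildlife capture tables, soil
measurements against undisturbed references, and Welfare Quality principle
scores — for Native Silvopastoral (NS), Intensive Silvopastoral (IS) and
Monoculture (MS) farms.

Archetype theme means are synthetic calibration constants encoding the
qualitative contrasts expected between systems (NS strong on Participation,
Land, Biodiversity and Cultural Diversity; IS strong on Holistic Management;
every system weak on Atmosphere and Water; silvopastoral systems weak on
Decent Livelihood); they are not measured values.

Randomness is controlled by a single root seed with deterministic per-farm
derivation, so regenerating any one farm is stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .adapters import CAPTURE_COLUMNS, CaptureTable, SoilMeasurementSet, WQScoreSet
from .aggregation import Accuracy, FarmInputs, IndicatorScore
from .framework import Framework, load_framework

__all__ = [
    "ArchetypeProfile",
    "CaptureParams",
    "SyntheticStudy",
    "DEFAULT_PROFILES",
    "SOIL_REFERENCES",
    "simulate_farm",
    "simulate_study",
]


@dataclass(frozen=True)
class CaptureParams:
    """Expected captures for one taxon group."""

    abundance: float  # Poisson mean of total individuals caught
    richness: float  # Poisson mean of the species pool size (min 1)
    endemic_frac: float
    at_risk_frac: float
    introduced_frac: float

    def __post_init__(self) -> None:
        if self.abundance < 0 or self.richness < 0:
            raise ValueError("abundance and richness must be non-negative")
        for name in ("endemic_frac", "at_risk_frac", "introduced_frac"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass(frozen=True)
class ArchetypeProfile:
    """Generator parameters for one production-system archetype."""

    system_type: str  # NS | IS | MS
    theme_means: dict[str, float]  # theme_id -> mean percent
    theme_sd: float  # dispersion of indicator percents around the theme mean
    captures: dict[str, CaptureParams]  # taxon_group -> params
    soil_ratio_mean: float  # mean measured/reference ratio (Beta-distributed)
    soil_ratio_conc: float  # Beta concentration (a+b); higher = tighter
    wq_means: dict[str, float]  # principle -> mean score
    wq_sd: float

    def __post_init__(self) -> None:
        for tid, m in self.theme_means.items():
            if not 0.0 <= m <= 100.0:
                raise ValueError(f"theme mean for {tid!r} out of [0, 100]: {m}")
        if self.theme_sd < 0 or self.wq_sd < 0:
            raise ValueError("dispersions must be non-negative")
        if not 0.0 < self.soil_ratio_mean <= 1.0:
            raise ValueError("soil_ratio_mean must be in (0, 1]")


@dataclass
class SyntheticStudy:
    seed: int
    farms: list[FarmInputs]


#: Reference values from undisturbed soils (constant across the cohort).
SOIL_REFERENCES: dict[str, tuple[float, str]] = {
    "texture_score": (100.0, "index"),
    "organic_matter_pct": (6.0, "%"),
    "no3_nh4_ratio": (8.0, "ratio"),
    "total_organic_p": (500.0, "mg/kg"),
    "total_organic_c": (45.0, "g/kg"),
}

_BASE_THEME_MEANS = {
    "corporate-ethics": 50.0,
    "accountability": 50.0,
    "participation": 50.0,
    "rule-of-law": 70.0,
    "holistic-management": 50.0,
    "atmosphere": 25.0,
    "water": 30.0,
    "land": 50.0,
    "biodiversity": 50.0,
    "materials-and-energy": 50.0,
    "animal-welfare": 70.0,
    "investment": 70.0,
    "vulnerability": 50.0,
    "product-quality-and-information": 50.0,
    "local-economy": 85.0,
    "decent-livelihood": 45.0,
    "fair-trading-practices": 70.0,
    "labor-rights": 62.0,
    "equity": 55.0,
    "human-safety-and-health": 55.0,
    "cultural-diversity": 50.0,
}


def _means(**overrides: float) -> dict[str, float]:
    d = dict(_BASE_THEME_MEANS)
    d.update(overrides)
    return d


DEFAULT_PROFILES: dict[str, ArchetypeProfile] = {
    "NS": ArchetypeProfile(
        system_type="NS",
        theme_means=_means(
            participation=85.0,
            land=80.0,
            biodiversity=78.0,
            **{"cultural-diversity": 72.0},
            equity=72.0,
            **{"human-safety-and-health": 75.0},
            **{"decent-livelihood": 30.0},
            vulnerability=58.0,
        ),
        theme_sd=8.0,
        captures={
            "birds": CaptureParams(60, 10, 0.35, 0.15, 0.05),
            "bats": CaptureParams(40, 8, 0.35, 0.12, 0.05),
            "rodents": CaptureParams(25, 5, 0.30, 0.10, 0.08),
        },
        soil_ratio_mean=0.85,
        soil_ratio_conc=40.0,
        wq_means={
            "good_feeding": 78.0,
            "good_health": 74.0,
            "appropriate_behavior": 82.0,
            "overall": 78.0,
        },
        wq_sd=6.0,
    ),
    "IS": ArchetypeProfile(
        system_type="IS",
        theme_means=_means(
            **{"holistic-management": 72.0},
            land=68.0,
            biodiversity=62.0,
            equity=62.0,
            **{"decent-livelihood": 32.0},
        ),
        theme_sd=8.0,
        captures={
            "birds": CaptureParams(45, 7, 0.25, 0.10, 0.10),
            "bats": CaptureParams(30, 6, 0.25, 0.08, 0.10),
            "rodents": CaptureParams(18, 4, 0.20, 0.06, 0.12),
        },
        soil_ratio_mean=0.72,
        soil_ratio_conc=40.0,
        wq_means={
            "good_feeding": 80.0,
            "good_health": 76.0,
            "appropriate_behavior": 74.0,
            "overall": 77.0,
        },
        wq_sd=6.0,
    ),
    "MS": ArchetypeProfile(
        system_type="MS",
        theme_means=_means(
            atmosphere=10.0,
            land=48.0,
            biodiversity=32.0,
            **{"animal-welfare": 62.0},
            investment=60.0,
            **{"local-economy": 82.0},
        ),
        theme_sd=8.0,
        captures={
            "birds": CaptureParams(20, 4, 0.10, 0.05, 0.25),
            "bats": CaptureParams(12, 3, 0.10, 0.04, 0.20),
            "rodents": CaptureParams(8, 2, 0.08, 0.03, 0.30),
        },
        soil_ratio_mean=0.50,
        soil_ratio_conc=40.0,
        wq_means={
            "good_feeding": 68.0,
            "good_health": 64.0,
            "appropriate_behavior": 58.0,
            "overall": 63.0,
        },
        wq_sd=6.0,
    ),
}


def _trunc_norm(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    """Truncated normal on [0, 100]; sd = 0 degenerates to the mean."""
    if sd == 0.0:
        return np.full(size, float(mean))
    a, b = (0.0 - mean) / sd, (100.0 - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _sample_accuracy(rng: np.random.Generator) -> Accuracy:
    return Accuracy(
        timeframe="current" if rng.random() < 0.9 else "outdated",
        data_type=rng.choice(DATA_TYPE_CHOICES, p=DATA_TYPE_PROBS),
        methodology="safa_conform" if rng.random() < 0.85 else "other",
    )


DATA_TYPE_CHOICES = ("primary", "secondary", "estimate")
DATA_TYPE_PROBS = (0.75, 0.15, 0.10)


def _simulate_captures(
    rng: np.random.Generator, farm_id: str, params: dict[str, CaptureParams]
) -> CaptureTable:
    rows = []
    for group, p in params.items():
        n_total = int(rng.poisson(p.abundance))
        if n_total == 0:
            continue
        pool = max(1, int(rng.poisson(p.richness)))
        pool = min(pool, n_total)  # cannot observe more species than individuals
        counts = rng.multinomial(n_total, np.full(pool, 1.0 / pool))
        for j, c in enumerate(counts):
            if c == 0:
                continue
            endemic = bool(rng.random() < p.endemic_frac)
            # endemic and introduced are mutually exclusive
            introduced = (not endemic) and bool(rng.random() < p.introduced_frac)
            rows.append(
                {
                    "taxon_group": group,
                    "species": f"{group}_sp{j + 1:02d}",
                    "count": int(c),
                    "endemic": endemic,
                    "at_risk": bool(rng.random() < p.at_risk_frac),
                    "introduced": introduced,
                }
            )
    df = pd.DataFrame(rows, columns=CAPTURE_COLUMNS)
    return CaptureTable(farm_id, df)


def _simulate_soil(
    rng: np.random.Generator, farm_id: str, ratio_mean: float, conc: float
) -> SoilMeasurementSet:
    props = {}
    for prop, (reference, units) in SOIL_REFERENCES.items():
        if ratio_mean >= 1.0:
            ratio = 1.0
        else:
            a = ratio_mean * conc
            b = (1.0 - ratio_mean) * conc
            ratio = float(rng.beta(a, b))
        props[prop] = (reference * ratio, reference, units)
    return SoilMeasurementSet(farm_id, props)


def simulate_farm(
    profile: ArchetypeProfile,
    farm_id: str,
    seed: int | np.random.SeedSequence,
    framework: Framework | None = None,
) -> FarmInputs:
    """Generate one farm's complete raw input bundle.

    Generic indicator percents are drawn per theme from a truncated normal
    around the archetype's theme mean; adapter indicators get capture, soil
    and WQ data instead of direct scores.
    """
    fw = framework if framework is not None else load_framework()
    rng = np.random.default_rng(seed)

    generic: list[IndicatorScore] = []
    for theme in fw.themes:
        mean = profile.theme_means.get(theme.id, 50.0)
        inds = [
            i
            for s in fw.subthemes_of(theme.id)
            for i in fw.indicators_of(s.id)
            if i.indicator_type != "adapter"
        ]
        pcts = _trunc_norm(rng, mean, profile.theme_sd, len(inds))
        for ind, pct in zip(inds, pcts):
            generic.append(
                IndicatorScore(farm_id, ind.id, float(pct), _sample_accuracy(rng))
            )

    captures = _simulate_captures(rng, farm_id, profile.captures)
    soil = _simulate_soil(rng, farm_id, profile.soil_ratio_mean, profile.soil_ratio_conc)
    wq_scores = {
        name: float(_trunc_norm(rng, mean, profile.wq_sd, 1)[0])
        for name, mean in profile.wq_means.items()
    }
    wq = WQScoreSet(farm_id, wq_scores)
    return FarmInputs(farm_id, profile.system_type, generic, captures, soil, wq)


def simulate_study(
    n_ns: int = 3,
    n_is: int = 3,
    n_ms: int = 3,
    seed: int = 0,
    profiles: dict[str, ArchetypeProfile] | None = None,
    framework: Framework | None = None,
) -> SyntheticStudy:
    """Generate a full multi-farm study (default: three farms per archetype,
    mirroring a nine-farm cohort).

    Farms receive ids NS1..NSn, IS1..ISn, MS1..MSn and independent
    deterministic sub-seeds derived from the root seed.
    """
    if n_ns + n_is + n_ms < 1:
        raise ValueError("at least one farm required")
    if min(n_ns, n_is, n_ms) < 0:
        raise ValueError("farm counts must be non-negative")
    profs = profiles if profiles is not None else DEFAULT_PROFILES
    fw = framework if framework is not None else load_framework()
    farms: list[FarmInputs] = []
    index = 0
    for sys_type, n in (("NS", n_ns), ("IS", n_is), ("MS", n_ms)):
        for k in range(1, n + 1):
            sub_seed = np.random.SeedSequence(entropy=seed, spawn_key=(index,))
            farms.append(simulate_farm(profs[sys_type], f"{sys_type}{k}", sub_seed, fw))
            index += 1
    return SyntheticStudy(seed, farms)
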