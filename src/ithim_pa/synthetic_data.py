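"""Synthetic inputs for the full pipeline: travel surveys, background
physical activity, and burden tables.

The survey generator emulates four setting profiles (England & Wales,
Switzerland, the Netherlands, California) whose sex-level mode-time
marginals match the published daily averages, with illustrative age
gradients: walking declines with age in E&W and California but rises into
old age in Switzerland and the Netherlands; cycling collapses with age
everywhere except the Netherlands, where it holds until about 70.  Records
deliberately include under-age respondents, small communities and sub-3-min
trips so the harmonisation filter has work to do; calibration targets are
defined for the *post-filter* population.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cra_engine import BurdenTable
from .travel_survey import DEFAULT_AGE_BANDS, MODES, SEXES, TravelRecord, format_band

#: Adult population share per default age band (young-adult heavy, as in a
#: western European age pyramid restricted to 15+).
BAND_POPULATION_WEIGHTS = (0.24, 0.25, 0.24, 0.12, 0.09, 0.06)

#: Sex-level mean daily minutes per mode (population based, post-filter).
SETTING_MODE_MINUTES: dict[str, dict[str, dict[str, float]]] = {
    "ew": {
        "male": {"walk": 10.7, "cycle": 1.4, "public_transport": 7.1, "car": 38.1, "other": 3.6},
        "female": {"walk": 12.4, "cycle": 0.4, "public_transport": 7.8, "car": 34.1, "other": 0.8},
    },
    "ch": {
        "male": {"walk": 23.4, "cycle": 4.5, "public_transport": 13.9, "car": 44.7, "other": 5.6},
        "female": {"walk": 28.5, "cycle": 2.9, "public_transport": 14.0, "car": 31.1, "other": 2.4},
    },
    "nl": {
        "male": {"walk": 9.3, "cycle": 12.7, "public_transport": 8.7, "car": 40.7, "other": 5.1},
        "female": {"walk": 10.4, "cycle": 11.7, "public_transport": 8.7, "car": 28.6, "other": 3.4},
    },
    "ca": {
        "male": {"walk": 7.5, "cycle": 2.0, "public_transport": 5.9, "car": 61.8, "other": 2.5},
        "female": {"walk": 8.9, "cycle": 0.5, "public_transport": 6.3, "car": 56.8, "other": 1.1},
    },
}

# Illustrative per-band multipliers (young -> old) before normalisation.
_WALK_GRADIENT = {
    "declining": (1.3, 1.1, 1.0, 0.9, 0.8, 0.6),
    "rising": (0.8, 0.9, 1.0, 1.2, 1.3, 0.9),
}
_CYCLE_GRADIENT = {
    "collapsing": (1.8, 1.2, 0.9, 0.6, 0.3, 0.1),
    "delayed": (1.3, 1.2, 1.1, 0.8, 0.5, 0.2),
    "flat_to_70": (1.0, 1.0, 1.0, 1.0, 0.8, 0.4),
}
SETTING_GRADIENTS = {
    "ew": {"walk": _WALK_GRADIENT["declining"], "cycle": _CYCLE_GRADIENT["collapsing"]},
    "ch": {"walk": _WALK_GRADIENT["rising"], "cycle": _CYCLE_GRADIENT["delayed"]},
    "nl": {"walk": _WALK_GRADIENT["rising"], "cycle": _CYCLE_GRADIENT["flat_to_70"]},
    "ca": {"walk": _WALK_GRADIENT["declining"], "cycle": _CYCLE_GRADIENT["collapsing"]},
}


def _normalised_gradient(mult, band_weights) -> np.ndarray:
    m = np.asarray(mult, dtype=float)
    w = np.asarray(band_weights, dtype=float)
    return m / float((w * m).sum() / w.sum())


def stratified_targets(
    setting: str,
    age_bands=DEFAULT_AGE_BANDS,
    band_weights=BAND_POPULATION_WEIGHTS,
) -> dict[tuple[str, tuple[int, int], str], float]:
    """Per-(sex, band, mode) target means whose population-weighted band
    average reproduces the setting's sex-level marginals exactly."""
    sex_level = SETTING_MODE_MINUTES[setting]
    grads = SETTING_GRADIENTS[setting]
    targets = {}
    for sex in SEXES:
        for mode in MODES:
            mult = grads.get(mode, (1.0,) * len(age_bands))
            norm = _normalised_gradient(mult, band_weights)
            for band, g in zip(age_bands, norm):
                targets[(sex, band, mode)] = sex_level[sex][mode] * float(g)
    return targets


@dataclass
class SettingProfile:
    """Recipe for one synthetic travel survey."""

    name: str
    targets: dict[tuple[str, tuple[int, int], str], float]
    age_bands: tuple = DEFAULT_AGE_BANDS
    band_weights: tuple = BAND_POPULATION_WEIGHTS
    nontraveller_share: float = 0.15
    n_persons: int = 20_000
    seed: int = 0
    time_cv: float = 0.8             # spread of per-mode minutes among participants
    community_sizes: tuple = (15_000, 60_000, 250_000, 1_000_000)
    # contamination removed by the harmonisation filter:
    small_community_frac: float = 0.04
    underage_frac: float = 0.03
    short_trip_prob: float = 0.10

    def __post_init__(self) -> None:
        if not 0 <= self.nontraveller_share <= 1:
            raise ValueError("nontraveller_share must be in [0, 1]")
        if self.nontraveller_share == 1 and any(v > 0 for v in self.targets.values()):
            raise ValueError(
                "infeasible profile: positive travel-time target with "
                "nontraveller_share = 1"
            )
        if self.n_persons < 1:
            raise ValueError("n_persons must be >= 1")
        for key, v in self.targets.items():
            if v < 0:
                raise ValueError(f"negative target for {key}")


def setting_profile(setting: str, n_persons: int = 20_000, seed: int = 0,
                    **overrides) -> SettingProfile:
    """Built-in profile for one of the four study areas ('ew','ch','nl','ca')."""
    return SettingProfile(
        name=setting,
        targets=stratified_targets(setting),
        n_persons=n_persons,
        seed=seed,
        **overrides,
    )


def _rounded_counts(total: int, weights) -> np.ndarray:
    """Integer allocation proportional to weights, largest-remainder method."""
    w = np.asarray(weights, dtype=float)
    ideal = total * w / w.sum()
    base = np.floor(ideal).astype(int)
    rem = total - base.sum()
    order = np.argsort(-(ideal - base))
    base[order[:rem]] += 1
    return base


def _split_trips(total_min: float, rng: np.random.Generator, mode: str):
    if total_min >= 6.0 and rng.random() < 0.5:
        half = total_min / 2.0
        return [(mode, half), (mode, half)]
    return [(mode, total_min)]


def generate_travel_survey(profile: SettingProfile) -> list[TravelRecord]:
    """Draw a person-level survey whose filtered, summarised stratum means
    match the profile targets.

    Per stratum, a fixed share of persons are non-travellers; among
    travellers each mode has a participation probability, and participant
    minutes follow a 3-minute-shifted lognormal rescaled so the stratum
    population mean (zeros included) hits the target.  Under-age persons,
    small-community persons and sub-3-minute trips are added on top as
    filter fodder.
    """
    rng = np.random.default_rng(profile.seed)
    records: list[TravelRecord] = []
    pid = 0

    n_core = profile.n_persons
    sex_counts = _rounded_counts(n_core, [0.5, 0.5])
    for sex, n_sex in zip(SEXES, sex_counts):
        band_counts = _rounded_counts(int(n_sex), profile.band_weights)
        for band, n_s in zip(profile.age_bands, band_counts):
            if n_s == 0:
                continue
            n_nt = int(round(profile.nontraveller_share * n_s))
            n_trav = n_s - n_nt
            trips_per_person: list[list] = [[] for _ in range(n_s)]
            for mode in MODES:
                target = profile.targets[(sex, band, mode)]
                if target == 0:
                    continue
                if n_trav == 0:
                    raise ValueError(
                        f"infeasible target {target} for ({sex}, {format_band(band)}, "
                        f"{mode}) with nontraveller_share 1 in stratum"
                    )
                # participation chosen so the participant mean stays >= ~6 min
                p = min(0.9, target / ((1 - profile.nontraveller_share) * 8.0))
                k = max(1, int(round(p * n_trav)))
                m_part = target * n_s / k  # participant mean that hits the target
                m_part = max(m_part, 3.5)
                shift = 3.0
                y = rng.lognormal(
                    mean=np.log(max(m_part - shift, 0.5)),
                    sigma=np.sqrt(np.log(1 + profile.time_cv**2)),
                    size=k,
                )
                y *= (m_part - shift) / y.mean()  # pin the participant mean
                times = shift + y
                who = rng.choice(n_trav, size=k, replace=False)
                for idx, t in zip(who, times):
                    trips_per_person[idx].extend(_split_trips(float(t), rng, mode))
            ages = rng.integers(band[0], min(band[1], 100), size=n_s)
            comms = rng.choice(profile.community_sizes, size=n_s)
            for i in range(n_s):
                trips = list(trips_per_person[i])
                if rng.random() < profile.short_trip_prob:
                    trips.append(
                        (rng.choice(MODES), float(rng.uniform(0.5, 2.9)))
                    )
                records.append(
                    TravelRecord(
                        person_id=f"{profile.name}-{pid}",
                        sex=sex,
                        age=int(ages[i]),
                        community_size=int(comms[i]),
                        trips=tuple(trips),
                    )
                )
                pid += 1

    # filter fodder: removed entirely by the harmonisation filter
    n_small = int(round(profile.small_community_frac * n_core))
    n_young = int(round(profile.underage_frac * n_core))
    for _ in range(n_small):
        records.append(TravelRecord(
            person_id=f"{profile.name}-{pid}",
            sex=rng.choice(SEXES),
            age=int(rng.integers(16, 90)),
            community_size=int(rng.integers(500, 9_999)),
            trips=((rng.choice(MODES), float(rng.uniform(5, 40))),),
        ))
        pid += 1
    for _ in range(n_young):
        records.append(TravelRecord(
            person_id=f"{profile.name}-{pid}",
            sex=rng.choice(SEXES),
            age=int(rng.integers(5, 16)),
            community_size=int(rng.choice(profile.community_sizes)),
            trips=((rng.choice(MODES), float(rng.uniform(5, 30))),),
        ))
        pid += 1
    return records


# ---------------------------------------------------------------------------
# Burden of disease

#: Per-disease, per-sex annual baselines (DALYs, deaths) for the study
#: population, diseases associated with physical inactivity only.  Breast
#: cancer applies to women; depression carries no deaths.
DEFAULT_BURDEN_ANCHORS: dict[str, dict[str, tuple[float, float]]] = {
    "stroke": {"male": (201_995, 14_047), "female": (226_967, 22_603)},
    "ihd": {"male": (620_598, 38_329), "female": (337_852, 31_224)},
    "other_cvd": {"male": (171_381, 10_388), "female": (149_553, 12_442)},
    "diabetes": {"male": (64_498, 1_850), "female": (56_938, 1_977)},
    "colon_cancer": {"male": (76_689, 4_375), "female": (58_147, 3_850)},
    "breast_cancer": {"female": (201_757, 9_096)},
    "dementia": {"male": (89_714, 5_366), "female": (151_156, 11_873)},
    "depression": {"male": (137_704, 0.0), "female": (230_906, 0.0)},
}

#: Burden concentrates in older bands (young -> old).
DEFAULT_BURDEN_AGE_WEIGHTS = (0.02, 0.05, 0.13, 0.18, 0.27, 0.35)

#: YLL share of DALYs; depression is morbidity only.
DEFAULT_YLL_SHARE = {"default": 0.7, "depression": 0.0}


def generate_burden_table(
    anchors: dict | None = None,
    age_split_weights=DEFAULT_BURDEN_AGE_WEIGHTS,
    age_bands=DEFAULT_AGE_BANDS,
    yll_share: dict | None = None,
) -> BurdenTable:
    """Burden table anchored exactly to per-disease, per-sex totals.

    The age split across bands and the YLL/YLD split within DALYs are
    configurable synthetic structure; sex totals are conserved exactly.
    """
    anchors = anchors if anchors is not None else DEFAULT_BURDEN_ANCHORS
    yll_share = yll_share if yll_share is not None else DEFAULT_YLL_SHARE
    w = np.asarray(age_split_weights, dtype=float)
    if len(w) != len(age_bands):
        raise ValueError("one age weight per band required")
    if abs(w.sum() - 1) > 1e-9:
        raise ValueError("age_split_weights must sum to 1")
    rows = []
    for disease, by_sex in anchors.items():
        frac = yll_share.get(disease, yll_share.get("default", 0.7))
        for sex, (dalys, deaths) in by_sex.items():
            if dalys < 0 or deaths < 0:
                raise ValueError(f"negative anchor for ({disease}, {sex})")
            for band, wt in zip(age_bands, w):
                d = dalys * wt
                yll = d * frac
                rows.append({
                    "disease": disease, "sex": sex, "age_band": format_band(band),
                    "deaths": deaths * wt, "yll": yll, "ylds": d - yll, "dalys": d,
                })
    return BurdenTable(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Background physical activity

#: Non-travel physical activity (household, sport, work above the 1.5-MET
#: floor) in marginal MET·h/week for young adults; declines with age.
#: Levels keep baseline total exposure in the neighbourhood of the published
#: reference doses, consistent with the scale of reported impacts.
DEFAULT_BACKGROUND_LEVELS = {"male": 9.0, "female": 7.5}
DEFAULT_BACKGROUND_AGE_MULTIPLIERS = (1.15, 1.05, 1.0, 0.85, 0.65, 0.45)


def generate_background_pa(
    levels: dict[str, float] | None = None,
    age_multipliers=DEFAULT_BACKGROUND_AGE_MULTIPLIERS,
    age_bands=DEFAULT_AGE_BANDS,
    jitter_cv: float = 0.0,
    seed: int = 0,
) -> dict[tuple[str, tuple[int, int]], float]:
    """Per-stratum background marginal MET·h/week with a declining age
    gradient; optional multiplicative lognormal jitter, deterministic under
    ``seed``."""
    levels = levels if levels is not None else DEFAULT_BACKGROUND_LEVELS
    rng = np.random.default_rng(seed)
    out = {}
    for sex in SEXES:
        level = levels[sex]
        if level < 0:
            raise ValueError("background level must be >= 0")
        for band, m in zip(age_bands, age_multipliers):
            v = level * m
            if jitter_cv > 0:
                sigma = np.sqrt(np.log(1 + jitter_cv**2))
                v *= float(rng.lognormal(-sigma**2 / 2, sigma))
            out[(sex, band)] = v
    return out
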