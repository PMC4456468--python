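"""Travel-survey handling: person-level records to stratified travel-time summaries.

The unit of analysis is a person-day of travel. Summaries are *population
based*: people with no qualifying trips stay in the denominator with zero
minutes, which is what makes cross-survey mode-time comparisons meaningful.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MODES = ("walk", "cycle", "public_transport", "car", "other")
SEXES = ("male", "female")

#: Default adult age bands [lo, hi); the last band is open-ended in practice.
DEFAULT_AGE_BANDS: tuple[tuple[int, int], ...] = (
    (15, 30), (30, 45), (45, 60), (60, 70), (70, 80), (80, 120),
)


def format_band(band: tuple[int, int]) -> str:
    lo, hi = band
    return f"{lo}+" if hi >= 120 else f"{lo}-{hi - 1}"


def parse_band(label: str) -> tuple[int, int]:
    label = label.strip()
    if label.endswith("+"):
        return (int(label[:-1]), 120)
    lo, hi = label.split("-")
    return (int(lo), int(hi) + 1)


@dataclass(frozen=True)
class TravelRecord:
    """One surveyed person-day: demographics plus a (possibly empty) trip list."""

    person_id: str
    sex: str
    age: int
    community_size: int
    trips: tuple[tuple[str, float], ...] = ()
    survey_weight: float = 1.0

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"record {self.person_id}: unknown sex {self.sex!r}")
        if self.age < 0:
            raise ValueError(f"record {self.person_id}: negative age {self.age}")
        if self.survey_weight < 0:
            raise ValueError(f"record {self.person_id}: negative survey weight")
        for mode, dur in self.trips:
            if mode not in MODES:
                raise ValueError(f"record {self.person_id}: unknown mode {mode!r}")
            if dur <= 0:
                raise ValueError(
                    f"record {self.person_id}: non-positive trip duration {dur}"
                )


@dataclass
class StratumTravelSummary:
    """Mean daily minutes per mode for each sex x age-band stratum.

    ``entries`` maps (sex, band, mode) -> population-based mean minutes/day;
    ``stratum_weight`` holds the summed survey weight per (sex, band), used
    when collapsing bands to sex-level marginals.  Empty strata are stored as
    NaN, never silently as zero.
    """

    setting: str
    entries: dict[tuple[str, tuple[int, int], str], float]
    age_bands: tuple[tuple[int, int], ...] = DEFAULT_AGE_BANDS
    stratum_weight: dict[tuple[str, tuple[int, int]], float] = field(default_factory=dict)

    def mean_minutes(self, sex: str, band: tuple[int, int], mode: str) -> float:
        return self.entries[(sex, band, mode)]

    def total_minutes(self, sex: str, band: tuple[int, int]) -> float:
        return float(sum(self.entries[(sex, band, m)] for m in MODES))

    def strata(self) -> list[tuple[str, tuple[int, int]]]:
        return [(sex, band) for sex in SEXES for band in self.age_bands]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "setting": self.setting,
                "sex": sex,
                "age_band": format_band(band),
                "mode": mode,
                "mean_min_per_day": self.entries[(sex, band, mode)],
            }
            for sex in SEXES
            for band in self.age_bands
            for mode in MODES
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, setting: str | None = None) -> "StratumTravelSummary":
        bands = sorted({parse_band(b) for b in df["age_band"]})
        entries = {
            (r.sex, parse_band(r.age_band), r.mode): float(r.mean_min_per_day)
            for r in df.itertuples()
        }
        name = setting if setting is not None else str(df["setting"].iloc[0])
        return cls(setting=name, entries=entries, age_bands=tuple(bands))


def filter_records(
    records: list[TravelRecord],
    min_trip_minutes: float = 3.0,
    min_community_size: int = 10_000,
    min_age: int = 16,
) -> list[TravelRecord]:
    """Harmonisation filter: drop small communities and under-age respondents,
    then drop trips shorter than ``min_trip_minutes`` trip-wise.

    A person whose every trip falls under the duration floor becomes a
    non-traveller but is *kept*, so population-based means stay unbiased.
    Idempotent.
    """
    if min_trip_minutes < 0:
        raise ValueError("min_trip_minutes must be >= 0")
    out = []
    for rec in records:
        if rec.community_size < min_community_size or rec.age < min_age:
            continue
        kept = tuple(t for t in rec.trips if t[1] >= min_trip_minutes)
        out.append(rec if kept == rec.trips else replace(rec, trips=kept))
    return out


def _band_of(age: int, age_bands) -> tuple[int, int] | None:
    for lo, hi in age_bands:
        if lo <= age < hi:
            return (lo, hi)
    return None


def summarize_travel(
    records: list[TravelRecord],
    age_bands=DEFAULT_AGE_BANDS,
    setting: str = "survey",
) -> StratumTravelSummary:
    """Weighted population-based mean minutes/day per (sex, band, mode).

    Non-travellers contribute zeros; weights default to 1.  An empty stratum
    yields NaN and a log warning rather than a silent zero.
    """
    bands = tuple(tuple(b) for b in age_bands)
    for (lo1, hi1), (lo2, hi2) in zip(bands, bands[1:]):
        if hi1 > lo2:
            raise ValueError("age bands must be disjoint and ordered")

    wsum: dict[tuple[str, tuple[int, int]], float] = {
        (s, b): 0.0 for s in SEXES for b in bands
    }
    tsum: dict[tuple[str, tuple[int, int], str], float] = {
        (s, b, m): 0.0 for s in SEXES for b in bands for m in MODES
    }
    for rec in records:
        band = _band_of(rec.age, bands)
        if band is None:
            continue
        key = (rec.sex, band)
        wsum[key] += rec.survey_weight
        for mode, dur in rec.trips:
            tsum[(rec.sex, band, mode)] += rec.survey_weight * dur

    entries = {}
    for sex in SEXES:
        for band in bands:
            w = wsum[(sex, band)]
            if w == 0:
                logger.warning(
                    "empty stratum (%s, %s) in %s: means recorded as missing",
                    sex, format_band(band), setting,
                )
            for mode in MODES:
                entries[(sex, band, mode)] = (
                    tsum[(sex, band, mode)] / w if w > 0 else float("nan")
                )
    return StratumTravelSummary(
        setting=setting, entries=entries, age_bands=bands, stratum_weight=wsum
    )


def mode_shares(
    summary: StratumTravelSummary, group_by_sex_only: bool = False
) -> dict:
    """Share of total travel time per mode.

    Per (sex, band) stratum by default; with ``group_by_sex_only`` the band
    means are first collapsed to a sex-level mean weighted by stratum
    population weight (equal weights if the summary carries none).  Missing
    (empty-stratum) cells are skipped; a populated stratum with zero total
    travel is an error.
    """
    shares: dict = {}
    if group_by_sex_only:
        for sex in SEXES:
            vals = np.array(
                [
                    [summary.entries[(sex, b, mode)] for b in summary.age_bands]
                    for mode in MODES
                ]
            )
            present = ~np.isnan(vals).any(axis=0)
            if not present.any():
                continue  # no data for this sex at all
            weights = np.array(
                [summary.stratum_weight.get((sex, b), 1.0) for b in summary.age_bands]
            )[present]
            if weights.sum() == 0:
                weights = np.ones_like(weights)
            weights = weights / weights.sum()
            means = {
                mode: float(np.sum(weights * vals[i, present]))
                for i, mode in enumerate(MODES)
            }
            total = sum(means.values())
            if total <= 0:
                raise ValueError(f"zero total travel time for sex group {sex!r}")
            for mode in MODES:
                shares[(sex, mode)] = means[mode] / total
    else:
        for sex in SEXES:
            for band in summary.age_bands:
                total = summary.total_minutes(sex, band)
                if np.isnan(total):
                    continue  # empty stratum, flagged at summarise time
                if not total > 0:
                    raise ValueError(
                        f"zero total travel time in stratum ({sex}, {format_band(band)})"
                    )
                for mode in MODES:
                    shares[(sex, band, mode)] = summary.entries[(sex, band, mode)] / total
    return shares
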