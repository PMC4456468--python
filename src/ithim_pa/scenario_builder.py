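"""Counterfactual travel scenarios for a baseline population.

Two constructions are supported: *absolute* adoption, where the baseline
population takes on the comparison area's minutes of walking and cycling,
and *relative* (constant travel-time budget) adoption, where the comparison
area's mode shares are applied to the baseline's own total travel time.
"""

from __future__ import annotations

from dataclasses import dataclass

from .travel_survey import MODES, SEXES, StratumTravelSummary, format_band, mode_shares


@dataclass
class Scenario:
    """Counterfactual walking/cycling minutes per (sex, age-band) stratum.

    Non-active modes do not enter the physical-activity pathway but the
    stratum total is carried for reporting.  ``kind`` is 'absolute' or
    'relative'; for relative scenarios the total equals the baseline total.
    """

    name: str
    kind: str
    walk_min: dict[tuple[str, tuple[int, int]], float]
    cycle_min: dict[tuple[str, tuple[int, int]], float]
    total_min: dict[tuple[str, tuple[int, int]], float]

    def __post_init__(self) -> None:
        if self.kind not in ("absolute", "relative"):
            raise ValueError(f"unknown scenario kind {self.kind!r}")
        for d in (self.walk_min, self.cycle_min, self.total_min):
            for key, v in d.items():
                if v < 0:
                    raise ValueError(f"negative scenario time for stratum {key}")


def baseline_scenario(base: StratumTravelSummary) -> Scenario:
    """The null scenario: the baseline's own travel pattern."""
    strata = base.strata()
    return Scenario(
        name=f"{base.setting} (baseline)",
        kind="absolute",
        walk_min={s: base.entries[(*s, "walk")] for s in strata},
        cycle_min={s: base.entries[(*s, "cycle")] for s in strata},
        total_min={s: base.total_minutes(*s) for s in strata},
    )


def _check_structure(base: StratumTravelSummary, comparison: StratumTravelSummary) -> None:
    missing = [
        (sex, format_band(band), mode)
        for sex in SEXES
        for band in base.age_bands
        for mode in MODES
        if (sex, band, mode) not in comparison.entries
    ]
    if missing:
        raise ValueError(
            "comparison summary is missing strata present in the baseline: "
            + ", ".join(map(str, missing[:10]))
        )


def _fill_sparse_strata(comparison: StratumTravelSummary) -> StratumTravelSummary:
    """Fill strata that are empty (NaN means) from the nearest complete band.

    Sparse old-age cells are common in smaller surveys; the nearest band of
    the same sex donates its mode means, preferring the adjacent younger band.
    """
    import math

    def complete(sex, band):
        return all(
            not math.isnan(comparison.entries[(sex, band, m)]) for m in MODES
        )

    entries = dict(comparison.entries)
    bands = comparison.age_bands
    for sex in SEXES:
        for i, band in enumerate(bands):
            if complete(sex, band):
                continue
            donors = sorted(
                (j for j in range(len(bands)) if j != i and complete(sex, bands[j])),
                key=lambda j: (abs(j - i), i - j),
            )
            if not donors:
                raise ValueError(f"no complete band for sex {sex!r} in comparison")
            donor = bands[donors[0]]
            for m in MODES:
                entries[(sex, band, m)] = comparison.entries[(sex, donor, m)]
    if entries == comparison.entries:
        return comparison
    return StratumTravelSummary(
        setting=comparison.setting, entries=entries,
        age_bands=bands, stratum_weight=comparison.stratum_weight,
    )


def build_absolute_scenario(
    base: StratumTravelSummary, comparison: StratumTravelSummary
) -> Scenario:
    """Adopt the comparison area's absolute walking and cycling minutes."""
    _check_structure(base, comparison)
    comparison = _fill_sparse_strata(comparison)
    strata = base.strata()
    walk = {s: comparison.entries[(*s, "walk")] for s in strata}
    cycle = {s: comparison.entries[(*s, "cycle")] for s in strata}
    total = {
        s: base.total_minutes(*s)
        - base.entries[(*s, "walk")]
        - base.entries[(*s, "cycle")]
        + walk[s]
        + cycle[s]
        for s in strata
    }
    return Scenario(
        name=f"{base.setting} adopting {comparison.setting} (absolute)",
        kind="absolute",
        walk_min=walk, cycle_min=cycle, total_min=total,
    )


def build_relative_scenario(
    base: StratumTravelSummary,
    comparison: StratumTravelSummary,
    sex_level_shares: bool = False,
) -> Scenario:
    """Apply the comparison area's mode shares to the baseline's travel budget.

    Shares are computed per (sex, band) stratum; ``sex_level_shares``
    collapses them to sex-level marginals first (the arithmetic of published
    sex-level tables).  Total time per stratum is conserved exactly.
    """
    _check_structure(base, comparison)
    comparison = _fill_sparse_strata(comparison)
    shares = mode_shares(comparison, group_by_sex_only=sex_level_shares)
    walk, cycle, total = {}, {}, {}
    for sex, band in base.strata():
        base_total = base.total_minutes(sex, band)
        comp_total = comparison.total_minutes(sex, band)
        if not comp_total > 0:
            raise ValueError(
                f"zero comparison total in stratum ({sex}, {format_band(band)})"
            )
        skey = (sex,) if sex_level_shares else (sex, band)
        walk[(sex, band)] = shares[(*skey, "walk")] * base_total
        cycle[(sex, band)] = shares[(*skey, "cycle")] * base_total
        total[(sex, band)] = base_total
    return Scenario(
        name=f"{base.setting} adopting {comparison.setting} (relative)",
        kind="relative",
        walk_min=walk, cycle_min=cycle, total_min=total,
    )
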