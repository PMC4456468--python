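"""CSV readers and writers for every pipeline table.

All formats are long-form CSV.  Surveys use two files — a persons file and
a trips file — because a trips-only file cannot represent people who did
not travel, and those people belong in every denominator.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .cra_engine import BurdenTable, ImpactResult
from .dose_response import DoseResponseSpec
from .exposure_model import METDistribution
from .scenario_builder import Scenario
from .travel_survey import StratumTravelSummary, TravelRecord, format_band, parse_band


def write_survey(records: list[TravelRecord], persons_path, trips_path) -> None:
    persons = pd.DataFrame(
        [
            {
                "person_id": r.person_id, "sex": r.sex, "age": r.age,
                "community_size": r.community_size, "weight": r.survey_weight,
            }
            for r in records
        ]
    )
    trips = pd.DataFrame(
        [
            {"person_id": r.person_id, "mode": str(mode), "duration_min": dur}
            for r in records
            for mode, dur in r.trips
        ],
        columns=["person_id", "mode", "duration_min"],
    )
    persons.to_csv(persons_path, index=False)
    trips.to_csv(trips_path, index=False)


def read_survey(persons_path, trips_path) -> list[TravelRecord]:
    persons = pd.read_csv(persons_path, dtype={"person_id": str})
    trips = pd.read_csv(trips_path, dtype={"person_id": str})
    by_person: dict[str, list] = {pid: [] for pid in persons["person_id"]}
    for t in trips.itertuples():
        by_person[t.person_id].append((t.mode, float(t.duration_min)))
    return [
        TravelRecord(
            person_id=p.person_id,
            sex=p.sex,
            age=int(p.age),
            community_size=int(p.community_size),
            trips=tuple(by_person[p.person_id]),
            survey_weight=float(getattr(p, "weight", 1.0)),
        )
        for p in persons.itertuples()
    ]


def write_summary(summary: StratumTravelSummary, path) -> None:
    summary.to_frame().to_csv(path, index=False)


def read_summary(path, setting: str | None = None) -> StratumTravelSummary:
    return StratumTravelSummary.from_frame(pd.read_csv(path), setting=setting)


def write_scenario(scenario: Scenario, path) -> None:
    rows = [
        {
            "name": scenario.name, "kind": scenario.kind,
            "sex": sex, "age_band": format_band(band),
            "walk_min": scenario.walk_min[(sex, band)],
            "cycle_min": scenario.cycle_min[(sex, band)],
            "total_min": scenario.total_min[(sex, band)],
        }
        for (sex, band) in scenario.walk_min
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_scenario(path) -> Scenario:
    df = pd.read_csv(path)
    keys = [(r.sex, parse_band(r.age_band)) for r in df.itertuples()]
    return Scenario(
        name=str(df["name"].iloc[0]),
        kind=str(df["kind"].iloc[0]),
        walk_min=dict(zip(keys, df["walk_min"].astype(float))),
        cycle_min=dict(zip(keys, df["cycle_min"].astype(float))),
        total_min=dict(zip(keys, df["total_min"].astype(float))),
    )


def write_met_distributions(dists: dict[str, METDistribution], path) -> None:
    pd.DataFrame(
        [
            {
                "activity": d.activity, "location_kind": d.location,
                "location_value": d.location_value,
                "spread_kind": d.spread_kind, "spread_value": d.spread_value,
            }
            for d in dists.values()
        ]
    ).to_csv(path, index=False)


def read_met_distributions(path) -> dict[str, METDistribution]:
    df = pd.read_csv(path)
    return {
        r.activity: METDistribution(
            r.activity, r.location_kind, float(r.location_value),
            r.spread_kind, float(r.spread_value),
        )
        for r in df.itertuples()
    }


def write_background(background: dict, path) -> None:
    rows = [
        {"sex": sex, "age_band": format_band(band), "mmet_h_per_week": v}
        for (sex, band), v in background.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_background(path) -> dict:
    df = pd.read_csv(path)
    return {
        (r.sex, parse_band(r.age_band)): float(r.mmet_h_per_week)
        for r in df.itertuples()
    }


def write_dose_response(specs, path) -> None:
    pd.DataFrame(
        [
            {
                "disease": s.disease, "rr_mean": s.rr_ref_mean, "rr_sd": s.rr_ref_sd,
                "x_ref_mmeth_wk": s.x_ref, "sex": s.sex_applicability,
                "outcome_types": "|".join(sorted(s.outcome_types)), "group": s.group,
            }
            for s in specs
        ]
    ).to_csv(path, index=False)


def read_dose_response(path) -> tuple[DoseResponseSpec, ...]:
    df = pd.read_csv(path)
    return tuple(
        DoseResponseSpec(
            disease=r.disease, rr_ref_mean=float(r.rr_mean),
            rr_ref_sd=float(r.rr_sd), x_ref=float(r.x_ref_mmeth_wk),
            sex_applicability=r.sex,
            outcome_types=frozenset(str(r.outcome_types).split("|")),
            group=r.group,
        )
        for r in df.itertuples()
    )


def write_burden(burden: BurdenTable, path) -> None:
    burden.df.to_csv(path, index=False)


def read_burden(path) -> BurdenTable:
    return BurdenTable(pd.read_csv(path))


def write_impacts(result: ImpactResult, path) -> None:
    result.df.to_csv(path, index=False)


def read_impacts(path) -> ImpactResult:
    return ImpactResult(pd.read_csv(path))


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
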