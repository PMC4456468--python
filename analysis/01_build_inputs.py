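#!/usr/bin/env python
"""Build every model input from the synthetic-data generators.

Draws a person-level travel survey for each of the four settings (England &
Wales baseline plus the Swiss, Dutch and Californian comparators), applies
the harmonisation filter (trips >= 3 min, communities >= 10,000, age >= 16),
and summarises population-based mean travel minutes per sex x age-band x
mode.  Also writes the background physical-activity table, the MET intensity
table, the dose-response table and the burden-of-disease table.

Small summary tables land in results/; the bulky person/trip files go to
scratch/surveys/ for audit.
"""

import argparse
from pathlib import Path

import ithim_pa as ip
from ithim_pa import io

SETTINGS = ["ew", "ch", "nl", "ca"]


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=7)
    parser.add_argument("--n-persons", type=int, default=20_000)
    parser.add_argument("--results", type=Path, default=Path("results"))
    parser.add_argument("--scratch", type=Path, default=Path("scratch/surveys"))
    args = parser.parse_args()

    io.ensure_dir(args.results)
    io.ensure_dir(args.scratch)

    for i, setting in enumerate(SETTINGS):
        profile = ip.setting_profile(setting, args.n_persons, seed=args.seed + i)
        records = ip.generate_travel_survey(profile)
        io.write_survey(
            records,
            args.scratch / f"persons_{setting}.csv",
            args.scratch / f"trips_{setting}.csv",
        )
        filtered = ip.filter_records(records)
        summary = ip.summarize_travel(filtered, setting=setting)
        io.write_summary(summary, args.results / f"summary_{setting}.csv")
        male_walk = sum(
            summary.stratum_weight[("male", b)] * summary.entries[("male", b, "walk")]
            for b in summary.age_bands
        ) / sum(summary.stratum_weight[("male", b)] for b in summary.age_bands)
        print(
            f"{setting}: {len(records)} records generated, {len(filtered)} kept; "
            f"male walk mean {male_walk:.1f} min/day"
        )

    io.write_background(
        ip.generate_background_pa(seed=args.seed), args.results / "background_pa.csv"
    )
    io.write_met_distributions(ip.DEFAULT_MET_DISTRIBUTIONS, args.results / "mets.csv")
    io.write_dose_response(
        ip.DEFAULT_DOSE_RESPONSE_SPECS, args.results / "dose_response.csv"
    )
    burden = ip.generate_burden_table()
    io.write_burden(burden, args.results / "burden.csv")
    totals = burden.totals()
    print(
        f"burden table: {totals['dalys']:,.0f} DALYs, {totals['deaths']:,.0f} "
        "deaths at baseline"
    )


if __name__ == "__main__":
    main()
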