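#!/usr/bin/env python
"""Construct the six counterfactual travel scenarios for the baseline.

For each comparison area (Switzerland, Netherlands, California) two
scenarios are built on the England & Wales baseline: *absolute* adoption of
the comparator's walking and cycling minutes, and *relative* adoption of its
mode shares within the unchanged E&W travel-time budget.
"""

import argparse
from pathlib import Path

import ithim_pa as ip
from ithim_pa import io


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--results", type=Path, default=Path("results"))
    args = parser.parse_args()

    base = io.read_summary(args.results / "summary_ew.csv")
    for setting in ("ch", "nl", "ca"):
        comp = io.read_summary(args.results / f"summary_{setting}.csv")
        for kind, build in (
            ("absolute", ip.build_absolute_scenario),
            ("relative", ip.build_relative_scenario),
        ):
            scen = build(base, comp)
            io.write_scenario(scen, args.results / f"scenario_{setting}_{kind}.csv")
            walk = sum(scen.walk_min.values()) / len(scen.walk_min)
            cycle = sum(scen.cycle_min.values()) / len(scen.cycle_min)
            print(
                f"{setting}/{kind}: band-average walk {walk:.1f}, "
                f"cycle {cycle:.1f} min/day"
            )


if __name__ == "__main__":
    main()
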