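"""Comparative risk assessment: impact fractions and burden deltas.

The potential impact fraction compares population-mean relative risk under
the baseline exposure distribution with the counterfactual:

    PIF = (sum_i RR(x_i^base) - sum_i RR(x_i^scen)) / sum_i RR(x_i^base)

over equi-probable quantile points i.  Applied to baseline burden (deaths,
YLL, YLD, DALYs), deltas are negative when burden is prevented.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exposure_model import ExposureDistribution
from .travel_survey import format_band, parse_band

OUTCOMES = ("deaths", "yll", "ylds", "dalys")


@dataclass
class BurdenTable:
    """Deaths/YLL/YLD/DALYs per (disease, sex, age_band), counts per year.

    Backed by a DataFrame with columns disease, sex, age_band (label),
    deaths, yll, ylds, dalys.  DALYs must equal YLL + YLD per cell within a
    0.5% rounding tolerance.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"disease", "sex", "age_band", *OUTCOMES}
        if not required <= set(self.df.columns):
            raise ValueError(f"burden table missing columns {required - set(self.df.columns)}")
        if (self.df[list(OUTCOMES)] < 0).any().any():
            raise ValueError("burden counts must be >= 0")
        resid = self.df["dalys"] - (self.df["yll"] + self.df["ylds"])
        scale = self.df["dalys"].clip(lower=1.0)
        if (resid.abs() / scale > 0.005).any():
            raise ValueError("dalys must equal yll + ylds within 0.5% per cell")

    def cell(self, disease: str, sex: str, band) -> dict[str, float]:
        label = band if isinstance(band, str) else format_band(band)
        row = self.df[
            (self.df.disease == disease)
            & (self.df.sex == sex)
            & (self.df.age_band == label)
        ]
        if row.empty:
            return {o: 0.0 for o in OUTCOMES}
        return {o: float(row[o].sum()) for o in OUTCOMES}

    def diseases(self) -> list[str]:
        return list(dict.fromkeys(self.df["disease"]))

    def age_bands(self) -> list[tuple[int, int]]:
        return sorted({parse_band(b) for b in self.df["age_band"]})

    def totals(self) -> dict[str, float]:
        return {o: float(self.df[o].sum()) for o in OUTCOMES}


@dataclass
class ImpactResult:
    """Per-(disease, sex) changes in deaths and DALYs across Monte Carlo
    iterations, as median with a 95% credible interval.

    Backed by a DataFrame with columns disease, sex, outcome
    ('deaths'|'dalys'), median, ci_low, ci_high; includes 'total' rows per
    sex and a grand 'total'/'both' row.  Negative values are prevented
    burden.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        bad = (self.df.ci_low > self.df["median"] + 1e-9) | (
            self.df["median"] > self.df.ci_high + 1e-9
        )
        if bad.any():
            raise ValueError("credible interval must bracket the median")

    def lookup(self, disease: str, sex: str, outcome: str) -> tuple[float, float, float]:
        row = self.df[
            (self.df.disease == disease)
            & (self.df.sex == sex)
            & (self.df.outcome == outcome)
        ]
        if row.empty:
            raise KeyError((disease, sex, outcome))
        r = row.iloc[0]
        return float(r["median"]), float(r.ci_low), float(r.ci_high)

    def total(self, outcome: str, sex: str = "both") -> tuple[float, float, float]:
        return self.lookup("total", sex, outcome)


def pif(
    baseline: ExposureDistribution,
    scenario: ExposureDistribution,
    rr_curve,
) -> float:
    """Potential impact fraction from baseline to scenario exposure.

    Positive PIF means the scenario lowers population risk.  Zero when the
    distributions coincide; bounded above by 1.
    """
    xb = baseline.quantile_points
    xs = scenario.quantile_points
    if xb.shape != xs.shape:
        raise ValueError(
            f"quantile counts differ: baseline {xb.shape[0]} vs scenario {xs.shape[0]}"
        )
    rr_b = np.asarray(rr_curve(xb), dtype=float)
    rr_s = np.asarray(rr_curve(xs), dtype=float)
    return float((rr_b.sum() - rr_s.sum()) / rr_b.sum())


def burden_delta(
    pif_value: float,
    burden_cell: dict[str, float],
    outcome_types: frozenset[str] | set[str] = frozenset({"deaths", "yll", "yld"}),
) -> dict[str, float]:
    """Change in each outcome: delta = -PIF x baseline, negative = prevented.

    Outcomes outside ``outcome_types`` stay 0; the DALY delta is the sum of
    the YLL and YLD deltas, so a morbidity-only disease still moves DALYs.
    """
    d_deaths = -pif_value * burden_cell["deaths"] if "deaths" in outcome_types else 0.0
    d_yll = -pif_value * burden_cell["yll"] if "yll" in outcome_types else 0.0
    d_yld = -pif_value * burden_cell["ylds"] if "yld" in outcome_types else 0.0
    return {"deaths": d_deaths, "yll": d_yll, "ylds": d_yld, "dalys": d_yll + d_yld}


def aggregate_impacts(cells: pd.DataFrame) -> pd.DataFrame:
    """Sum per-(disease, sex, band) deltas to per-(disease, sex) and totals.

    ``cells`` needs columns disease, sex and any subset of outcome columns;
    returns per-disease rows plus 'total' per sex and a 'total' x 'both'
    grand-total row.  Sums are exact, so stratum-then-disease equals
    disease-then-stratum.
    """
    value_cols = [c for c in cells.columns if c in OUTCOMES or c.startswith("delta_")]
    per_disease = cells.groupby(["disease", "sex"], as_index=False)[value_cols].sum()
    sex_tot = cells.groupby("sex", as_index=False)[value_cols].sum()
    sex_tot.insert(0, "disease", "total")
    grand = cells[value_cols].sum().to_frame().T
    grand.insert(0, "disease", "total")
    grand.insert(1, "sex", "both")
    return pd.concat([per_disease, sex_tot, grand], ignore_index=True)
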