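"""Potential impact fractions, burden deltas and aggregation."""

import numpy as np
import pandas as pd
import pytest

import ithim_pa as ip
from ithim_pa.cra_engine import BurdenTable, ImpactResult
from ithim_pa.dose_response import DEFAULT_DOSE_RESPONSE_SPECS
from ithim_pa.exposure_model import ExposureDistribution

CVD = DEFAULT_DOSE_RESPONSE_SPECS[0]
STRATUM = ("male", (30, 45))


def expo(points):
    return ExposureDistribution(STRATUM, np.sort(np.asarray(points, dtype=float)))


def rr_curve(x):
    return ip.relative_risk(x, CVD, 0.84, 0.5)


class TestPif:
    def test_null_scenario_zero(self):
        d = expo([1, 3, 5, 8, 13])
        assert ip.pif(d, d, rr_curve) == 0.0

    def test_single_quantile_closed_form(self):
        base = expo([0.0])
        scen = expo([CVD.x_ref])
        value = ip.pif(base, scen, lambda x: ip.relative_risk(x, CVD, 0.84, 1.0))
        assert value == pytest.approx((1 - 0.84) / 1.0, abs=1e-12)

    def test_mismatched_quantile_counts_rejected(self):
        with pytest.raises(ValueError, match="quantile counts"):
            ip.pif(expo([1, 2, 3]), expo([1, 2]), rr_curve)

    def test_equals_person_level_sum_on_matching_population(self):
        """A population holding each quantile value in equal numbers gives the
        identical person-sum PIF."""
        rng = np.random.default_rng(11)
        base_pts = np.sort(rng.uniform(0, 20, size=5))
        scen_pts = np.sort(rng.uniform(0, 20, size=5))
        base, scen = expo(base_pts), expo(scen_pts)
        pop_base = np.repeat(base_pts, 20_000)
        pop_scen = np.repeat(scen_pts, 20_000)
        rr_b, rr_s = rr_curve(pop_base), rr_curve(pop_scen)
        brute = (rr_b.sum() - rr_s.sum()) / rr_b.sum()
        assert ip.pif(base, scen, rr_curve) == pytest.approx(brute, abs=1e-12)

    def test_sign_follows_exposure_dominance(self):
        base = expo([1, 2, 4, 7, 11])
        more = expo(np.asarray([1, 2, 4, 7, 11]) + 2.0)
        assert ip.pif(base, more, rr_curve) > 0
        assert ip.pif(more, base, rr_curve) < 0

    def test_bounded_above_by_one(self):
        base = expo([0, 0, 0, 0, 0])
        scen = expo([500, 500, 500, 500, 500])
        assert ip.pif(base, scen, rr_curve) <= 1


class TestBurdenDelta:
    CELL = {"deaths": 100.0, "yll": 700.0, "ylds": 300.0, "dalys": 1000.0}

    def test_zero_pif_zero_delta(self):
        d = ip.burden_delta(0.0, self.CELL)
        assert all(v == 0 for v in d.values())

    def test_proportionality(self):
        d = ip.burden_delta(0.1, self.CELL)
        assert d["dalys"] == pytest.approx(-100.0)
        assert d["deaths"] == pytest.approx(-10.0)

    def test_morbidity_only_disease_moves_dalys_not_deaths(self):
        d = ip.burden_delta(0.1, self.CELL, outcome_types=frozenset({"yld"}))
        assert d["deaths"] == 0.0 and d["yll"] == 0.0
        assert d["dalys"] == pytest.approx(-30.0)

    def test_daly_delta_is_yll_plus_yld(self):
        d = ip.burden_delta(0.25, self.CELL)
        assert d["dalys"] == pytest.approx(d["yll"] + d["ylds"])

    def test_delta_bounded_by_baseline(self):
        for p in (-1.0, -0.3, 0.5, 1.0):
            d = ip.burden_delta(p, self.CELL)
            assert abs(d["dalys"]) <= self.CELL["dalys"] + 1e-9


class TestAggregation:
    def test_single_cell_total(self):
        cells = pd.DataFrame(
            [{"disease": "ihd", "sex": "male", "dalys": -5.0, "deaths": -1.0}]
        )
        out = ip.aggregate_impacts(cells)
        grand = out[(out.disease == "total") & (out.sex == "both")]
        assert grand["dalys"].iloc[0] == pytest.approx(-5.0)

    def test_matches_naive_double_loop(self):
        rng = np.random.default_rng(5)
        rows = [
            {
                "disease": dis, "sex": sex, "age_band": band,
                "dalys": float(rng.normal()), "deaths": float(rng.normal()),
            }
            for dis in ("a", "b", "c")
            for sex in ("male", "female")
            for band in ("15-29", "30-44")
        ]
        cells = pd.DataFrame(rows)
        out = ip.aggregate_impacts(cells)
        naive = sum(r["dalys"] for r in rows)
        grand = out[(out.disease == "total") & (out.sex == "both")]["dalys"].iloc[0]
        assert grand == pytest.approx(naive, abs=1e-9)
        male = out[(out.disease == "total") & (out.sex == "male")]["dalys"].iloc[0]
        female = out[(out.disease == "total") & (out.sex == "female")]["dalys"].iloc[0]
        assert male + female == pytest.approx(grand, abs=1e-9)

    def test_associative_stratum_disease_order(self):
        rng = np.random.default_rng(6)
        rows = [
            {
                "disease": dis, "sex": "male", "age_band": band,
                "dalys": float(rng.normal()),
            }
            for dis in ("a", "b")
            for band in ("15-29", "30-44", "45-59")
        ]
        cells = pd.DataFrame(rows)
        by_disease_first = (
            cells.groupby(["disease", "sex"])["dalys"].sum().groupby("sex").sum()
        )
        by_stratum_first = (
            cells.groupby(["sex", "age_band"])["dalys"].sum().groupby("sex").sum()
        )
        assert by_disease_first["male"] == pytest.approx(by_stratum_first["male"])


class TestBurdenTable:
    def test_daly_consistency_enforced(self):
        df = pd.DataFrame([{
            "disease": "ihd", "sex": "male", "age_band": "30-44",
            "deaths": 10, "yll": 100, "ylds": 50, "dalys": 200,
        }])
        with pytest.raises(ValueError, match="yll"):
            BurdenTable(df)

    def test_negative_counts_rejected(self):
        df = pd.DataFrame([{
            "disease": "ihd", "sex": "male", "age_band": "30-44",
            "deaths": -1, "yll": 100, "ylds": 50, "dalys": 150,
        }])
        with pytest.raises(ValueError):
            BurdenTable(df)

    def test_missing_cell_reads_as_zero(self, burden):
        cell = burden.cell("breast_cancer", "male", "30-44")
        assert cell == {"deaths": 0.0, "yll": 0.0, "ylds": 0.0, "dalys": 0.0}


def test_impact_result_interval_must_bracket_median():
    df = pd.DataFrame([{
        "disease": "ihd", "sex": "male", "outcome": "dalys",
        "median": -5.0, "ci_low": -2.0, "ci_high": -1.0,
    }])
    with pytest.raises(ValueError, match="bracket"):
        ImpactResult(df)
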