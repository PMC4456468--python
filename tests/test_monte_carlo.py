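"""Uncertainty propagation, credible intervals and tornado sensitivity."""

import logging

import numpy as np
import pytest

import ithim_pa as ip
from ithim_pa.dose_response import DoseResponseSpec
from ithim_pa.exposure_model import METDistribution
from ithim_pa.monte_carlo import central_parameters, evaluate_deltas

from conftest import make_inputs


class TestCredibleInterval:
    def test_constant_samples(self):
        assert ip.credible_interval([4.2] * 10) == (4.2, 4.2, 4.2)

    def test_interpolated_median(self):
        lo, med, hi = ip.credible_interval(list(range(1, 101)))
        assert med == pytest.approx(50.5)

    def test_standard_normal_quantiles(self):
        draws = np.random.default_rng(0).standard_normal(10**6)
        lo, med, hi = ip.credible_interval(draws)
        assert lo == pytest.approx(-1.96, abs=0.01)
        assert med == pytest.approx(0.0, abs=0.01)
        assert hi == pytest.approx(1.96, abs=0.01)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ip.credible_interval([])


class TestRunSimulation:
    def test_same_seed_identical(self, ch_inputs):
        cfg = ip.SimulationConfig(n_iterations=400, seed=9)
        a = ip.run_simulation(cfg, ch_inputs)
        b = ip.run_simulation(cfg, ch_inputs)
        assert a.df.equals(b.df)

    def test_different_seeds_differ(self, ch_inputs):
        a = ip.run_simulation(ip.SimulationConfig(n_iterations=400, seed=1), ch_inputs)
        b = ip.run_simulation(ip.SimulationConfig(n_iterations=400, seed=2), ch_inputs)
        assert not a.df.equals(b.df)

    def test_degenerate_spreads_collapse_interval(self, summaries, burden, background):
        """With every stochastic source switched off, the Monte Carlo median
        equals the deterministic pipeline output and the CI has zero width."""
        inputs = make_inputs(summaries["ew"], summaries["ch"], burden, background)
        cfg = ip.SimulationConfig(
            n_iterations=200, seed=3, sample_rr=False, sample_k=False,
            k_range=(0.5, 0.5),
        )
        result = ip.run_simulation(cfg, inputs)
        assert np.allclose(result.df.ci_low, result.df.ci_high)
        central = central_parameters(inputs, cfg)
        det = evaluate_deltas(central, inputs, cfg)
        total_det = sum(arr["dalys"][0] for arr in det.values())
        med, lo, hi = result.total("dalys")
        assert med == pytest.approx(total_det, rel=1e-12)

    def test_interval_brackets_median_everywhere(self, ch_inputs):
        res = ip.run_simulation(ip.SimulationConfig(n_iterations=500, seed=5), ch_inputs)
        assert (res.df.ci_low <= res.df["median"] + 1e-12).all()
        assert (res.df["median"] <= res.df.ci_high + 1e-12).all()

    def test_small_iteration_count_warns(self, ch_inputs, caplog):
        with caplog.at_level(logging.WARNING):
            ip.SimulationConfig(n_iterations=50, seed=1)
        assert "unstable" in caplog.text

    def test_per_disease_k_option_runs(self, ch_inputs):
        cfg = ip.SimulationConfig(n_iterations=200, seed=4, shared_k=False)
        res = ip.run_simulation(cfg, ch_inputs)
        assert np.isfinite(res.total("dalys")[0])

    def test_met_uncertainty_mode_widens_interval(self, ch_inputs):
        pop = ip.run_simulation(
            ip.SimulationConfig(n_iterations=1000, seed=6), ch_inputs
        )
        unc = ip.run_simulation(
            ip.SimulationConfig(n_iterations=1000, seed=6, met_variation="uncertainty"),
            ch_inputs,
        )
        def width(r):
            _, lo, hi = r.total("dalys")
            return hi - lo

        assert width(unc) > width(pop)

    def test_monte_carlo_error_scales_with_sqrt_iterations(self, ch_inputs):
        """Doubling the iteration count shrinks the sampling error of the
        median by roughly sqrt(2)."""

        def median_sd(n, seeds):
            meds = [
                ip.run_simulation(
                    ip.SimulationConfig(n_iterations=n, seed=s), ch_inputs
                ).total("dalys")[0]
                for s in seeds
            ]
            return np.std(meds)

        sd_small = median_sd(400, range(100, 130))
        sd_big = median_sd(800, range(200, 230))
        assert 1.2 <= sd_small / sd_big <= 1.7


class TestTornado:
    def test_zero_spread_parameter_ranked_last(self, summaries, burden, background):
        inputs = make_inputs(summaries["ew"], summaries["ch"], burden, background)
        cfg = ip.SimulationConfig(n_iterations=100, seed=1)
        zero_spread = tuple(
            DoseResponseSpec(
                s.disease, s.rr_ref_mean, 0.0, s.x_ref, s.sex_applicability,
                s.outcome_types, group=s.group,
            )
            for s in inputs.dr_specs
        )
        inputs2 = ip.ModelInputs(
            inputs.baseline, inputs.scenario, inputs.background,
            inputs.met_dists, zero_spread, inputs.burden,
        )
        df = ip.tornado_analysis(cfg, inputs2, parameters=["met_walk", "rr_cvd"])
        assert df.iloc[-1].parameter == "rr_cvd"
        assert df.iloc[-1]["range"] == pytest.approx(0.0, abs=1e-9)

    def test_ranking_invariant_under_parameter_order(self, ch_inputs):
        cfg = ip.SimulationConfig(n_iterations=100, seed=1)
        params = ["met_walk", "k", "rr_cvd", "met_cycle"]
        a = ip.tornado_analysis(cfg, ch_inputs, parameters=params)
        b = ip.tornado_analysis(cfg, ch_inputs, parameters=params[::-1])
        assert list(a.parameter) == list(b.parameter)

    def test_unknown_parameter_lists_valid_names(self, ch_inputs):
        cfg = ip.SimulationConfig(n_iterations=100, seed=1)
        with pytest.raises(ValueError, match="met_walk"):
            ip.tornado_analysis(cfg, ch_inputs, parameters=["nope"])

    def test_matches_direct_percentile_sweep_with_single_driver(
        self, summaries, burden, background
    ):
        inputs = make_inputs(summaries["ew"], summaries["ch"], burden, background)
        cfg = ip.SimulationConfig(n_iterations=100, seed=1)
        df = ip.tornado_analysis(cfg, inputs, parameters=["met_walk"])
        central = central_parameters(inputs, cfg)
        lo_params = {k: v.copy() for k, v in central.items()}
        lo_params["met_walk"] = np.array([inputs.met_dists["walk"].quantile(0.05)])
        lo_direct = sum(
            a["dalys"][0] for a in evaluate_deltas(lo_params, inputs, cfg).values()
        )
        assert df.iloc[0].low_output == pytest.approx(lo_direct, rel=1e-12)
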