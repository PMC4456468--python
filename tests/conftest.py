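import numpy as np
import pytest

import ithim_pa as ip
from ithim_pa.synthetic_data import SETTING_MODE_MINUTES
from ithim_pa.travel_survey import MODES, SEXES, StratumTravelSummary

#: single all-adult band used for sex-level (published-table) arithmetic
ONE_BAND = ((15, 120),)


def sex_level_summary(setting: str) -> StratumTravelSummary:
    """Summary built directly from a setting's published sex-level mode minutes."""
    entries = {
        (sex, ONE_BAND[0], mode): SETTING_MODE_MINUTES[setting][sex][mode]
        for sex in SEXES
        for mode in MODES
    }
    return StratumTravelSummary(
        setting=setting,
        entries=entries,
        age_bands=ONE_BAND,
        stratum_weight={(sex, ONE_BAND[0]): 1.0 for sex in SEXES},
    )


def synthetic_summary(setting: str, n: int = 20_000, seed: int = 7):
    records = ip.generate_travel_survey(ip.setting_profile(setting, n, seed=seed))
    return ip.summarize_travel(ip.filter_records(records), setting=setting)


@pytest.fixture(scope="session")
def summaries():
    """Filtered, summarised synthetic surveys for the four settings."""
    return {
        s: synthetic_summary(s, seed=7 + i)
        for i, s in enumerate(["ew", "ch", "nl", "ca"])
    }


@pytest.fixture(scope="session")
def burden():
    return ip.generate_burden_table()


@pytest.fixture(scope="session")
def background():
    return ip.generate_background_pa(seed=7)


def make_inputs(base, comparison, burden, background, kind="absolute"):
    build = (
        ip.build_absolute_scenario if kind == "absolute" else ip.build_relative_scenario
    )
    return ip.ModelInputs(
        baseline=ip.baseline_scenario(base),
        scenario=build(base, comparison),
        background=background,
        met_dists=ip.DEFAULT_MET_DISTRIBUTIONS,
        dr_specs=ip.DEFAULT_DOSE_RESPONSE_SPECS,
        burden=burden,
    )


@pytest.fixture(scope="session")
def ch_inputs(summaries, burden, background):
    return make_inputs(summaries["ew"], summaries["ch"], burden, background)
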