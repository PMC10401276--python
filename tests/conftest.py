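import dataclasses

import numpy as np
import pandas as pd
import pytest

from cornvi.bands import BandSet
from cornvi.screening import score_correlations, stable_set, summarize_year
from cornvi.synthetic import SimConfig, panels_from_observations, simulate_experiment


def random_bandsets(n: int, seed: int = 0) -> list[BandSet]:
    """Random valid BandSets with bands well inside (0, 1)."""
    rng = np.random.default_rng(seed)
    values = rng.uniform(0.01, 0.99, size=(n, 5))
    return [BandSet(*row) for row in values]


@pytest.fixture(scope="session")
def default_config() -> SimConfig:
    return SimConfig(seed=11)


@pytest.fixture(scope="session")
def default_sim(default_config):
    return simulate_experiment(default_config)


@pytest.fixture(scope="session")
def small_scene_config() -> SimConfig:
    """A scene small enough for fast classifier tests (labels relaxed)."""
    return SimConfig(seed=7, plot_px=16, gap_px=8, margin_px=8,
                     weed_fraction=0.08, labels_per_class=300)


@pytest.fixture(scope="session")
def replicate_stats(default_config):
    """Per-year screen statistics over 100 replicate experiments.

    For each replicate x year: whether each planted chlorophyll VI is in
    the stable set, and |r(MTCI, yield)| at the R1 and V5 flights.
    """
    planted = ("MTCI", "LCI", "mND705")
    rows = []
    for rep in range(100):
        config = dataclasses.replace(default_config, seed=20_000 + rep)
        sim = simulate_experiment(config)
        panels = panels_from_observations(sim.observations, planted)
        records = score_correlations(panels, sim.yields)
        for year in config.years:
            year_records = records[records["year"] == year]
            stable = stable_set(summarize_year(year_records))
            mtci = (year_records[year_records["vi_name"] == "MTCI"]
                    .set_index("stage")["r"].abs())
            rows.append({
                "rep": rep, "year": year,
                **{f"stable_{vi}": vi in stable for vi in planted},
                "abs_r_R1": mtci["R1"], "abs_r_V5": mtci["V5"],
            })
    return pd.DataFrame(rows)
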