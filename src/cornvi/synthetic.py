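"""Synthetic three-year split-plot corn experiment with UAV reflectance.

The generator emulates the statistical structure the screening pipeline
assumes, so every stage is testable without field data:

* **Design** — a split-plot randomized complete block: 4 cover-crop
  treatments (winter pea, radish/mix, cereal rye, no cover) x 4 blocks =
  16 subplots per year, 3 years, with 7 UAV flights per season spanning
  vegetative (V5..Vn) to reproductive (R1..R5) corn stages.
* **Latent vigor** — each plot carries a vigor v in [0, 1] composed of a
  year shift, a treatment effect, a block effect and plot noise.  Yield is
  linearly linked to vigor: yield = a + b*v + eps (Mg/ha at 15.5%
  moisture).
* **Reflectance** — per flight, the plot's five-band reflectance is a
  two-endmember linear mixture of soil and leaf spectra weighted by canopy
  cover c(t) (logistic rise to a vigor-dependent plateau).  Leaf visible
  reflectance decays exponentially with the chlorophyll proxy
  chl(t) = v * g(t), where g is unimodal and peaks in the R1-R3 window —
  so red-edge chlorophyll indices (MTCI, LCI, mND705) track vigor most
  strongly around silking, which is exactly the behavior the screen is
  meant to detect.
* **Scenes** — optional pixel-level rendering: rectangular plot polygons on
  a grid, in-plot pixels split corn/soil by canopy fraction, weedy patches
  in the alleys, plus a labelled pixel set for classifier training.

Everything is driven by one seed and is bit-for-bit reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Sequence

import numpy as np
import pandas as pd

from .bands import BAND_NAMES, BandSet
from .imagery import PixelLabelSet, PlotPolygon, Scene
from .vi_registry import FlightMeta, VIMatrix, compute_panel

__all__ = ["SimConfig", "SimResult", "simulate_experiment", "simulate_scene",
           "null_scenario", "leaf_reflectance", "soil_reflectance",
           "panels_from_observations"]

#: Dry-soil and weed endmember reflectance (blue, green, red, rededge, nir).
SOIL_ENDMEMBER = np.array([0.10, 0.14, 0.18, 0.22, 0.26])
WEED_ENDMEMBER = np.array([0.07, 0.13, 0.10, 0.20, 0.30])

#: Default flight schedule: (phenology stage, days after planting).
DEFAULT_FLIGHTS = (("V5", 35), ("V7", 46), ("V10", 55), ("Vn", 67),
                   ("R1", 83), ("R3", 95), ("R5", 115))

PLANTING_MONTH_DAY = (4, 10)


@dataclass(frozen=True)
class SimConfig:
    """Generative parameters of the synthetic experiment.

    Defaults encode the study conditions: 3 seasons x 16 subplots x 7
    flights, treatment effect sizes calibrated so that the planted
    chlorophyll indices reach |r| >= 0.7 with yield around R1, and a yield
    link giving season means in the 6-11 Mg/ha range.
    """

    seed: int = 0
    n_years: int = 3
    first_year: int = 2020
    treatments: tuple[str, ...] = ("winter_pea", "radish_mix", "rye", "no_cover")
    treatment_effects: tuple[float, ...] = (0.10, -0.06, -0.08, 0.04)
    n_blocks: int = 4
    year_vigor_shift: tuple[float, ...] = (0.0, -0.06, 0.03)
    vigor_mean: float = 0.55
    block_sd: float = 0.03
    plot_sd: float = 0.05
    flights: tuple[tuple[str, int], ...] = DEFAULT_FLIGHTS
    # yield link: Mg/ha = intercept + slope * vigor + N(0, sd)
    yield_intercept: float = 2.0
    yield_slope: float = 12.0
    yield_sd: float = 0.30
    # reflectance noise
    band_noise_sd: float = 0.004
    pixel_noise_sd: float = 0.012
    # canopy-cover logistic and chlorophyll trajectory
    canopy_midpoint_dap: float = 45.0
    canopy_rate_dap: float = 8.0
    canopy_base: float = 0.55
    canopy_span: float = 0.40
    chl_peak_dap: float = 87.0
    chl_width_dap: float = 26.0
    # scene rendering
    pixel_size_m: float = 0.04
    plot_px: int = 90
    gap_px: int = 34
    margin_px: int = 24
    weed_fraction: float = 0.02
    labels_per_class: int = 5000

    def __post_init__(self) -> None:
        if len(self.treatment_effects) != len(self.treatments):
            raise ValueError("one effect per treatment required")
        if len(self.year_vigor_shift) < self.n_years:
            raise ValueError("need a vigor shift per simulated year")
        for name in ("block_sd", "plot_sd", "yield_sd", "band_noise_sd",
                     "pixel_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        daps = [dap for _, dap in self.flights]
        if daps != sorted(daps):
            raise ValueError("flights must be sorted by DAP")
        if not 0 <= self.weed_fraction < 1:
            raise ValueError("weed_fraction must be in [0, 1)")

    @property
    def years(self) -> tuple[int, ...]:
        return tuple(self.first_year + i for i in range(self.n_years))


def null_scenario(config: SimConfig) -> SimConfig:
    """The negative control: yields decoupled from vigor (b = 0)."""
    return dataclasses.replace(config, yield_slope=0.0)


# ---------------------------------------------------------------------------
# deterministic reflectance components

def canopy_cover(dap: float, vigor: float, config: SimConfig) -> float:
    """Logistic canopy-cover rise to a vigor-dependent plateau."""
    plateau = config.canopy_base + config.canopy_span * vigor
    rise = 1.0 / (1.0 + np.exp(-(dap - config.canopy_midpoint_dap)
                               / config.canopy_rate_dap))
    return float(np.clip(plateau * rise, 0.0, 1.0))


def chlorophyll_proxy(dap: float, vigor: float, config: SimConfig) -> float:
    """chl(t) = v * g(t) with g unimodal, peaking in the R1-R3 window."""
    g = np.exp(-0.5 * ((dap - config.chl_peak_dap) / config.chl_width_dap) ** 2)
    return float(vigor * g)


def leaf_reflectance(chl: float, vigor: float) -> np.ndarray:
    """Leaf endmember spectrum (blue, green, red, rededge, nir).

    Visible bands decay exponentially with chlorophyll (strongest in red),
    the red edge decays mildly, and NIR increases with vigor (canopy
    structure), reproducing the qualitative crop-spectrum shape: low
    visible reflectance, sharp red-edge transition, high NIR plateau.
    """
    return np.array([
        0.04 + 0.10 * np.exp(-2.0 * chl),
        0.06 + 0.12 * np.exp(-1.6 * chl),
        0.03 + 0.10 * np.exp(-3.0 * chl),
        0.16 + 0.18 * np.exp(-0.8 * chl),
        0.32 + 0.28 * vigor,
    ])


def soil_reflectance() -> np.ndarray:
    return SOIL_ENDMEMBER.copy()


def plot_reflectance(dap: float, vigor: float, config: SimConfig
                     ) -> tuple[float, float, np.ndarray]:
    """(canopy cover, chl, noiseless mixture spectrum) for one plot-flight."""
    cover = canopy_cover(dap, vigor, config)
    chl = chlorophyll_proxy(dap, vigor, config)
    mixture = (1.0 - cover) * SOIL_ENDMEMBER + cover * leaf_reflectance(chl, vigor)
    return cover, chl, mixture


# ---------------------------------------------------------------------------
# experiment simulation

@dataclass
class SimResult:
    """Outputs of one simulated experiment.

    yields: plot yield table (year, plot_id, treatment, block, yield_mg_ha).
    observations: long per-flight reflectance table with noisy five-band
    plot means (one row per year x flight x plot).
    truth: plots (latent vigor) and flights (noiseless canopy/chl/bands).
    """

    config: SimConfig
    yields: pd.DataFrame
    observations: pd.DataFrame
    truth_plots: pd.DataFrame
    truth_flights: pd.DataFrame


def _flight_date(year: int, dap: int) -> str:
    planting = date(year, *PLANTING_MONTH_DAY)
    return (planting + timedelta(days=int(dap))).isoformat()


def simulate_experiment(config: SimConfig) -> SimResult:
    """Draw one full experiment (all years, flights and plots) from the config."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    effects = dict(zip(config.treatments, config.treatment_effects))

    yield_rows, obs_rows, plot_rows, flight_rows = [], [], [], []
    for year_index, year in enumerate(config.years):
        block_effects = rng.normal(0.0, config.block_sd, size=config.n_blocks)
        for block in range(1, config.n_blocks + 1):
            for treatment in config.treatments:
                plot_id = f"B{block}-{treatment}"
                vigor = (config.vigor_mean
                         + config.year_vigor_shift[year_index]
                         + effects[treatment]
                         + block_effects[block - 1]
                         + rng.normal(0.0, config.plot_sd))
                vigor = float(np.clip(vigor, 0.0, 1.0))
                grain = (config.yield_intercept + config.yield_slope * vigor
                         + rng.normal(0.0, config.yield_sd))
                grain = float(max(grain, 0.05))
                yield_rows.append({"year": year, "plot_id": plot_id,
                                   "treatment": treatment, "block": block,
                                   "yield_mg_ha": grain})
                plot_rows.append({"year": year, "plot_id": plot_id,
                                  "treatment": treatment, "block": block,
                                  "vigor": vigor})
                for stage, dap in config.flights:
                    cover, chl, mixture = plot_reflectance(dap, vigor, config)
                    observed = np.clip(
                        mixture + rng.normal(0.0, config.band_noise_sd, size=5),
                        0.0, 1.0)
                    flight_rows.append({
                        "year": year, "plot_id": plot_id, "stage": stage,
                        "dap": dap, "canopy": cover, "chl": chl,
                        **{f"true_{b}": mixture[i] for i, b in enumerate(BAND_NAMES)},
                    })
                    obs_rows.append({
                        "year": year, "plot_id": plot_id,
                        "date": _flight_date(year, dap), "dap": dap,
                        "stage": stage,
                        **{b: observed[i] for i, b in enumerate(BAND_NAMES)},
                    })

    return SimResult(
        config=config,
        yields=pd.DataFrame(yield_rows),
        observations=pd.DataFrame(obs_rows),
        truth_plots=pd.DataFrame(plot_rows),
        truth_flights=pd.DataFrame(flight_rows),
    )


def panels_from_observations(observations: pd.DataFrame,
                             names: Sequence[str]) -> list[VIMatrix]:
    """Build one VIMatrix per (year, flight) from the long observation table."""
    panels = []
    for (year, flight_date, dap, stage), group in observations.groupby(
            ["year", "date", "dap", "stage"], sort=True):
        bandsets = {
            row.plot_id: BandSet(row.blue, row.green, row.red, row.rededge, row.nir)
            for row in group.itertuples()
        }
        panels.append(compute_panel(
            bandsets, names, FlightMeta(str(flight_date), int(dap), str(stage)),
            int(year)))
    panels.sort(key=lambda p: (p.year, p.flight.dap))
    return panels


# ---------------------------------------------------------------------------
# pixel-level scene rendering

def simulate_scene(result: SimResult, year: int, stage: str,
                   config: SimConfig | None = None
                   ) -> tuple[Scene, PixelLabelSet, list[PlotPolygon]]:
    """Render one flight as a raster scene with labels and plot polygons.

    Plots sit on a 4-wide grid of squares (``plot_px`` pixels a side,
    ``gap_px`` alleys).  Within a plot, a canopy-fraction share of pixels is
    corn (the plot's observed five-band mean plus pixel noise); the rest and
    all alleys are soil, with a ``weed_fraction`` share of background pixels
    replaced by weed patches.  The labelled pixel set samples
    ``labels_per_class`` true-class pixels per class.  Deterministic given
    (config.seed, year, stage).
    """
    config = config or result.config
    flight = result.observations.query("year == @year and stage == @stage")
    if flight.empty:
        raise ValueError(f"no simulated flight for year={year}, stage={stage!r}")
    truth = result.truth_flights.query("year == @year and stage == @stage"
                                       ).set_index("plot_id")
    plot_ids = list(flight["plot_id"])
    n_plots = len(plot_ids)
    n_cols_grid = 4
    n_rows_grid = int(np.ceil(n_plots / n_cols_grid))

    pitch = config.plot_px + config.gap_px
    width = 2 * config.margin_px + n_cols_grid * config.plot_px \
        + (n_cols_grid - 1) * config.gap_px
    height = 2 * config.margin_px + n_rows_grid * config.plot_px \
        + (n_rows_grid - 1) * config.gap_px

    stage_index = [s for s, _ in config.flights].index(stage)
    year_index = list(config.years).index(year)
    rng = np.random.default_rng([config.seed, year_index, stage_index, 7])

    data = np.empty((5, height, width))
    data[:] = SOIL_ENDMEMBER[:, None, None]
    class_map = np.full((height, width), "soil", dtype=object)

    polygons = []
    ps = config.pixel_size_m
    for k, row in enumerate(flight.itertuples()):
        gr, gc = divmod(k, n_cols_grid)
        r0 = config.margin_px + gr * pitch
        c0 = config.margin_px + gc * pitch
        n_px = config.plot_px ** 2
        cover = float(truth.loc[row.plot_id, "canopy"])
        if not 0.0 <= cover <= 1.0:
            raise ValueError(f"canopy fraction {cover} outside [0, 1]")
        n_corn = int(round(cover * n_px))
        order = rng.permutation(n_px)
        corn_flat = order[:n_corn]
        rr = r0 + corn_flat // config.plot_px
        cc = c0 + corn_flat % config.plot_px
        plot_bands = np.array([row.blue, row.green, row.red, row.rededge, row.nir])
        data[:, rr, cc] = plot_bands[:, None]
        class_map[rr, cc] = "corn"
        from shapely.geometry import box

        polygons.append(PlotPolygon(row.plot_id, box(
            c0 * ps, r0 * ps, (c0 + config.plot_px) * ps, (r0 + config.plot_px) * ps)))

    background = np.nonzero(class_map == "soil")
    n_weed = int(round(config.weed_fraction * height * width))
    pick = rng.choice(background[0].size, size=min(n_weed, background[0].size),
                      replace=False)
    wr, wc = background[0][pick], background[1][pick]
    data[:, wr, wc] = WEED_ENDMEMBER[:, None]
    class_map[wr, wc] = "weed"

    data += rng.normal(0.0, config.pixel_noise_sd, size=data.shape)
    np.clip(data, 0.0, 1.0, out=data)
    scene = Scene(data, pixel_size=ps, origin=(0.0, 0.0), is_reflectance=True)

    xs, ys, labels = [], [], []
    for cls in ("corn", "soil", "weed"):
        rows_cls, cols_cls = np.nonzero(class_map == cls)
        if rows_cls.size == 0:  # class absent (e.g. weed_fraction = 0)
            continue
        if rows_cls.size < config.labels_per_class:
            raise ValueError(
                f"scene has only {rows_cls.size} {cls!r} pixels, fewer than "
                f"labels_per_class={config.labels_per_class}")
        pick = rng.choice(rows_cls.size, size=config.labels_per_class, replace=False)
        xs.append((cols_cls[pick] + 0.5) * ps)
        ys.append((rows_cls[pick] + 0.5) * ps)
        labels.append(np.full(config.labels_per_class, cls, dtype=object))
    label_set = PixelLabelSet(np.concatenate(xs), np.concatenate(ys),
                              np.concatenate(labels),
                              min_per_class=min(5000, config.labels_per_class))
    return scene, label_set, polygons
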