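"""Vegetation-index formulas, band resolution and the per-flight panel."""

import math

import numpy as np
import pandas as pd
import pytest

from cornvi.bands import BandSet, BandValidationError, WavelengthError, resolve_band
from cornvi.vi_registry import (
    FlightMeta, FormulaSyntaxError, UnknownVIError, compile_formula, compute_panel,
    compute_vi, get_definition, panels_from_long_frame, panels_to_long_frame,
    register_from_config, registered_names,
)
from conftest import random_bandsets


def bands(**kwargs) -> BandSet:
    defaults = dict(blue=0.05, green=0.1, red=0.1, rededge=0.3, nir=0.45)
    defaults.update(kwargs)
    return BandSet(**defaults)


# Independent direct-arithmetic oracle: every registered formula coded by
# hand, bypassing the expression grammar the registry compiles through.
ORACLE = {
    "NDVI": lambda b, g, r, re, n: (n - r) / (n + r),
    "GNDVI": lambda b, g, r, re, n: (n - g) / (n + g),
    "reNDVI": lambda b, g, r, re, n: (n - re) / (n + re),
    "SR705": lambda b, g, r, re, n: n / re,
    "MTCI": lambda b, g, r, re, n: (n - re) / (re - r),
    "LCI": lambda b, g, r, re, n: (n - re) / (n + r),
    "RIrededge": lambda b, g, r, re, n: n / re - 1,
    "CIgreen": lambda b, g, r, re, n: n / g - 1,
    "RIgreen": lambda b, g, r, re, n: n / g - 1,
    "PBI": lambda b, g, r, re, n: n / g,
    "CVI": lambda b, g, r, re, n: n * r / g**2,
    "mND705": lambda b, g, r, re, n: (n - re) / (n + re - 2 * b),
    "mSR705": lambda b, g, r, re, n: (n - b) / (re - b),
    "DATT": lambda b, g, r, re, n: (n - re) / (n - r),
    "SAVI": lambda b, g, r, re, n: 1.5 * (n - r) / (n + r + 0.5),
    "OSAVI": lambda b, g, r, re, n: (n - r) / (n + r + 0.16),
    "MSAVI": lambda b, g, r, re, n: 0.5 * (2 * n + 1 - math.sqrt((2 * n + 1) ** 2 - 8 * (n - r))),
    "RDVI": lambda b, g, r, re, n: (n - r) / math.sqrt(n + r),
    "EVI": lambda b, g, r, re, n: 2.5 * (n - r) / (n + 6 * r - 7.5 * b + 1),
    "WDRVI": lambda b, g, r, re, n: (0.2 * n - r) / (0.2 * n + r),
    "VARI": lambda b, g, r, re, n: (g - r) / (g + r - b),
    "TGI": lambda b, g, r, re, n: -0.5 * ((668 - 475) * (r - g) - (668 - 560) * (r - b)),
    "TVI": lambda b, g, r, re, n: 0.5 * (120 * (n - g) - 200 * (r - g)),
    "MCARI": lambda b, g, r, re, n: ((re - r) - 0.2 * (re - g)) * (re / r),
    "MCARI2": lambda b, g, r, re, n: 1.5 * (2.5 * (n - r) - 1.3 * (n - g))
    / math.sqrt((2 * n + 1) ** 2 - (6 * n - 5 * math.sqrt(r)) - 0.5),
    "TCARI_OSAVI": lambda b, g, r, re, n: (3 * ((re - r) - 0.2 * (re - g) * (re / r)))
    / ((n - r) / (n + r + 0.16)),
    "ARI": lambda b, g, r, re, n: 1 / g - 1 / re,
    "mARI": lambda b, g, r, re, n: n * (1 / g - 1 / re),
    "CRIrededge": lambda b, g, r, re, n: 1 / b - 1 / re,
    "RVI": lambda b, g, r, re, n: n / r,
    "SR445": lambda b, g, r, re, n: n / b,
}


class TestBandSet:
    def test_rejects_out_of_range_and_nonfinite(self):
        with pytest.raises(BandValidationError):
            bands(nir=1.2)
        with pytest.raises(BandValidationError):
            bands(red=-0.01)
        with pytest.raises(BandValidationError):
            bands(blue=float("nan"))

    @pytest.mark.parametrize("wavelength, band", [
        (705, "rededge"), (445, "blue"), (750, "nir"), (560, "green"), (668, "red"),
    ])
    def test_resolve_band_table(self, wavelength, band):
        assert resolve_band(wavelength) == band

    def test_resolve_band_errors_name_the_wavelength(self):
        with pytest.raises(WavelengthError, match="outside sensor range"):
            resolve_band(1240)
        with pytest.raises(WavelengthError, match="600"):
            resolve_band(600)  # in range, not in the mapping table


class TestComputeVI:
    @pytest.mark.parametrize("name, bandset, expected", [
        ("NDVI", bands(nir=0.3, red=0.3), 0.0),
        ("NDVI", bands(nir=0.5, red=0.1), 0.4 / 0.6),
        ("MTCI", bands(nir=0.45, rededge=0.30, red=0.10), 0.75),
        ("LCI", bands(nir=0.45, rededge=0.30, red=0.10), 0.15 / 0.55),
        ("mND705", bands(nir=0.45, rededge=0.30, blue=0.05), 0.15 / 0.65),
    ])
    def test_hand_computed_values(self, name, bandset, expected):
        assert compute_vi(name, bandset) == pytest.approx(expected, abs=1e-12)

    def test_zero_denominator_is_missing_not_an_exception(self):
        assert math.isnan(compute_vi("MTCI", bands(rededge=0.2, red=0.2)))
        assert math.isnan(compute_vi("VARI", bands(green=0.1, red=0.1, blue=0.2)))

    def test_unregistered_name_lists_registry(self):
        with pytest.raises(UnknownVIError, match="NDVI"):
            compute_vi("NOPE", bands())

    def test_lookup_is_case_insensitive_and_slash_tolerant(self):
        b = bands()
        assert compute_vi("mtci", b) == compute_vi("MTCI", b)
        assert get_definition("TCARI/OSAVI").name == "TCARI_OSAVI"

    def test_every_formula_matches_direct_arithmetic_oracle(self):
        assert set(ORACLE) == set(registered_names())
        for bandset in random_bandsets(1000, seed=42):
            b, g, r, re, n = bandset.as_tuple()
            for name, oracle in ORACLE.items():
                expected = oracle(b, g, r, re, n)
                got = compute_vi(name, bandset)
                assert got == pytest.approx(expected, rel=1e-12, abs=1e-12), name

    @pytest.mark.parametrize("name", [
        "NDVI", "MTCI", "LCI", "SR705", "reNDVI", "DATT", "mSR705", "VARI"])
    @pytest.mark.parametrize("c", [0.5, 2.0])
    def test_scale_invariance_of_degree_zero_ratios(self, name, c):
        for original in random_bandsets(50, seed=3):
            bandset = BandSet(*(v / 2.1 for v in original.as_tuple()))
            scaled = BandSet(*(v * c for v in bandset.as_tuple()))
            assert compute_vi(name, scaled) == pytest.approx(
                compute_vi(name, bandset), rel=1e-9)

    @pytest.mark.parametrize("name", ["NDVI", "GNDVI", "reNDVI", "mND705"])
    def test_normalized_difference_indices_bounded(self, name):
        # mND705's bound requires the physical regime blue <= min(rededge, nir)
        # (vegetation and soil both absorb strongly in blue); the two-band
        # normalized differences are bounded unconditionally.
        for bandset in random_bandsets(300, seed=9):
            if name == "mND705" and bandset.blue > min(bandset.rededge, bandset.nir):
                continue
            value = compute_vi(name, bandset)
            if math.isfinite(value):
                assert -1.0 - 1e-12 <= value <= 1.0 + 1e-12


class TestRegistryExtension:
    def test_register_from_config_with_constants(self):
        (definition,) = register_from_config({
            "testNDRE2": {"formula": "(NIR - k * RE) / (NIR + k * RE)",
                          "constants": {"k": 1.0}, "overwrite": True}})
        value = definition.func(0.05, 0.1, 0.1, 0.3, 0.45)
        assert value == pytest.approx(0.15 / 0.75)
        assert definition.required_bands == {"rededge", "nir"}

    @pytest.mark.parametrize("formula", [
        "__import__('os')", "NIR.real", "lambda: 1", "exp(NIR)", "X + 1",
    ])
    def test_unsafe_or_unknown_formulas_rejected(self, formula):
        with pytest.raises(FormulaSyntaxError):
            compile_formula(formula)


class TestComputePanel:
    flight = FlightMeta("2020-07-01", 83, "R1")

    def test_cellwise_values_and_shape(self):
        plots = {"p1": bands(nir=0.3, red=0.3), "p2": bands(nir=0.5, red=0.1)}
        panel = compute_panel(plots, ["NDVI"], self.flight, 2020)
        assert panel.values.shape == (2, 1)
        assert panel.values.loc["p1", "NDVI"] == pytest.approx(0.0)
        assert panel.values.loc["p2", "NDVI"] == pytest.approx(0.4 / 0.6)

    def test_empty_inputs_error(self):
        with pytest.raises(ValueError):
            compute_panel({}, ["NDVI"], self.flight, 2020)
        with pytest.raises(ValueError):
            compute_panel({"p1": bands()}, [], self.flight, 2020)

    def test_per_cell_missingness(self):
        plots = {"p1": bands(rededge=0.2, red=0.2), "p2": None}
        panel = compute_panel(plots, ["MTCI", "NDVI"], self.flight, 2020)
        assert math.isnan(panel.values.loc["p1", "MTCI"])
        assert math.isfinite(panel.values.loc["p1", "NDVI"])
        assert panel.values.loc["p2"].isna().all()

    def test_permutation_equivariance_in_plot_order(self):
        plots = {f"p{i}": b for i, b in enumerate(random_bandsets(6, seed=5))}
        names = ["NDVI", "MTCI", "SAVI"]
        forward = compute_panel(plots, names, self.flight, 2020)
        reversed_panel = compute_panel(dict(reversed(list(plots.items()))),
                                       names, self.flight, 2020)
        pd.testing.assert_frame_equal(
            forward.values.sort_index(), reversed_panel.values.sort_index())

    def test_long_csv_round_trip(self, tmp_path):
        plots = {f"p{i}": b for i, b in enumerate(random_bandsets(4, seed=8))}
        panels = [compute_panel(plots, ["NDVI", "MTCI"], self.flight, 2020),
                  compute_panel(plots, ["NDVI", "MTCI"],
                                FlightMeta("2020-07-20", 102, "R3"), 2020)]
        long = panels_to_long_frame(panels)
        path = tmp_path / "panel.csv"
        long.to_csv(path, index=False)
        back = panels_from_long_frame(pd.read_csv(path))
        assert len(back) == 2
        for a, b in zip(panels, back):
            assert a.flight == b.flight
            pd.testing.assert_frame_equal(
                a.values.sort_index().sort_index(axis=1),
                b.values.sort_index().sort_index(axis=1), check_names=False)
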