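"""Correlation screen, stability selection and cross-year Venn partition."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from cornvi.bands import BandSet
from cornvi.screening import (
    VennPartition, correlation_heatmap_table, pearson, score_correlations,
    stable_set, summarize_year, venn_partition,
)
from cornvi.vi_registry import FlightMeta, VIMatrix


def brute_force_r(x, y):
    """Covariance / (sigma_x * sigma_y), coded from the definition."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    cov = np.mean((x - x.mean()) * (y - y.mean()))
    return cov / (x.std() * y.std())


def make_panel(values: dict, stage="R1", dap=83, year=2020) -> VIMatrix:
    frame = pd.DataFrame(values)
    frame.index = [f"p{i}" for i in range(len(frame))]
    frame.index.name = "plot_id"
    return VIMatrix(year, FlightMeta(f"{year}-07-01", dap, stage), frame)


def make_yields(values, year=2020) -> pd.DataFrame:
    return pd.DataFrame({
        "year": year, "plot_id": [f"p{i}" for i in range(len(values))],
        "treatment": "t", "block": 1, "yield_mg_ha": values,
    })


class TestPearson:
    @pytest.mark.parametrize("x, y, expected", [
        ((1, 2, 3), (2, 4, 6), 1.0),
        ((1, 2, 3), (6, 4, 2), -1.0),
        ((1, 2, 3), (1, 3, 2), 0.5),
    ])
    def test_hand_computed_r(self, x, y, expected):
        r, p, n = pearson(x, y)
        assert r == pytest.approx(expected, abs=1e-12)
        assert n == 3

    def test_too_few_pairs(self):
        with pytest.raises(ValueError, match="3"):
            pearson([1, 2], [3, 4])

    def test_zero_variance_warns_and_returns_missing(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            r, p, n = pearson([1, 2, 3, 4], [5, 5, 5, 5])
        assert math.isnan(r) and math.isnan(p) and n == 4

    def test_pairwise_missing_removal(self):
        x = [1, 2, np.nan, 4, 5]
        y = [2, 4, 6, np.nan, 10]
        r, p, n = pearson(x, y)
        assert n == 3 and r == pytest.approx(1.0)

    def test_matches_covariance_oracle_on_random_vectors(self):
        rng = np.random.default_rng(12)
        for _ in range(1000):
            n = rng.integers(3, 30)
            x, y = rng.normal(size=n), rng.normal(size=n)
            assert pearson(x, y)[0] == pytest.approx(brute_force_r(x, y), abs=1e-12)

    def test_affine_invariance_and_antisymmetry(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=20), rng.normal(size=20)
        r0 = pearson(x, y)[0]
        assert pearson(3.0 * x + 7.0, y)[0] == pytest.approx(r0, abs=1e-12)
        assert pearson(x, 0.5 * y - 2.0)[0] == pytest.approx(r0, abs=1e-12)
        assert pearson(-2.0 * x, y)[0] == pytest.approx(-r0, abs=1e-12)


class TestScoreCorrelations:
    def test_threshold_scoring_rule(self):
        rng = np.random.default_rng(0)
        y = np.linspace(5, 12, 16)
        strong_pos = y + rng.normal(0, 0.4, 16)          # r well above 0.7
        strong_neg = -y + rng.normal(0, 0.4, 16)
        weak = rng.normal(0, 1, 16)
        panel = make_panel({"POS": strong_pos, "NEG": strong_neg, "WEAK": weak})
        records = score_correlations(panel, make_yields(y)).set_index("vi_name")
        for vi in ("POS", "NEG", "WEAK"):
            expected = int(abs(records.loc[vi, "r"]) >= 0.7)
            assert records.loc[vi, "score"] == expected
        assert records.loc["POS", "score"] == 1
        assert records.loc["NEG", "score"] == 1  # absolute-value rule
        assert records.loc["WEAK", "score"] == 0

    def test_no_shared_plots_errors(self):
        panel = make_panel({"NDVI": [0.1, 0.2, 0.3]})
        yields = make_yields([5, 6, 7], year=2020)
        yields["plot_id"] = ["q0", "q1", "q2"]
        with pytest.raises(ValueError, match="shared"):
            score_correlations(panel, yields)

    def test_constant_yield_degrades_to_missing_scores(self):
        panel = make_panel({"NDVI": [0.1, 0.2, 0.3, 0.4]})
        records = score_correlations(panel, make_yields([5.0] * 4))
        assert math.isnan(records["r"].iloc[0])
        assert records["score"].iloc[0] == 0


def records_from_scores(score_map: dict, year=2020) -> pd.DataFrame:
    """Build per-flight records with given 0/1 scores for each VI."""
    rows = []
    for vi, scores in score_map.items():
        for k, s in enumerate(scores):
            rows.append({"vi_name": vi, "year": year, "date": f"d{k}", "dap": 30 + k,
                         "stage": f"S{k}", "r": 0.9 if s else 0.1, "p": 0.01,
                         "n_pairs": 16, "score": s})
    return pd.DataFrame(rows)


class TestSummarizeYear:
    def test_cumulative_and_stable(self):
        summary = summarize_year(records_from_scores({
            "A": [1, 0, 1, 1], "B": [1, 0, 0, 0], "C": [0, 0, 0, 0]}))
        summary = summary.set_index("vi_name")
        assert summary.loc["A", "cumulative_score"] == 3 and summary.loc["A", "stable"]
        assert summary.loc["B", "cumulative_score"] == 1 and not summary.loc["B", "stable"]
        assert not summary.loc["C", "stable"]

    def test_tier_ties_share_rank_alphabetically(self):
        summary = summarize_year(records_from_scores({
            "Z": [1, 1, 1, 1], "A": [1, 1, 1, 1], "M": [1, 1, 1, 0]}))
        assert list(summary["vi_name"][:3]) == ["A", "Z", "M"]
        assert list(summary["tier"][:3]) == [1, 1, 2]

    def test_single_flight_errors(self):
        single = records_from_scores({"A": [1]})
        with pytest.raises(ValueError, match="2 flights"):
            summarize_year(single)

    def test_threshold_and_min_count_monotonicity(self):
        rng = np.random.default_rng(7)
        y = np.linspace(5, 12, 16)
        panels = [make_panel({"A": y + rng.normal(0, s, 16),
                              "B": rng.normal(size=16)}, stage=f"S{k}", dap=40 + k)
                  for k, s in enumerate([0.5, 1.5, 3.0, 6.0])]
        yields = make_yields(y)
        low = score_correlations(panels, yields, threshold=0.6)
        high = score_correlations(panels, yields, threshold=0.8)
        for vi in ("A", "B"):
            assert (high[high.vi_name == vi]["score"].sum()
                    <= low[low.vi_name == vi]["score"].sum())
        summary = score_correlations(panels, yields)
        assert stable_set(summarize_year(summary, min_count=3)) <= \
            stable_set(summarize_year(summary, min_count=2))


class TestVennPartition:
    def test_identical_singletons(self):
        part = venn_partition({2020: {"x"}, 2021: {"x"}, 2022: {"x"}})
        assert part.region(2020, 2021, 2022) == ("x",)
        assert part.union == ("x",)
        assert all(not members for key, members in part.regions.items()
                   if len(key) < 3)

    def test_three_set_example_against_brute_force(self):
        sets = {"A": {"a", "b"}, "B": {"b", "c"}, "C": {"c", "a"}}
        part = venn_partition(sets)
        assert part.region("A", "B") == ("b",)
        assert part.region("B", "C") == ("c",)
        assert part.region("A", "C") == ("a",)
        assert part.region("A", "B", "C") == ()
        assert part.union == ("a", "b", "c")
        # brute force: every element lands in exactly the region of its members
        for element in part.union:
            membership = frozenset(y for y, s in sets.items() if element in s)
            assert element in part.regions[membership]

    def test_regions_disjoint_and_reconstruct_inputs(self):
        rng = np.random.default_rng(3)
        universe = [f"vi{i}" for i in range(20)]
        for _ in range(50):
            sets = {year: {vi for vi in universe if rng.random() < 0.4}
                    for year in (2020, 2021, 2022)}
            if any(not s for s in sets.values()):
                continue
            part = venn_partition(sets)
            all_members = list(itertools.chain.from_iterable(part.regions.values()))
            assert len(all_members) == len(set(all_members)) == len(part.union)
            for year, original in sets.items():
                rebuilt = {vi for key, members in part.regions.items()
                           if year in key for vi in members}
                assert rebuilt == set(original)

    def test_wrong_set_count_rejected(self):
        with pytest.raises(ValueError):
            venn_partition({2020: {"a"}, 2021: {"b"}})


def test_heatmap_table_blanks_subthreshold_cells():
    records = records_from_scores({"A": [1, 0], "B": [0, 1]})
    table = correlation_heatmap_table(records)
    assert table.loc["A"].notna().tolist() == [True, False]
    assert table.loc["B"].notna().tolist() == [False, True]
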