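"""Correlation-threshold stability selection of vegetation indices.

The screen works in three steps, applied per growing season:

1. For every flight, the Pearson correlation between each VI and plot yield
   is computed across subplots (pairwise-complete; n = number of plots with
   both values).  A flight-level score of 1 is assigned whenever
   |r| >= threshold (default 0.7, the conventional "strong correlation"
   cut-off); otherwise 0.
2. Scores are accumulated over the season's flights.  A VI is *stable* when
   its cumulative score reaches ``min_count`` (default 2: strong on at
   least two dates of the same season).  Tiers rank VIs by descending
   cumulative score; ties share a tier and are listed alphabetically.
3. The three seasonal stable sets are intersected into the 7-region Venn
   partition; indices common to all three seasons are the season-robust
   predictors carried into yield modelling.

p-values accompany every r (t transform, n-2 df, two-sided) but play no
part in selection — the screen is defined purely by the |r| threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .vi_registry import VIMatrix

__all__ = [
    "validate_yield_table",
    "pearson",
    "score_correlations",
    "summarize_year",
    "venn_partition",
    "VennPartition",
    "correlation_heatmap_table",
]


def validate_yield_table(yields: pd.DataFrame) -> pd.DataFrame:
    """Check the per-plot yield table: columns, positivity, one row per plot-year."""
    required = {"year", "plot_id", "treatment", "block", "yield_mg_ha"}
    missing = required - set(yields.columns)
    if missing:
        raise ValueError(f"yield table missing columns: {sorted(missing)}")
    if (yields["yield_mg_ha"] <= 0).any():
        raise ValueError("yields must be positive (Mg/ha at 15.5% moisture)")
    if yields.duplicated(["year", "plot_id"]).any():
        raise ValueError("duplicate (year, plot_id) rows in yield table")
    return yields


def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, int]:
    """Pairwise-complete Pearson correlation with a two-sided p-value.

    Returns (r, p, n) where n counts the complete pairs.  Degenerate
    zero-variance input yields (nan, nan, n) with a warning rather than an
    error, so a constant-yield season degrades to missing instead of
    aborting the screen.  Fewer than 3 complete pairs is an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = int(x.size)
    if n < 3:
        raise ValueError(f"need at least 3 complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("zero-variance input: correlation undefined, returning missing",
                      stacklevel=2)
        return (float("nan"), float("nan"), n)
    result = stats.pearsonr(x, y)
    return (float(result.statistic), float(result.pvalue), n)


def score_correlations(panels: Iterable[VIMatrix] | VIMatrix, yields: pd.DataFrame,
                       threshold: float = 0.7) -> pd.DataFrame:
    """Per-VI, per-flight correlation records with the 0/1 threshold score.

    Returns one row per (year, flight, VI): columns vi_name, year, date,
    dap, stage, r, p, n_pairs, score.  score = 1 iff |r| >= threshold
    (missing r scores 0).  Raises if a flight shares fewer than 3 plots
    with the yield table.
    """
    if isinstance(panels, VIMatrix):
        panels = [panels]
    validate_yield_table(yields)
    records = []
    for panel in panels:
        year_yields = yields.loc[yields["year"] == panel.year].set_index("plot_id")
        shared = panel.values.index.intersection(year_yields.index)
        if len(shared) < 3:
            raise ValueError(
                f"year {panel.year} flight {panel.flight.stage}: only {len(shared)} "
                "plots shared between VI panel and yield table (need >= 3)")
        y = year_yields.loc[shared, "yield_mg_ha"].to_numpy(dtype=float)
        for vi_name in panel.vi_names:
            x = panel.values.loc[shared, vi_name].to_numpy(dtype=float)
            if np.isfinite(x).sum() < 3:
                r, p, n = float("nan"), float("nan"), int(np.isfinite(x).sum())
            else:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    r, p, n = pearson(x, y)
            score = int(np.isfinite(r) and abs(r) >= threshold)
            records.append({
                "vi_name": vi_name, "year": panel.year, "date": panel.flight.date,
                "dap": panel.flight.dap, "stage": panel.flight.stage,
                "r": r, "p": p, "n_pairs": n, "score": score,
            })
    return pd.DataFrame.from_records(records)


def summarize_year(records: pd.DataFrame, min_count: int = 2, top_k: int = 3
                   ) -> pd.DataFrame:
    """Season summary: cumulative score, stability flag and tier per VI.

    cumulative_score sums the flight scores; stable <=> cumulative_score >=
    min_count; tier is the dense rank of distinct cumulative scores among
    VIs that scored at least once (tier 1 = maximum), reported for the top_k
    tiers and NA beyond.  VIs tied on cumulative score share a tier and sort
    alphabetically.  Requires records from at least two flights (the
    cumulative criterion is undefined on a single date).
    """
    if records["year"].nunique() != 1:
        raise ValueError("summarize_year expects records from a single year")
    if records[["date", "dap", "stage"]].drop_duplicates().shape[0] < 2:
        raise ValueError("cumulative scoring needs records from >= 2 flights")
    summary = (records.groupby("vi_name", sort=True)["score"].sum()
               .rename("cumulative_score").reset_index())
    summary["year"] = records["year"].iloc[0]
    summary["stable"] = summary["cumulative_score"] >= min_count
    scored = sorted(summary.loc[summary["cumulative_score"] > 0,
                                "cumulative_score"].unique(), reverse=True)
    tier_of = {score: rank + 1 for rank, score in enumerate(scored[:top_k])}
    summary["tier"] = summary["cumulative_score"].map(tier_of).astype("Int64")
    summary = summary.sort_values(
        ["cumulative_score", "vi_name"], ascending=[False, True]
    ).reset_index(drop=True)
    return summary[["vi_name", "year", "cumulative_score", "stable", "tier"]]


def stable_set(summary: pd.DataFrame) -> set[str]:
    return set(summary.loc[summary["stable"], "vi_name"])


@dataclass(frozen=True)
class VennPartition:
    """The 7 disjoint regions of three seasonal stable sets.

    ``regions`` maps a frozenset of year labels (the years a VI is stable
    in, among the three) to the sorted list of VI names exactly in that
    combination.  ``union`` is every VI stable in at least one year.
    """

    years: tuple
    regions: Mapping[frozenset, tuple[str, ...]]
    union: tuple[str, ...]

    def region(self, *years) -> tuple[str, ...]:
        return self.regions[frozenset(years)]

    def counts(self) -> dict[str, int]:
        named = {}
        for key, members in self.regions.items():
            label = "&".join(str(y) for y in sorted(key))
            named[label] = len(members)
        named["union"] = len(self.union)
        return named

    def in_at_least(self, k: int) -> tuple[str, ...]:
        """VIs stable in at least k of the three years."""
        members = [vi for key, vis in self.regions.items() if len(key) >= k
                   for vi in vis]
        return tuple(sorted(members))


def venn_partition(stable_sets: Mapping[object, Iterable[str]]) -> VennPartition:
    """Partition exactly three seasonal stable sets into 7 disjoint Venn regions."""
    if len(stable_sets) != 3:
        raise ValueError(f"venn_partition expects exactly 3 year-sets, got {len(stable_sets)}")
    sets = {year: frozenset(vis) for year, vis in stable_sets.items()}
    years = tuple(sorted(sets))
    union = frozenset().union(*sets.values())
    regions: dict[frozenset, tuple[str, ...]] = {}
    for k in (1, 2, 3):
        for combo in combinations(years, k):
            inside = frozenset(combo)
            members = union
            for year in combo:
                members = members & sets[year]
            for year in set(years) - inside:
                members = members - sets[year]
            regions[inside] = tuple(sorted(members))
    return VennPartition(years=years, regions=regions, union=tuple(sorted(union)))


def correlation_heatmap_table(records: pd.DataFrame, threshold: float = 0.7
                              ) -> pd.DataFrame:
    """Rows = VIs, columns = flights (stage at DAP), cells = r where |r| >= threshold.

    Mirrors the season correlation heat map: sub-threshold correlations are
    blanked (NaN) so only the scored cells remain visible.
    """
    table = records.copy()
    table["flight"] = table["stage"] + " (" + table["dap"].astype(str) + " DAP)"
    wide = table.pivot_table(index="vi_name", columns="flight", values="r",
                             sort=False)
    order = (table.drop_duplicates("flight").sort_values("dap")["flight"].tolist())
    wide = wide[order]
    return wide.where(wide.abs() >= threshold)
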