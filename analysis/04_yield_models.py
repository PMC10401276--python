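#!/usr/bin/env python
"""Per-stage simple linear yield models for the season-robust VIs.

Fits yield = b0 + b1 * VI per (year, stage) for the five cross-year stable
chlorophyll indices, reports R^2 / MAPE / significance, marks the per-stage
winner, tallies season win counts, and compares treatments on the R1-stage
VI values with LSD letters.
"""

import argparse
from pathlib import Path

import pandas as pd

from cornvi.screening import stable_set, summarize_year, score_correlations, venn_partition
from cornvi.synthetic import panels_from_observations
from cornvi.vi_registry import registered_names
from cornvi.yield_model import fit_simple_lm, lsd_letters, select_best

RESULTS = Path(__file__).resolve().parents[1] / "results"


def core_vis(observations, yields) -> tuple[str, ...]:
    panels = panels_from_observations(observations, registered_names())
    records = score_correlations(panels, yields)
    sets = {int(y): stable_set(summarize_year(records[records["year"] == y]))
            for y in sorted(records["year"].unique())}
    part = venn_partition(sets)
    return part.region(*part.years)


def main(alpha: float) -> None:
    observations = pd.read_csv(RESULTS / "observations.csv")
    yields = pd.read_csv(RESULTS / "yields.csv")
    core = core_vis(observations, yields)
    print(f"Season-robust VIs (stable in all three years): {', '.join(core)}\n")

    panels = panels_from_observations(observations, core)
    fits = []
    for panel in panels:
        year_yields = yields[yields["year"] == panel.year].set_index("plot_id")
        shared = panel.values.index.intersection(year_yields.index)
        for vi in panel.vi_names:
            fits.append(fit_simple_lm(
                panel.values.loc[shared, vi],
                year_yields.loc[shared, "yield_mg_ha"],
                vi_name=vi, year=panel.year, stage=panel.flight.stage))

    winners, win_counts = select_best(fits, per="stage")
    winner_keys = set(zip(winners["year"], winners["stage"], winners["vi_name"]))
    table = pd.DataFrame([{
        "year": f.year, "stage": f.stage, "vi_name": f.vi_name,
        "R2": round(f.r_squared, 2), "stars": f.stars,
        "MAPE": round(f.mape_pct, 2),
        "best": (f.year, f.stage, f.vi_name) in winner_keys,
    } for f in fits])
    table.to_csv(RESULTS / "stage_vi_models.csv", index=False)

    for year, group in winners.groupby("year"):
        print(f"{year} per-stage winners:")
        for row in group.itertuples():
            print(f"  {row.stage:<3} {row.vi_name:<10} R2={row.r_squared:.2f}"
                  f"{row.stars} MAPE={row.mape_pct:.2f}%")
    print("\nSeason win counts:", win_counts.to_dict())

    # treatment separation on the R1-stage VI values
    letter_rows = []
    for panel in (p for p in panels if p.flight.stage == "R1"):
        meta = yields[yields["year"] == panel.year].set_index("plot_id")
        for vi in panel.vi_names:
            frame = meta.join(panel.values[vi].rename("value")).reset_index()
            grouping = lsd_letters(frame, alpha=alpha, response="value")
            letter_rows.append(grouping.means.assign(
                year=panel.year, vi_name=vi, lsd=grouping.lsd))
    pd.concat(letter_rows).to_csv(RESULTS / "r1_vi_lsd_letters.csv", index=False)
    print(f"\nTables written to {RESULTS}/")


if __name__ == "__main__":
    parser = argparse.ArgumentParser()
    parser.add_argument("--alpha", type=float, default=0.05)
    main(parser.parse_args().alpha)
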