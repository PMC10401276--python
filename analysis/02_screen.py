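#!/usr/bin/env python
"""Correlation-threshold stability screen over the full 31-index library.

Reads the simulated observations from results/ (run 01_simulate.py first),
computes the per-flight VI panels, scores every VI against yield per flight
(|r| >= 0.7), accumulates per-season stability, and partitions the three
seasonal stable sets into the cross-year Venn regions.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from cornvi.screening import (
    correlation_heatmap_table, score_correlations, stable_set, summarize_year,
    venn_partition,
)
from cornvi.synthetic import panels_from_observations
from cornvi.vi_registry import panels_to_long_frame, registered_names

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main(threshold: float) -> None:
    observations = pd.read_csv(RESULTS / "observations.csv")
    yields = pd.read_csv(RESULTS / "yields.csv")
    names = registered_names()
    panels = panels_from_observations(observations, names)
    panels_to_long_frame(panels).to_csv(RESULTS / "vi_panels.csv", index=False)

    records = score_correlations(panels, yields, threshold=threshold)
    records.to_csv(RESULTS / "correlations.csv", index=False)

    stable_sets, summaries = {}, []
    for year in sorted(records["year"].unique()):
        year_records = records[records["year"] == year]
        correlation_heatmap_table(year_records, threshold).to_csv(
            RESULTS / f"heatmap_{year}.csv")
        summary = summarize_year(year_records)
        summaries.append(summary)
        stable_sets[int(year)] = stable_set(summary)
        print(f"{year}: {len(stable_sets[int(year)])} stable VIs "
              f"(|r| >= {threshold} on >= 2 flights): "
              f"{', '.join(sorted(stable_sets[int(year)]))}")
    pd.concat(summaries).to_csv(RESULTS / "stability.csv", index=False)

    part = venn_partition(stable_sets)
    regions = {"&".join(map(str, sorted(k))): list(v)
               for k, v in part.regions.items()}
    (RESULTS / "venn_regions.json").write_text(
        json.dumps({"regions": regions, "union": list(part.union),
                    "counts": part.counts()}, indent=2))
    print(f"\nUnion of stable VIs: {len(part.union)}; "
          f"in >= 2 seasons: {len(part.in_at_least(2))}; "
          f"in all three seasons: {part.region(*part.years)}")


if __name__ == "__main__":
    parser = argparse.ArgumentParser()
    parser.add_argument("--threshold", type=float, default=0.7)
    main(parser.parse_args().threshold)
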