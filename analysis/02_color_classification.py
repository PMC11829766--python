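#!/usr/bin/env python
"""Color-identity analysis of the time-lapse cohort.

Normalizes measured RGB onto the ternary simplex, assigns each cell one of
the 25 color-identity regions, classes regions as frequent (>10%) / rare
(<2.5%) / intermediate, and exports ternary-plot coordinates.  Reports how
many regions are occupied and how the frequency classes split.

Reads results/simulated/timelapse/, writes results/colors/.
"""

from pathlib import Path

import pandas as pd

from clonebow import PipelineConfig, io
from clonebow.colors import ternary_xy
from clonebow.pipelines import classify_color_table

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cells = io.read_cell_table(BASE / "simulated" / "timelapse" / "cells.tsv")
    cfg = PipelineConfig()
    t0 = cells[cells["time_hpf"] == cells["time_hpf"].min()]
    classified, report = classify_color_table(t0, cfg)

    out = BASE / "colors"
    out.mkdir(parents=True, exist_ok=True)
    report.to_csv(out / "region_frequencies.tsv", sep="\t", index=False)

    rgb = classified[["r_mean", "g_mean", "b_mean"]].to_numpy(float)
    frac = rgb / rgb.sum(axis=1, keepdims=True)
    xy = ternary_xy(frac)
    pd.DataFrame({
        "cell_id": classified["cell_id"],
        "region_index": classified["region_index"],
        "ternary_x": xy[:, 0], "ternary_y": xy[:, 1],
    }).to_csv(out / "ternary_coordinates.tsv", sep="\t", index=False)

    occupied = report[report["count"] > 0]
    by_class = occupied["frequency_class"].value_counts().to_dict()
    print(f"classified {len(classified)} cells at t0 "
          f"({len(t0) - len(classified)} unrecombined/dim excluded)")
    print(f"occupied regions: {len(occupied)} of 25; classes: {by_class}")


if __name__ == "__main__":
    main()
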