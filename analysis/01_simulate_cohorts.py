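#!/usr/bin/env python
"""Generate the two synthetic cohorts the downstream analyses consume.

Cohort A emulates the time-lapse design: 44 multicolor boundary clones
imaged hourly from 32 to 45 hpf.  Cohort B emulates the two-timepoint
functional design: clones imaged at 36 and 48 hpf, where tdTomato-positive
(red) clones carry a manipulation that shifts divisions toward the
neurogenic mode and non-red clones are internal controls.

Writes cell tables, track tables and ground-truth sidecars under
results/simulated/.
"""

from pathlib import Path

from clonebow import SimulationConfig, io, simulate_dataset

OUT = Path(__file__).resolve().parent.parent / "results" / "simulated"
SEED = 20260925


def write_cohort(name: str, cfg: SimulationConfig, at_times=None) -> None:
    cells, tracks, gt, _ = simulate_dataset(cfg, at_times=at_times)
    d = OUT / name
    d.mkdir(parents=True, exist_ok=True)
    io.write_cell_table(cells, d / "cells.tsv")
    io.write_track_table(tracks, d / "tracks.tsv")
    gt.cells.to_csv(d / "truth_cells.tsv", sep="\t", index=False)
    gt.divisions.to_csv(d / "truth_divisions.tsv", sep="\t", index=False)
    gt.sister_delays.to_csv(d / "truth_sister_delays.tsv", sep="\t",
                            index=False)
    io.write_run_log(d / "runlog.json", cfg, cfg.seed,
                     ["cells.tsv", "tracks.tsv"])
    print(f"{name}: {cfg.n_founders} clones, {len(cells)} cell rows -> {d}")


def main() -> None:
    timelapse = SimulationConfig(seed=SEED, n_founders=44)
    write_cohort("timelapse", timelapse)

    functional = SimulationConfig(
        seed=SEED + 1, n_founders=60, t_start=32.0, t_end=48.0,
        red_manipulated_fraction=1.0,
        manipulated_mode_probs=(0.25, 0.25, 0.50),
    )
    write_cohort("functional", functional, at_times=[36.0, 48.0])


if __name__ == "__main__":
    main()
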