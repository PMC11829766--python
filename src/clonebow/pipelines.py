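"""End-to-end workflows.

Two analysis modes mirror the two experimental designs the package
supports:

* **time-lapse clonal tracking** — clones are called by color + contact at
  the first frame (t0), filtered for traceability, and followed through
  the track topology to yield proliferative capacity, division-mode
  shares and time-course, sister statistics and clonal growth;
* **two-timepoint functional comparison** — tracked clones imaged at two
  timepoints are classed red / non-red by mean red fraction, their
  composition yields endpoint division-mode counts, and red vs non-red
  groups are compared per quantity.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import clones as clone_calling
from . import colors, io, lineage_stats
from . import stats as grouping
from .config import PipelineConfig
from .lineage import NEURON, NN, PN, PP, PROGENITOR, LineageTree

logger = logging.getLogger(__name__)


def classify_color_table(
    cells: pd.DataFrame, cfg: PipelineConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Region assignment per classifiable cell plus a region-frequency
    report (count, fraction, frequency class per region)."""
    total = cells["r_mean"] + cells["g_mean"] + cells["b_mean"]
    ok = total >= cfg.min_total_intensity
    classified = cells[ok].copy()
    if classified.empty:
        raise colors.UnclassifiableColorError("no classifiable cells in table")
    classified["region_index"] = colors.assign_color_identities(
        classified[["r_mean", "g_mean", "b_mean"]].to_numpy()
    )
    report = colors.region_frequency_table(
        classified["region_index"], cfg.thresholds
    )
    return classified, report


def _attach_clone_ids(
    trees: Sequence[LineageTree], members: pd.DataFrame
) -> dict[str, str]:
    """Map each tree to the called clone containing (the majority of) its
    t0 cells."""
    cell_to_clone = dict(zip(members["cell_id"], members["clone_id"]))
    out = {}
    for tree in trees:
        votes: dict[str, int] = {}
        for node in tree.iter_nodes():
            c = cell_to_clone.get(node.cell_id)
            if c is not None:
                votes[c] = votes.get(c, 0) + 1
        if votes:
            out[tree.root] = max(sorted(votes), key=lambda k: votes[k])
    return out


def timelapse_workflow(
    cells: pd.DataFrame,
    tracks: pd.DataFrame,
    cfg: Optional[PipelineConfig] = None,
    traceability_filter: bool = True,
) -> dict:
    """Full time-lapse clonal analysis from a cell table + track table."""
    cfg = cfg or PipelineConfig()
    t0 = float(cells["time_hpf"].min())
    tf = float(cells["time_hpf"].max())
    window = (t0, tf)

    cells_t0 = cells[cells["time_hpf"] == t0]
    classified_t0, freq_report = classify_color_table(cells_t0, cfg)
    freq_classes = dict(
        zip(freq_report["region_index"], freq_report["frequency_class"])
    )

    members, called = clone_calling.call_clones_all(cells_t0, cfg)
    if traceability_filter:
        kept = []
        for boundary, group in called.groupby("boundary_id"):
            m = members[members["clone_id"].isin(group["clone_id"])]
            kept.append(
                clone_calling.filter_traceable(
                    group.reset_index(drop=True), m, freq_classes, cfg
                )
            )
        followed = pd.concat(kept, ignore_index=True) if kept else called
    else:
        followed = called

    trees = io.trees_from_track_table(tracks)
    tree_clone = _attach_clone_ids(trees, members)
    followed_ids = set(followed["clone_id"])
    followed_trees = [
        t for t in trees if tree_clone.get(t.root) in followed_ids
    ]
    for t in followed_trees:
        t.clone_id = tree_clone[t.root]

    divisions = lineage_stats.classify_divisions(
        followed_trees, cells, cfg, window=window
    )
    assigned = divisions[divisions["mode"].isin([PP, PN, NN])]
    mode_counts = assigned["mode"].value_counts().to_dict()
    shares = (
        lineage_stats.division_mode_shares(mode_counts)
        if len(assigned) else {PP: np.nan, PN: np.nan, NN: np.nan}
    )
    capacity = lineage_stats.proliferative_capacity(followed_trees, window)
    # endpoint fates from the observed table (reconstructed tracks carry no
    # fate information)
    followed_cell_ids = {
        n.cell_id for t in followed_trees for n in t.iter_nodes()
    }
    cells_tf = cells[
        (cells["time_hpf"] == tf) & cells["cell_id"].isin(followed_cell_ids)
    ]
    fated_tf = lineage_stats.fate_table(cells_tf, cfg)
    n_p = int((fated_tf["fate"] == "P").sum())
    n_n = int((fated_tf["fate"] == "N").sum())
    if n_p + n_n:
        capacity["n_cells_tf"] = n_p + n_n
        capacity["pct_P_tf"] = 100.0 * n_p / (n_p + n_n)
        capacity["pct_N_tf"] = 100.0 * n_n / (n_p + n_n)
    timecourse = (
        lineage_stats.mode_timecourse(assigned)
        if len(assigned) else {"sparse": True}
    )
    growth = lineage_stats.clone_growth(followed_trees, [t0, tf])
    growth_sum = lineage_stats.growth_summary(growth, [t0, tf])

    mode_by_mother = dict(zip(divisions["mother"], divisions["mode"]))
    sister_rows = []
    for tree in followed_trees:
        if len(tree.cells_alive_at(t0)) == 2:
            sister_rows.append(
                lineage_stats.sister_analysis(
                    tree, t0, tf, cfg.frame_interval, modes=mode_by_mother
                )
            )
    sisters = pd.DataFrame(sister_rows)
    delays = lineage_stats.sister_delays_from_trees(followed_trees, window)

    return {
        "window": window,
        "frequency_report": freq_report,
        "members_t0": members,
        "clones_t0": called,
        "followed_clones": followed,
        "trees": followed_trees,
        "divisions": divisions,
        "mode_counts": mode_counts,
        "mode_shares": shares,
        "capacity": capacity,
        "timecourse": timecourse,
        "growth": growth,
        "growth_summary": growth_sum,
        "sisters": sisters,
        "sister_delays": delays,
    }


def clone_partition_agreement(
    members: pd.DataFrame, truth_cells: pd.DataFrame
) -> float:
    """Adjusted Rand agreement between a called clone partition and the
    ground-truth clone labels, over cells present in both."""
    called = members.dropna(subset=["clone_id"])[["cell_id", "clone_id"]]
    merged = called.merge(
        truth_cells[["cell_id", "clone_id"]].rename(
            columns={"clone_id": "true_clone"}
        ),
        on="cell_id",
    )
    return grouping.adjusted_rand_index(
        merged["clone_id"], merged["true_clone"]
    )


def functional_workflow(
    cells: pd.DataFrame,
    tracks: pd.DataFrame,
    cfg: Optional[PipelineConfig] = None,
    times: tuple[float, float] = (36.0, 48.0),
) -> dict:
    """Two-timepoint red vs non-red clonal comparison.

    Clone membership follows the track topology (cells are annotated and
    linked by the tracking step); color classes each clone red / non-red /
    excluded by its mean red fraction over both timepoints.  Per clone
    and timepoint: progenitor / neuron composition and endpoint
    division-mode counts; red vs non-red groups are then compared with
    the normality-gated two-group test.
    """
    cfg = cfg or PipelineConfig()
    t1, t2 = times
    trees = io.trees_from_track_table(tracks)
    clone_rows = []
    per_clone_comp = []
    for tree in trees:
        ids = [n.cell_id for n in tree.iter_nodes()]
        rows = cells[cells["cell_id"].isin(ids)]
        rows_t1 = rows[rows["time_hpf"] == t1]
        rows_t2 = rows[rows["time_hpf"] == t2]
        if rows_t1.empty and rows_t2.empty:
            continue
        rgb = rows[["r_mean", "g_mean", "b_mean"]].to_numpy(float)
        try:
            condition = colors.classify_red_condition(rgb, cfg.thresholds)
        except colors.UnclassifiableColorError:
            continue
        if condition == colors.EXCLUDED:
            logger.info("clone %s excluded: intermediate red fraction",
                        tree.root)
            continue
        founders = max(len(tree.cells_alive_at(min(n.birth for n in
                                                   tree.iter_nodes()))), 1)
        rec = {"clone_id": tree.root, "condition": condition}
        for label, sub in (("t1", rows_t1), ("t2", rows_t2)):
            if sub.empty:
                continue
            comp = lineage_stats.infer_division_modes_endpoint(
                sub, cfg, founders=founders
            )
            total_fated = comp["P"] + comp["N"]
            rec[f"n_cells_{label}"] = len(sub)
            rec[f"pct_P_{label}"] = 100.0 * comp["P"] / total_fated
            rec[f"pct_N_{label}"] = 100.0 * comp["N"] / total_fated
            for m in (PP, PN, NN):
                rec[f"{m}_{label}"] = comp[m]
                rec[f"pct_{m}_{label}"] = comp[f"pct_{m}"]
        clone_rows.append(rec)
    per_clone = pd.DataFrame(clone_rows)
    if per_clone.empty:
        raise ValueError("no classifiable clones")

    comparisons = {}
    red = per_clone[per_clone["condition"] == colors.RED]
    ctrl = per_clone[per_clone["condition"] == colors.NONRED]
    for metric in ("pct_N_t2", "pct_P_t2", "pct_PP_t2", "pct_PN_t2",
                   "pct_NN_t2", "n_cells_t1", "n_cells_t2"):
        if metric not in per_clone.columns:
            continue
        a = ctrl[metric].dropna()
        b = red[metric].dropna()
        if len(a) and len(b):
            comparisons[metric] = grouping.compare_two_groups(
                a, b, labels=("nonred", "red")
            )
    return {
        "per_clone": per_clone,
        "n_red": int(len(red)),
        "n_nonred": int(len(ctrl)),
        "comparisons": comparisons,
    }
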