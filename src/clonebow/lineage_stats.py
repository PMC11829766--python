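"""Lineage-level statistics.

Implements the quantitative read-outs of a tracked clonal cohort: cell
fate calls (progenitor vs neuron by position and apical contact),
division-mode classification from daughter geometry and fate (PP / PN /
NN, with a censoring rule for daughters tracked less than a set number of
hours after division), endpoint composition-based mode inference for
two-timepoint experiments, proliferative capacity, sister-cell
concordance and synchrony, clonal growth, and the division-mode
time-course with its regression slope.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import PipelineConfig
from .lineage import NEURON, NN, PN, PP, PROGENITOR, UNASSIGNED, LineageTree

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FateCall:
    fate: str  # P | N | unassigned
    basis: str  # position | apical_contact | both


def assign_fate(
    dv_um: float,
    apical_contact: Optional[bool],
    cfg: PipelineConfig,
) -> FateCall:
    """Call progenitor / neuron from dorsoventral position and apical
    contact.

    A progenitor has a ventricular-proximal nucleus *and* an apical
    contact; a neuron has a mantle-proximal nucleus and no contact.
    Conflicting evidence (e.g. ventricular position without contact) gives
    ``unassigned``.  Without a contact flag the call is position-only.
    """
    line = cfg.vz_boundary_um
    eps = 1e-9
    if dv_um < line - eps:
        side = "vz"
    elif dv_um > line + eps:
        side = "mz"
    else:
        side = "on_line"
    if apical_contact is None or (isinstance(apical_contact, float)
                                  and math.isnan(apical_contact)):
        if side == "vz":
            return FateCall(PROGENITOR, "position")
        if side == "mz":
            return FateCall(NEURON, "position")
        return FateCall(UNASSIGNED, "position")
    apical = bool(apical_contact)
    if side == "vz" and apical:
        return FateCall(PROGENITOR, "both")
    if side == "mz" and not apical:
        return FateCall(NEURON, "both")
    if side == "on_line":
        return FateCall(PROGENITOR if apical else UNASSIGNED, "apical_contact")
    logger.debug("conflicting fate evidence (side=%s, apical=%s)", side, apical)
    return FateCall(UNASSIGNED, "both")


def fate_table(cells: pd.DataFrame, cfg: PipelineConfig) -> pd.DataFrame:
    """Per-row fate calls for a cell table (adds ``fate`` and ``fate_basis``)."""
    has_flag = "apical_contact" in cells.columns
    fates, bases = [], []
    for _, row in cells.iterrows():
        flag = row["apical_contact"] if has_flag else None
        call = assign_fate(row[cfg.dv_axis], flag, cfg)
        fates.append(call.fate)
        bases.append(call.basis)
    return cells.assign(fate=fates, fate_basis=bases)


# ---------------------------------------------------------------------------
# track-based division-mode classification


def classify_division(
    time: float,
    d1: pd.Series,
    d2: pd.Series,
    d1_assessable: bool,
    d2_assessable: bool,
    d1_fate: str,
    d2_fate: str,
    cfg: PipelineConfig,
) -> str:
    """Classify one division from daughter geometry and fates.

    PN: daughters out of contact, on opposite sides of the VZ/MZ line.
    PP / NN: daughters in contact at the same dorsoventral level, both
    progenitors / both neurons.  Daughters that could not be assessed
    (tracked too briefly) or contradictory configurations give
    ``unassigned``.
    """
    if not (d1_assessable and d2_assessable):
        return UNASSIGNED
    p1 = np.array([d1[cfg.ap_axis], d1[cfg.ml_axis], d1[cfg.dv_axis]], float)
    p2 = np.array([d2[cfg.ap_axis], d2[cfg.ml_axis], d2[cfg.dv_axis]], float)
    dist = float(np.linalg.norm(p1 - p2))
    dv1, dv2 = float(d1[cfg.dv_axis]), float(d2[cfg.dv_axis])
    line = cfg.vz_boundary_um
    in_contact = dist <= cfg.d_contact
    same_dv = abs(dv1 - dv2) <= cfg.dv_tol
    opposite = (dv1 - line) * (dv2 - line) < 0
    if not in_contact and opposite:
        return PN
    if in_contact and same_dv:
        if d1_fate == PROGENITOR and d2_fate == PROGENITOR:
            return PP
        if d1_fate == NEURON and d2_fate == NEURON:
            return NN
        logger.debug("contradictory division at t=%.2f: contact but fates %s/%s",
                     time, d1_fate, d2_fate)
        return UNASSIGNED
    return UNASSIGNED


def classify_divisions(
    trees: Sequence[LineageTree],
    cells: pd.DataFrame,
    cfg: PipelineConfig,
    window: Optional[tuple[float, float]] = None,
) -> pd.DataFrame:
    """Classify every division of a tracked cohort from the cell table.

    A daughter is assessable when it divides again (it is then a
    progenitor by definition) or when it remains observable for at least
    ``cfg.fate_exclusion_h`` hours after the division; otherwise the
    division mode is not ascribed.  Geometry is read at the first frame at
    which both daughters appear; fate at ``cfg.fate_exclusion_h`` hours
    after the division.
    """
    cells_by_id = {cid: grp.sort_values("time_hpf")
                   for cid, grp in cells.groupby("cell_id")}
    rows = []
    for tree in trees:
        for div in tree.divisions:
            if window is not None and not (window[0] <= div.time <= window[1]):
                continue
            d_info = []
            for did in div.daughters:
                node = tree.nodes[did]
                divides_later = bool(node.children)
                sub = cells_by_id.get(did)
                if sub is None or sub.empty:
                    d_info.append(None)
                    continue
                last_seen = float(sub["time_hpf"].max())
                assessable = divides_later or (
                    last_seen - div.time >= cfg.fate_exclusion_h - 1e-9
                )
                first = sub.iloc[0]
                if divides_later:
                    fate = PROGENITOR
                else:
                    later = sub[sub["time_hpf"] >= div.time + cfg.fate_exclusion_h - 1e-9]
                    at = later.iloc[0] if not later.empty else sub.iloc[-1]
                    flag = at.get("apical_contact")
                    fate = assign_fate(at[cfg.dv_axis], flag, cfg).fate
                d_info.append((first, assessable, fate))
            if any(x is None for x in d_info):
                mode = UNASSIGNED
            else:
                (r1, a1, f1), (r2, a2, f2) = d_info
                mode = classify_division(div.time, r1, r2, a1, a2, f1, f2, cfg)
            rows.append({"clone_id": tree.clone_id, "mother": div.mother,
                         "time_hpf": div.time, "mode": mode,
                         "condition": tree.condition})
    return pd.DataFrame(
        rows, columns=["clone_id", "mother", "time_hpf", "mode", "condition"]
    )


def division_mode_shares(counts: dict[str, int]) -> dict[str, float]:
    """Percent shares of assigned division modes (PP/PN/NN)."""
    total = sum(counts.get(m, 0) for m in (PP, PN, NN))
    if total == 0:
        raise ValueError("no assigned divisions")
    return {m: 100.0 * counts.get(m, 0) / total for m in (PP, PN, NN)}


# ---------------------------------------------------------------------------
# endpoint (composition-based) inference


def _mutually_nearest_pairs(
    pos: np.ndarray, d_contact: float, dv_tol: float, dv: np.ndarray
) -> list[tuple[int, int]]:
    """Iteratively extract mutually-nearest pairs that are in contact and
    at the same dorsoventral level."""
    active = list(range(len(pos)))
    pairs = []
    while len(active) >= 2:
        sub = np.array(active)
        d = np.linalg.norm(pos[sub][:, None, :] - pos[sub][None, :, :], axis=2)
        np.fill_diagonal(d, np.inf)
        nearest = d.argmin(axis=1)
        found = None
        order = np.argsort(d.min(axis=1), kind="stable")
        for a in order:
            b = nearest[a]
            if nearest[b] != a:
                continue
            if d[a, b] > d_contact:
                continue
            if abs(dv[sub[a]] - dv[sub[b]]) > dv_tol:
                continue
            found = (int(sub[a]), int(sub[b]))
            break
        if found is None:
            break
        pairs.append(found)
        active = [i for i in active if i not in found]
    return pairs


def infer_division_modes_endpoint(
    clone_cells: pd.DataFrame,
    cfg: PipelineConfig,
    founders: int = 1,
) -> dict[str, float]:
    """Infer division-mode counts from a clone's composition at one
    timepoint.

    Literal counting rule (default): every PP division leaves one extra
    progenitor and every PN division one neuron, so PP count = number of
    progenitors and PN count = number of neurons.  NN divisions are
    considered only in clones with an even number of neurons: one NN per
    mutually-nearest neuron pair in contact at the same dorsoventral level
    (``nn_rule="paired"``) or one per neuron pair (``nn_rule="all_even"``),
    each counted pair removing two from the PN tally.

    With ``endpoint_convention="founder_discount"`` the founder cells are
    discounted and NN-consumed progenitors restored
    (PP = P - founders + NN), which makes the endpoint counts equal the
    track-based division counts on fully tracked data.
    """
    fated = fate_table(clone_cells, cfg)
    p_count = int((fated["fate"] == PROGENITOR).sum())
    n_count = int((fated["fate"] == NEURON).sum())
    if p_count + n_count == 0:
        raise ValueError("clone has no fated cells")
    neurons = fated[fated["fate"] == NEURON]
    nn_pairs = 0
    # the literal rule considers NN only in even-neuron clones; the
    # founder-discount convention drops that parity gate (an odd neuron
    # count can still contain one geometric NN pair plus a PN neuron)
    parity_ok = (
        n_count % 2 == 0 or cfg.endpoint_convention == "founder_discount"
    )
    if n_count >= 2 and parity_ok:
        if cfg.nn_rule == "all_even":
            nn_pairs = n_count // 2
        else:
            pos = neurons[[cfg.ap_axis, cfg.ml_axis, cfg.dv_axis]].to_numpy(float)
            dv = neurons[cfg.dv_axis].to_numpy(float)
            nn_pairs = len(
                _mutually_nearest_pairs(pos, cfg.d_contact, cfg.dv_tol, dv)
            )
    if cfg.endpoint_convention == "founder_discount":
        pp = max(p_count - founders + nn_pairs, 0)
    else:
        pp = p_count
    pn = n_count - 2 * nn_pairs
    total = pp + pn + nn_pairs
    shares = (
        {m: 100.0 * c / total for m, c in ((PP, pp), (PN, pn), (NN, nn_pairs))}
        if total > 0 else {PP: np.nan, PN: np.nan, NN: np.nan}
    )
    return {"PP": pp, "PN": pn, "NN": nn_pairs,
            "P": p_count, "N": n_count,
            "pct_PP": shares[PP], "pct_PN": shares[PN], "pct_NN": shares[NN]}


# ---------------------------------------------------------------------------
# cohort summaries


def proliferative_capacity(
    trees: Sequence[LineageTree],
    window: Optional[tuple[float, float]] = None,
) -> dict[str, float]:
    """Fraction of t0 progenitors that divide in the window, and endpoint
    fate fractions over all tracked cells at the end of the window."""
    if not trees:
        raise ValueError("no trees")
    if window is None:
        t0 = min(min(n.birth for n in t.iter_nodes()) for t in trees)
        tf = max(d.time for t in trees for d in t.divisions) if any(
            t.divisions for t in trees) else t0
        window = (t0, tf)
    t0, tf = window
    dividing = 0
    total = 0
    endpoint_fates = {PROGENITOR: 0, NEURON: 0}
    for tree in trees:
        for node in tree.cells_alive_at(t0):
            total += 1
            if node.children and t0 <= node.end <= tf:
                dividing += 1
        for node in tree.iter_nodes():
            alive = node.birth <= tf and (not node.children or node.end > tf)
            if alive and node.fate in endpoint_fates:
                endpoint_fates[node.fate] += 1
    if total == 0:
        raise ValueError("no progenitors at window start")
    n_end = sum(endpoint_fates.values())
    return {
        "n_progenitors_t0": total,
        "n_dividing": dividing,
        "pct_dividing": 100.0 * dividing / total,
        "pct_nondividing": 100.0 * (total - dividing) / total,
        "n_cells_tf": n_end,
        "pct_P_tf": 100.0 * endpoint_fates[PROGENITOR] / n_end if n_end else np.nan,
        "pct_N_tf": 100.0 * endpoint_fates[NEURON] / n_end if n_end else np.nan,
    }


def sister_analysis(
    tree: LineageTree,
    t0: float,
    tf: float,
    frame_interval: float = 1.0,
    modes: Optional[dict[str, str]] = None,
) -> dict[str, object]:
    """Sister-cell statistics for a two-cell clone at t0.

    Concordance: both sisters divide, or neither.  Synchrony (defined only
    when both divide): synchronous when the division times differ by at
    most one frame, otherwise asynchronous, with the delay in hours.  When
    per-cell division modes are supplied, mode concordance is reported.
    """
    cells_t0 = tree.cells_alive_at(t0)
    if len(cells_t0) != 2:
        raise ValueError("sister analysis requires a two-cell clone at t0")
    a, b = cells_t0
    t_a = a.end if a.children and a.end <= tf else None
    t_b = b.end if b.children and b.end <= tf else None
    both = t_a is not None and t_b is not None
    neither = t_a is None and t_b is None
    out: dict[str, object] = {
        "clone_id": tree.clone_id,
        "concordance": "same" if (both or neither) else "different",
        "synchrony": "NA",
        "delay_h": np.nan,
        "mode_concordance": "NA",
    }
    if both:
        delay = abs(t_a - t_b)
        out["delay_h"] = float(delay)
        out["synchrony"] = (
            "synchronous" if delay <= frame_interval + 1e-9 else "asynchronous"
        )
        if modes is not None:
            m_a, m_b = modes.get(a.cell_id), modes.get(b.cell_id)
            if m_a in (PP, PN, NN) and m_b in (PP, PN, NN):
                out["mode_concordance"] = "same" if m_a == m_b else "different"
    return out


def sister_delays_from_trees(
    trees: Sequence[LineageTree], window: tuple[float, float]
) -> list[float]:
    """Realized |Δt| between the divisions of sister pairs (daughters of a
    common division, including pre-window founder divisions) where both
    sisters divide within the window."""
    delays = []
    for tree in trees:
        for div in tree.divisions:
            d1, d2 = (tree.nodes[d] for d in div.daughters)
            if all(d.children and window[0] <= d.end <= window[1] for d in (d1, d2)):
                delays.append(abs(d1.end - d2.end))
    return delays


def clone_growth(
    trees: Sequence[LineageTree], times: Sequence[float]
) -> pd.DataFrame:
    """Cells per clone at each timepoint, with cohort mean and s.d.

    Clone sizes should be non-decreasing in time; violations (possible
    with lost tracks in imported data) are logged, not raised.
    """
    rows = []
    for tree in trees:
        counts = []
        for t in times:
            alive = [n for n in tree.iter_nodes()
                     if n.birth <= t and (not n.children or n.end > t)]
            counts.append(len(alive))
        if any(b < a for a, b in zip(counts, counts[1:])):
            logger.warning("clone %s shrinks over time (lost tracks?)",
                           tree.clone_id)
        rows.append({"clone_id": tree.clone_id, "condition": tree.condition,
                     **{f"n_at_{t:g}": c for t, c in zip(times, counts)}})
    df = pd.DataFrame(rows)
    return df


def growth_summary(growth: pd.DataFrame, times: Sequence[float]) -> pd.DataFrame:
    recs = []
    for t in times:
        col = growth[f"n_at_{t:g}"]
        recs.append({"time_hpf": t, "mean_cells": col.mean(),
                     "sd_cells": col.std(ddof=1), "n_clones": len(col)})
    return pd.DataFrame(recs)


def mode_timecourse(
    divisions: pd.DataFrame,
    bin_width: float = 1.0,
    min_divisions_per_bin: int = 1,
) -> dict[str, object]:
    """Per-time-bin PP/PN fractions with least-squares slope and R².

    Fractions are over assigned PP+PN divisions per bin; the regression is
    fraction vs bin center.  A single usable bin (or a constant fraction)
    leaves the slope undefined / R² = 0 by convention, with a sparse-data
    flag.
    """
    assigned = divisions[divisions["mode"].isin([PP, PN])]
    if assigned.empty:
        raise ValueError("no assigned PP/PN divisions")
    t = assigned["time_hpf"].to_numpy(float)
    bins = np.floor(t / bin_width) * bin_width + bin_width / 2
    frame = pd.DataFrame({"bin": bins, "mode": assigned["mode"].to_numpy()})
    per_bin = frame.groupby("bin")["mode"].agg(
        n="size", pp=lambda s: (s == PP).sum()
    ).reset_index()
    per_bin = per_bin[per_bin["n"] >= min_divisions_per_bin]
    per_bin["frac_PP"] = per_bin["pp"] / per_bin["n"]
    per_bin["frac_PN"] = 1.0 - per_bin["frac_PP"]
    out: dict[str, object] = {"bins": per_bin, "sparse": len(per_bin) < 2}
    for which in ("PP", "PN"):
        y = per_bin[f"frac_{which}"].to_numpy(float)
        x = per_bin["bin"].to_numpy(float)
        if len(per_bin) < 2:
            out[which] = {"slope": np.nan, "r2": np.nan, "p": np.nan,
                          "flag": "single_bin"}
            continue
        if np.allclose(y, y[0]):
            out[which] = {"slope": 0.0, "r2": 0.0, "p": np.nan,
                          "flag": "constant"}
            continue
        res = sps.linregress(x, y)
        out[which] = {"slope": float(res.slope), "r2": float(res.rvalue ** 2),
                      "p": float(res.pvalue), "flag": ""}
    return out
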