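"""Synthetic multicolor clone generator.

Produces cohorts of color-labeled clonal lineages with known ground truth,
emulating the statistical structure of a Brainbow-type time-lapse
experiment in the embryonic hindbrain:

* per-founder recombination outcomes over a configurable transgene copy
  number (colors are copy-weighted averages of the three fluorophore axes;
  founders with no recombined copy keep the far-red default and carry no
  RGB signal);
* stochastic progenitor divisions on the hourly imaging grid with division
  modes drawn as PP / PN / NN; neurons never divide;
* sister coupling: after a PP division the second sister's division is
  offset from the first by a zero-clipped normal delay (the clipped
  normal(2.8, 1.9) h has mean ~2.86 h and puts ~11% of pairs within the
  same frame, i.e. synchronous);
* rendering onto a cell table: progenitors sit in the ventricular zone with
  apical contact, neurons translocate to the mantle zone one frame after
  their birth, sister geometry respects the division-mode spatial criteria
  (PP/NN pairs in contact at the same dorsoventral level; PN daughters out
  of contact on opposite sides of the VZ/MZ line), and measured channels
  are the true color plus independent Gaussian noise clipped at zero.
"""

from __future__ import annotations

import heapq
import itertools
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import OUTCOME_RGB, OUTCOMES, InvalidConfigError, SimulationConfig
from .lineage import NEURON, NN, PN, PP, PROGENITOR, LineageTree

CELL_COLUMNS = [
    "cell_id", "time_hpf", "x_um", "y_um", "z_um",
    "r_mean", "g_mean", "b_mean", "apical_contact",
    "embryo_id", "boundary_id",
]

TRACK_COLUMNS = ["cell_id", "parent_id", "birth_hpf", "end_hpf"]

_CLONES_PER_BOUNDARY = 4
_BOUNDARIES_PER_EMBRYO = 3
_ANCHOR_SPACING_UM = 120.0
_AP_SPACING_UM = 25.0
_P_CLUSTER_WIDTH_UM = 8.0
_N_SLOT_SPACING_UM = 30.0
_NN_PAIR_HALF_GAP_UM = 4.0
_P_DEPTH_BELOW_LINE_UM = 6.0
_N_DEPTH_PAST_LINE_UM = 14.0


@dataclass(frozen=True)
class FounderState:
    """Recombination outcome of one founder."""

    color: Optional[tuple[float, float, float]]  # simplex point; None if unrecombined
    unrecombined: bool
    manipulated: bool
    n_copies: int
    outcomes: tuple[str, ...]

    @property
    def condition(self) -> str:
        return "red" if self.manipulated else "control"


@dataclass
class GroundTruth:
    """Sidecar truth tables keyed by cell_id / clone_id."""

    cells: pd.DataFrame
    divisions: pd.DataFrame
    sister_delays: pd.DataFrame
    config: SimulationConfig


def simulate_recombination(
    config: SimulationConfig, n: int, rng: Optional[np.random.Generator] = None
) -> list[FounderState]:
    """Draw recombination outcomes for ``n`` founders.

    Each founder carries ``k`` transgene copies (from the copy-number
    distribution); each copy independently resolves to the far-red default
    or one of the three recombined fluorophores.  The founder color is the
    average of its recombined copies' RGB axis vectors; a founder whose
    copies all stay unrecombined has no RGB color and is flagged.
    """
    if n < 1:
        raise ValueError("need n >= 1 founders")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    copy_vals = sorted(config.copy_number_distribution)
    weights = np.array(
        [config.copy_number_distribution[k] for k in copy_vals], dtype=float
    )
    total = weights.sum()
    if total <= 0:
        raise InvalidConfigError("copy-number distribution has zero weight")
    weights = weights / total
    probs = np.asarray(config.recombination_probs, dtype=float)
    founders = []
    for _ in range(n):
        k = int(rng.choice(copy_vals, p=weights))
        outcome_idx = rng.choice(len(OUTCOMES), size=k, p=probs)
        outcomes = tuple(OUTCOMES[i] for i in outcome_idx)
        recombined = [o for o in outcomes if o != "default_farred"]
        if recombined:
            color = tuple(
                float(np.mean([OUTCOME_RGB[o][axis] for o in recombined]))
                for axis in range(3)
            )
            unrec = False
        else:
            color, unrec = None, True
        has_red = "tdtomato" in outcomes
        manipulated = bool(
            has_red and rng.random() < config.red_manipulated_fraction
        )
        founders.append(
            FounderState(color, unrec, manipulated, k, outcomes)
        )
    return founders


def _grid_after(config: SimulationConfig, after: float) -> float:
    """First frame-grid time strictly after ``after``."""
    k = int(np.floor((after - config.t_start) / config.frame_interval + 1e-9)) + 1
    return config.t_start + k * config.frame_interval


def _draw_division_time(
    rng: np.random.Generator, config: SimulationConfig, after: float, p: float
) -> Optional[float]:
    """Geometric per-frame division clock starting strictly after ``after``
    (and after ``t_start``: clones are established, not caught mid-division,
    at the first frame); None when the cell does not divide within the
    window."""
    t = _grid_after(config, max(after, config.t_start))
    while t <= config.t_end + 1e-9:
        if rng.random() < p:
            if config.half_frame_jitter and rng.random() < 0.5:
                jittered = t - 0.5 * config.frame_interval
                if jittered > after:
                    return jittered
            return t
        t += config.frame_interval
    return None


def _snap_to_grid(config: SimulationConfig, t: float) -> float:
    step = config.frame_interval * (0.5 if config.half_frame_jitter else 1.0)
    k = round((t - config.t_start) / step)
    return config.t_start + k * step


def simulate_clone(
    config: SimulationConfig,
    founder: FounderState,
    rng: Optional[np.random.Generator] = None,
    clone_id: str = "clone",
) -> LineageTree:
    """Simulate one clonal lineage from ``t_start`` (or one frame earlier
    when the founder pre-divides) to ``t_end``.

    Division modes are drawn per event from ``mode_probs`` (or the
    manipulated override for manipulated founders).  PP sisters are
    coupled: the first sister's division follows its own per-frame clock
    and the second divides after a zero-clipped normal delay, snapped to
    the frame grid.  Realized both-divided sister delays are recorded in
    ``tree.meta["sister_delays"]``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    mode_probs = (
        config.manipulated_mode_probs
        if (founder.manipulated and config.manipulated_mode_probs is not None)
        else config.mode_probs
    )
    div_p = (
        config.manipulated_division_prob
        if (founder.manipulated and config.manipulated_division_prob is not None)
        else config.division_prob_per_frame
    )
    cum_modes = np.cumsum(mode_probs)

    counter = itertools.count(1)

    def new_id() -> str:
        return f"{clone_id}.{next(counter)}"

    tree = LineageTree(root="", clone_id=clone_id, condition=founder.condition)
    tree.meta = {
        "true_color": founder.color,
        "unrecombined": founder.unrecombined,
        "manipulated": founder.manipulated,
        "sister_delays": [],
    }

    sizes = sorted(config.t0_size_probs)
    size_w = np.array([config.t0_size_probs[s] for s in sizes], float)
    t0_size = int(rng.choice(sizes, p=size_w / size_w.sum()))
    birth = (config.t_start if t0_size == 1
             else config.t_start - config.frame_interval)
    root_id = new_id()
    tree.add_root(root_id, birth)

    # event queue of scheduled divisions: (time, tiebreak, cell_id, forced_mode)
    heap: list[tuple[float, int, str, Optional[str]]] = []
    tie = itertools.count()

    def schedule(cell_id: str, time: Optional[float], forced: Optional[str] = None):
        if time is not None and time <= config.t_end + 1e-9:
            heapq.heappush(heap, (time, next(tie), cell_id, forced))

    def draw_mode() -> str:
        u = rng.random()
        return (PP, PN, NN)[int(np.searchsorted(cum_modes, u, side="right"))]

    def couple_sisters(d_first: str, d_second: str, t_div: float):
        """Schedule a PP pair: first by its own clock, second offset by the
        sister delay."""
        t_a = _draw_division_time(rng, config, t_div, div_p)
        if t_a is None:
            schedule(d_second, _draw_division_time(rng, config, t_div, div_p))
            return
        schedule(d_first, t_a)
        delay = max(0.0, rng.normal(config.sister_delay_mean, config.sister_delay_sd))
        t_b = _snap_to_grid(config, t_a + delay)
        t_b = max(t_b, t_a)
        if t_b <= config.t_end + 1e-9:
            schedule(d_second, t_b)
            tree.meta["sister_delays"].append(
                {"mother": d_first, "t_first": t_a, "t_second": t_b,
                 "delay_h": t_b - t_a}
            )

    # founders of 2- or 3-cell t0 clones divided (PP) before the window
    if t0_size == 1:
        schedule(root_id, _draw_division_time(rng, config, birth, div_p))
    else:
        c1, c2 = new_id(), new_id()
        tree.add_division(root_id, birth, (c1, c2),
                          (PROGENITOR, PROGENITOR), PP)
        if t0_size == 2:
            first, second = (c1, c2) if rng.random() < 0.5 else (c2, c1)
            couple_sisters(first, second, birth)
        else:
            c3, c4 = new_id(), new_id()
            tree.add_division(c1, birth, (c3, c4),
                              (PROGENITOR, PROGENITOR), PP)
            first, second = (c3, c4) if rng.random() < 0.5 else (c4, c3)
            couple_sisters(first, second, birth)
            schedule(c2, _draw_division_time(rng, config, birth, div_p))

    while heap:
        t_div, _, cell_id, forced = heapq.heappop(heap)
        mode = forced if forced is not None else draw_mode()
        d1, d2 = new_id(), new_id()
        fates = {PP: (PROGENITOR, PROGENITOR), PN: (PROGENITOR, NEURON),
                 NN: (NEURON, NEURON)}[mode]
        tree.add_division(cell_id, t_div, (d1, d2), fates, mode)
        if mode == PP:
            first, second = (d1, d2) if rng.random() < 0.5 else (d2, d1)
            couple_sisters(first, second, t_div)
        elif mode == PN:
            schedule(d1, _draw_division_time(rng, config, t_div, div_p))
        # NN: neither daughter divides
    for node in tree.iter_nodes():
        if not node.children:
            node.end = config.t_end
    tree.validate()
    return tree


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[list[LineageTree], list[FounderState]]:
    """Simulate ``config.n_founders`` clones, assigned to boundaries of
    virtual embryos (four clones per boundary, three boundaries per
    embryo)."""
    rng = np.random.default_rng(config.seed)
    founders = simulate_recombination(config, config.n_founders, rng)
    trees = []
    for i, founder in enumerate(founders):
        boundary_idx = i // _CLONES_PER_BOUNDARY
        slot = i % _CLONES_PER_BOUNDARY
        embryo = boundary_idx // _BOUNDARIES_PER_EMBRYO + 1
        b_local = boundary_idx % _BOUNDARIES_PER_EMBRYO + 1
        clone_id = f"e{embryo}_b{b_local}_cl{slot + 1}"
        tree = simulate_clone(config, founder, rng, clone_id=clone_id)
        tree.meta.update(
            embryo_id=f"e{embryo}", boundary_id=f"e{embryo}_b{b_local}", slot=slot
        )
        trees.append(tree)
    return trees, founders


def _clone_positions(tree: LineageTree, config: SimulationConfig) -> dict:
    """Static (ap, ml, dv, apical) geometry per cell of one clone.

    Progenitors occupy a tight cluster in the ventricular zone (binary-
    subdivided mediolateral offsets keep PP sisters in contact at the same
    dorsoventral level); each PN neuron gets an isolated mantle-zone slot
    on one side of the clone; each NN pair gets an adjacent mantle-zone
    slot pair on the other side, mutually nearest and in contact.
    """
    interface = config.vz_fraction * config.dv_extent_um
    z_p = interface - _P_DEPTH_BELOW_LINE_UM
    z_n = interface + _N_DEPTH_PAST_LINE_UM
    slot = tree.meta.get("slot", 0)
    anchor_ml = _ANCHOR_SPACING_UM * (slot + 1)
    anchor_ap = _AP_SPACING_UM * slot

    offsets: dict[str, float] = {tree.root: 0.0}
    widths: dict[str, float] = {tree.root: _P_CLUSTER_WIDTH_UM}
    positions: dict[str, tuple[float, float, float, bool]] = {}
    nn_pairs = 0
    lone_n = 0

    def place_p(cid: str):
        positions[cid] = (anchor_ap, anchor_ml + offsets[cid], z_p, True)

    place_p(tree.root)
    for div in sorted(tree.divisions, key=lambda d: (d.time, d.mother)):
        d1, d2 = div.daughters
        off, w = offsets[div.mother], widths[div.mother]
        if div.mode == PP:
            offsets[d1], offsets[d2] = off - w / 4, off + w / 4
            widths[d1] = widths[d2] = w / 2
            place_p(d1)
            place_p(d2)
        elif div.mode == PN:
            offsets[d1], widths[d1] = off, w
            place_p(d1)
            lone_ml = anchor_ml - _N_SLOT_SPACING_UM * (lone_n + 1)
            positions[d2] = (anchor_ap, lone_ml, z_n, False)
            lone_n += 1
        else:  # NN
            base = anchor_ml + _N_SLOT_SPACING_UM * (nn_pairs + 1)
            positions[d1] = (anchor_ap, base - _NN_PAIR_HALF_GAP_UM, z_n, False)
            positions[d2] = (anchor_ap, base + _NN_PAIR_HALF_GAP_UM, z_n, False)
            nn_pairs += 1
    return positions


def render_cell_table(
    trees: Sequence[LineageTree],
    config: SimulationConfig,
    at_times: Sequence[float],
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Materialize trees as (cell table, track table, ground truth).

    The cell table has one row per cell per requested timepoint with
    noisy measured channels; clone identity is withheld from it and kept
    in the ground-truth sidecar.  The track table carries the lineage
    topology (parent links and birth/end times), standing in for a manual
    tracking session.
    """
    at_times = list(at_times)
    for t in at_times:
        if not (config.t_start - 1e-9 <= t <= config.t_end + 1e-9):
            raise ValueError(f"render time {t} outside [t_start, t_end]")
    if len(trees) == 0:
        warnings.warn("rendering an empty tree sequence", stacklevel=2)
        empty = pd.DataFrame(columns=CELL_COLUMNS)
        gt = GroundTruth(
            cells=pd.DataFrame(), divisions=pd.DataFrame(),
            sister_delays=pd.DataFrame(), config=config,
        )
        return empty, pd.DataFrame(columns=TRACK_COLUMNS), gt

    noise_rng = np.random.default_rng([config.seed, 7919])
    rows = []
    track_rows = []
    gt_cells = []
    gt_divs = []
    gt_delays = []
    for tree in trees:
        positions = _clone_positions(tree, config)
        color = tree.meta.get("true_color")
        for node in sorted(tree.iter_nodes(), key=lambda n: n.cell_id):
            ap, ml, dv, apical = positions[node.cell_id]
            track_rows.append(
                {"cell_id": node.cell_id, "parent_id": node.parent or "",
                 "birth_hpf": node.birth, "end_hpf": min(node.end, config.t_end)}
            )
            gt_cells.append(
                {"cell_id": node.cell_id, "clone_id": tree.clone_id,
                 "parent_id": node.parent or "", "birth_hpf": node.birth,
                 "end_hpf": min(node.end, config.t_end), "fate": node.fate,
                 "true_r": color[0] if color else 0.0,
                 "true_g": color[1] if color else 0.0,
                 "true_b": color[2] if color else 0.0,
                 "unrecombined": tree.meta.get("unrecombined", False),
                 "condition": tree.condition}
            )
            for t in at_times:
                if not (node.birth <= t < node.end or
                        (not node.children and np.isclose(t, config.t_end))):
                    continue
                if color is None:
                    true = np.zeros(3)
                else:
                    true = np.asarray(color, dtype=float)
                measured = true + noise_rng.normal(0.0, config.channel_noise_sd, 3)
                measured = np.clip(measured, 0.0, None)
                rows.append(
                    {"cell_id": node.cell_id, "time_hpf": t,
                     "x_um": ap, "y_um": ml, "z_um": dv,
                     "r_mean": measured[0], "g_mean": measured[1],
                     "b_mean": measured[2], "apical_contact": apical,
                     "embryo_id": tree.meta.get("embryo_id", "e1"),
                     "boundary_id": tree.meta.get("boundary_id", "b1")}
                )
        for div in tree.divisions:
            gt_divs.append(
                {"clone_id": tree.clone_id, "mother": div.mother,
                 "daughter1": div.daughters[0], "daughter2": div.daughters[1],
                 "time_hpf": div.time, "mode": div.mode,
                 "in_window": config.t_start <= div.time <= config.t_end}
            )
        for rec in tree.meta.get("sister_delays", []):
            gt_delays.append({"clone_id": tree.clone_id, **rec})

    cells = pd.DataFrame(rows, columns=CELL_COLUMNS)
    cells = cells.sort_values(["time_hpf", "boundary_id", "cell_id"],
                              kind="mergesort").reset_index(drop=True)
    tracks = pd.DataFrame(track_rows, columns=TRACK_COLUMNS)
    tracks = tracks.sort_values("cell_id", kind="mergesort").reset_index(drop=True)
    gt = GroundTruth(
        cells=pd.DataFrame(gt_cells),
        divisions=pd.DataFrame(gt_divs),
        sister_delays=pd.DataFrame(
            gt_delays, columns=["clone_id", "mother", "t_first", "t_second", "delay_h"]
        ),
        config=config,
    )
    return cells, tracks, gt


def simulate_dataset(
    config: SimulationConfig, at_times: Optional[Sequence[float]] = None
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth, list[LineageTree]]:
    """One-call cohort: simulate and render at every frame (default)."""
    trees, _ = simulate_cohort(config)
    if at_times is None:
        at_times = config.frames
    cells, tracks, gt = render_cell_table(trees, config, at_times)
    return cells, tracks, gt, trees
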