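"""Readers and writers.

Tab-delimited cell tables and track tables with documented headers, a
subset reader/writer for the spot/link tracking-XML dialect produced by
common Fiji tracking plugins (MaMuT/TrackMate style), YAML pipeline
configuration, and JSON run logs recording config hash, seed and version.
Readers reject malformed input with the offending column or line rather
than silently coercing it.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
import xml.etree.ElementTree as ET
from dataclasses import asdict
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .config import PipelineConfig
from .lineage import LineageTree
from .simulate import CELL_COLUMNS, TRACK_COLUMNS

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

MANDATORY_CELL_COLUMNS = [
    "cell_id", "time_hpf", "x_um", "y_um", "z_um",
    "r_mean", "g_mean", "b_mean", "embryo_id", "boundary_id",
]
NUMERIC_CELL_COLUMNS = ["time_hpf", "x_um", "y_um", "z_um",
                        "r_mean", "g_mean", "b_mean"]


class SchemaError(ValueError):
    pass


def read_cell_table(path: PathLike) -> pd.DataFrame:
    """Read a tab-delimited cell table.

    ``apical_contact`` is optional: when absent the column is added as
    missing and downstream fate calls fall back to position only (a
    warning is emitted).  Rows with non-numeric values in numeric columns
    are rejected with their line numbers.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in MANDATORY_CELL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
    bad_lines: list[int] = []
    for col in NUMERIC_CELL_COLUMNS:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & (df[col].str.len() > 0)
        empty = df[col].str.len() == 0
        bad_lines.extend((df.index[bad | empty] + 2).tolist())  # 1-based + header
        df[col] = converted
    if bad_lines:
        raise SchemaError(
            f"malformed numeric values at line(s) {sorted(set(bad_lines))}"
        )
    if not np.isfinite(df[NUMERIC_CELL_COLUMNS].to_numpy(float)).all():
        raise SchemaError("non-finite coordinate or channel values")
    if (df["time_hpf"] < 0).any():
        raise SchemaError("negative time_hpf")
    if "apical_contact" in df.columns:
        df["apical_contact"] = df["apical_contact"].map(
            {"True": True, "False": False, "1": True, "0": False,
             "true": True, "false": False}
        )
        if df["apical_contact"].isna().any():
            raise SchemaError("unparseable apical_contact values")
    else:
        warnings.warn(
            "apical_contact column absent: fate calls downgraded to "
            "position-only", stacklevel=2,
        )
        df["apical_contact"] = pd.NA
    return df[[c for c in CELL_COLUMNS if c in df.columns]]


def write_cell_table(cells: pd.DataFrame, path: PathLike) -> None:
    out = cells.copy()
    cols = [c for c in CELL_COLUMNS if c in out.columns]
    out[cols].to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_track_table(path: PathLike) -> pd.DataFrame:
    """Parent-child track table: cell_id, parent_id, birth_hpf, end_hpf."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
    for col in ("birth_hpf", "end_hpf"):
        converted = pd.to_numeric(df[col], errors="coerce")
        if converted.isna().any():
            lines = (df.index[converted.isna()] + 2).tolist()
            raise SchemaError(f"malformed {col} at line(s) {lines}")
        df[col] = converted
    return df[TRACK_COLUMNS]


def write_track_table(tracks: pd.DataFrame, path: PathLike) -> None:
    tracks[TRACK_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.6g")


def trees_from_track_table(tracks: pd.DataFrame) -> list[LineageTree]:
    """Reconstruct founder-rooted lineage trees from parent links.

    A cell with two children is a division (at the children's birth time);
    more than two children is a structural error, as is a cycle.
    """
    children: dict[str, list[str]] = {}
    parent = {}
    rows = {str(r.cell_id): r for r in tracks.itertuples(index=False)}
    for r in tracks.itertuples(index=False):
        cid, pid = str(r.cell_id), str(r.parent_id)
        if pid:
            if pid not in rows:
                raise SchemaError(f"unknown parent {pid!r} of {cid!r}")
            children.setdefault(pid, []).append(cid)
            parent[cid] = pid
    for pid, kids in children.items():
        if len(kids) > 2:
            raise SchemaError(f"cell {pid!r} has {len(kids)} daughters")
    roots = [cid for cid in rows if cid not in parent]
    trees = []
    for root in sorted(roots):
        tree = LineageTree(root="")
        tree.add_root(root, float(rows[root].birth_hpf))
        tree.nodes[root].end = float(rows[root].end_hpf)
        stack = [root]
        visited = {root}
        while stack:
            cid = stack.pop()
            kids = sorted(children.get(cid, []))
            if len(kids) == 1:
                raise SchemaError(f"cell {cid!r} has a single daughter")
            if len(kids) == 2:
                t_div = float(rows[kids[0]].birth_hpf)
                tree.nodes[cid].end = t_div
                tree.add_division(cid, t_div, (kids[0], kids[1]),
                                  ("P", "P"))
                for k in kids:
                    if k in visited:
                        raise SchemaError("cyclic parent links")
                    visited.add(k)
                    tree.nodes[k].end = float(rows[k].end_hpf)
                    stack.append(k)
        tree.clone_id = root
        trees.append(tree)
    return trees


# ---------------------------------------------------------------------------
# tracking-XML subset (spots + links)


def read_tracks_xml(
    path: PathLike, t0: float = 0.0, frame_interval: float = 1.0
) -> tuple[list[LineageTree], pd.DataFrame]:
    """Import a spot/link tracking-XML subset.

    Expects ``Spot`` elements with ``ID``, ``FRAME``, ``POSITION_X/Y/Z``
    and ``Edge`` elements with ``SPOT_SOURCE_ID``/``SPOT_TARGET_ID``.
    Chains of singly linked spots collapse into one cell; a spot with two
    outgoing links is a division; more than two is an error, as are
    cycles.  Frames map to hpf as ``t0 + frame * frame_interval``.

    Returns the trees and a spot table (cell_id, time_hpf, x/y/z).
    """
    root = ET.parse(str(path)).getroot()
    spots: dict[str, dict] = {}
    for spot in root.iter("Spot"):
        sid = spot.get("ID")
        if sid is None:
            raise SchemaError("Spot without ID")
        frame = spot.get("FRAME")
        if frame is None:
            raise SchemaError(f"Spot {sid} without FRAME")
        spots[sid] = {
            "frame": int(float(frame)),
            "x": float(spot.get("POSITION_X", "nan")),
            "y": float(spot.get("POSITION_Y", "nan")),
            "z": float(spot.get("POSITION_Z", "nan")),
        }
    out_links: dict[str, list[str]] = {}
    in_deg: dict[str, int] = {}
    for edge in root.iter("Edge"):
        src, tgt = edge.get("SPOT_SOURCE_ID"), edge.get("SPOT_TARGET_ID")
        if src not in spots or tgt not in spots:
            raise SchemaError("edge references unknown spot")
        out_links.setdefault(src, []).append(tgt)
        in_deg[tgt] = in_deg.get(tgt, 0) + 1
    for sid, outs in out_links.items():
        if len(outs) > 2:
            raise SchemaError(f"spot {sid} has {len(outs)} outgoing links")
    for sid, deg in in_deg.items():
        if deg > 1:
            raise SchemaError(f"spot {sid} has {deg} incoming links")
    # cycle check: follow links counting steps
    order: list[str] = []
    state: dict[str, int] = {}

    def visit(sid: str):
        stack = [(sid, iter(out_links.get(sid, [])))]
        state[sid] = 1
        while stack:
            cur, it = stack[-1]
            nxt = next(it, None)
            if nxt is None:
                state[cur] = 2
                order.append(cur)
                stack.pop()
                continue
            st = state.get(nxt, 0)
            if st == 1:
                raise SchemaError("cyclic links")
            if st == 0:
                state[nxt] = 1
                stack.append((nxt, iter(out_links.get(nxt, []))))

    for sid in spots:
        if state.get(sid, 0) == 0:
            visit(sid)

    def hpf(frame: int) -> float:
        return t0 + frame * frame_interval

    # collapse chains into cells
    trees = []
    spot_rows = []
    root_spots = sorted(
        (s for s in spots if in_deg.get(s, 0) == 0), key=lambda s: int(s)
    )
    for rs in root_spots:
        tree = LineageTree(root="")

        def walk(start: str) -> tuple[str, float, float, list[str]]:
            """Follow the chain from ``start`` to a division or leaf.
            Returns (cell_id, birth, end, daughter chain starts)."""
            chain = [start]
            cur = start
            while len(out_links.get(cur, [])) == 1:
                cur = out_links[cur][0]
                chain.append(cur)
            birth = hpf(spots[start]["frame"])
            outs = out_links.get(cur, [])
            end = hpf(spots[cur]["frame"] + 1)
            for sid in chain:
                spot_rows.append(
                    {"cell_id": f"s{start}", "time_hpf": hpf(spots[sid]["frame"]),
                     "x_um": spots[sid]["x"], "y_um": spots[sid]["y"],
                     "z_um": spots[sid]["z"]}
                )
            return f"s{start}", birth, end, outs

        cid, birth, end, outs = walk(rs)
        tree.add_root(cid, birth)
        pending = [(cid, end, outs)]
        while pending:
            cid, end, outs = pending.pop()
            if not outs:
                tree.nodes[cid].end = end
                continue
            d_results = [walk(o) for o in sorted(outs, key=int)]
            t_div = min(r[1] for r in d_results)
            tree.add_division(cid, t_div,
                              (d_results[0][0], d_results[1][0]), ("P", "P"))
            for dcid, dbirth, dend, douts in d_results:
                pending.append((dcid, dend, douts))
        tree.clone_id = tree.root
        trees.append(tree)
    return trees, pd.DataFrame(
        spot_rows, columns=["cell_id", "time_hpf", "x_um", "y_um", "z_um"]
    )


def write_tracks_xml(
    tracks: pd.DataFrame,
    cells: pd.DataFrame,
    path: PathLike,
    t0: float,
    frame_interval: float = 1.0,
) -> None:
    """Export cells + parent links in the spot/link XML subset (one spot
    per cell per observed frame, chained by edges)."""
    root = ET.Element("TrackModel")
    all_spots = ET.SubElement(root, "AllSpots")
    all_tracks = ET.SubElement(root, "AllTracks")
    track_el = ET.SubElement(all_tracks, "Track")
    spot_id = 0
    last_spot_of_cell: dict[str, int] = {}
    first_spot_of_cell: dict[str, int] = {}
    frames: dict[int, ET.Element] = {}
    for t, group in cells.sort_values(["time_hpf", "cell_id"]).groupby("time_hpf"):
        frame = int(round((t - t0) / frame_interval))
        fr_el = frames.get(frame)
        if fr_el is None:
            fr_el = ET.SubElement(all_spots, "SpotsInFrame", frame=str(frame))
            frames[frame] = fr_el
        for _, row in group.iterrows():
            ET.SubElement(
                fr_el, "Spot", ID=str(spot_id), name=str(row["cell_id"]),
                FRAME=str(frame),
                POSITION_X=f"{row['x_um']:.6g}",
                POSITION_Y=f"{row['y_um']:.6g}",
                POSITION_Z=f"{row['z_um']:.6g}",
            )
            cid = str(row["cell_id"])
            if cid in last_spot_of_cell:
                ET.SubElement(
                    track_el, "Edge",
                    SPOT_SOURCE_ID=str(last_spot_of_cell[cid]),
                    SPOT_TARGET_ID=str(spot_id),
                )
            else:
                first_spot_of_cell[cid] = spot_id
            last_spot_of_cell[cid] = spot_id
            spot_id += 1
    for r in tracks.itertuples(index=False):
        cid, pid = str(r.cell_id), str(r.parent_id)
        if pid and pid in last_spot_of_cell and cid in first_spot_of_cell:
            ET.SubElement(
                track_el, "Edge",
                SPOT_SOURCE_ID=str(last_spot_of_cell[pid]),
                SPOT_TARGET_ID=str(first_spot_of_cell[cid]),
            )
    ET.indent(root)
    ET.ElementTree(root).write(str(path), encoding="unicode",
                               xml_declaration=True)


# ---------------------------------------------------------------------------
# config + run log


def read_pipeline_config(path: PathLike) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig.from_dict(data)


def config_hash(cfg) -> str:
    payload = json.dumps(asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def write_run_log(
    path: PathLike, cfg, seed: int, outputs: Sequence[str],
    extra: Optional[dict] = None,
) -> None:
    from . import __version__

    log = {
        "version": __version__,
        "seed": seed,
        "config_hash": config_hash(cfg),
        "config": asdict(cfg),
        "outputs": list(outputs),
    }
    if extra:
        log.update(extra)
    with open(path, "w") as fh:
        json.dump(log, fh, indent=2, default=str)
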