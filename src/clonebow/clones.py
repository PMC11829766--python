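"""Clone calling: color identity + spatial contact.

Cells observed in one boundary at one timepoint are grouped into clones as
the connected components of the graph joining cells that share a color-
identity region and lie within the contact distance.  Clones are numbered
by mediolateral, then dorsoventral position; traceability filters keep the
clones the time-lapse analysis follows (rare colors, one to three cells,
progenitor domain at t0; frequent colors only when isolated).
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform

from . import colors
from .config import PipelineConfig

logger = logging.getLogger(__name__)


def _classifiable(cells: pd.DataFrame, cfg: PipelineConfig) -> pd.Series:
    total = cells["r_mean"] + cells["g_mean"] + cells["b_mean"]
    return total >= cfg.min_total_intensity


def call_clones(
    cells: pd.DataFrame,
    cfg: Optional[PipelineConfig] = None,
    d_contact: Optional[float] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition one boundary/timepoint of cells into clones.

    Returns ``(members, clones)``: per-cell clone assignment (cells whose
    total intensity is below the classifiable floor get a null clone), and
    a per-clone summary with ids of the form ``<boundary>-<ordinal>``
    numbered mediolaterally (left to right), then dorsoventrally.
    """
    cfg = cfg or PipelineConfig()
    if d_contact is None:
        d_contact = cfg.d_contact
    if d_contact <= 0:
        raise ValueError("d_contact must be > 0")
    if cells.empty:
        return (
            cells.assign(clone_id=pd.Series(dtype=object),
                         region_index=pd.Series(dtype="Int64")),
            pd.DataFrame(columns=["clone_id", "boundary_id", "region_index",
                                  "n_cells", "ml_um", "dv_um"]),
        )
    if cells["boundary_id"].nunique() > 1 or cells["time_hpf"].nunique() > 1:
        raise ValueError("call_clones expects one boundary and one timepoint")

    # permutation invariance: canonical order by cell_id
    cells = cells.sort_values("cell_id", kind="mergesort").reset_index(drop=True)
    ok = _classifiable(cells, cfg)
    region = pd.array(np.full(len(cells), -1), dtype="Int64")
    if ok.any():
        region[np.asarray(ok)] = colors.assign_color_identities(
            cells.loc[ok, ["r_mean", "g_mean", "b_mean"]].to_numpy()
        )
    cells = cells.assign(region_index=region)

    coords = cells[[cfg.ap_axis, cfg.ml_axis, cfg.dv_axis]].to_numpy(float)
    n = len(cells)
    labels = np.full(n, -1)
    next_label = 0
    for reg in sorted({int(r) for r in region[np.asarray(ok)]}):
        idx = np.flatnonzero(np.asarray(region == reg) & np.asarray(ok))
        if idx.size == 1:
            labels[idx] = next_label
            next_label += 1
            continue
        dm = squareform(pdist(coords[idx]))
        adj = csr_matrix(dm <= d_contact)
        n_comp, comp = connected_components(adj, directed=False)
        labels[idx] = comp + next_label
        next_label += n_comp

    cells = cells.assign(_label=labels)
    boundary = str(cells["boundary_id"].iloc[0])
    grouped = (
        cells[cells["_label"] >= 0]
        .groupby("_label")
        .agg(
            region_index=("region_index", "first"),
            n_cells=("cell_id", "size"),
            ml_um=(cfg.ml_axis, "mean"),
            dv_um=(cfg.dv_axis, "mean"),
        )
        .reset_index()
    )
    grouped = grouped.sort_values(["ml_um", "dv_um"], kind="mergesort")
    grouped["clone_id"] = [
        f"{boundary}-{i + 1}" for i in range(len(grouped))
    ]
    label_to_id = dict(zip(grouped["_label"], grouped["clone_id"]))
    members = cells.assign(
        clone_id=[label_to_id.get(l) for l in cells["_label"]]
    ).drop(columns="_label")
    clones = grouped.drop(columns="_label")[
        ["clone_id", "region_index", "n_cells", "ml_um", "dv_um"]
    ]
    clones.insert(1, "boundary_id", boundary)
    return members, clones.reset_index(drop=True)


def call_clones_all(
    cells: pd.DataFrame, cfg: Optional[PipelineConfig] = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run :func:`call_clones` per (boundary, timepoint) group."""
    cfg = cfg or PipelineConfig()
    members_parts, clone_parts = [], []
    for (_, t), group in cells.groupby(["boundary_id", "time_hpf"], sort=True):
        m, c = call_clones(group, cfg)
        m = m.assign(time_hpf=t)
        c = c.assign(time_hpf=t)
        members_parts.append(m)
        clone_parts.append(c)
    if not members_parts:
        return call_clones(cells, cfg)
    return (
        pd.concat(members_parts, ignore_index=True),
        pd.concat(clone_parts, ignore_index=True),
    )


def in_progenitor_domain(
    cells: pd.DataFrame, cfg: PipelineConfig
) -> pd.Series:
    """Progenitor-domain membership: apical contact, or a nucleus within
    the ventricular-zone band."""
    dv = cells[cfg.dv_axis]
    band = dv <= cfg.vz_boundary_um
    apical = cells.get("apical_contact")
    if apical is None:
        return band
    return band | apical.astype(bool)


def filter_traceable(
    clones: pd.DataFrame,
    members: pd.DataFrame,
    frequency_classes: dict[int, str],
    cfg: Optional[PipelineConfig] = None,
    min_cells: int = 1,
    max_cells: int = 3,
    require_progenitor_domain: bool = True,
) -> pd.DataFrame:
    """Keep the clones the time-lapse analysis can follow from t0.

    All kept clones have ``min_cells``–``max_cells`` members, all in the
    progenitor domain when required.  Clones whose color region is not
    rare are kept only when isolated: no other clone of the same region
    within ``isolation_factor * d_contact``.
    """
    cfg = cfg or PipelineConfig()
    if clones.empty:
        return clones
    keep = (clones["n_cells"] >= min_cells) & (clones["n_cells"] <= max_cells)

    if require_progenitor_domain:
        domain = in_progenitor_domain(members, cfg)
        all_in = members.assign(_in=domain).groupby("clone_id")["_in"].all()
        keep &= clones["clone_id"].map(all_in).fillna(False).astype(bool)

    iso_radius = cfg.isolation_factor * cfg.d_contact
    freq = clones["region_index"].map(
        lambda r: frequency_classes.get(int(r), colors.RARE)
    )
    not_rare = freq != colors.RARE
    if not_rare.any():
        pos = clones[["ml_um", "dv_um"]].to_numpy(float)
        for i in np.flatnonzero(not_rare.to_numpy()):
            same = clones["region_index"] == clones["region_index"].iloc[i]
            same = same.to_numpy()
            same[i] = False
            if same.any():
                d = np.linalg.norm(pos[same] - pos[i], axis=1)
                if (d <= iso_radius).any():
                    keep.iloc[i] = False
                    logger.info(
                        "dropping non-isolated frequent-color clone %s",
                        clones["clone_id"].iloc[i],
                    )
    return clones[keep].reset_index(drop=True)


def link_clones_across_timepoints(
    clones_t1: pd.DataFrame,
    clones_t2: pd.DataFrame,
    ambiguity_tol: float = 1e-6,
) -> pd.DataFrame:
    """Greedy one-to-one matching of clones between two timepoints of the
    same boundary: identical color region, nearest (ML, DV) position.

    Returns one row per t1 clone with the matched t2 clone id (or null),
    and an ``ambiguous`` flag when two candidates were equidistant within
    ``ambiguity_tol`` (such clones are flagged, not auto-assigned).
    """
    results = []
    if not clones_t1.empty and not clones_t2.empty:
        b1 = set(clones_t1["boundary_id"])
        b2 = set(clones_t2["boundary_id"])
        if b1 != b2:
            raise ValueError("timepoints come from different boundaries")
    used_t2: set[str] = set()
    # candidate edges sorted by distance -> greedy one-to-one
    edges = []
    for i, c1 in clones_t1.iterrows():
        for j, c2 in clones_t2.iterrows():
            if c1["region_index"] != c2["region_index"]:
                continue
            d = float(np.hypot(c1["ml_um"] - c2["ml_um"], c1["dv_um"] - c2["dv_um"]))
            edges.append((d, i, j))
    edges.sort(key=lambda e: e[0])
    match: dict[int, tuple[int, float]] = {}
    used1: set[int] = set()
    for d, i, j in edges:
        if i in used1 or j in used_t2:
            continue
        match[i] = (j, d)
        used1.add(i)
        used_t2.add(j)
    for i, c1 in clones_t1.iterrows():
        row = {
            "clone_id_t1": c1["clone_id"],
            "clone_id_t2": None,
            "region_index": c1["region_index"],
            "distance": np.nan,
            "ambiguous": False,
        }
        if i in match:
            j, d = match[i]
            ties = [
                e for e in edges
                if e[1] == i and e[2] not in (used_t2 - {j})
                and abs(e[0] - d) <= ambiguity_tol and e[2] != j
            ]
            if ties:
                row["ambiguous"] = True
                logger.warning(
                    "ambiguous link for clone %s: equidistant candidates",
                    c1["clone_id"],
                )
            else:
                row["clone_id_t2"] = clones_t2.loc[j, "clone_id"]
                row["distance"] = d
        results.append(row)
    return pd.DataFrame(
        results,
        columns=["clone_id_t1", "clone_id_t2", "region_index", "distance",
                 "ambiguous"],
    )
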