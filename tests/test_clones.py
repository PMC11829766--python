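"""Clone calling by color + contact, traceability filters, linking."""

import numpy as np
import pandas as pd
import pytest

from clonebow import PipelineConfig, colors
from clonebow.clones import (
    call_clones,
    call_clones_all,
    filter_traceable,
    link_clones_across_timepoints,
)
from clonebow.pipelines import clone_partition_agreement


def make_cells(rows):
    """Rows: (cell_id, x, y, z, r, g, b, apical)."""
    return pd.DataFrame(
        [{"cell_id": cid, "time_hpf": 32.0, "x_um": x, "y_um": y, "z_um": z,
          "r_mean": r, "g_mean": g, "b_mean": b, "apical_contact": ap,
          "embryo_id": "e1", "boundary_id": "b1"}
         for cid, x, y, z, r, g, b, ap in rows]
    )


RED = (1.0, 0.02, 0.02)
GREEN = (0.02, 1.0, 0.02)


class TestCallClones:
    def test_contact_chain_same_color_is_one_clone(self):
        cells = make_cells([
            ("a", 0, 0, 0, *RED, True),
            ("b", 0, 8, 0, *RED, True),
            ("c", 0, 16, 0, *RED, True),
        ])
        members, clones = call_clones(cells)
        assert len(clones) == 1
        assert clones["n_cells"].iloc[0] == 3

    def test_distant_same_color_cells_are_separate_clones(self):
        cells = make_cells([
            ("a", 0, 0, 0, *RED, True),
            ("b", 0, 50, 0, *RED, True),
        ])
        _, clones = call_clones(cells)
        assert len(clones) == 2

    def test_adjacent_different_color_cells_are_separate_clones(self):
        cells = make_cells([
            ("a", 0, 0, 0, *RED, True),
            ("b", 0, 5, 0, *GREEN, True),
        ])
        _, clones = call_clones(cells)
        assert len(clones) == 2

    def test_numbering_follows_mediolateral_order(self):
        cells = make_cells([
            ("a", 0, 200, 0, *RED, True),
            ("b", 0, 50, 0, *GREEN, True),
        ])
        _, clones = call_clones(cells)
        ordered = clones.sort_values("ml_um")
        assert list(ordered["clone_id"]) == ["b1-1", "b1-2"]

    def test_partition_covers_each_classifiable_cell_once(self, cohort):
        cells = cohort["cells"]
        t0 = cells[cells["time_hpf"] == 32.0]
        members, _ = call_clones_all(t0)
        total = members["r_mean"] + members["g_mean"] + members["b_mean"]
        classifiable = members[total >= PipelineConfig().min_total_intensity]
        assert classifiable["clone_id"].notna().all()

    def test_row_order_does_not_change_partition(self, cohort, rng):
        cells = cohort["cells"]
        t0 = cells[(cells["time_hpf"] == 32.0)
                   & (cells["boundary_id"] == "e1_b1")]
        m1, _ = call_clones(t0)
        shuffled = t0.sample(frac=1.0, random_state=4)
        m2, _ = call_clones(shuffled)
        p1 = dict(zip(m1["cell_id"], m1["clone_id"]))
        p2 = dict(zip(m2["cell_id"], m2["clone_id"]))
        assert p1 == p2

    def test_shrinking_contact_distance_never_merges_clones(self, cohort):
        cells = cohort["cells"]
        t0 = cells[(cells["time_hpf"] == 32.0)
                   & (cells["boundary_id"] == "e1_b1")]
        m_small, _ = call_clones(t0, d_contact=6.0)
        m_large, _ = call_clones(t0, d_contact=12.0)
        small = dict(zip(m_small["cell_id"], m_small["clone_id"]))
        large = dict(zip(m_large["cell_id"], m_large["clone_id"]))
        # refinement: cells together at d=6 must be together at d=12
        for a in small:
            for b in small:
                if small[a] is not None and small[a] == small[b]:
                    assert large[a] == large[b]

    def test_zero_noise_partition_matches_ground_truth_exactly(
        self, cohort_zero_noise
    ):
        cells = cohort_zero_noise["cells"]
        t0 = cells[cells["time_hpf"] == 32.0]
        members, _ = call_clones_all(t0)
        ari = clone_partition_agreement(members, cohort_zero_noise["gt"].cells)
        assert ari == pytest.approx(1.0)

    def test_mixed_boundaries_rejected(self, cohort):
        cells = cohort["cells"]
        t0 = cells[cells["time_hpf"] == 32.0]
        with pytest.raises(ValueError):
            call_clones(t0)  # more than one boundary in one call


class TestFilterTraceable:
    def _clone_frame(self, sizes, regions, ml, dv=None):
        n = len(sizes)
        dv = dv or [20.0] * n
        clones = pd.DataFrame({
            "clone_id": [f"b1-{i+1}" for i in range(n)],
            "boundary_id": "b1",
            "region_index": regions,
            "n_cells": sizes,
            "ml_um": ml,
            "dv_um": dv,
        })
        rows = []
        for i in range(n):
            for j in range(sizes[i]):
                rows.append({"cell_id": f"c{i}_{j}", "clone_id": f"b1-{i+1}",
                             "z_um": dv[i], "apical_contact": True})
        return clones, pd.DataFrame(rows)

    def test_rare_small_vz_clone_kept_and_oversized_dropped(self):
        clones, members = self._clone_frame([2, 4], [3, 7], [50.0, 200.0])
        freq = {3: colors.RARE, 7: colors.RARE}
        kept = filter_traceable(clones, members, freq)
        assert list(kept["clone_id"]) == ["b1-1"]

    def test_nonisolated_frequent_clones_dropped(self):
        clones, members = self._clone_frame(
            [2, 2, 2], [5, 5, 9], [100.0, 110.0, 300.0]
        )
        freq = {5: colors.FREQUENT, 9: colors.RARE}
        kept = filter_traceable(clones, members, freq)
        # the two frequent-color clones are 10 um apart (< 2 * d_contact)
        assert list(kept["clone_id"]) == ["b1-3"]

    def test_isolated_frequent_clone_kept(self):
        clones, members = self._clone_frame([2, 2], [5, 5], [100.0, 400.0])
        freq = {5: colors.FREQUENT}
        kept = filter_traceable(clones, members, freq)
        assert len(kept) == 2

    def test_mantle_zone_clone_dropped_when_domain_required(self):
        clones, members = self._clone_frame([2], [3], [50.0], dv=[55.0])
        members["apical_contact"] = False
        kept = filter_traceable(clones, members, {3: colors.RARE})
        assert kept.empty


class TestLinking:
    def _clones(self, specs, boundary="b1"):
        return pd.DataFrame(
            [{"clone_id": cid, "boundary_id": boundary, "region_index": reg,
              "n_cells": 2, "ml_um": ml, "dv_um": dv}
             for cid, reg, ml, dv in specs]
        )

    def test_unique_colors_link_bijectively(self):
        t1 = self._clones([("b1-1", 3, 100, 20), ("b1-2", 8, 200, 20)])
        t2 = self._clones([("b1-1", 8, 205, 22), ("b1-2", 3, 104, 21)])
        links = link_clones_across_timepoints(t1, t2)
        got = dict(zip(links["clone_id_t1"], links["clone_id_t2"]))
        assert got == {"b1-1": "b1-2", "b1-2": "b1-1"}

    def test_dropout_reported_unmatched(self):
        t1 = self._clones([("b1-1", 3, 100, 20), ("b1-2", 8, 200, 20)])
        t2 = self._clones([("b1-1", 3, 100, 20)])
        links = link_clones_across_timepoints(t1, t2)
        row = links[links["clone_id_t1"] == "b1-2"].iloc[0]
        assert row["clone_id_t2"] is None

    def test_equidistant_candidates_flagged_not_assigned(self):
        t1 = self._clones([("b1-1", 3, 100, 20)])
        t2 = self._clones([("b1-1", 3, 90, 20), ("b1-2", 3, 110, 20)])
        links = link_clones_across_timepoints(t1, t2)
        assert links["ambiguous"].iloc[0]
        assert links["clone_id_t2"].iloc[0] is None

    def test_synthetic_two_timepoint_links_agree_with_ground_truth(
        self, cohort
    ):
        """Clones called independently at 32 and 45 hpf link to the same
        ground-truth clone in >= 95% of cases at default noise."""
        cells, gt = cohort["cells"], cohort["gt"]
        truth = dict(zip(gt.cells["cell_id"], gt.cells["clone_id"]))
        agree = total = 0
        for boundary, sub in cells.groupby("boundary_id"):
            m1, c1 = call_clones(sub[sub["time_hpf"] == 32.0])
            m2, c2 = call_clones(sub[sub["time_hpf"] == 45.0])
            links = link_clones_across_timepoints(c1, c2)
            links = links.dropna(subset=["clone_id_t2"])

            def majority(members, clone_id):
                ids = members.loc[members["clone_id"] == clone_id, "cell_id"]
                lab = [truth[c] for c in ids if c in truth]
                return max(set(lab), key=lab.count) if lab else None

            for _, row in links.iterrows():
                total += 1
                if majority(m1, row["clone_id_t1"]) == majority(
                    m2, row["clone_id_t2"]
                ):
                    agree += 1
        assert total > 50
        assert agree / total >= 0.95
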