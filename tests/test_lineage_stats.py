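"""Fate calls, division-mode classification, endpoint inference, sisters,
growth and the mode time-course."""

import numpy as np
import pandas as pd
import pytest

from clonebow import PipelineConfig, SimulationConfig, simulate_cohort
from clonebow.lineage import NEURON, NN, PN, PP, PROGENITOR, UNASSIGNED, LineageTree
from clonebow.lineage_stats import (
    assign_fate,
    classify_division,
    classify_divisions,
    clone_growth,
    division_mode_shares,
    growth_summary,
    infer_division_modes_endpoint,
    mode_timecourse,
    proliferative_capacity,
    sister_analysis,
    sister_delays_from_trees,
)

CFG = PipelineConfig()  # VZ/MZ line at 30 um


class TestAssignFate:
    @pytest.mark.parametrize(
        "dv, apical, fate, basis",
        [
            (20.0, True, PROGENITOR, "both"),
            (45.0, False, NEURON, "both"),
            (20.0, False, UNASSIGNED, "both"),   # conflicting evidence
            (45.0, True, UNASSIGNED, "both"),
            (20.0, None, PROGENITOR, "position"),
            (45.0, None, NEURON, "position"),
            (30.0, None, UNASSIGNED, "position"),  # exactly on the line
        ],
    )
    def test_fate_rules(self, dv, apical, fate, basis):
        call = assign_fate(dv, apical, CFG)
        assert call.fate == fate
        assert call.basis == basis


def _rec(x, y, z, apical=True):
    return pd.Series({"x_um": x, "y_um": y, "z_um": z,
                      "apical_contact": apical})


class TestClassifyDivision:
    def test_contacting_same_level_progenitors_are_pp(self):
        mode = classify_division(
            34.0, _rec(0, 0, 24), _rec(0, 5, 24), True, True,
            PROGENITOR, PROGENITOR, CFG,
        )
        assert mode == PP

    def test_separated_daughters_across_the_line_are_pn(self):
        mode = classify_division(
            34.0, _rec(0, 0, 24), _rec(0, 25, 44, apical=False), True, True,
            PROGENITOR, NEURON, CFG,
        )
        assert mode == PN

    def test_briefly_tracked_daughter_leaves_mode_unassigned(self):
        mode = classify_division(
            34.0, _rec(0, 0, 24), _rec(0, 5, 24), True, False,
            PROGENITOR, PROGENITOR, CFG,
        )
        assert mode == UNASSIGNED

    def test_contact_with_opposite_fates_is_contradictory(self):
        mode = classify_division(
            34.0, _rec(0, 0, 29), _rec(0, 5, 31, apical=False), True, True,
            PROGENITOR, NEURON, CFG,
        )
        assert mode == UNASSIGNED

    def test_raising_exclusion_window_never_adds_assigned_modes(
        self, cohort
    ):
        counts = []
        for hours in (0.0, 3.0, 6.0):
            cfg = PipelineConfig(fate_exclusion_h=hours)
            from clonebow.io import trees_from_track_table

            trees = trees_from_track_table(cohort["tracks"])
            div = classify_divisions(trees, cohort["cells"], cfg,
                                     window=(32.0, 45.0))
            counts.append((div["mode"] != UNASSIGNED).sum())
        assert counts[0] >= counts[1] >= counts[2]


class TestModeShares:
    def test_shares_from_counts(self):
        shares = division_mode_shares({PP: 19, PN: 28, NN: 1})
        assert round(shares[PP]) == 40
        assert round(shares[PN]) == 58
        assert round(shares[NN]) == 2

    def test_empty_counts_rejected(self):
        with pytest.raises(ValueError):
            division_mode_shares({})


def _endpoint_frame(p_positions, n_positions):
    rows = []
    for i, (y, z) in enumerate(p_positions):
        rows.append({"cell_id": f"p{i}", "x_um": 0.0, "y_um": y, "z_um": z,
                     "apical_contact": True})
    for i, (y, z) in enumerate(n_positions):
        rows.append({"cell_id": f"n{i}", "x_um": 0.0, "y_um": y, "z_um": z,
                     "apical_contact": False})
    return pd.DataFrame(rows)


class TestEndpointInference:
    def test_pure_progenitor_clone_counts_pp(self):
        cells = _endpoint_frame([(0, 24), (8, 24), (16, 24)], [])
        out = infer_division_modes_endpoint(cells, CFG)
        assert (out[PP], out[PN], out[NN]) == (3, 0, 0)
        assert out["pct_PP"] == 100.0

    def test_contacting_even_neuron_pair_counts_nn(self):
        cells = _endpoint_frame([], [(0, 44), (8, 44)])
        out = infer_division_modes_endpoint(cells, CFG)
        assert (out[PP], out[PN], out[NN]) == (0, 0, 1)
        assert out["pct_NN"] == 100.0

    def test_odd_neuron_count_blocks_nn_under_literal_rule(self):
        cells = _endpoint_frame([(0, 24), (8, 24)], [(40, 44)])
        out = infer_division_modes_endpoint(cells, CFG)
        assert (out[PP], out[PN], out[NN]) == (2, 1, 0)

    def test_distant_neuron_pair_is_two_pn(self):
        cells = _endpoint_frame([], [(0, 44), (40, 44)])
        out = infer_division_modes_endpoint(cells, CFG)
        assert (out[PP], out[PN], out[NN]) == (0, 2, 0)

    def test_all_even_rule_pairs_every_even_clone(self):
        cfg = PipelineConfig(nn_rule="all_even")
        cells = _endpoint_frame([], [(0, 44), (40, 44)])
        out = infer_division_modes_endpoint(cells, cfg)
        assert out[NN] == 1

    def test_unfated_clone_rejected(self):
        cells = _endpoint_frame([], [])
        with pytest.raises(ValueError):
            infer_division_modes_endpoint(cells, CFG)

    def test_matches_track_counts_on_fully_tracked_zero_noise_data(
        self, cohort_zero_noise
    ):
        """Composition-based counts (founder-discount convention, no
        censoring) equal the generator's per-clone division-mode counts."""
        cfg = PipelineConfig(endpoint_convention="founder_discount",
                             fate_exclusion_h=0.0)
        scfg = cohort_zero_noise["config"]
        cells, gt = cohort_zero_noise["cells"], cohort_zero_noise["gt"]
        trees = {t.clone_id: t for t in cohort_zero_noise["trees"]}
        tf_cells = cells[cells["time_hpf"] == scfg.t_end].merge(
            gt.cells[["cell_id", "clone_id"]], on="cell_id"
        )
        for clone_id, sub in tf_cells.groupby("clone_id"):
            founders = len(trees[clone_id].cells_alive_at(scfg.t_start))
            got = infer_division_modes_endpoint(sub, cfg, founders=founders)
            want = (
                gt.divisions[(gt.divisions["clone_id"] == clone_id)
                             & gt.divisions["in_window"]]["mode"]
                .value_counts().to_dict()
            )
            assert all(got[m] == want.get(m, 0) for m in (PP, PN, NN))


class TestProliferativeCapacity:
    def test_no_divisions_means_all_nondividing(self):
        cfg = SimulationConfig(seed=1, n_founders=30,
                               division_prob_per_frame=0.0)
        trees, _ = simulate_cohort(cfg)
        out = proliferative_capacity(trees, (32.0, 45.0))
        assert out["pct_dividing"] == 0.0
        assert out["pct_nondividing"] == 100.0

    def test_dividing_fraction_matches_geometric_survival(self):
        """Single founders with an uncoupled per-frame hazard divide with
        probability 1 - (1-p)^13 over 13 hourly frames (closed form)."""
        p = 0.1
        cfg = SimulationConfig(seed=13, n_founders=600, t0_size_probs={1: 1.0},
                               division_prob_per_frame=p)
        trees, _ = simulate_cohort(cfg)
        out = proliferative_capacity(trees, (32.0, 45.0))
        expected = 1 - (1 - p) ** 13
        se = np.sqrt(expected * (1 - expected) / 600)
        assert abs(out["pct_dividing"] / 100 - expected) < 3 * se

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            proliferative_capacity([], (32.0, 45.0))


def _two_cell_tree(t_div_a, t_div_b, tf=45.0):
    tree = LineageTree(root="")
    tree.add_root("f", 31.0)
    tree.add_division("f", 31.0, ("a", "b"), (PROGENITOR, PROGENITOR), PP)
    for cid, t_div in (("a", t_div_a), ("b", t_div_b)):
        if t_div is None:
            tree.nodes[cid].end = tf
        else:
            tree.add_division(cid, t_div, (f"{cid}1", f"{cid}2"),
                              (PROGENITOR, NEURON), PN)
            for d in (f"{cid}1", f"{cid}2"):
                tree.nodes[d].end = tf
    return tree


class TestSisterAnalysis:
    def test_asynchronous_pair_reports_delay(self):
        out = sister_analysis(_two_cell_tree(34.5, 37.0), 32.0, 45.0)
        assert out["concordance"] == "same"
        assert out["synchrony"] == "asynchronous"
        assert out["delay_h"] == pytest.approx(2.5)

    def test_synchronous_pair(self):
        out = sister_analysis(_two_cell_tree(34.5, 34.5), 32.0, 45.0)
        assert out["synchrony"] == "synchronous"
        assert out["delay_h"] == 0.0

    def test_neither_dividing_is_concordant_without_synchrony(self):
        out = sister_analysis(_two_cell_tree(None, None), 32.0, 45.0)
        assert out["concordance"] == "same"
        assert out["synchrony"] == "NA"

    def test_discordant_pair(self):
        out = sister_analysis(_two_cell_tree(34.0, None), 32.0, 45.0)
        assert out["concordance"] == "different"

    def test_mode_concordance_reported(self):
        out = sister_analysis(
            _two_cell_tree(34.0, 36.0), 32.0, 45.0,
            modes={"a": PN, "b": PP},
        )
        assert out["mode_concordance"] == "different"

    def test_non_two_cell_clone_rejected(self):
        tree = LineageTree(root="")
        tree.add_root("f", 32.0)
        with pytest.raises(ValueError):
            sister_analysis(tree, 32.0, 45.0)

    def test_delays_collects_both_divided_pairs(self):
        tree = _two_cell_tree(34.0, 36.5)
        assert sister_delays_from_trees([tree], (32.0, 45.0)) == [2.5]


class TestCloneGrowth:
    def test_bookkeeping(self):
        doubled = _two_cell_tree(34.0, 36.0)
        static = _two_cell_tree(None, None)
        growth = clone_growth([doubled, static], [32.0, 45.0])
        assert growth["n_at_32"].tolist() == [2, 2]
        assert growth["n_at_45"].tolist() == [4, 2]

    def test_mean_size_equals_branching_identity(self):
        """Conservation: mean clone size at tf equals founders per clone
        plus mean in-window divisions per clone."""
        cfg = SimulationConfig(seed=8, n_founders=300, t0_size_probs={2: 1.0})
        trees, _ = simulate_cohort(cfg)
        growth = clone_growth(trees, [32.0, 45.0])
        summary = growth_summary(growth, [32.0, 45.0])
        divs = np.mean([
            len([d for d in t.divisions if d.time >= 32.0]) for t in trees
        ])
        assert summary.loc[1, "mean_cells"] == pytest.approx(2.0 + divs)


class TestModeTimecourse:
    def _df(self, entries):
        return pd.DataFrame([{"time_hpf": t, "mode": m} for t, m in entries])

    def test_constant_fraction_has_zero_slope_by_convention(self):
        df = self._df([(32.2, PP), (33.2, PP), (34.2, PP)])
        out = mode_timecourse(df)
        assert out["PP"]["slope"] == 0.0
        assert out["PP"]["r2"] == 0.0

    def test_alternating_bins_match_hand_computed_least_squares(self):
        # fractions (1, 0, 1, 0) at bin centers 32.5..35.5:
        # slope = sum((x-xbar)(y-ybar)) / sum((x-xbar)^2) = -1.0 / 5.0
        df = self._df([(32.2, PP), (33.2, PN), (34.2, PP), (35.2, PN)])
        out = mode_timecourse(df)
        assert out["PP"]["slope"] == pytest.approx(-0.2)
        assert out["PN"]["slope"] == pytest.approx(0.2)

    def test_single_bin_flagged(self):
        df = self._df([(32.2, PP), (32.4, PN)])
        out = mode_timecourse(df)
        assert out["sparse"]
        assert out["PP"]["flag"] == "single_bin"

    def test_fractions_per_bin_sum_to_one(self):
        df = self._df([(32.2, PP), (32.4, PN), (33.1, PN), (33.9, PP)])
        out = mode_timecourse(df)
        bins = out["bins"]
        assert ((bins["frac_PP"] + bins["frac_PN"]) == 1.0).all()
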