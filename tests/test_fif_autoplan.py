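import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from autotan.dose_engine import DoseGrid
from autotan.fif_autoplan import (
    AutoplanConfig,
    DegenerateAperture,
    autoplan,
    dmax_percent,
    find_and_partition_hotspot,
    max_segments,
    optimize_segment_weights,
    optimize_weights_core,
    propose_segment,
    threshold_schedule,
)
from autotan.target_volumes import TargetPartition


class TestMaxSegments:
    @pytest.mark.parametrize("dmax,expected", [(115, 4), (105, 0), (112.6, 3), (100, 0), (107.4, 0)])
    def test_worked_values(self, dmax, expected):
        assert max_segments(dmax) == expected

    @settings(deadline=None, derandomize=True)
    @given(st.floats(0.1, 200), st.floats(0, 50))
    def test_nonnegative_and_monotone(self, d, delta):
        assert max_segments(d) >= 0
        assert max_segments(d + delta) >= max_segments(d)


class TestThresholdSchedule:
    @pytest.mark.parametrize(
        "n,expected",
        [(1, [2.5]), (2, [2.5, 1.0]), (4, [2.5, 2.0, 1.5, 1.0])],
    )
    def test_linear_interpolation(self, n, expected):
        assert threshold_schedule(n) == pytest.approx(expected)

    @settings(deadline=None, derandomize=True)
    @given(st.integers(1, 30))
    def test_endpoints_and_monotone(self, n):
        sched = threshold_schedule(n)
        assert sched[0] == 2.5 and sched[-1] == (1.0 if n > 1 else 2.5)
        assert all(a >= b for a, b in zip(sched, sched[1:]))


class TestHotspot:
    def test_uniform_dose_hotspot_is_whole_ptv(self, coarse_pipeline):
        part = coarse_pipeline["partition"]
        ph = coarse_pipeline["phantom"]
        vals = np.where(part.ptv.values.astype(bool), 40.0, 0.0).astype(np.float32)
        dose = DoseGrid(ph.density.like(vals), "normalized")
        tip_hot, base_hot = find_and_partition_hotspot(dose, part, 2.5)
        assert np.array_equal(
            tip_hot.values | base_hot.values, part.ptv.values.astype(bool)
        )

    def test_single_hot_voxel_in_tip(self, coarse_pipeline):
        part = coarse_pipeline["partition"]
        ph = coarse_pipeline["phantom"]
        vals = np.where(part.ptv.values.astype(bool), 40.0, 0.0).astype(np.float32)
        hot_idx = tuple(np.argwhere(part.tip.values)[0])
        vals[hot_idx] = 44.0
        dose = DoseGrid(ph.density.like(vals), "normalized")
        tip_hot, base_hot = find_and_partition_hotspot(dose, part, 2.5)
        assert tip_hot.values.sum() == 1 and tip_hot.values[hot_idx]
        assert not base_hot.values.any()

    def test_matches_per_voxel_scan(self, coarse_pipeline):
        part = coarse_pipeline["partition"]
        dose = coarse_pipeline["open_dose"]
        tip_hot, base_hot = find_and_partition_hotspot(dose, part, 2.5)
        ptv = part.ptv.values.astype(bool)
        dmax = dose.values[ptv].max()
        count = sum(
            1
            for idx in np.argwhere(ptv)
            if dose.values[tuple(idx)] >= 0.975 * dmax
        )
        assert int(tip_hot.values.sum() + base_hot.values.sum()) == count


class TestProposeSegment:
    def test_tip_hotspot_moves_only_anterior_leaves(self, coarse_pipeline):
        ph = coarse_pipeline["phantom"]
        part = coarse_pipeline["partition"]
        dose = coarse_pipeline["open_dose"]
        beam = coarse_pipeline["plan_open"].beams[0]
        tip_hot, _ = find_and_partition_hotspot(dose, part, 2.5)
        assert tip_hot.values.any()
        empty = ph.density.like(np.zeros(ph.density.dims, dtype=bool))
        seg = propose_segment(beam, tip_hot, empty, ph)
        cp1 = beam.open_field.aperture
        touched = 0
        for i in range(cp1.n_rows):
            lo1, hi1 = cp1.leaf_pairs[i]
            lo, hi = seg.leaf_pairs[i]
            if (lo, hi) != (lo1, hi1):
                touched += 1
                if hi > lo:  # partially closed row: posterior bank untouched
                    assert lo == pytest.approx(lo1)
                    assert hi < hi1
        assert touched > 0
        assert cp1.contains_rowwise(seg)

    def test_full_field_hotspot_degenerates(self, coarse_pipeline):
        ph = coarse_pipeline["phantom"]
        beam = coarse_pipeline["plan_open"].beams[0]
        body = ph.masks["body"]  # projects over the entire open area
        with pytest.raises(DegenerateAperture):
            propose_segment(beam, body, body, ph)

    def test_interior_base_island_yields_single_interval_rows(self, coarse_pipeline):
        ph = coarse_pipeline["phantom"]
        part = coarse_pipeline["partition"]
        beam = coarse_pipeline["plan_open"].beams[0]
        # small island strictly inside the base
        island = np.zeros(ph.density.dims, dtype=bool)
        base_idx = np.argwhere(part.base.values)
        center = base_idx[len(base_idx) // 2]
        for d in base_idx:
            if np.all(np.abs(d - center) <= 1):
                island[tuple(d)] = True
        island_grid = ph.density.like(island)
        empty = ph.density.like(np.zeros(ph.density.dims, dtype=bool))
        seg = propose_segment(beam, empty, island_grid, ph)
        cp1 = beam.open_field.aperture
        assert cp1.contains_rowwise(seg)
        for i in range(cp1.n_rows):
            lo1, hi1 = cp1.leaf_pairs[i]
            lo, hi = seg.leaf_pairs[i]
            if (lo, hi) != (lo1, hi1) and hi > lo:
                # posterior extension: the opening is one interval touching
                # the anterior side, the posterior bank advanced
                assert lo > lo1 and hi == pytest.approx(hi1)


class TestOptimizeWeightsCore:
    def test_two_voxel_system_matches_grid_search(self):
        cfg = AutoplanConfig()
        open_cols = np.array([[1.2, 1.0]])  # hot voxel, normal voxel (Gy/fx at w_open=1)
        seg_cols = np.array([[0.0, 1.0]])  # segment blocks the hot voxel
        open_calc = np.array([1.0])
        seg_calc = np.array([1.0])
        rx_total, n_fx, target = 40.0, 20, 2.0
        w, _ = optimize_weights_core(
            open_cols, seg_cols, np.array([0]), open_calc, seg_calc,
            rx_total, n_fx, target, cfg, np.array([0.05]),
        )

        def objective(wv):
            vox = (1 - wv) * open_cols[0] + wv * seg_cols[0]
            calc = (1 - wv) * open_calc[0] + wv * seg_calc[0]
            d = vox * (target / calc) * n_fx
            rel = (d - rx_total) / rx_total
            over = np.clip(d - 1.05 * rx_total, 0, None) / rx_total
            return 50 * np.mean(rel**2) + 50 * np.mean(over**2)

        grid = np.linspace(0, 0.5, 5001)
        best = grid[np.argmin([objective(g) for g in grid])]
        assert w[0] == pytest.approx(best, abs=1e-3)


class TestAutoplan:
    def test_zero_budget_returns_equivalent_plan(self, coarse_pipeline):
        """A plan already at or below the stop level gains no segments."""
        final = coarse_pipeline["plan_final"]
        part = coarse_pipeline["partition"]
        ph = coarse_pipeline["phantom"]
        again, trace = autoplan(final, ph, part, calculator=coarse_pipeline["calc"])
        assert [len(b.control_points) for b in again.beams] == [
            len(b.control_points) for b in final.beams
        ]
        for b0, b1 in zip(final.beams, again.beams):
            assert [cp.weight for cp in b0.control_points] == pytest.approx(
                [cp.weight for cp in b1.control_points]
            )

    def test_first_segment_weight_is_double_the_hotspot(self, coarse_pipeline):
        rec = coarse_pipeline["trace"].records[1]
        assert rec["h_pct"] == 2.5
        assert rec["weight"] == pytest.approx(0.05)

    def test_segment_count_within_budget_and_dmax_reduced(self, coarse_pipeline):
        open_dmax = coarse_pipeline["trace"].records[0]["dmax_pct"]
        n_seg = sum(len(b.control_points) - 1 for b in coarse_pipeline["plan_final"].beams)
        assert n_seg <= max_segments(open_dmax)
        final_dmax = dmax_percent(
            coarse_pipeline["final_dose"],
            coarse_pipeline["partition"].ptv,
            coarse_pipeline["plan_final"].prescription.total_dose,
        )
        assert final_dmax <= open_dmax + 0.1

    def test_weights_sum_to_one_and_lung_block_preserved(self, coarse_pipeline):
        for beam in coarse_pipeline["plan_final"].beams:
            assert beam.weights_sum() == pytest.approx(1.0)
            cp1 = beam.open_field.aperture
            for cp in beam.control_points[1:]:
                assert cp1.contains_rowwise(cp.aperture)

    def test_input_plan_unmutated_and_rerun_identical(self, coarse_pipeline):
        plan = coarse_pipeline["plan_open"]
        ph = coarse_pipeline["phantom"]
        part = coarse_pipeline["partition"]
        before = [cp.weight for b in plan.beams for cp in b.control_points]
        a, _ = autoplan(plan, ph, part, calculator=coarse_pipeline["calc"])
        after = [cp.weight for b in plan.beams for cp in b.control_points]
        assert before == after  # working-copy contract
        b, _ = autoplan(plan, ph, part, calculator=coarse_pipeline["calc"])
        assert [cp.weight for bm in a.beams for cp in bm.control_points] == [
            cp.weight for bm in b.beams for cp in bm.control_points
        ]
        assert [bm.beam_mu for bm in a.beams] == [bm.beam_mu for bm in b.beams]

    def test_retained_segments_meet_min_mu(self, coarse_pipeline):
        cfg = AutoplanConfig()
        for beam in coarse_pipeline["plan_final"].beams:
            for cp in beam.control_points[1:]:
                assert beam.beam_mu * cp.weight >= cfg.min_segment_mu - 1e-6

    def test_optimize_without_segments_is_identity(self, coarse_pipeline):
        plan = coarse_pipeline["plan_open"]
        out = optimize_segment_weights(
            plan,
            coarse_pipeline["phantom"],
            coarse_pipeline["ptv"],
            calculator=coarse_pipeline["calc"],
        )
        assert [len(b.control_points) for b in out.beams] == [
            len(b.control_points) for b in plan.beams
        ]
        assert [cp.weight for b in out.beams for cp in b.control_points] == [
            cp.weight for b in plan.beams for cp in b.control_points
        ]
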