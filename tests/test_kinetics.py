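"""Oncosimulator cell-population kinetics, treatment effects and
redistribution."""

import math

import numpy as np
import pytest

from oncosim import (
    GCState,
    VoxelGrid,
    apply_chemo_hit,
    apply_radio_fraction,
    cytokinetic_step,
    eq7_growth_rate,
    growth_fraction,
    lq_surviving_fraction,
    make_phantom,
    redistribute_cells,
    simulate,
)
from oncosim.cohort import stationary_composition
from oncosim.kinetics import TreatmentEvent, TreatmentSchedule


class TestLQModel:
    @pytest.mark.parametrize(
        "dose,ckr",
        [(5.0, 0.928), (10.0, 0.999), (15.0, 1.000), (20.0, 1.000)],
    )
    def test_cell_kill_rates_at_reference_radiosensitivity(self, dose, ckr):
        """Typical radiosensitivity alpha=0.35/Gy, beta=0.035/Gy^2."""
        assert round(1.0 - lq_surviving_fraction(dose, 0.35, 0.035), 3) == ckr

    def test_zero_dose_and_negative_dose(self):
        assert lq_surviving_fraction(0.0, 0.35, 0.035) == 1.0
        with pytest.raises(ValueError):
            lq_surviving_fraction(-1.0, 0.35, 0.035)

    def test_fractionation_identity(self):
        """Splitting a dose in two spares survivors by exp(2 beta D^2)."""
        a, b, D = 0.35, 0.035, 7.5
        two = lq_surviving_fraction(D, a, b) ** 2
        one = lq_surviving_fraction(2 * D, a, b)
        assert two / one == pytest.approx(math.exp(2 * b * D * D), rel=1e-12)


class TestCytokinetics:
    def test_total_count_conserved_without_losses_or_mitoses(self, params):
        p = params.with_(R_A=0.0, R_ADiff=0.0, R_NDiff=0.0)
        index = p.build_index()
        grid = VoxelGrid(1, 1, 1)
        state = GCState(grid, index, np.zeros((index.n_comp, 1)), capacity=np.inf)
        # cohort in the middle of S phase: no division for several steps
        state.data[index.cycle_slice("STEM").start + 3, 0] = 100.0
        before = state.total_count()
        cytokinetic_step(state, p)
        assert state.total_count() == pytest.approx(before)
        # moved by exactly one age bin
        assert state.data[index.cycle_slice("STEM").start + 4, 0] == pytest.approx(100.0)

    def test_symmetric_stem_growth_doubles_per_cycle(self):
        p_ = dict(T_c=24.0, P_sym=1.0, P_sleep=0.0, R_A=0.0, R_ADiff=0.0,
                  R_NDiff=0.0, N_LIMP=1, dt=2.0)
        from oncosim import VirtualTumorParameters

        p = VirtualTumorParameters(**p_)
        index = p.build_index()
        state = GCState(VoxelGrid(1, 1, 1), index,
                        np.zeros((index.n_comp, 1)), capacity=np.inf)
        state.data[index.cycle_slice("STEM").start, 0] = 1.0
        n_per_cycle = index.n_cycle_bins
        for cycle in range(1, 6):
            for _ in range(n_per_cycle):
                cytokinetic_step(state, p)
            assert state.total_count() == pytest.approx(2.0**cycle, rel=1e-9)

    def test_apoptotic_cohort_cleared_after_TA(self, params):
        p = params.with_(T_A=params.dt)  # single apoptosis bin
        index = p.build_index()
        state = GCState(VoxelGrid(1, 1, 1), index,
                        np.zeros((index.n_comp, 1)), capacity=np.inf)
        state.data[index.apop.start, 0] = 50.0
        cytokinetic_step(state, p)
        assert state.data[index.apop].sum() == 0.0

    def test_dt_larger_than_smallest_phase_rejected(self, params):
        with pytest.raises(ValueError, match="phase"):
            params.with_(dt=5.0).build_index()  # M phase is 2.4 h


class TestChemoHit:
    def test_zero_ckr_is_identity(self, small_phantom, params):
        state = small_phantom[0]
        before = state.data.copy()
        apply_chemo_hit(state, "vincristine", 0.0)
        assert np.array_equal(state.data, before)

    def test_full_ckr_empties_stem_and_limp(self, small_phantom, params):
        state = small_phantom[0]
        index = state.index
        eligible = state.data[index.hierarchy_mask].sum()
        apply_chemo_hit(state, "vincristine", 1.0)
        assert state.data[index.hierarchy_mask].sum() == 0.0
        assert state.data[index.hit_chemo_slice("vincristine")].sum() == pytest.approx(
            eligible
        )

    def test_combined_ckr_hits_expected_fraction(self, params):
        """Table-8-style combination CKR 0.568 on 1e6 eligible cells."""
        index = params.build_index()
        state = GCState(VoxelGrid(1, 1, 1), index,
                        np.zeros((index.n_comp, 1)), capacity=np.inf)
        state.data[index.cycle_slice("STEM").start, 0] = 1.0e6
        apply_chemo_hit(state, "actinomycin", 0.568)
        assert state.data[index.hit_chemo_slice("actinomycin")].sum() == pytest.approx(
            5.68e5
        )

    def test_unknown_drug_rejected(self, small_phantom):
        with pytest.raises(KeyError):
            apply_chemo_hit(small_phantom[0], "cisplatin", 0.5)


class TestRadioFraction:
    def test_zero_dose_is_identity(self, small_phantom, params):
        state = small_phantom[0]
        before = state.data.copy()
        apply_radio_fraction(state, 0.0, params)
        assert np.allclose(state.data, before)

    def test_kill_fraction_matches_lq(self, small_phantom, params):
        state = small_phantom[0]
        index = state.index
        eligible = state.data[index.hierarchy_mask].sum()
        apply_radio_fraction(state, 15.0, params)
        killed = state.data[index.hit_radio].sum()
        expected = 1.0 - lq_surviving_fraction(15.0, params.alpha, params.beta)
        assert killed / eligible == pytest.approx(expected, rel=1e-12)
        # direct LQ evaluation: 1 - exp(-(0.35*15 + 0.035*225)) = 1 - exp(-13.125)
        assert expected == pytest.approx(1.0 - math.exp(-13.125), rel=1e-12)

    def test_phase_multipliers_scale_the_exponent(self, small_phantom, params):
        state = small_phantom[0]
        index = state.index
        p = params.with_(phase_radiosensitivity={"G1": 0.0, "S": 0.0, "G2": 0.0,
                                                 "M": 0.0, "G0": 1.0})
        g0_before = state.data[index.g0_mask].sum()
        cyc_before = state.data[index.cycling_mask].sum()
        apply_radio_fraction(state, 10.0, p)
        assert state.data[index.cycling_mask].sum() == pytest.approx(cyc_before)
        kill = 1.0 - lq_surviving_fraction(10.0, p.alpha, p.beta)
        assert state.data[index.g0_mask].sum() == pytest.approx(
            g0_before * (1 - kill)
        )


class TestRedistribution:
    def test_identity_when_within_capacity(self, small_phantom):
        state = small_phantom[0]
        before = state.data.copy()
        redistribute_cells(state)
        assert np.array_equal(state.data, before)

    def test_overloaded_voxel_exports_along_direction(self, params):
        index = params.build_index()
        grid = VoxelGrid(3, 3, 3)
        state = GCState.empty(grid, index)
        g1 = index.cycle_slice("STEM").start
        center = 13  # (1,1,1)
        plus_x = 22  # (2,1,1)
        state.data[g1, center] = 1.4 * state.capacity
        state.data[g1, plus_x] = 0.5 * state.capacity  # tumor neighbor in +x
        direction = np.zeros((grid.n_voxels, 3))
        direction[center] = (1.0, 0.0, 0.0)
        redistribute_cells(state, direction)
        assert state.data[g1, center] == pytest.approx(state.capacity)
        assert state.data[g1, plus_x] == pytest.approx(0.9 * state.capacity)

    def test_total_count_exactly_conserved(self, params):
        rng = np.random.default_rng(7)
        index = params.build_index()
        grid = VoxelGrid(5, 5, 5)
        state = GCState.empty(grid, index)
        state.data[:] = rng.random((index.n_comp, grid.n_voxels)) * state.capacity / 10
        state.data[:, 62] *= 40  # force an overload
        direction = rng.normal(size=(grid.n_voxels, 3))
        before = state.total_count()
        redistribute_cells(state, direction)
        assert state.total_count() == pytest.approx(before, rel=1e-12)
        assert (state.data >= 0).all()


class TestSimulate:
    def test_free_growth_doubling_time_matches_renewal_relation(self, params):
        index = params.build_index()
        comp = stationary_composition(params, index)["composition"]
        grid = VoxelGrid(10, 10, 10)
        state, _ = make_phantom(grid, index, (5, 5, 5), 1.5, comp)
        res = simulate(state, params, horizon_h=300, seed=0)
        sel = res.time_h >= 100
        rate = np.polyfit(res.time_h[sel], np.log(res.series["living"][sel]), 1)[0]
        assert rate == pytest.approx(eq7_growth_rate(params), rel=0.05)

    def test_lethal_chemo_eradicates_living_cells(self, params):
        index = params.build_index()
        grid = VoxelGrid(3, 3, 3)
        state, _ = make_phantom(grid, index, (1.5, 1.5, 1.5), 1.0, {"G1": 1.0})
        schedule = TreatmentSchedule(
            [TreatmentEvent(0.0, "chemo", drug="vincristine", ckr=1.0)]
        )
        res = simulate(state, params, schedule, horizon_h=400, seed=0)
        assert res.series["living"][-1] == pytest.approx(0.0, abs=1e-6)
        assert res.series["total"][-1] == pytest.approx(0.0, abs=1e-6)

    def test_identical_inputs_give_bit_identical_results(self, params):
        index = params.build_index()
        grid = VoxelGrid(5, 5, 5)

        def run():
            state, _ = make_phantom(grid, index, (2.5, 2.5, 2.5), 1.8, {"G1": 1.0})
            sched = TreatmentSchedule([TreatmentEvent(48.0, "radio", dose_gy=5.0)])
            return simulate(state, params, sched, horizon_h=120, seed=42)

        a, b = run(), run()
        assert np.array_equal(a.final_state.data, b.final_state.data)
        for key in a.series:
            assert np.array_equal(a.series[key], b.series[key])

    def test_horizon_before_last_event_rejected(self, params, small_phantom):
        sched = TreatmentSchedule([TreatmentEvent(100.0, "radio", dose_gy=2.0)])
        with pytest.raises(ValueError, match="horizon"):
            simulate(small_phantom[0], params, sched, horizon_h=50)


class TestGrowthFraction:
    def test_pure_cycling_and_even_split(self, params):
        index = params.build_index()
        state = GCState(VoxelGrid(1, 1, 1), index,
                        np.zeros((index.n_comp, 1)), capacity=np.inf)
        state.data[index.cycle_slice("STEM").start, 0] = 10.0
        assert growth_fraction(state) == 1.0
        state.data[index.g0_index("STEM"), 0] = 10.0
        assert growth_fraction(state) == 0.5

    def test_empty_state_rejected(self, params):
        state = GCState.empty(VoxelGrid(2, 2, 2), params.build_index())
        with pytest.raises(ValueError):
            growth_fraction(state)
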