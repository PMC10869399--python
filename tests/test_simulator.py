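"""The VCBM: initialisation, behavioural rules, mechanics, volume, simulation."""

import numpy as np
import pytest

import vcbm
from vcbm import (
    HEALTHY,
    MATURE,
    TUMOUR,
    BiphasicParams,
    MechanicsConfig,
    PhaseParams,
    SimulationError,
    VolumeCalibration,
)
from vcbm.simulator import _complete_adjacency

from conftest import pair_state


def growth_params(**kw):
    defaults = dict(p0=0.5, p_psc=0.0, d_max=50.0, g_age=30.0)
    defaults.update(kw)
    return PhaseParams(**defaults)


class TestInitTissue:
    def test_3x3_has_nine_cells_one_tumour(self, mech):
        state = vcbm.init_tissue(3, 3, mech)
        assert state.n_cells == 9
        assert state.n_tumour == 1

    def test_interior_cells_have_six_neighbours_at_spacing_s(self, mech):
        state = vcbm.init_tissue(8, 8, mech)
        interior = [
            i
            for i in range(state.n_cells)
            if len(state.adjacency.neighbors(i)) == 6
        ]
        assert len(interior) > 0
        for i in interior[:5]:
            for j in state.adjacency.neighbors(i):
                gap = np.linalg.norm(state.positions[i] - state.positions[j])
                assert gap == pytest.approx(mech.s, rel=1e-9)

    def test_spatial_extent_of_20x20_lattice(self, mech):
        state = vcbm.init_tissue(20, 20, mech)
        ext = state.positions.max(axis=0) - state.positions.min(axis=0)
        assert ext[0] == pytest.approx(19 * mech.s, rel=0.05)
        assert ext[1] == pytest.approx(19 * mech.s * np.sqrt(3) / 2, rel=0.05)

    def test_too_small_grid_raises(self, mech):
        with pytest.raises(SimulationError, match="3x3"):
            vcbm.init_tissue(2, 5, mech)


class TestProliferationProbability:
    @pytest.mark.parametrize(
        "d, p0, d_max, expected",
        [
            (0.0, 0.7, 10.0, 0.7),  # at the boundary the full constant applies
            (10.0, 0.7, 10.0, 0.0),  # at or beyond d_max no proliferation
            (15.0, 0.7, 10.0, 0.0),
            (5.0, 0.5, 10.0, 0.25),  # linear in between
        ],
    )
    def test_linear_nutrient_proxy(self, d, p0, d_max, expected):
        params = PhaseParams(p0=p0, p_psc=0.0, d_max=d_max, g_age=48.0)
        assert vcbm.proliferation_probability(d, params) == pytest.approx(expected)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            vcbm.proliferation_probability(-1.0, growth_params())


class TestEdgeRestLength:
    def test_mature_pair_has_full_rest_length(self, mech):
        assert vcbm.edge_rest_length(MATURE, 200.0, mech) == mech.s

    def test_one_hour_after_division(self):
        mech = MechanicsConfig(s=1.0, t_age=24.0)
        assert vcbm.edge_rest_length(1.0, 1.0, mech) == pytest.approx(1.0 / 24.0)

    def test_midway_through_maturation(self):
        mech = MechanicsConfig(s=2.0, t_age=24.0)
        assert vcbm.edge_rest_length(12.0, 12.0, mech) == pytest.approx(1.0)

    def test_youngest_endpoint_governs(self, mech):
        assert vcbm.edge_rest_length(6.0, MATURE, mech) == pytest.approx(
            mech.s * 6.0 / mech.t_age
        )


class TestMovement:
    def test_pair_at_rest_length_does_not_move(self, mech):
        state = pair_state(mech.s, mech)
        before = state.positions.copy()
        vcbm.movement_step(state, mech)
        np.testing.assert_allclose(state.positions, before, atol=1e-15)

    def test_stretched_pair_relaxes_by_hand_computed_amount(self):
        mech = MechanicsConfig(s=1.0, lam=0.25)
        state = pair_state(2.0, mech)
        vcbm.movement_step(state, mech)
        gap = state.positions[1, 0] - state.positions[0, 0]
        assert gap == pytest.approx(1.5, abs=1e-12)

    @pytest.mark.parametrize("lam", [0.1, 0.25, 0.4])
    @pytest.mark.parametrize("gap0", [0.3, 1.7, 3.0])
    def test_geometric_relaxation_closed_form(self, lam, gap0):
        mech = MechanicsConfig(s=1.0, lam=lam)
        state = pair_state(gap0, mech)
        gap = gap0
        for _ in range(12):
            vcbm.movement_step(state, mech)
            new_gap = abs(state.positions[1, 0] - state.positions[0, 0])
            assert new_gap - mech.s == pytest.approx(
                (1 - 2 * lam) * (gap - mech.s), abs=1e-12
            )
            gap = new_gap

    def test_pair_midpoint_is_stationary(self, mech):
        state = pair_state(2.5, mech)
        mid0 = state.positions.mean(axis=0)
        for _ in range(5):
            vcbm.movement_step(state, mech)
        np.testing.assert_allclose(state.positions.mean(axis=0), mid0, atol=1e-14)

    def test_coincident_points_are_split_not_divided_by_zero(self, mech):
        state = pair_state(0.0, mech)
        vcbm.movement_step(state, mech)
        assert np.all(np.isfinite(state.positions))
        assert np.linalg.norm(state.positions[1] - state.positions[0]) > 0


class TestDivision:
    def test_p0_zero_changes_nothing(self, mech, rng):
        state = vcbm.init_tissue(5, 5, mech)
        n0 = state.n_cells
        vcbm.division_step(state, growth_params(p0=0.0), mech, rng)
        assert state.n_cells == n0

    def test_forced_division_adds_one_cell_with_equidistant_daughters(
        self, mech, rng
    ):
        state = vcbm.init_tissue(5, 5, mech)
        parent = int(np.flatnonzero(state.kinds == TUMOUR)[0])
        old_pos = state.positions[parent].copy()
        n0 = state.n_cells
        vcbm.division_step(state, growth_params(p0=1.0), mech, rng)
        assert state.n_cells == n0 + 1
        d1 = np.linalg.norm(state.positions[parent] - old_pos)
        d2 = np.linalg.norm(state.positions[n0] - old_pos)
        assert d1 == pytest.approx(d2, rel=1e-12)
        assert d1 == pytest.approx(mech.s / (2 * mech.t_age), rel=1e-12)
        assert state.t_d[parent] == 0.0 and state.t_d[n0] == 0.0

    def test_age_gate_blocks_young_cells(self, mech, rng):
        state = vcbm.init_tissue(5, 5, mech)
        state.t_d[state.kinds == TUMOUR] = 10.0  # younger than g_age
        n0 = state.n_cells
        vcbm.division_step(state, growth_params(p0=1.0, g_age=48.0), mech, rng)
        assert state.n_cells == n0

    def test_cells_beyond_d_max_cannot_divide(self, mech, rng):
        state = vcbm.init_tissue(9, 9, mech)
        centre = int(np.flatnonzero(state.kinds == TUMOUR)[0])
        # solid tumour; only the interior centre cell is old enough to divide
        state.kinds[:] = TUMOUR
        state.t_d[:] = 0.0
        state.t_d[centre] = MATURE
        n0 = state.n_cells
        params = growth_params(p0=1.0, d_max=1e-6)  # centre is too far inside
        vcbm.division_step(state, params, mech, rng)
        assert state.n_cells == n0


class TestInvasion:
    def test_p_psc_zero_keeps_healthy_count(self, mech, rng):
        state = vcbm.init_tissue(5, 5, mech)
        h0 = state.n_healthy
        vcbm.invasion_step(state, growth_params(p_psc=0.0), rng)
        assert state.n_healthy == h0

    def test_forced_invasion_converts_exactly_one_neighbour(self, mech, rng):
        state = vcbm.init_tissue(5, 5, mech)
        h0 = state.n_healthy
        vcbm.invasion_step(state, growth_params(p_psc=1.0), rng)
        assert state.n_healthy == h0 - 1
        assert state.n_cells == 25  # conversion, not insertion

    def test_divided_cells_skip_invasion(self, mech, rng):
        state = vcbm.init_tissue(5, 5, mech)
        h0 = state.n_healthy
        vcbm.division_step(state, growth_params(p0=1.0), mech, rng)
        vcbm.invasion_step(state, growth_params(p_psc=1.0), rng)
        # the only boundary cells are the two fresh daughters, which both skip
        assert state.n_healthy == h0

    def test_interior_cell_without_healthy_neighbours_converts_nothing(
        self, mech, rng
    ):
        state = vcbm.init_tissue(5, 5, mech)
        state.kinds[:] = TUMOUR  # no healthy cells at all
        h0 = state.n_healthy
        vcbm.invasion_step(state, growth_params(p_psc=1.0), rng)
        assert state.n_healthy == h0 == 0


class TestMeasureVolume:
    def test_single_cell_reads_half_diameter_cubed(self, mech, calib):
        state = vcbm.init_tissue(5, 5, mech)
        assert vcbm.measure_volume(state, calib) == pytest.approx(
            calib.cell_diameter**3 / 2
        )

    def test_two_cells_three_mm_apart(self, mech, calib):
        state = pair_state(3.0, mech)
        # width = 3 + 1, perpendicular length = 0 + 1 -> 4 * 1 / 2
        assert vcbm.measure_volume(state, calib) == pytest.approx(2.0)

    def test_disc_much_larger_than_cell_approaches_d_cubed_over_two(self, calib):
        d = 40.0
        ang = np.linspace(0, 2 * np.pi, 100, endpoint=False)
        pts = (d / 2) * np.column_stack([np.cos(ang), np.sin(ang)])
        state = vcbm.TissueState(
            positions=pts,
            kinds=np.full(len(pts), TUMOUR, dtype=np.int8),
            t_d=np.full(len(pts), MATURE),
            adjacency=_complete_adjacency(0),
        )
        vol = vcbm.measure_volume(state, calib)
        assert vol == pytest.approx(d**3 / 2, rel=4 * calib.cell_diameter / d)

    def test_no_tumour_raises(self, mech, calib):
        state = vcbm.init_tissue(3, 3, mech)
        state.kinds[:] = HEALTHY
        with pytest.raises(SimulationError, match="no tumour"):
            vcbm.measure_volume(state, calib)


class TestBurnIn:
    def test_target_already_met_returns_unchanged(self, mech, calib, rng):
        state = vcbm.init_tissue(5, 5, mech)
        before = state.positions.copy()
        out = vcbm.burn_in(state, growth_params(), mech, calib, 0.1, rng)
        np.testing.assert_array_equal(out.positions, before)

    def test_no_growth_mechanism_raises_at_cap(self, mech, calib, rng):
        state = vcbm.init_tissue(5, 5, mech)
        params = growth_params(p0=0.0, p_psc=0.0)
        with pytest.raises(SimulationError, match="burn-in"):
            vcbm.burn_in(state, params, mech, calib, 50.0, rng, max_steps=30)

    def test_tumour_count_is_monotone_over_burn_in(self, mech, calib, rng):
        state = vcbm.init_tissue(9, 9, mech)
        n0 = state.n_tumour
        out = vcbm.burn_in(state, growth_params(), mech, calib, 10.0, rng)
        assert out.n_tumour >= n0
        assert vcbm.measure_volume(out, calib) >= 10.0


class TestSimulate:
    def test_no_growth_keeps_volume_within_two_percent(self, mech, calib, rng):
        state = vcbm.init_tissue(7, 7, mech)
        params = growth_params(p0=0.0, p_psc=0.0)
        series = vcbm.simulate(params, np.arange(0, 4.0), state, mech, calib, rng)
        assert np.all(np.abs(series.volumes / series.volumes[0] - 1) <= 0.02)

    def test_identical_phases_reproduce_monophasic_for_any_tau(
        self, mech, calib
    ):
        state = vcbm.init_tissue(7, 7, mech)
        theta = growth_params(p0=0.3, g_age=26.0)
        days = np.arange(0, 5.0)
        mono = vcbm.simulate(
            theta, days, state, mech, calib, np.random.default_rng(9)
        )
        for tau in (2, 3, 4):
            bi = BiphasicParams(theta1=theta, theta2=theta, tau=tau)
            series = vcbm.simulate(
                bi, days, state, mech, calib, np.random.default_rng(9)
            )
            np.testing.assert_array_equal(series.volumes, mono.volumes)

    def test_different_second_phase_changes_trajectory_after_switch(
        self, mech, calib
    ):
        state = vcbm.init_tissue(7, 7, mech)
        theta1 = growth_params(p0=0.3, g_age=26.0)
        theta2 = growth_params(p0=0.0, p_psc=0.0, g_age=26.0)
        days = np.arange(0, 5.0)
        bi = BiphasicParams(theta1=theta1, theta2=theta2, tau=2)
        mono = vcbm.simulate(
            theta1, days, state, mech, calib, np.random.default_rng(9)
        )
        series = vcbm.simulate(
            bi, days, state, mech, calib, np.random.default_rng(9)
        )
        np.testing.assert_array_equal(series.volumes[:3], mono.volumes[:3])
        assert not np.array_equal(series.volumes[3:], mono.volumes[3:])

    def test_seed_determinism(self, mech, calib):
        state = vcbm.init_tissue(7, 7, mech)
        days = np.arange(0, 4.0)
        a = vcbm.simulate(
            growth_params(), days, state, mech, calib, np.random.default_rng(3)
        )
        b = vcbm.simulate(
            growth_params(), days, state, mech, calib, np.random.default_rng(3)
        )
        np.testing.assert_array_equal(a.volumes, b.volumes)

    def test_invalid_parameters_rejected_before_stepping(self, mech, calib, rng):
        state = vcbm.init_tissue(5, 5, mech)
        bad = growth_params(g_age=10.0)  # g_age below t_age = 24
        with pytest.raises(ValueError, match="g_age"):
            vcbm.simulate(bad, np.arange(0, 3.0), state, mech, calib, rng)

    def test_runaway_guard_freezes_tail(self, mech, calib, rng):
        state = vcbm.init_tissue(7, 7, mech)
        params = growth_params(p0=1.0, g_age=25.0, p_psc=0.2)
        series = vcbm.simulate(
            params, np.arange(0, 10.0), state, mech, calib, rng,
            max_volume=30.0,
        )
        assert len(series) == 10
        frozen = series.volumes[series.volumes >= 30.0]
        assert len(frozen) >= 2  # cap reached and tail filled
        assert len(np.unique(frozen)) == 1


class TestVolumeCalibrationAndSeries:
    def test_series_validation(self):
        with pytest.raises(ValueError):
            vcbm.TumourSeries(days=[0, 1], volumes=[1.0, -2.0])
        with pytest.raises(ValueError):
            vcbm.TumourSeries(days=[1, 0], volumes=[1.0, 2.0])

    def test_theta_round_trip(self):
        theta = np.array([0.2, 0.1, 30.0, 120.0])
        p = vcbm.theta_to_params(theta, "monophasic")
        assert p == PhaseParams(0.2, 0.1, 30.0, 120.0)
        bi = vcbm.theta_to_params(np.r_[theta, theta, 5.0], "biphasic")
        assert bi.tau == 5 and bi.theta1 == bi.theta2 == p
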